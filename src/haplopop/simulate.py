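"""Synthetic haploid populations with known truth for end-to-end testing.

Genealogies come from msprime's coalescent with recombination (haploid
samples).  Parameters are expressed on the pairwise-coalescent timescale:
``theta`` is the expected per-site pairwise diversity (2·Ne·μ for haploids)
and ``rho`` the scaled recombination rate on the same timescale (the quantity
the sigma-d-squared LD fit estimates), so ``rho/theta`` equals the ratio of
the per-generation recombination and mutation rates.  Defaults echo the
study system this emulates: n = 32 haploid strains, genome-wide diversity
about 0.3%, recombination about 1/100 of the mutation rate, and an optional
5-strain clade that split long ago.

Signals with known truth can be injected after the fact: a partial sweep
(one carrier haplotype copied across an interval) and a divergent segment
(clade-specific derived alleles at a target density).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
from numpy.polynomial import Polynomial

from .io import (
    AnnotationSet,
    Feature,
    GenotypeMatrix,
    MarkerTable,
    ReferenceGenome,
    write_bed,
    write_fasta,
    write_gff3,
    write_markers,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_NE = 10_000.0  # arbitrary internal scale; only theta and rho matter

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class CladeSpec:
    members: tuple[int, ...] = (15, 16, 17, 18, 29)
    split_time: float = 3.0  # units of the pairwise coalescent timescale


@dataclass
class SweepSpec:
    carriers: tuple[int, ...]
    chrom: str
    start: int
    end: int


@dataclass
class DivergentSpec:
    chrom: str
    start: int
    end: int
    divergence: float = 0.05


@dataclass
class SimulationConfig:
    n_samples: int = 32
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    theta: float = 0.003
    rho: float = 0.003 / 100.0
    clade: CladeSpec | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.theta < 0 or self.rho < 0:
            raise ValueError("theta and rho must be non-negative")
        if self.clade is not None:
            bad = [m for m in self.clade.members if not 0 <= m < self.n_samples]
            if bad:
                raise ValueError(f"clade members out of range: {bad}")


@dataclass
class TruthRecord:
    """Ground truth of a simulated data set, consistent with the emitted files."""

    config: SimulationConfig
    realized_pi: dict[str, float] = field(default_factory=dict)
    sweep: SweepSpec | None = None
    divergent: DivergentSpec | None = None
    realized_dxy: float | None = None
    map_coefficients: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)


def _seed_stream(seed: int, k: int) -> list[int]:
    """k msprime-safe seeds (1 .. 2^31-2) derived from one master seed."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 2, size=k)]


def random_reference(chrom_lengths: dict[str, int], seed: int) -> ReferenceGenome:
    """A random A/C/G/T reference with the given chromosome lengths."""
    rng = np.random.default_rng(seed)
    return ReferenceGenome(
        list(chrom_lengths),
        ["".join(rng.choice(_BASES, size=L)) for L in chrom_lengths.values()],
    )


def simulate_population(
    config: SimulationConfig,
    reference: ReferenceGenome | None = None,
) -> tuple[ReferenceGenome, GenotypeMatrix, TruthRecord]:
    """Simulate haploid genotypes under the neutral coalescent with recombination.

    The reference carries the ancestral allele at every variant site (random
    bases elsewhere, or the supplied ``reference`` sequence if given); sample
    calls are allele indices with 0 = ancestral.
    With a clade spec, the clade members descend from a population that split
    ``split_time`` coalescent-time units ago, making them monophyletic and
    divergent.  Deterministic given ``config.seed``.
    """
    n = config.n_samples
    mu = config.theta / (2.0 * _NE)
    r = config.rho / (2.0 * _NE)
    rng = np.random.default_rng(config.seed)
    seeds = _seed_stream(config.seed, 2 * len(config.chrom_lengths))

    names: list[str] = []
    seqs: list[str] = []
    all_chrom: list[str] = []
    all_pos: list[np.ndarray] = []
    all_ref: list[str] = []
    all_alts: list[tuple[str, ...]] = []
    all_calls: list[np.ndarray] = []
    realized_pi: dict[str, float] = {}

    if config.clade is not None:
        members = np.array(config.clade.members, dtype=int)
        others = np.setdiff1d(np.arange(n), members)
        order = np.concatenate([others, members])  # msprime row r holds sample order[r]
        row_of = np.empty(n, dtype=int)
        row_of[order] = np.arange(n)  # row_of[sample] = its msprime row
        dem = msprime.Demography()
        dem.add_population(name="main", initial_size=_NE)
        dem.add_population(name="clade", initial_size=_NE)
        dem.add_population(name="anc", initial_size=_NE)
        dem.add_population_split(
            time=config.clade.split_time * _NE, derived=["main", "clade"], ancestral="anc"
        )
        samples = [
            msprime.SampleSet(n - members.size, population="main", ploidy=1),
            msprime.SampleSet(members.size, population="clade", ploidy=1),
        ]
        anc_kwargs = dict(samples=samples, demography=dem)
    else:
        row_of = np.arange(n)
        anc_kwargs = dict(samples=n, population_size=_NE)

    for ci, (chrom, L) in enumerate(config.chrom_lengths.items()):
        ts = msprime.sim_ancestry(
            sequence_length=L,
            recombination_rate=r,
            ploidy=1,
            random_seed=seeds[2 * ci],
            **anc_kwargs,
        )
        mts = msprime.sim_mutations(ts, rate=mu, random_seed=seeds[2 * ci + 1])
        if reference is not None:
            seq = np.array(list(reference.sequence(chrom)))
        else:
            seq = rng.choice(_BASES, size=L)
        pos_list: list[int] = []
        ref_list: list[str] = []
        alts_list: list[tuple[str, ...]] = []
        calls_list: list[np.ndarray] = []
        for var in mts.variants():
            p = int(var.site.position)
            g = var.genotypes
            observed = np.unique(g)
            anc = var.site.ancestral_state
            anc_idx = var.alleles.index(anc)
            # remap: ancestral -> 0, observed derived alleles -> 1..k
            derived = [a for a in observed if a != anc_idx]
            remap = {anc_idx: 0}
            for k_i, a in enumerate(derived, start=1):
                remap[int(a)] = k_i
            if len(derived) == 0 or (len(observed) == 1 and observed[0] == anc_idx):
                continue  # monomorphic among the samples
            if len(observed) == 1:
                continue  # monomorphic derived; treat as invariant
            ref_base = str(seq[p])
            if ref_base not in "ACGT":
                ref_base = "A"
            other = [b for b in "ACGT" if b != ref_base]
            alt_bases = tuple(rng.choice(other, size=len(derived), replace=False))
            # row_of[sample] = its msprime row, so gather rows in sample order
            remapped = np.array([remap[int(a)] for a in g], dtype=np.int16)
            calls_final = remapped[row_of]
            pos_list.append(p)
            ref_list.append(ref_base)
            alts_list.append(alt_bases)
            calls_list.append(calls_final)
        names.append(chrom)
        seqs.append("".join(seq))
        S = len(pos_list)
        all_chrom.extend([chrom] * S)
        all_pos.append(np.array(pos_list, dtype=np.int64))
        all_ref.extend(ref_list)
        all_alts.extend(alts_list)
        if S:
            all_calls.append(np.stack(calls_list, axis=1))
        if S:
            c = np.stack(calls_list, axis=1)
            diffs = (n * n - sum((c == a).sum(0) ** 2 for a in range(int(c.max()) + 1))) / 2.0
            realized_pi[chrom] = float(diffs.sum() / (n * (n - 1) / 2.0) / L)
        else:
            realized_pi[chrom] = 0.0

    reference = ReferenceGenome(names, seqs)
    S_total = sum(p.size for p in all_pos)
    calls = (
        np.concatenate(all_calls, axis=1) if S_total else np.zeros((n, 0), dtype=np.int16)
    )
    matrix = GenotypeMatrix(
        samples=[f"s{i:02d}" for i in range(n)],
        chrom=np.array(all_chrom, dtype=object),
        pos=np.concatenate(all_pos) if all_pos else np.array([], dtype=np.int64),
        ref=np.array(all_ref, dtype=object),
        alts=all_alts,
        calls=calls,
        qual=np.full(S_total, 99.0),
        depth=np.full((n, S_total), 50, dtype=np.int32),
        het=np.zeros((n, S_total), dtype=bool),
    )
    truth = TruthRecord(config=config, realized_pi=realized_pi)
    return reference, matrix, truth


def to_analysis_matrix(matrix: GenotypeMatrix, chrom_lengths: dict[str, int]):
    """Wrap a simulated matrix as a fully-callable AnalysisMatrix (no masking)."""
    from .qc import SiteMask, apply_mask_and_complete

    callable_iv = {c: np.array([[0, L]], dtype=np.int64) for c, L in chrom_lengths.items()}
    return apply_mask_and_complete(matrix, SiteMask(), callable_intervals=callable_iv)


# ---------------------------------------------------------------------------
# signal injection


def inject_partial_sweep(
    matrix: GenotypeMatrix,
    carriers,
    chrom: str,
    start: int,
    end: int,
) -> GenotypeMatrix:
    """Copy one carrier's haplotype across all carriers inside [start, end).

    Carriers become identical over the interval (within-carrier π = 0), the
    footprint of a partial sweep shared by that subset.
    """
    carriers = np.asarray(carriers, dtype=int)
    if carriers.size == 0:
        raise ValueError("empty carrier set")
    calls = matrix.calls.copy()
    sel = (matrix.chrom == chrom) & (matrix.pos >= start) & (matrix.pos < end)
    cols = np.flatnonzero(sel)
    calls[np.ix_(carriers, cols)] = calls[carriers[0], cols][None, :]
    return dataclasses.replace(matrix, calls=calls)


def inject_divergent_segment(
    matrix: GenotypeMatrix,
    clade,
    chrom: str,
    start: int,
    end: int,
    divergence: float,
    seed: int,
    reference: ReferenceGenome | None = None,
) -> tuple[GenotypeMatrix, float]:
    """Give the clade a shared derived allele at each segment site w.p. ``divergence``.

    Returns the modified matrix and the realized between-group dxy of the
    segment (fixed clade differences / segment length, plus pre-existing
    polymorphism is unaffected outside the chosen sites).
    """
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    clade = np.asarray(clade, dtype=int)
    n = matrix.n_samples
    if clade.size == 0 or clade.size >= n:
        raise ValueError("clade must be a proper non-empty subset of samples")
    rng = np.random.default_rng(seed)
    hit = start + np.flatnonzero(rng.random(end - start) < divergence)

    chrom_sel = matrix.chrom == chrom
    pos_here = matrix.pos[chrom_sel]
    existing_cols = {int(p): c for p, c in zip(pos_here, np.flatnonzero(chrom_sel))}

    calls = matrix.calls.copy()
    alts = [tuple(a) for a in matrix.alts]
    new_sites = []
    for p in hit:
        p = int(p)
        if p in existing_cols:
            c = existing_cols[p]
            new_allele = len(alts[c]) + 1
            calls[clade, c] = new_allele
            # extend alt list with a base different from ref
            ref_base = str(matrix.ref[c])
            used = set(alts[c]) | {ref_base}
            alt_base = next(b for b in "ACGT" if b not in used) if len(used) < 4 else "N"
            alts[c] = alts[c] + (alt_base,)
        else:
            ref_base = reference.sequence(chrom)[p] if reference is not None else "A"
            alt_base = next(b for b in "ACGT" if b != ref_base)
            row = np.zeros(n, dtype=np.int16)
            row[clade] = 1
            new_sites.append((p, ref_base, (alt_base,), row))

    if new_sites:
        new_sites.sort()
        ins_pos = np.array([s[0] for s in new_sites], dtype=np.int64)
        ins_calls = np.stack([s[3] for s in new_sites], axis=1)
        # merge into the chromosome, keeping global ordering by chromosome block
        order_keys = []
        chrom_names = list(dict.fromkeys(matrix.chrom.tolist()))
        if chrom not in chrom_names:
            chrom_names.append(chrom)
        chrom_rank = {c: i for i, c in enumerate(chrom_names)}
        all_chrom = np.concatenate([matrix.chrom, np.array([chrom] * len(new_sites), object)])
        all_pos = np.concatenate([matrix.pos, ins_pos])
        order = np.lexsort((all_pos, np.array([chrom_rank[c] for c in all_chrom])))
        all_ref = np.concatenate([matrix.ref, np.array([s[1] for s in new_sites], object)])
        all_alts = alts + [s[2] for s in new_sites]
        all_calls = np.concatenate([calls, ins_calls], axis=1)
        all_qual = np.concatenate([matrix.qual, np.full(len(new_sites), 99.0)])
        all_depth = np.concatenate(
            [matrix.depth, np.full((n, len(new_sites)), 50, dtype=np.int32)], axis=1
        )
        all_het = np.concatenate(
            [matrix.het, np.zeros((n, len(new_sites)), dtype=bool)], axis=1
        )
        out = GenotypeMatrix(
            samples=matrix.samples,
            chrom=all_chrom[order],
            pos=all_pos[order],
            ref=all_ref[order],
            alts=[all_alts[i] for i in order],
            calls=all_calls[:, order],
            qual=all_qual[order],
            depth=all_depth[:, order],
            het=all_het[:, order],
        )
    else:
        out = dataclasses.replace(matrix, calls=calls, alts=alts)

    # realized segment dxy from the final matrix
    others = np.setdiff1d(np.arange(n), clade)
    sel = (out.chrom == chrom) & (out.pos >= start) & (out.pos < end)
    ca = out.calls[np.ix_(clade, np.flatnonzero(sel))]
    cb = out.calls[np.ix_(others, np.flatnonzero(sel))]
    kmax = int(out.calls.max()) + 1 if out.calls.size else 1
    cross = 0.0
    for a in range(kmax):
        cross += ((ca == a).sum(0) * (cb == a).sum(0)).sum()
    n_cross = clade.size * others.size
    total_pairs_sites = sel.sum() * n_cross
    diff = (sel.sum() * n_cross - cross) / n_cross
    realized = float(diff / (end - start))
    return out, realized


# ---------------------------------------------------------------------------
# annotation + sequence layout


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    sense = [c for c in _all_codons() if c not in STOP_CODONS and c != "ATG"]
    body = "".join(rng.choice(sense) for _ in range(n_codons - 2))
    return "ATG" + body + str(rng.choice(STOP_CODONS))


def _all_codons() -> list[str]:
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


_RC = str.maketrans("ACGTN", "TGCAN")


def generate_annotation(
    reference: ReferenceGenome, seed: int, gene_density: float = 0.5
) -> tuple[AnnotationSet, ReferenceGenome]:
    """Lay out genes, ncRNAs, repeats and landmark features along the genome.

    Returns the annotation and a copy of the reference whose sequence has
    been rewritten inside the generated features so the generator contracts
    hold: CDS translate without internal stops, every intron carries a CTAAC
    branchpoint motif at offset >= 12, repeat tracts satisfy the masking
    rules, and telomeres/centromere intervals exist per chromosome.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    features: list[Feature] = []
    new_seqs: list[str] = []
    gene_no = 0
    for chrom, seq in zip(reference.names, reference.sequences):
        L = len(seq)
        s = list(seq)
        tel = min(2000, L // 20)
        features.append(Feature("telomere", chrom, 0, tel, "+", id=f"{chrom}_telL"))
        features.append(Feature("telomere", chrom, L - tel, L, "+", id=f"{chrom}_telR"))
        cen_half = min(2500, L // 20)
        cen = (L // 2 - cen_half, L // 2 + cen_half)
        features.append(Feature("centromere", chrom, cen[0], cen[1], "+", id=f"{chrom}_cen"))

        cursor = tel + 200
        while cursor < L - tel - 1200:
            cursor += int(rng.integers(150, 600))
            if cursor >= L - tel - 1200:
                break
            u = rng.random()
            if u < gene_density:
                gene_no += 1
                gid = f"gene{gene_no:04d}"
                strand = "+" if rng.random() < 0.5 else "-"
                utr5_len = int(rng.integers(80, 160))
                utr3_len = int(rng.integers(80, 160))
                n_codons = int(rng.integers(120, 280))
                cds = _random_cds(rng, n_codons)
                split = 3 * int(rng.integers(30, n_codons - 30))
                exon1, exon2 = cds[:split], cds[split:]
                intron_len = int(rng.integers(80, 160))
                motif_at = int(rng.integers(12, intron_len - 30))
                intron = list("".join(rng.choice(_BASES, size=intron_len)))
                intron[0:2] = "GT"
                intron[-2:] = "AG"
                intron[motif_at : motif_at + 5] = "CTAAC"
                intron = "".join(intron)
                utr5 = "".join(rng.choice(_BASES, size=utr5_len))
                utr3 = "".join(rng.choice(_BASES, size=utr3_len))
                sense = [
                    ("five_prime_UTR", utr5),
                    ("CDS", exon1),
                    ("intron", intron),
                    ("CDS", exon2),
                    ("three_prime_UTR", utr3),
                ]
                total = sum(len(x[1]) for x in sense)
                if cursor + total >= L - tel or (cursor < cen[1] and cursor + total > cen[0]):
                    cursor = max(cursor, cen[1] + 200)
                    continue
                if strand == "+":
                    parts = sense
                    written = "".join(x[1] for x in sense)
                else:
                    written = "".join(x[1] for x in sense).translate(_RC)[::-1]
                    parts = [(t, x) for t, x in reversed(sense)]
                s[cursor : cursor + total] = written
                features.append(
                    Feature("gene", chrom, cursor, cursor + total, strand, id=gid)
                )
                off = cursor
                for t, piece in parts:
                    features.append(
                        Feature(t, chrom, off, off + len(piece), strand,
                                id=f"{gid}_{t}_{off}", parent=gid)
                    )
                    off += len(piece)
                cursor += total
            elif u < gene_density + 0.15:
                ln = int(rng.integers(120, 400))
                typ = str(rng.choice(["ncRNA", "ncRNA", "tRNA", "rRNA", "snoRNA"]))
                if cursor + ln >= L - tel or (cursor < cen[1] and cursor + ln > cen[0]):
                    cursor = max(cursor, cen[1] + 200)
                    continue
                features.append(Feature(typ, chrom, cursor, cursor + ln, "+", id=f"{typ}{cursor}"))
                cursor += ln
            elif u < gene_density + 0.25:
                ln = int(rng.integers(200, 600))
                typ = str(rng.choice(["pseudogene", "transposable_element"]))
                if cursor + ln >= L - tel or (cursor < cen[1] and cursor + ln > cen[0]):
                    cursor = max(cursor, cen[1] + 200)
                    continue
                features.append(Feature(typ, chrom, cursor, cursor + ln, "+", id=f"{typ}{cursor}"))
                cursor += ln
            else:
                # a low-complexity repeat tract that the masking rules catch
                unit = str(rng.choice(["A", "AT", "CAG"]))
                units = int(rng.integers(7, 15)) if len(unit) > 1 else int(rng.integers(11, 20))
                tract = unit * units
                if cursor + len(tract) >= L - tel or (cursor < cen[1] and cursor + len(tract) > cen[0]):
                    cursor = max(cursor, cen[1] + 200)
                    continue
                s[cursor : cursor + len(tract)] = tract
                features.append(
                    Feature("repeat", chrom, cursor, cursor + len(tract), "+", id=f"rep{cursor}")
                )
                cursor += len(tract)
        new_seqs.append("".join(s))
    return AnnotationSet(features), ReferenceGenome(list(reference.names), new_seqs)


# ---------------------------------------------------------------------------
# genetic map + fixture emission


def truth_genetic_map(
    chrom_lengths: dict[str, int], seed: int, cm_per_bp: float = 3e-4
) -> tuple[dict[str, list[float]], MarkerTable]:
    """A smooth monotone quartic cM map per chromosome plus a noisy marker table."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    coeffs: dict[str, list[float]] = {}
    rows = []
    for chrom, L in chrom_lengths.items():
        total = cm_per_bp * L * float(rng.uniform(0.8, 1.2))
        w = rng.uniform(0.05, 0.3, size=3)
        # cM(x) = total * (u + w1 u^2 + w2 u^3 + w3 u^4)/(1 + w1 + w2 + w3), u = x/L
        norm = 1.0 + w.sum()
        c = [0.0, total / norm, total * w[0] / norm, total * w[1] / norm, total * w[2] / norm]
        coeffs[chrom] = [c[0], c[1] / L, c[2] / L**2, c[3] / L**3, c[4] / L**4]
        n_markers = 12
        bps = np.linspace(0, L, n_markers).astype(np.int64)
        poly = Polynomial(coeffs[chrom])
        cms = poly(bps.astype(float)) + rng.normal(0, 0.05, size=n_markers)
        cms = np.maximum(cms, 0.0)
        for b, cm in zip(bps, cms):
            rows.append((chrom, int(b), float(cm)))
    return coeffs, MarkerTable(pd.DataFrame(rows, columns=["chrom", "bp", "cM"]))


def write_allsites_vcf(
    reference: ReferenceGenome, matrix: GenotypeMatrix, path: str | Path
) -> None:
    """Stream an all-sites VCF: every reference position, variants spliced in."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=haplopop\n")
        for c, l in reference.lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        n = matrix.n_samples
        mono_tail = "\t".join(["0:50"] * n)
        for chrom, seq in zip(reference.names, reference.sequences):
            on = np.flatnonzero(matrix.chrom == chrom)
            var_pos = {int(matrix.pos[c]): c for c in on}
            for p in range(len(seq)):
                if p in var_pos:
                    c = var_pos[p]
                    alt = ",".join(matrix.alts[c]) if matrix.alts[c] else "."
                    gts = "\t".join(
                        f"{int(matrix.calls[i, c])}:{int(matrix.depth[i, c])}" for i in range(n)
                    )
                    fh.write(
                        f"{chrom}\t{p + 1}\t.\t{matrix.ref[c]}\t{alt}\t{matrix.qual[c]:g}\tPASS\t.\tGT:DP\t{gts}\n"
                    )
                else:
                    fh.write(f"{chrom}\t{p + 1}\t.\t{seq[p]}\t.\t99\tPASS\t.\tGT:DP\t{mono_tail}\n")


SCENARIOS = ("neutral", "sweep", "divergent_clade", "full")


def generate_fixture(
    out_dir: str | Path,
    scenario: str,
    seed: int,
    chrom_length: int = 100_000,
    n_samples: int = 32,
    theta: float = 0.003,
    write_all_sites: bool = True,
) -> dict[str, Path]:
    """Write a complete input set (FASTA, VCFs, BED, GFF3, markers, truth JSON).

    Scenarios: ``neutral`` (one chromosome, no signal), ``sweep`` (8-carrier
    partial sweep over the middle 50 kb), ``divergent_clade`` (5-strain clade
    plus a 5%-divergent 1-kb segment), ``full`` (clade genome-wide, sweep on
    chr1, divergent segment on chr3, neutral chr2).  Deterministic per seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rho = theta / 100.0
    clade = CladeSpec() if scenario in ("divergent_clade", "full") else None
    if scenario == "full":
        lengths = {f"chr{i}": chrom_length for i in (1, 2, 3)}
    else:
        lengths = {"chr1": chrom_length}
    config = SimulationConfig(
        n_samples=n_samples, chrom_lengths=lengths, theta=theta, rho=rho, clade=clade, seed=seed
    )
    # annotation layout first, so variant REF alleles match the final sequence
    base_ref = random_reference(lengths, seed=seed + 3)
    annotation, reference = generate_annotation(base_ref, seed=seed + 7)
    _, matrix, truth = simulate_population(config, reference=reference)

    if scenario in ("sweep", "full"):
        carriers = tuple(range(8))
        mid = chrom_length // 2
        half = min(25_000, chrom_length // 4)
        matrix = inject_partial_sweep(matrix, carriers, "chr1", mid - half, mid + half)
        truth.sweep = SweepSpec(carriers=carriers, chrom="chr1", start=mid - half, end=mid + half)
    if scenario in ("divergent_clade", "full"):
        chrom = "chr3" if scenario == "full" else "chr1"
        seg_start = int(0.8 * chrom_length)
        spec = DivergentSpec(chrom=chrom, start=seg_start, end=seg_start + 1000)
        matrix, realized = inject_divergent_segment(
            matrix,
            np.array(clade.members),
            spec.chrom,
            spec.start,
            spec.end,
            spec.divergence,
            seed=seed + 101,
            reference=reference,
        )
        truth.divergent = spec
        truth.realized_dxy = realized

    map_coeffs, markers = truth_genetic_map(lengths, seed=seed + 13)
    truth.map_coefficients = map_coeffs

    paths = {
        "reference": out / "reference.fasta",
        "snps_vcf": out / "snps.vcf",
        "callable_bed": out / "callable.bed",
        "annotation": out / "annotation.gff3",
        "markers": out / "markers.tsv",
        "truth": out / "truth.json",
    }
    write_fasta(reference, paths["reference"])
    write_vcf(matrix, paths["snps_vcf"], contig_lengths=reference.lengths)
    write_bed({c: np.array([[0, L]]) for c, L in lengths.items()}, paths["callable_bed"])
    write_gff3(annotation, paths["annotation"])
    write_markers(markers, paths["markers"])
    paths["truth"].write_text(truth.to_json() + "\n")
    if write_all_sites:
        paths["allsites_vcf"] = out / "allsites.vcf"
        write_allsites_vcf(reference, matrix, paths["allsites_vcf"])
    return paths
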