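"""Functional site classification and Nei–Gojobori synonymous/nonsynonymous counting.

Every retained site gets exactly one class (precedence CDS > UTR > intron >
ncRNA > intergenic); tRNA/rRNA/snoRNA, pseudogenes, repeats and masked
features are excluded rather than counted as intergenic.  CDS sites carry a
fractional synonymous site count per the Nei–Gojobori (NG86) scheme: at each
codon position the synonymous fraction is the share of the three possible
single-base changes that preserve the amino acid, with changes to stop codons
counted as nonsynonymous.  Differences between codons are averaged over all
mutational pathways that avoid stop codons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io import AnnotationSet, ReferenceGenome
from .qc import AnalysisMatrix, intervals_length, positions_in_intervals

BASES = "ACGT"
_CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_TABLE))

# site classes
INTERGENIC, SYNONYMOUS, NONSYNONYMOUS, CDS_MIXED, INTRON, UTR5, UTR3, NCRNA, EXCLUDED = range(9)
CLASS_NAMES = {
    INTERGENIC: "intergenic",
    SYNONYMOUS: "synonymous",
    NONSYNONYMOUS: "nonsynonymous",
    CDS_MIXED: "CDS_mixed",
    INTRON: "intron",
    UTR5: "five_prime_UTR",
    UTR3: "three_prime_UTR",
    NCRNA: "ncRNA",
    EXCLUDED: "excluded",
}

BRANCHPOINT_MOTIF = "CTAAC"
_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def translate(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop codon."""
    if codon in STOP_CODONS:
        return None
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 fractional (synonymous, nonsynonymous) site counts of a sense codon.

    At each position, synonymous fraction = (# of the 3 single-base changes
    preserving the amino acid) / 3; changes to stop codons are nonsynonymous.
    The two counts always sum to exactly 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in STOP_CODONS and _CODON_TABLE[mut] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@dataclass
class CodonDiff:
    syn_diffs: float
    nonsyn_diffs: float
    n_pathways: int
    all_through_stops: bool = False


@lru_cache(maxsize=None)
def codon_pair_differences(codon_a: str, codon_b: str) -> CodonDiff:
    """Pathway-averaged synonymous/nonsynonymous differences between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded and the rest re-weighted.  If every
    pathway hits a stop, the raw nucleotide difference count is split equally
    between the two categories and the result flagged.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c in STOP_CODONS or c not in _CODON_TABLE:
            raise ValueError(f"{c!r} is not a sense codon")
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return CodonDiff(0.0, 0.0, 1)
    syn_tot = nonsyn_tot = 0.0
    n_ok = 0
    for order in permutations(diff_pos):
        cur = a
        syn = nonsyn = 0.0
        ok = True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_ok += 1
    if n_ok == 0:
        d = len(diff_pos)
        return CodonDiff(d / 2.0, d / 2.0, 0, all_through_stops=True)
    return CodonDiff(syn_tot / n_ok, nonsyn_tot / n_ok, n_ok)


# ---------------------------------------------------------------------------
# genome-wide classification


@dataclass
class SiteClassMap:
    """Per-position class codes and CDS synonymous fractions, per chromosome.

    ``gene_codons`` maps gene id -> (chrom, strand, positions) where
    ``positions`` is the (3k,) array of genomic positions of the gene's CDS in
    translation order (minus-strand genes run right to left).
    """

    classes: dict[str, np.ndarray]  # int8 arrays, one per chromosome
    syn_frac: dict[str, np.ndarray]  # float32, NaN outside analysable CDS
    gene_codons: dict[str, tuple[str, str, np.ndarray]] = field(default_factory=dict)

    def class_of(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self.classes[chrom][np.asarray(pos, dtype=np.int64)]

    def counts(self, callable_intervals: dict[str, np.ndarray]) -> dict[str, float]:
        """Callable-site totals per class; synonymous/nonsynonymous are fractional."""
        out = {name: 0.0 for name in CLASS_NAMES.values()}
        for chrom, iv in callable_intervals.items():
            if chrom not in self.classes:
                continue
            cls = self.classes[chrom]
            sf = self.syn_frac[chrom]
            for s, e in np.asarray(iv).reshape(-1, 2):
                seg = cls[s:e]
                for code, name in CLASS_NAMES.items():
                    if code in (SYNONYMOUS, NONSYNONYMOUS):
                        continue
                    out[name] += float(np.count_nonzero(seg == code))
                in_cds = np.isin(seg, (SYNONYMOUS, NONSYNONYMOUS, CDS_MIXED))
                frac = sf[s:e][in_cds]
                out["synonymous"] += float(np.nansum(frac))
                out["nonsynonymous"] += float(np.nansum(1.0 - frac))
        return out


def _element_called_ok(
    chrom: str, start: int, end: int, callable_iv: dict[str, np.ndarray],
    min_called: int = 50, max_missing_frac: float = 1.0 / 3.0,
) -> bool:
    """Element retention rule: enough called sites and not too many missing."""
    from .qc import clip_intervals

    iv = callable_iv.get(chrom)
    called = intervals_length(clip_intervals(iv, start, end)) if iv is not None else 0
    length = end - start
    missing_frac = 1.0 - called / length if length else 1.0
    return called >= min_called and missing_frac < max_missing_frac


def _find_branchpoint(intron_seq: str, min_offset: int = 7) -> int | None:
    """Leftmost CTAAC at/after ``min_offset`` (0-based); exact beats one-mismatch."""
    m = len(BRANCHPOINT_MOTIF)
    exact = intron_seq.find(BRANCHPOINT_MOTIF, min_offset)
    if exact >= 0:
        return exact
    for i in range(min_offset, len(intron_seq) - m + 1):
        window = intron_seq[i : i + m]
        if sum(a != b for a, b in zip(window, BRANCHPOINT_MOTIF)) == 1:
            return i
    return None


def classify_sites(
    annotation: AnnotationSet,
    reference: ReferenceGenome,
    matrix: AnalysisMatrix,
    strict_intergenic_flank: int = 0,
) -> SiteClassMap:
    """Assign every site a functional class and CDS sites their NG86 fractions.

    Intron sites are restricted to positions 8 (1-based, from the 5' splice
    site) up to the base before the branchpoint motif CTAAC (one mismatch
    allowed; introns without a motif are excluded).  Elements with < 50 called
    bp or >= 1/3 missing sites are removed.  ``strict_intergenic_flank`` > 0
    additionally excludes that many bases up/downstream of UTR boundaries from
    the intergenic class.
    """
    lengths = reference.lengths
    classes = {c: np.full(L, INTERGENIC, dtype=np.int8) for c, L in lengths.items()}
    syn_frac = {c: np.full(L, np.nan, dtype=np.float32) for c, L in lengths.items()}
    callable_iv = matrix.callable

    def paint(chrom, start, end, code):
        classes[chrom][max(0, start) : min(lengths[chrom], end)] = code

    # hard exclusions first
    for f in annotation.of_type(
        "pseudogene", "repeat", "transposable_element", "centromere", "telomere",
        "tRNA", "rRNA", "snoRNA", "other",
    ):
        paint(f.chrom, f.start, f.end, EXCLUDED)
    # gene bodies default to excluded; subfeatures overwrite below
    for f in annotation.of_type("gene"):
        paint(f.chrom, f.start, f.end, EXCLUDED)

    # ncRNA, then intron, then UTRs, then CDS — increasing precedence
    for f in annotation.of_type("ncRNA"):
        if _element_called_ok(f.chrom, f.start, f.end, callable_iv):
            paint(f.chrom, f.start, f.end, NCRNA)

    for f in annotation.of_type("intron"):
        if not _element_called_ok(f.chrom, f.start, f.end, callable_iv):
            continue
        seq = reference.sequence(f.chrom)[f.start : f.end]
        if f.strand == "-":
            seq = _revcomp(seq)
        bp = _find_branchpoint(seq)
        if bp is None or bp <= 7:
            continue
        if f.strand == "+":
            paint(f.chrom, f.start + 7, f.start + bp, INTRON)
        else:
            paint(f.chrom, f.end - bp, f.end - 7, INTRON)

    for f in annotation.of_type("five_prime_UTR", "three_prime_UTR"):
        if _element_called_ok(f.chrom, f.start, f.end, callable_iv):
            paint(f.chrom, f.start, f.end, UTR5 if f.type == "five_prime_UTR" else UTR3)

    gene_codons: dict[str, tuple[str, str, np.ndarray]] = {}
    for gene in annotation.of_type("gene"):
        cds_parts = [f for f in annotation.children_of(gene.id) if f.type == "CDS"]
        if not cds_parts:
            continue
        cds_parts.sort(key=lambda f: f.start)
        total_len = sum(f.end - f.start for f in cds_parts)
        if total_len % 3 != 0:
            warnings.warn(f"CDS length of gene {gene.id} not divisible by 3; excluded")
            continue
        called = sum(
            intervals_length(
                np.asarray(
                    [
                        (max(f.start, s), min(f.end, e))
                        for s, e in np.asarray(
                            callable_iv.get(gene.chrom, np.empty((0, 2)))
                        ).reshape(-1, 2)
                        if max(f.start, s) < min(f.end, e)
                    ],
                    dtype=np.int64,
                ).reshape(-1, 2)
            )
            for f in cds_parts
        )
        if called < 50 or 1.0 - called / total_len >= 1.0 / 3.0:
            continue
        positions = np.concatenate([np.arange(f.start, f.end) for f in cds_parts])
        if gene.strand == "-":
            positions = positions[::-1]
        gene_codons[gene.id] = (gene.chrom, gene.strand, positions)

        seq = reference.sequence(gene.chrom)
        chrom_callable = positions_in_intervals(
            positions, callable_iv.get(gene.chrom, np.empty((0, 2)))
        )
        n_codons = total_len // 3
        for k in range(n_codons):
            gpos = positions[3 * k : 3 * k + 3]
            codon = "".join(seq[p] for p in gpos)
            if gene.strand == "-":
                codon = codon.translate(_RC)
            if not chrom_callable[3 * k : 3 * k + 3].all():
                classes[gene.chrom][gpos] = EXCLUDED
                continue
            if any(b not in BASES for b in codon) or codon in STOP_CODONS:
                classes[gene.chrom][gpos] = EXCLUDED
                continue
            aa = _CODON_TABLE[codon]
            for j, p in enumerate(gpos):
                syn = 0.0
                for b in BASES:
                    if b == codon[j]:
                        continue
                    mut = codon[:j] + b + codon[j + 1 :]
                    if mut not in STOP_CODONS and _CODON_TABLE[mut] == aa:
                        syn += 1.0 / 3.0
                syn_frac[gene.chrom][p] = syn
                if syn >= 1.0 - 1e-9:
                    classes[gene.chrom][p] = SYNONYMOUS
                elif syn <= 1e-9:
                    classes[gene.chrom][p] = NONSYNONYMOUS
                else:
                    classes[gene.chrom][p] = CDS_MIXED

    if strict_intergenic_flank > 0:
        for f in annotation.of_type("five_prime_UTR", "three_prime_UTR"):
            L = lengths[f.chrom]
            for s, e in (
                (max(0, f.start - strict_intergenic_flank), f.start),
                (f.end, min(L, f.end + strict_intergenic_flank)),
            ):
                seg = classes[f.chrom][s:e]
                seg[seg == INTERGENIC] = EXCLUDED

    # non-callable positions are excluded regardless of annotation
    for chrom, L in lengths.items():
        inside = np.zeros(L, dtype=bool)
        for s, e in np.asarray(callable_iv.get(chrom, np.empty((0, 2)))).reshape(-1, 2):
            inside[s:e] = True
        classes[chrom][~inside] = EXCLUDED

    return SiteClassMap(classes=classes, syn_frac=syn_frac, gene_codons=gene_codons)
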