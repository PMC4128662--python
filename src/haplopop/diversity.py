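"""Nucleotide diversity, Tajima's D, frequency spectra, and divergence scans.

π is computed per site as the proportion of discordant unordered sample pairs
and averaged over all *called* sites, so monomorphic sites contribute zero to
the numerator but count in the denominator.  π is kept as a fraction
internally; table writers format it as % where appropriate.  All computations
use the general k-allele pairwise-mismatch form, so multi-allelic sites are
handled per formula rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import AnalysisMatrix, clip_intervals, intervals_length
from . import sites as _sites


def _allele_count_table(calls: np.ndarray) -> np.ndarray:
    """(S, k) allele counts from complete haploid calls (n, S)."""
    calls = np.asarray(calls)
    if calls.size == 0:
        return np.zeros((0, 1), dtype=np.int64)
    kmax = int(calls.max()) + 1
    S = calls.shape[1]
    counts = np.zeros((S, kmax), dtype=np.int64)
    for a in range(kmax):
        counts[:, a] = (calls == a).sum(axis=0)
    return counts


def site_pair_differences(calls: np.ndarray) -> np.ndarray:
    """Per-site count of discordant unordered pairs among n haploid samples."""
    counts = _allele_count_table(calls)
    n = calls.shape[0]
    return (n * n - (counts**2).sum(axis=1)) / 2.0


def nucleotide_diversity(calls: np.ndarray, n_called: int) -> float:
    """π over a region: mean per-site pairwise-difference proportion.

    ``calls`` holds the region's polymorphic sites (monomorphic columns are
    harmless); ``n_called`` is the total number of called sites in the region
    including monomorphic ones.
    """
    if n_called <= 0:
        raise ValueError("zero called sites")
    n = calls.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    npairs = n * (n - 1) / 2.0
    return float(site_pair_differences(calls).sum() / npairs / n_called)


def tajima_constants(n: int) -> dict[str, float]:
    """The standard Tajima (1989) normalising constants for sample size n."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(calls: np.ndarray) -> float:
    """Tajima's D over the given sites; NaN when there are no segregating sites."""
    n = calls.shape[0]
    diffs = site_pair_differences(calls)
    seg = diffs > 0
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    k_hat = diffs.sum() / (n * (n - 1) / 2.0)
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # degenerate for n = 2, where both estimators coincide
        return float("nan")
    return float((k_hat - S / c["a1"]) / np.sqrt(var))


# ---------------------------------------------------------------------------
# window machinery


def _window_starts(length: int, size: int, step: int) -> np.ndarray:
    """Windows anchored at 0; the first window reaching the end is the last."""
    if size <= 0 or step <= 0 or step > size:
        raise ValueError("need 0 < step <= size")
    starts = [0]
    while starts[-1] + size < length:
        starts.append(starts[-1] + step)
    return np.array(starts, dtype=np.int64)


def _class_positions_ok(class_map, chrom, pos, class_filter):
    codes = class_map.class_of(chrom, pos)
    want = _class_codes(class_filter)
    return np.isin(codes, want)


def _class_codes(class_filter) -> np.ndarray:
    name_to_code = {v: k for k, v in _sites.CLASS_NAMES.items()}
    if isinstance(class_filter, str):
        class_filter = [class_filter]
    return np.array([name_to_code[c] if isinstance(c, str) else int(c) for c in class_filter])


def window_scan(
    matrix: AnalysisMatrix,
    size: int = 20_000,
    step: int = 4_000,
    class_filter=None,
    class_map=None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window π and Tajima's D (defaults: 20 kb windows, 4 kb step).

    Emits per window: called-site count, SNP count, π and D.  Empty windows
    carry n_called = 0 and NaN statistics.  With ``class_filter`` (one or more
    class names) and a ``class_map``, both the SNPs and the called-site
    denominator are restricted to positions of those classes.
    """
    rows = []
    for chrom in matrix.chrom_names:
        iv = matrix.callable[chrom]
        length = (chrom_lengths or {}).get(chrom) or (int(iv[-1, 1]) if iv.size else 0)
        on = matrix.snp_index(chrom)
        pos = matrix.pos[on]
        calls = matrix.calls[:, on]
        if class_filter is not None:
            keep = _class_positions_ok(class_map, chrom, pos, class_filter)
            pos, calls = pos[keep], calls[:, keep]
        diffs = site_pair_differences(calls)
        n = matrix.n_samples
        npairs = n * (n - 1) / 2.0
        class_pos = None
        if class_filter is not None:
            codes = class_map.classes[chrom]
            want = _class_codes(class_filter)
            inside = np.zeros(len(codes), dtype=bool)
            for s, e in iv.reshape(-1, 2):
                inside[s:e] = True
            class_pos = np.flatnonzero(np.isin(codes, want) & inside)
        for start in _window_starts(length, size, step):
            end = min(start + size, length)
            if class_pos is not None:
                n_called = int(
                    np.searchsorted(class_pos, end) - np.searchsorted(class_pos, start)
                )
            else:
                n_called = intervals_length(clip_intervals(iv, start, end))
            lo, hi = np.searchsorted(pos, [start, end])
            w_diffs = diffs[lo:hi]
            n_snps = int((w_diffs > 0).sum())
            if n_called > 0:
                pi = float(w_diffs.sum() / npairs / n_called)
                d = tajimas_d(calls[:, lo:hi]) if n_snps > 0 else float("nan")
            else:
                pi, d = float("nan"), float("nan")
            rows.append((chrom, int(start), int(end), n_called, n_snps, pi, d))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_called", "n_snps", "pi", "tajimas_d"]
    )


# ---------------------------------------------------------------------------
# frequency spectrum


@dataclass
class SpectrumCounts:
    """Folded spectrum: counts of polymorphic sites by minor-allele count."""

    counts: np.ndarray  # index = minor allele count, 1..n//2 (index 0 unused)
    n: int
    n_multiallelic: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def minor_allele_spectrum(
    matrix: AnalysisMatrix,
    class_filter=None,
    class_map=None,
    collapse_group: list | None = None,
) -> SpectrumCounts:
    """Folded minor-allele-count spectrum over polymorphic sites.

    Multi-allelic sites are binned by the count of the most common non-major
    allele and tallied in ``n_multiallelic``.  ``collapse_group`` treats the
    listed samples as a single sample and excludes sites that vary within the
    group.
    """
    calls = matrix.calls
    pos_keep = np.ones(matrix.n_snps, dtype=bool)
    if class_filter is not None:
        pos_keep[:] = False
        for chrom in matrix.chrom_names:
            on = matrix.snp_index(chrom)
            if on.size:
                pos_keep[on] = _class_positions_ok(
                    class_map, chrom, matrix.pos[on], class_filter
                )
    if collapse_group:
        gidx = np.array(
            [matrix.samples.index(s) if isinstance(s, str) else int(s) for s in collapse_group]
        )
        within = np.any(calls[gidx] != calls[gidx[0]][None, :], axis=0)
        pos_keep &= ~within
        others = np.setdiff1d(np.arange(matrix.n_samples), gidx)
        calls = np.concatenate([calls[others], calls[gidx[:1]]], axis=0)
    n = calls.shape[0]
    counts = _allele_count_table(calls[:, pos_keep])
    spectrum = np.zeros(n // 2 + 1, dtype=np.int64)
    n_multi = 0
    for row in counts:
        present = row[row > 0]
        if present.size < 2:
            continue
        if present.size > 2:
            n_multi += 1
        srt = np.sort(row)[::-1]
        minor = int(min(srt[1], n // 2))
        spectrum[minor] += 1
    return SpectrumCounts(counts=spectrum, n=n, n_multiallelic=n_multi)


# ---------------------------------------------------------------------------
# gene-level diversity (Nei–Gojobori)


@dataclass
class GeneDiversity:
    gene_id: str
    chrom: str
    start: int
    end: int
    syn_sites: float
    nonsyn_sites: float
    pi_s: float
    pi_n: float
    ratio: float  # pi_n / pi_s, NaN when pi_s == 0
    tajimas_d: float
    eligible: bool  # syn_sites > 200


def gene_diversity(
    gene_id: str,
    matrix: AnalysisMatrix,
    class_map: "_sites.SiteClassMap",
    reference,
) -> GeneDiversity:
    """Per-gene πS, πN and Tajima's D via pathway-averaged codon differences.

    Site totals are the per-sample NG86 fractional counts averaged over
    samples; pairwise synonymous/nonsynonymous differences are averaged over
    all sample pairs.  Codons with any stop-codon variant among the samples
    are excluded entirely.  D is computed over all of the gene's called CDS
    sites, and a gene is flagged eligible when > 200 synonymous sites were
    analysable.
    """
    chrom, strand, positions = class_map.gene_codons[gene_id]
    seq = reference.sequence(chrom)
    n = matrix.n_samples
    npairs = n * (n - 1) / 2.0

    on = matrix.snp_index(chrom)
    pos_to_col = {int(p): i for p, i in zip(matrix.pos[on], on)}
    # which codons are analysable: syn_frac defined at all three positions
    sf = class_map.syn_frac[chrom]
    n_codons = positions.shape[0] // 3
    comp = _sites._RC

    syn_sites_total = 0.0
    nonsyn_sites_total = 0.0
    syn_diffs = 0.0
    nonsyn_diffs = 0.0
    cds_snp_cols = [pos_to_col[int(p)] for p in positions if int(p) in pos_to_col]

    for k in range(n_codons):
        gpos = positions[3 * k : 3 * k + 3]
        if np.isnan(sf[gpos]).any():
            continue
        ref_codon = "".join(seq[p] for p in gpos)
        if strand == "-":
            ref_codon = ref_codon.translate(comp)
        snp_here = [(j, pos_to_col[int(p)]) for j, p in enumerate(gpos) if int(p) in pos_to_col]
        if not snp_here:
            s0, n0 = _sites.codon_site_counts(ref_codon)
            syn_sites_total += s0
            nonsyn_sites_total += n0
            continue
        # build each sample's codon
        codons = [list(ref_codon) for _ in range(n)]
        ok = True
        for j, col in snp_here:
            alleles = [matrix.ref[col]] + list(matrix.alts[col])
            for i in range(n):
                b = alleles[matrix.calls[i, col]]
                if strand == "-":
                    b = b.translate(comp)
                codons[i][j] = b
        sample_codons = ["".join(c) for c in codons]
        variants: dict[str, int] = {}
        for c in sample_codons:
            variants[c] = variants.get(c, 0) + 1
        if any(v in _sites.STOP_CODONS or any(b not in _sites.BASES for b in v) for v in variants):
            continue  # codon excluded for all samples
        s_mean = n_mean = 0.0
        for v, cnt in variants.items():
            sv, nv = _sites.codon_site_counts(v)
            s_mean += sv * cnt
            n_mean += nv * cnt
        syn_sites_total += s_mean / n
        nonsyn_sites_total += n_mean / n
        vs = sorted(variants)
        for a_i in range(len(vs)):
            for b_i in range(a_i + 1, len(vs)):
                d = _sites.codon_pair_differences(vs[a_i], vs[b_i])
                w = variants[vs[a_i]] * variants[vs[b_i]]
                syn_diffs += d.syn_diffs * w
                nonsyn_diffs += d.nonsyn_diffs * w

    pi_s = (syn_diffs / npairs / syn_sites_total) if syn_sites_total > 0 else float("nan")
    pi_n = (nonsyn_diffs / npairs / nonsyn_sites_total) if nonsyn_sites_total > 0 else float("nan")
    ratio = pi_n / pi_s if pi_s and pi_s > 0 else float("nan")
    d_stat = tajimas_d(matrix.calls[:, cds_snp_cols]) if cds_snp_cols else float("nan")
    return GeneDiversity(
        gene_id=gene_id,
        chrom=chrom,
        start=int(positions.min()),
        end=int(positions.max()) + 1,
        syn_sites=syn_sites_total,
        nonsyn_sites=nonsyn_sites_total,
        pi_s=pi_s,
        pi_n=pi_n,
        ratio=ratio,
        tajimas_d=d_stat,
        eligible=syn_sites_total > 200,
    )


# ---------------------------------------------------------------------------
# between-group divergence


def group_divergence(
    matrix: AnalysisMatrix,
    group_a: list,
    group_b: list,
    size: int = 200,
    step: int = 40,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Dxy between two sample groups, with within-B π as control.

    Dxy per window = mean over cross-group pairs of the per-site difference
    proportion; the denominator is the window's called-site count.
    """

    def _idx(group):
        return np.array(
            [matrix.samples.index(s) if isinstance(s, str) else int(s) for s in group]
        )

    ia, ib = _idx(group_a), _idx(group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")

    rows = []
    nb = ib.size
    npairs_b = nb * (nb - 1) / 2.0
    for chrom in matrix.chrom_names:
        iv = matrix.callable[chrom]
        length = (chrom_lengths or {}).get(chrom) or (int(iv[-1, 1]) if iv.size else 0)
        on = matrix.snp_index(chrom)
        pos = matrix.pos[on]
        ca = matrix.calls[ia][:, on]
        cb = matrix.calls[ib][:, on]
        # cross-group mismatching pairs per site
        kmax = int(matrix.calls.max()) + 1 if matrix.calls.size else 1
        cnt_a = np.zeros((pos.size, kmax))
        cnt_b = np.zeros((pos.size, kmax))
        for a in range(kmax):
            cnt_a[:, a] = (ca == a).sum(axis=0)
            cnt_b[:, a] = (cb == a).sum(axis=0)
        cross_diff = ia.size * ib.size - (cnt_a * cnt_b).sum(axis=1)
        within_b_diff = (nb * nb - (cnt_b**2).sum(axis=1)) / 2.0
        for start in _window_starts(length, size, step):
            end = min(start + size, length)
            n_called = intervals_length(clip_intervals(iv, start, end))
            lo, hi = np.searchsorted(pos, [start, end])
            if n_called > 0:
                dxy = float(cross_diff[lo:hi].sum() / (ia.size * ib.size) / n_called)
                pi_b = float(within_b_diff[lo:hi].sum() / npairs_b / n_called)
            else:
                dxy, pi_b = float("nan"), float("nan")
            n_snps = int((cross_diff[lo:hi] + within_b_diff[lo:hi] > 0).sum())
            rows.append((chrom, int(start), int(end), n_called, n_snps, dxy, pi_b))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_called", "n_snps", "dxy", "pi_control"]
    )


# ---------------------------------------------------------------------------
# per-class summary (Table-2 style)


def class_diversity_table(matrix: AnalysisMatrix, class_map) -> pd.DataFrame:
    """Per-class called-site totals, SNP counts and pooled π.

    Synonymous/nonsynonymous columns use NG86 fractional site counts and
    pathway-averaged difference counts pooled over all analysable codons;
    other classes pool sites directly.
    """
    counts = class_map.counts(matrix.callable)
    n = matrix.n_samples
    npairs = n * (n - 1) / 2.0

    per_class_diffs = {name: 0.0 for name in counts}
    per_class_snps = {name: 0 for name in counts}
    for chrom in matrix.chrom_names:
        on = matrix.snp_index(chrom)
        if not on.size:
            continue
        codes = class_map.class_of(chrom, matrix.pos[on])
        diffs = site_pair_differences(matrix.calls[:, on])
        for code, name in _sites.CLASS_NAMES.items():
            if code in (_sites.SYNONYMOUS, _sites.NONSYNONYMOUS, _sites.CDS_MIXED):
                continue
            sel = codes == code
            per_class_snps[name] += int(sel.sum())
            per_class_diffs[name] += float(diffs[sel].sum())
        # CDS SNPs: split the site's pairwise differences by the NG86 fraction
        in_cds = np.isin(
            codes, (_sites.SYNONYMOUS, _sites.NONSYNONYMOUS, _sites.CDS_MIXED)
        )
        frac = class_map.syn_frac[chrom][matrix.pos[on][in_cds]]
        cds_diffs = diffs[in_cds]
        per_class_diffs["synonymous"] += float(np.nansum(cds_diffs * frac))
        per_class_diffs["nonsynonymous"] += float(np.nansum(cds_diffs * (1.0 - frac)))
        per_class_snps["synonymous"] += int((codes == _sites.SYNONYMOUS).sum())
        per_class_snps["nonsynonymous"] += int((codes == _sites.NONSYNONYMOUS).sum())
        per_class_snps["CDS_mixed"] += int((codes == _sites.CDS_MIXED).sum())

    total_called = sum(matrix.called_sites(c) for c in matrix.chrom_names)
    all_diffs = float(site_pair_differences(matrix.calls).sum())
    rows = [
        ("all", float(total_called), int(matrix.n_snps), all_diffs / npairs / total_called if total_called else float("nan"))
    ]
    for name in ("synonymous", "nonsynonymous", "intron", "five_prime_UTR", "three_prime_UTR", "ncRNA", "intergenic"):
        sites_n = counts[name]
        pi = per_class_diffs[name] / npairs / sites_n if sites_n > 0 else float("nan")
        rows.append((name, sites_n, per_class_snps[name], pi))
    return pd.DataFrame(rows, columns=["class", "n_sites", "n_snps", "pi"])
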