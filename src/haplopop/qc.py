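"""Read-level filters, genotype-call filters, and site masking.

The endpoint of this stage is the :class:`AnalysisMatrix`: the set of sites
where every sample has a confidently assigned call and which fall outside the
repeat/indel/feature masks.  Per-site statistics downstream need the count of
retained *monomorphic* sites as a denominator, so completeness is tracked as a
set of callable intervals per chromosome, not just as the SNP list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import MISSING, AnnotationSet, GenotypeMatrix, ReferenceGenome

MASKED_FEATURE_TYPES = ("transposable_element", "centromere", "telomere")


# ---------------------------------------------------------------------------
# interval helpers (0-based half-open throughout)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping intervals into a sorted disjoint set."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def intervals_length(intervals: np.ndarray) -> int:
    iv = merge_intervals(intervals)
    return int((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0


def clip_intervals(intervals: np.ndarray, start: int, end: int) -> np.ndarray:
    """Intersect a disjoint sorted interval set with [start, end)."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if iv.size == 0:
        return iv
    s = np.clip(iv[:, 0], start, end)
    e = np.clip(iv[:, 1], start, end)
    keep = s < e
    return np.stack([s[keep], e[keep]], axis=1)


def subtract_intervals(base: np.ndarray, cut: np.ndarray) -> np.ndarray:
    """Remove ``cut`` from ``base``; both are interval sets."""
    base = merge_intervals(base)
    cut = merge_intervals(cut)
    if base.size == 0 or cut.size == 0:
        return base
    out: list[tuple[int, int]] = []
    j = 0
    for s, e in base:
        cur = s
        while j < len(cut) and cut[j][1] <= cur:
            j += 1
        k = j
        while k < len(cut) and cut[k][0] < e:
            cs, ce = cut[k]
            if cs > cur:
                out.append((cur, cs))
            cur = max(cur, ce)
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def positions_in_intervals(pos: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    """Boolean mask: which positions fall inside the (merged) interval set."""
    pos = np.asarray(pos, dtype=np.int64)
    iv = merge_intervals(intervals)
    if iv.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(pos.shape, dtype=bool)
    inside[ok] = pos[ok] < iv[idx[ok], 1]
    return inside


# ---------------------------------------------------------------------------
# read filtering


@dataclass
class Read:
    name: str
    seq: str
    qual: np.ndarray  # phred scores, same length as seq


@dataclass
class ReadFilterParams:
    min_run_qual: int = 30
    min_run_len: int = 10
    tail_checkpoints: tuple[int, ...] = (150, 200)
    tail_bad_qual: int = 20
    tail_bad_frac: float = 0.10
    read_bad_frac: float = 0.10
    adapters: tuple[str, ...] = ()
    min_len: int = 45
    max_n_run: int = 3


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def _trim_to_quality_run(read: Read, params: ReadFilterParams) -> Read | None:
    ok = read.qual >= params.min_run_qual
    k = params.min_run_len
    if len(ok) < k:
        return None
    runs = np.convolve(ok.astype(int), np.ones(k, dtype=int), "valid") == k
    starts = np.flatnonzero(runs)
    if starts.size == 0:
        return None
    lo = starts[0]
    hi = starts[-1] + k  # end of the last full run; keep through the read end after it
    # trim each end up to (not into) its nearest full-quality run
    return Read(read.name, read.seq[lo:hi], read.qual[lo:hi]) if hi > lo else None


def _filter_one(read: Read, params: ReadFilterParams) -> Read | None:
    r = _trim_to_quality_run(read, params)
    if r is None:
        return None
    # drop low-quality 3' tails past fixed checkpoints
    for cp in params.tail_checkpoints:
        if len(r.seq) > cp:
            tail = r.qual[cp:]
            if np.mean(tail < params.tail_bad_qual) >= params.tail_bad_frac:
                r = Read(r.name, r.seq[:cp], r.qual[:cp])
    if np.mean(r.qual < params.tail_bad_qual) >= params.read_bad_frac:
        return None
    for ad in params.adapters:
        if ad:
            i = r.seq.find(ad)
            if i >= 0:
                r = Read(r.name, r.seq[:i], r.qual[:i])
    if len(r.seq) < params.min_len:
        return None
    if len(set(r.seq)) <= 1:
        return None
    if "N" * params.max_n_run in r.seq:
        return None
    return r


def filter_reads(
    pairs: list[tuple[Read, Read]], params: ReadFilterParams | None = None
) -> list[tuple[Read, Read]]:
    """Apply the read-level quality filters to paired-end reads.

    In order: end-trimming to the first/last run of ``min_run_len`` bases at
    phred >= ``min_run_qual``; removal of 3' regions past 150/200 bp with >=10%
    bases under phred 20; removal of reads with >=10% such bases overall;
    adapter trimming; minimum-length, single-base-composition, N-run, and
    mate-reverse-complement removal.  If one mate fails, the pair is dropped.
    """
    params = params or ReadFilterParams()
    out: list[tuple[Read, Read]] = []
    for r1, r2 in pairs:
        f1 = _filter_one(r1, params)
        f2 = _filter_one(r2, params)
        if f1 is None or f2 is None:
            continue
        if f1.seq == _revcomp(f2.seq):
            continue
        out.append((f1, f2))
    return out


# ---------------------------------------------------------------------------
# genotype-call filtering


def filter_calls(
    matrix: GenotypeMatrix,
    min_qual: float = 30,
    min_depth: int = 10,
    depth_sd_factor: float = 3.0,
    depth_rule: str = "mean_plus_3sd",
) -> GenotypeMatrix:
    """Mask unreliable calls: low site quality, out-of-range depth, heterozygotes.

    A call becomes MISSING if the site QUAL < ``min_qual``, the sample depth
    < ``min_depth`` or above the per-sample upper bound, or the call was
    flagged heterozygous (treated as an error in a haploid organism).  The
    upper bound is mean + ``depth_sd_factor``·SD of the sample's depth
    (``depth_rule="mean_plus_3sd"``), or ``depth_sd_factor``·SD as an absolute
    cap (``depth_rule="literal_3sd"``).
    """
    if depth_rule not in ("mean_plus_3sd", "literal_3sd"):
        raise ValueError(f"unknown depth_rule {depth_rule!r}")
    calls = matrix.calls.copy()
    depth = matrix.depth.astype(np.float64)
    mean = depth.mean(axis=1, keepdims=True)
    sd = depth.std(axis=1, keepdims=True)
    if depth_rule == "mean_plus_3sd":
        upper = mean + depth_sd_factor * sd
    else:
        upper = depth_sd_factor * sd
    bad_qual = np.isnan(matrix.qual) | (matrix.qual < min_qual)
    bad = (
        bad_qual[None, :]
        | (matrix.depth < min_depth)
        | (depth > upper)
        | matrix.het
    )
    calls[bad] = MISSING
    return replace(matrix, calls=calls, het=np.zeros_like(matrix.het))


# ---------------------------------------------------------------------------
# site masking


@dataclass
class SiteMask:
    """Per-chromosome masked intervals with reasons; effective mask = union."""

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, chrom: str, start: int, end: int, reason: str) -> None:
        if start < end:
            self.intervals.setdefault(chrom, []).append((start, end, reason))

    def union(self, chrom: str) -> np.ndarray:
        iv = self.intervals.get(chrom, [])
        if not iv:
            return np.empty((0, 2), dtype=np.int64)
        return merge_intervals(np.array([(s, e) for s, e, _ in iv], dtype=np.int64))

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return positions_in_intervals(pos, self.union(chrom))

    def to_bed_intervals(self) -> dict[str, np.ndarray]:
        return {c: self.union(c) for c in sorted(self.intervals)}


def _repeat_runs(seq: str, period: int, min_units: int) -> list[tuple[int, int]]:
    """Maximal runs where seq[i] == seq[i-period], with > min_units-1 full units.

    ``min_units`` is the smallest number of complete units that triggers
    masking (strict > on the rule's unit count).  Period-2/3 runs that are
    really homopolymers are skipped (they are caught at period 1).
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.shape[0]
    if n <= period:
        return []
    eq = arr[period:] == arr[:-period]
    out: list[tuple[int, int]] = []
    # run-length encode eq
    idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        start, end = int(a), int(b) + period  # region in sequence coordinates
        length = end - start
        if length // period < min_units:
            continue
        if period > 1 and len(set(seq[start:end])) == 1:
            continue  # degenerate: pure homopolymer
        out.append((start, end))
    return out


def build_site_mask(
    reference: ReferenceGenome,
    annotation: AnnotationSet | None = None,
    indel_positions: dict[str, np.ndarray] | None = None,
    flank: int = 10,
    homopolymer_units: int = 10,
    dimer_units: int = 6,
    trimer_units: int = 6,
) -> SiteMask:
    """Build the union mask of low-complexity repeats, indel flanks, and features.

    Masks maximal homopolymer runs longer than 9 bp, di- and trinucleotide
    repeats of more than 5 units, each with 10 bp flanks on both sides; 10 bp
    up- and downstream of indels; and all transposable-element, centromere and
    telomere features.
    """
    mask = SiteMask()
    for chrom, seq in zip(reference.names, reference.sequences):
        L = len(seq)
        for period, units, reason in (
            (1, homopolymer_units, "homopolymer"),
            (2, dimer_units, "dimer_repeat"),
            (3, trimer_units, "trimer_repeat"),
        ):
            for s, e in _repeat_runs(seq, period, units):
                mask.add(chrom, max(0, s - flank), min(L, e + flank), reason)
    if indel_positions:
        lengths = reference.lengths
        for chrom, positions in indel_positions.items():
            L = lengths[chrom]
            for p in np.atleast_1d(np.asarray(positions, dtype=np.int64)):
                mask.add(chrom, max(0, int(p) - flank), min(L, int(p) + flank + 1), "indel_flank")
    if annotation is not None:
        for f in annotation.of_type(*MASKED_FEATURE_TYPES):
            mask.add(f.chrom, f.start, f.end, f.type)
    return mask


# ---------------------------------------------------------------------------
# the analysis matrix


@dataclass
class AnalysisMatrix:
    """Complete, mask-filtered calls: the substrate of every downstream scan.

    ``calls`` holds the polymorphic sites only; monomorphic fully-called sites
    are represented by the ``callable`` interval sets so that per-site
    statistics have correct denominators.  Every SNP position lies inside the
    callable set of its chromosome.
    """

    samples: list[str]
    chrom: np.ndarray  # (S,) SNP chromosome
    pos: np.ndarray  # (S,) SNP position
    ref: np.ndarray
    alts: list[tuple[str, ...]]
    calls: np.ndarray  # (n, S) allele indices, no MISSING
    callable: dict[str, np.ndarray]  # chrom -> (k, 2) disjoint intervals

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return self.pos.shape[0]

    @property
    def chrom_names(self) -> list[str]:
        return list(self.callable.keys())

    def called_sites(self, chrom: str) -> int:
        return intervals_length(self.callable[chrom])

    def snp_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def subset_samples(self, names_or_idx) -> "AnalysisMatrix":
        idx = np.asarray(
            [self.samples.index(s) if isinstance(s, str) else int(s) for s in names_or_idx]
        )
        return AnalysisMatrix(
            samples=[self.samples[i] for i in idx],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alts=self.alts,
            calls=self.calls[idx],
            callable=self.callable,
        )


def apply_mask_and_complete(
    matrix: GenotypeMatrix,
    mask: SiteMask,
    callable_intervals: dict[str, np.ndarray] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> AnalysisMatrix:
    """Drop masked and incomplete sites and assemble the analysis matrix.

    ``callable_intervals`` is the track of sites confidently called in *all*
    samples (e.g. from an all-sites caller), as {chrom: (k, 2) intervals}.  If
    omitted, it is derived from the matrix itself, which then must contain
    invariant-site records for denominators to be meaningful.  Variant sites
    inside the mask, with any MISSING or heterozygous call, or outside the
    callable track are dropped, and dropped variant positions are carved out
    of the callable set.
    """
    for c in mask.intervals:
        known = set(matrix.chrom.tolist())
        if callable_intervals:
            known |= set(callable_intervals)
        if chrom_lengths:
            known |= set(chrom_lengths)
        if c not in known:
            raise ValueError(f"mask references unknown chromosome {c!r}")

    complete = ~np.any((matrix.calls == MISSING) | matrix.het, axis=0)
    # polymorphic among complete sites (incomplete ones are dropped regardless)
    poly = np.any(matrix.calls != matrix.calls[0][None, :], axis=0)

    chrom_names = list(dict.fromkeys(matrix.chrom.tolist()))
    if callable_intervals is not None:
        chrom_names = list(dict.fromkeys(chrom_names + list(callable_intervals)))

    callable_out: dict[str, np.ndarray] = {}
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for chrom in chrom_names:
        on = matrix.chrom == chrom
        masked_here = mask.contains(chrom, matrix.pos[on]) if on.any() else np.array([], bool)
        ok = complete[on] & ~masked_here
        if callable_intervals is not None:
            base = subtract_intervals(callable_intervals.get(chrom, np.empty((0, 2))), mask.union(chrom))
            in_track = positions_in_intervals(matrix.pos[on], base)
            ok &= in_track
            # variant positions present in the VCF but dropped as incomplete
            # must leave the callable track too
            dropped = matrix.pos[on][in_track & ~complete[on]]
            if dropped.size:
                cut = np.stack([dropped, dropped + 1], axis=1)
                base = subtract_intervals(base, cut)
            callable_out[chrom] = base
        else:
            pos_ok = matrix.pos[on][ok]
            iv = np.stack([pos_ok, pos_ok + 1], axis=1) if pos_ok.size else np.empty((0, 2), np.int64)
            callable_out[chrom] = merge_intervals(iv)
        keep_on = np.zeros(on.sum(), dtype=bool)
        keep_on[:] = ok & poly[on]
        keep[np.flatnonzero(on)] = keep_on

    idx = np.flatnonzero(keep)
    return AnalysisMatrix(
        samples=matrix.samples,
        chrom=matrix.chrom[idx],
        pos=matrix.pos[idx],
        ref=matrix.ref[idx],
        alts=[matrix.alts[i] for i in idx],
        calls=matrix.calls[:, idx].astype(np.int16),
        callable=callable_out,
    )
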