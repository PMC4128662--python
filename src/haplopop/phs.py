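"""The pairwise haplotype sharing (PHS) test for partial selective sweeps.

For two haploid samples i and j, an identity tract is a maximal chromosomal
interval over which their calls agree at every compared site; d_ijx is the
genetic length (cM) of the tract of pair (i, j) spanning position x.  With
d̄_ij and σ_ij the genome-wide mean and standard deviation of the pair's
tract lengths, the standardized length is

    Z_ijx = (d_ijx − d̄_ij) / σ_ij

and for an allele A carried by n_A samples at position x,

    PHS_A(x) = Σ_{carrier pairs} Z_ijx / C(n_A, 2) − Σ_{all pairs} Z_ijx / C(n, 2).

Large values mean the carriers share unexpectedly long haplotypes around x —
the footprint of a partial sweep.  Genetic positions come from a per-
chromosome quartic bp→cM map fitted to marker data; tracts are terminated at
clusters of missing data of at least 30 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

from .io import MarkerTable
from .qc import AnalysisMatrix


# ---------------------------------------------------------------------------
# genetic map


@dataclass
class ChromosomeMap:
    poly: Polynomial
    bp_min: float
    bp_max: float
    repaired: bool = False
    _grid: np.ndarray | None = None
    _grid_cm: np.ndarray | None = None

    def __call__(self, bp) -> np.ndarray:
        x = np.clip(np.asarray(bp, dtype=float), self.bp_min, self.bp_max)
        if self.repaired:
            return np.interp(x, self._grid, self._grid_cm)
        return self.poly(x)


@dataclass
class GeneticMap:
    """Per-chromosome polynomial bp→cM maps, monotone after repair."""

    maps: dict[str, ChromosomeMap] = field(default_factory=dict)

    def evaluate(self, chrom: str, bp) -> np.ndarray:
        return self.maps[chrom](bp)

    @classmethod
    def from_polynomials(cls, polys: dict[str, tuple[Polynomial, float, float]]) -> "GeneticMap":
        gm = cls()
        for chrom, (p, lo, hi) in polys.items():
            gm.maps[chrom] = _make_chrom_map(p, lo, hi)
        return gm


def _make_chrom_map(poly: Polynomial, lo: float, hi: float, grid_step: float = 1000.0) -> ChromosomeMap:
    grid = np.arange(lo, hi + grid_step, grid_step)
    grid = np.clip(grid, lo, hi)
    vals = poly(grid)
    if np.all(np.diff(vals) >= -1e-12):
        return ChromosomeMap(poly, lo, hi, repaired=False)
    return ChromosomeMap(
        poly, lo, hi, repaired=True, _grid=grid, _grid_cm=np.maximum.accumulate(vals)
    )


def fit_genetic_map(markers: MarkerTable, degree: int = 4) -> GeneticMap:
    """Fit a degree-4 polynomial bp→cM per chromosome.

    Evaluation outside the marker range clamps to the boundary values.  If the
    fitted polynomial decreases anywhere on a 1-kb grid, the map is repaired
    to its running maximum and flagged.
    """
    gm = GeneticMap()
    for chrom in markers.chroms:
        sub = markers.for_chrom(chrom)
        if len(sub) < degree + 1:
            raise ValueError(
                f"chromosome {chrom}: {len(sub)} markers < degree+1 = {degree + 1}"
            )
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        poly = Polynomial.fit(bp, cm, deg=degree)
        gm.maps[chrom] = _make_chrom_map(poly, bp.min(), bp.max())
    return gm


# ---------------------------------------------------------------------------
# identity tracts


@dataclass
class IdentityTract:
    pair: tuple[int, int]
    chrom: str
    start: int  # physical span, boundaries exclusive (flanking discordant sites)
    end: int
    genetic_length: float  # cM


def _gap_edges(callable_iv: np.ndarray, miss_cluster_bp: int) -> list[tuple[int, int]]:
    """(end-of-left, start-of-right) for uncovered spans >= miss_cluster_bp."""
    iv = np.asarray(callable_iv).reshape(-1, 2)
    out = []
    for k in range(iv.shape[0] - 1):
        if iv[k + 1, 0] - iv[k, 1] >= miss_cluster_bp:
            out.append((int(iv[k, 1]), int(iv[k + 1, 0])))
    return out


def _pair_breaks(
    disc_pos: np.ndarray, gaps: list[tuple[int, int]], chrom_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sorted breakpoints and a flag per inter-break interval: True = gap.

    Breakpoints are the chromosome ends, the edges of every >= threshold
    missing-data cluster, and the pair's discordant positions.  The interval
    between a gap's two edges is not a tract.
    """
    pts = [0, chrom_len]
    for a, b in gaps:
        pts.extend((a, b))
    breaks = np.unique(np.concatenate([np.asarray(pts, dtype=np.int64), disc_pos]))
    is_gap = np.zeros(breaks.size - 1, dtype=bool)
    for a, b in gaps:
        i = np.searchsorted(breaks, a)
        j = np.searchsorted(breaks, b)
        # no compared site lies strictly inside a gap, so edges are adjacent
        if j == i + 1:
            is_gap[i] = True
    return breaks, is_gap


def pairwise_identity_tracts(
    matrix: AnalysisMatrix,
    pair: tuple[int, int],
    gmap: GeneticMap,
    miss_cluster_bp: int = 30_000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[IdentityTract]:
    """All maximal identity tracts of one sample pair, genome-wide."""
    i, j = pair
    if not (0 <= i < matrix.n_samples and 0 <= j < matrix.n_samples):
        raise ValueError(f"unknown pair {pair}")
    out: list[IdentityTract] = []
    for chrom in matrix.chrom_names:
        iv = matrix.callable[chrom]
        L = (chrom_lengths or {}).get(chrom) or (int(iv[-1, 1]) if iv.size else 0)
        on = matrix.snp_index(chrom)
        disc = matrix.pos[on][matrix.calls[i, on] != matrix.calls[j, on]]
        breaks, is_gap = _pair_breaks(disc, _gap_edges(iv, miss_cluster_bp), L)
        cm = gmap.evaluate(chrom, breaks)
        for k in range(breaks.size - 1):
            if is_gap[k]:
                continue
            out.append(
                IdentityTract(
                    pair=(i, j),
                    chrom=chrom,
                    start=int(breaks[k]),
                    end=int(breaks[k + 1]),
                    genetic_length=float(cm[k + 1] - cm[k]),
                )
            )
    return out


@dataclass
class PairMoments:
    """Genome-wide tract-length mean and SD for every sample pair."""

    pair_i: np.ndarray  # (P,)
    pair_j: np.ndarray  # (P,)
    mean: np.ndarray  # (P,) cM
    sd: np.ndarray  # (P,) population SD, cM
    n_tracts: np.ndarray  # (P,)
    degenerate: np.ndarray  # (P,) bool: SD == 0 or < 2 tracts; Z forced to 0


def pair_tract_moments(tract_lengths: np.ndarray) -> tuple[float, float]:
    """Mean and population SD of one pair's tract genetic lengths."""
    t = np.asarray(tract_lengths, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 tracts for moments")
    return float(t.mean()), float(t.std())


class _ScanState:
    """Precomputed per-pair breakpoints and moments for a whole matrix."""

    def __init__(
        self,
        matrix: AnalysisMatrix,
        gmap: GeneticMap,
        miss_cluster_bp: int = 30_000,
        chrom_lengths: dict[str, int] | None = None,
    ):
        self.matrix = matrix
        self.gmap = gmap
        n = matrix.n_samples
        self.I, self.J = np.triu_indices(n, k=1)
        P = self.I.size
        self.breaks: dict[str, list[np.ndarray]] = {}
        self.breaks_cm: dict[str, list[np.ndarray]] = {}
        self.disc: dict[str, list[np.ndarray]] = {}
        sums = np.zeros(P)
        sqs = np.zeros(P)
        cnt = np.zeros(P, dtype=np.int64)
        for chrom in matrix.chrom_names:
            iv = matrix.callable[chrom]
            L = (chrom_lengths or {}).get(chrom) or (int(iv[-1, 1]) if iv.size else 0)
            gaps = _gap_edges(iv, miss_cluster_bp)
            on = matrix.snp_index(chrom)
            pos = matrix.pos[on]
            calls = matrix.calls[:, on]
            blist: list[np.ndarray] = []
            cmlist: list[np.ndarray] = []
            dlist: list[np.ndarray] = []
            for p in range(P):
                disc = pos[calls[self.I[p]] != calls[self.J[p]]]
                breaks, is_gap = _pair_breaks(disc, gaps, L)
                cm = np.asarray(self.gmap.evaluate(chrom, breaks), dtype=float)
                lengths = np.diff(cm)[~is_gap]
                sums[p] += lengths.sum()
                sqs[p] += (lengths**2).sum()
                cnt[p] += lengths.size
                blist.append(breaks)
                cmlist.append(cm)
                dlist.append(disc)
            self.breaks[chrom] = blist
            self.breaks_cm[chrom] = cmlist
            self.disc[chrom] = dlist
        mean = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0)
        var = np.where(cnt > 0, sqs / np.maximum(cnt, 1) - mean**2, 0.0)
        sd = np.sqrt(np.maximum(var, 0.0))
        degenerate = (cnt < 2) | (sd <= 0.0)
        self.moments = PairMoments(
            pair_i=self.I, pair_j=self.J, mean=mean, sd=sd, n_tracts=cnt, degenerate=degenerate
        )

    def z_matrix(self, chrom: str, query_pos: np.ndarray) -> np.ndarray:
        """(P, Q) standardized tract lengths spanning each query position.

        A pair discordant at the query position gets a zero-length tract
        there; degenerate (clone) pairs contribute Z = 0.
        """
        m = self.moments
        P = m.pair_i.size
        Q = query_pos.size
        Z = np.zeros((P, Q))
        for p in range(P):
            if m.degenerate[p]:
                continue
            breaks = self.breaks[chrom][p]
            cm = self.breaks_cm[chrom][p]
            li = np.searchsorted(breaks, query_pos, side="right") - 1
            li = np.clip(li, 0, breaks.size - 2)
            d = cm[li + 1] - cm[li]
            # a query at a discordant site has a zero-length tract; a query at
            # a gap edge instead starts the tract on the near side
            d = np.where(_isin_sorted(query_pos, self.disc[chrom][p]), 0.0, d)
            Z[p] = (d - m.mean[p]) / m.sd[p]
        return Z


def _isin_sorted(values: np.ndarray, sorted_arr: np.ndarray) -> np.ndarray:
    if sorted_arr.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_arr, values)
    ok = idx < sorted_arr.size
    out = np.zeros(values.shape, dtype=bool)
    out[ok] = sorted_arr[idx[ok]] == values[ok]
    return out


def phs_statistic(
    matrix: AnalysisMatrix,
    gmap: GeneticMap,
    chrom: str,
    x: int,
    allele: int,
    miss_cluster_bp: int = 30_000,
    state: "_ScanState | None" = None,
) -> float:
    """PHS of one allele at one position (see module docstring for the form)."""
    state = state or _ScanState(matrix, gmap, miss_cluster_bp)
    on = matrix.snp_index(chrom)
    col = on[np.searchsorted(matrix.pos[on], x)]
    if matrix.pos[col] != x or matrix.chrom[col] != chrom:
        raise ValueError(f"no SNP at {chrom}:{x}")
    carriers = matrix.calls[:, col] == allele
    n_a = int(carriers.sum())
    if n_a < 2:
        raise ValueError("allele needs at least 2 carriers")
    Z = state.z_matrix(chrom, np.array([x]))[:, 0]
    pair_mask = carriers[state.I] & carriers[state.J]
    n = matrix.n_samples
    return float(Z[pair_mask].sum() / (n_a * (n_a - 1) / 2) - Z.sum() / (n * (n - 1) / 2))


def phs_scan(
    matrix: AnalysisMatrix,
    gmap: GeneticMap,
    top_fraction: float = 0.001,
    miss_cluster_bp: int = 30_000,
    ranking: str = "frequency",
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """PHS for every allele with >= 2 carriers at every SNP, with candidates.

    Candidates are the records whose PHS reaches the top ``top_fraction``
    within their carrier-count class (``ranking="frequency"``, the default:
    the null distribution of PHS depends strongly on allele frequency) or
    globally (``ranking="global"``).
    """
    if ranking not in ("frequency", "global"):
        raise ValueError(f"unknown ranking {ranking!r}")
    state = _ScanState(matrix, gmap, miss_cluster_bp, chrom_lengths)
    n = matrix.n_samples
    npairs = n * (n - 1) / 2.0
    recs = []
    for chrom in matrix.chrom_names:
        on = matrix.snp_index(chrom)
        if on.size == 0:
            continue
        pos = matrix.pos[on]
        calls = matrix.calls[:, on]
        Z = state.z_matrix(chrom, pos)  # (P, S)
        all_mean = Z.sum(axis=0) / npairs
        kmax = int(calls.max()) + 1
        for a in range(kmax):
            C = calls == a  # (n, S)
            n_a = C.sum(axis=0)
            ok = n_a >= 2
            if not ok.any():
                continue
            pair_mask = C[state.I] & C[state.J]  # (P, S)
            pair_sum = np.where(pair_mask, Z, 0.0).sum(axis=0)
            phs = pair_sum[ok] / (n_a[ok] * (n_a[ok] - 1) / 2.0) - all_mean[ok]
            alleles_str = [
                (matrix.ref[c] if a == 0 else (matrix.alts[c][a - 1] if a - 1 < len(matrix.alts[c]) else str(a)))
                for c in on[ok]
            ]
            for s_idx, al, na, v in zip(np.flatnonzero(ok), alleles_str, n_a[ok], phs):
                recs.append((chrom, int(pos[s_idx]), al, int(na), float(na) / n, float(v)))
    df = pd.DataFrame(recs, columns=["chrom", "pos", "allele", "n_carriers", "freq", "phs"])
    if df.empty:
        df["candidate"] = pd.Series(dtype=bool)
        return df
    cand = np.zeros(len(df), dtype=bool)
    if ranking == "global":
        thr = np.quantile(df["phs"].to_numpy(), 1.0 - top_fraction)
        cand = df["phs"].to_numpy() >= thr
    else:
        for na, grp in df.groupby("n_carriers"):
            thr = np.quantile(grp["phs"].to_numpy(), 1.0 - top_fraction)
            cand[grp.index.to_numpy()] = grp["phs"].to_numpy() >= thr
    df["candidate"] = cand
    return df
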