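"""Population structure: p-distances, neighbor joining, SNP thinning, PCA."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .qc import AnalysisMatrix


@dataclass
class DistanceMatrix:
    values: np.ndarray  # (n, n) symmetric, zero diagonal
    labels: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise ValueError("distance matrix must be square and symmetric")


@dataclass
class PopTree:
    """Unrooted NJ tree as newick; branch lengths as computed (may be negative)."""

    newick: str
    labels: list[str]


def p_distance_matrix(matrix: AnalysisMatrix) -> DistanceMatrix:
    """Pairwise p-distance: proportion of called sites at which samples differ.

    Monomorphic called sites contribute to the denominator only, so the
    denominator is the total callable-site count.
    """
    total = sum(matrix.called_sites(c) for c in matrix.chrom_names)
    if total <= 0:
        raise ValueError("no called sites")
    n = matrix.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = (matrix.calls != matrix.calls[i][None, :]).sum(axis=1) / total
    return DistanceMatrix(values=d, labels=list(matrix.samples))


def neighbor_joining(dist: DistanceMatrix) -> PopTree:
    """Saitou–Nei neighbor joining with deterministic lexicographic tie-breaks.

    Pairs minimising the Q criterion are joined iteratively; when several
    pairs tie, the pair whose (sorted) representative leaf labels are
    lexicographically smallest is chosen.
    """
    n = len(dist.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dist.values.astype(float).copy()
    # each active node: (newick fragment, smallest leaf label under it)
    nodes = [(lab, lab) for lab in dist.labels]
    active = list(range(n))

    def fmt(x: float) -> str:
        return f"{x:.10g}"

    while len(active) > 3:
        r = len(active)
        R = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - R[i] - R[j]
                key = tuple(sorted((nodes[i][1], nodes[j][1])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        bi = D[i, j] / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        new = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        frag = f"({nodes[i][0]}:{fmt(bi)},{nodes[j][0]}:{fmt(bj)})"
        nodes.append((frag, min(nodes[i][1], nodes[j][1])))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    bi = (D[i, j] + D[i, k] - D[j, k]) / 2.0
    bj = (D[i, j] + D[j, k] - D[i, k]) / 2.0
    bk = (D[i, k] + D[j, k] - D[i, j]) / 2.0
    newick = (
        f"({nodes[i][0]}:{fmt(bi)},{nodes[j][0]}:{fmt(bj)},{nodes[k][0]}:{fmt(bk)});"
    )
    return PopTree(newick=newick, labels=list(dist.labels))


def thin_snps(matrix: AnalysisMatrix, spacing: int = 50_000, seed: int = 0) -> np.ndarray:
    """Select SNPs separated by approximately ``spacing`` bp.

    Per chromosome: the first SNP is chosen uniformly at random among SNPs
    within ``spacing`` of the 5'-most SNP; thereafter the closest SNP at least
    ``spacing`` downstream of the last pick is taken, to the chromosome end.
    Returns global site indices; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for chrom in matrix.chrom_names:
        on = matrix.snp_index(chrom)
        if on.size == 0:
            continue
        pos = matrix.pos[on]
        first_candidates = np.flatnonzero(pos <= pos[0] + spacing)
        cur = int(rng.choice(first_candidates))
        chosen.append(int(on[cur]))
        while True:
            nxt = np.searchsorted(pos, pos[cur] + spacing, side="left")
            if nxt >= pos.size:
                break
            cur = int(nxt)
            chosen.append(int(on[cur]))
    return np.array(chosen, dtype=np.int64)


def pca(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PCA of haploid genotypes encoded 0/1 (major/minor), plain centring.

    Returns (eigenvalues, coordinates): eigenvalues of the sample covariance
    in decreasing order and per-sample coordinates on each component.  The
    sign convention makes the largest-magnitude SNP loading positive.
    Constant SNP columns are dropped with a warning.
    """
    calls = np.asarray(calls)
    n, S = calls.shape
    if n < 3 or S < 2:
        raise ValueError("PCA needs at least 3 samples and 2 SNPs")
    X = np.zeros((n, S))
    for s in range(S):
        vals, cnts = np.unique(calls[:, s], return_counts=True)
        major = vals[np.argmax(cnts)]  # ties -> lowest allele index (np.unique sorted)
        X[:, s] = calls[:, s] != major
    const = X.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant SNP columns")
        X = X[:, ~const]
    if X.shape[1] == 0:
        return np.zeros(n - 1), np.zeros((n, n - 1))
    Xc = X - X.mean(axis=0, keepdims=True)
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = sv**2 / (n - 1)
    coords = U * sv
    for j in range(Vt.shape[0]):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1
            coords[:, j] *= -1
    return eigvals, coords
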