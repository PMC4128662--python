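"""Linkage disequilibrium decay and population recombination rate estimation.

r² is the squared correlation of allelic states at two sites across haploid
genomes.  Its expected decline with the scaled recombination distance
C = ρ·d (ρ = 4Nr per bp) is the sigma-d-squared curve
σd²(C) = (10 + C) / (22 + 13C + C²); fitting the binned observed decay to
this curve by least squares yields ρ̂.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .qc import AnalysisMatrix


def pairwise_r2(
    matrix: AnalysisMatrix, maf_min: float = 0.10, max_dist: int = 500_000
) -> pd.DataFrame:
    """r² for all within-chromosome SNP pairs with MAF >= ``maf_min``.

    Multi-allelic sites are reduced to major-allele-vs-rest (flagged in the
    output).  Returns columns distance, r2, multiallelic.
    """
    frames = []
    n = matrix.n_samples
    for chrom in matrix.chrom_names:
        on = matrix.snp_index(chrom)
        if on.size < 2:
            continue
        calls = matrix.calls[:, on]
        pos = matrix.pos[on]
        kmax = int(calls.max()) + 1
        counts = np.stack([(calls == a).sum(axis=0) for a in range(kmax)], axis=1)
        major = counts.argmax(axis=1)  # ties -> lowest allele index
        multi = (counts > 0).sum(axis=1) > 2
        x = (calls != major[None, :]).astype(np.float64)
        p = x.mean(axis=0)
        keep = np.minimum(p, 1 - p) >= maf_min
        if keep.sum() < 2:
            continue
        x, p, pos, multi = x[:, keep], p[keep], pos[keep], multi[keep]
        xc = x - p[None, :]
        sd = np.sqrt(p * (1 - p))
        dists, r2s, flags = [], [], []
        # banded evaluation: only partners within max_dist of each focal SNP
        jmax = np.searchsorted(pos, pos + max_dist, side="right")
        for i in range(pos.size - 1):
            hi = jmax[i]
            if hi <= i + 1:
                continue
            cov = xc[:, i] @ xc[:, i + 1 : hi] / n
            r2 = (cov / (sd[i] * sd[i + 1 : hi])) ** 2
            dists.append(pos[i + 1 : hi] - pos[i])
            r2s.append(np.clip(r2, 0.0, 1.0))
            flags.append(multi[i + 1 : hi] | multi[i])
        if dists:
            frames.append(
                pd.DataFrame(
                    {
                        "distance": np.concatenate(dists),
                        "r2": np.concatenate(r2s),
                        "multiallelic": np.concatenate(flags),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["distance", "r2", "multiallelic"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class LDDecay:
    """Mean r² in non-overlapping distance bins."""

    table: pd.DataFrame  # columns: bin_start, bin_end, midpoint, mean_r2, n_pairs


def bin_ld_decay(pairs: pd.DataFrame, bin_size: int = 1000) -> LDDecay:
    """Bin pair distances into non-overlapping ``bin_size`` bins, half-open."""
    if len(pairs) == 0:
        raise ValueError("no SNP pairs to bin")
    b = (pairs["distance"].to_numpy() // bin_size).astype(np.int64)
    df = pd.DataFrame({"bin": b, "r2": pairs["r2"].to_numpy()})
    g = df.groupby("bin")["r2"].agg(["mean", "count"]).reset_index()
    return LDDecay(
        pd.DataFrame(
            {
                "bin_start": g["bin"] * bin_size,
                "bin_end": (g["bin"] + 1) * bin_size,
                "midpoint": (g["bin"] + 0.5) * bin_size,
                "mean_r2": g["mean"],
                "n_pairs": g["count"],
            }
        )
    )


def expected_r2(C, n: int | None = None):
    """Expected r² at scaled recombination distance C = ρ·d.

    σd²(C) = (10 + C)/(22 + 13C + C²).  With ``n`` given, adds the 1/n
    finite-sample term (off by default).
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    sigma = (10.0 + C) / (22.0 + 13.0 * C + C**2)
    if n is not None:
        sigma = sigma + 1.0 / n
    out = sigma if sigma.shape else float(sigma)
    return out


@dataclass
class RhoEstimate:
    rho: float  # 4Nr per bp
    fit_min: int
    fit_max: int
    rss: float
    n_pairs: int
    n_bins: int


def estimate_rho(
    decay: LDDecay,
    fit_min: int = 1000,
    fit_max: int = 100_000,
    weighted: bool = True,
    n: int | None = None,
) -> RhoEstimate:
    """Least-squares fit of σd²(ρ·midpoint) to the binned decay over [fit_min, fit_max].

    Bins are weighted by pair count (``weighted=False`` for a plain fit); the
    1-D minimisation is over log ρ, bounded, ρ >= 0.
    """
    t = decay.table
    sel = (t["bin_start"] >= fit_min) & (t["bin_end"] <= fit_max)
    sub = t[sel]
    if len(sub) < 3:
        raise ValueError("need at least 3 bins inside the fit range")
    mid = sub["midpoint"].to_numpy()
    obs = sub["mean_r2"].to_numpy()
    w = sub["n_pairs"].to_numpy().astype(float) if weighted else np.ones(len(sub))

    def obj(log10_rho: float) -> float:
        rho = 10.0**log10_rho
        return float((w * (obs - expected_r2(rho * mid, n=n)) ** 2).sum())

    res = minimize_scalar(
        obj, bounds=(-9.0, 0.0), method="bounded", options={"xatol": 1e-10, "maxiter": 2000}
    )
    rho = 10.0**res.x
    return RhoEstimate(
        rho=float(rho),
        fit_min=fit_min,
        fit_max=fit_max,
        rss=float(res.fun),
        n_pairs=int(sub["n_pairs"].sum()),
        n_bins=int(len(sub)),
    )
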