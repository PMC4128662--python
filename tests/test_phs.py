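"""Genetic-map fitting, identity tracts, and the PHS statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial import Polynomial

from haplopop.io import MarkerTable
from haplopop.phs import (
    GeneticMap,
    fit_genetic_map,
    pair_tract_moments,
    pairwise_identity_tracts,
    phs_scan,
    phs_statistic,
    _ScanState,
)
from tests.conftest import make_analysis_matrix


def _markers(chrom, bps, cms):
    return MarkerTable(pd.DataFrame({"chrom": chrom, "bp": bps, "cM": cms}))


def linear_map(chrom="chr1", slope=1.0, length=1000):
    return GeneticMap.from_polynomials({chrom: (Polynomial([0.0, slope]), 0.0, float(length))})


class TestGeneticMap:
    def test_linear_markers_reproduced(self):
        bps = np.array([0, 10_000, 40_000, 70_000, 100_000, 130_000], dtype=float)
        cms = bps * 2e-4
        gmap = fit_genetic_map(_markers("c", bps, cms))
        assert gmap.evaluate("c", bps) == pytest.approx(cms, abs=1e-9)

    def test_five_markers_interpolated_exactly(self):
        bps = np.array([0, 25_000, 50_000, 75_000, 100_000], dtype=float)
        poly = Polynomial([0.0, 3e-4, 0.0, 0.0, 1e-21])
        cms = poly(bps)
        gmap = fit_genetic_map(_markers("c", bps, cms))
        assert gmap.evaluate("c", bps) == pytest.approx(cms, abs=1e-9)

    def test_clamped_outside_marker_range(self):
        bps = np.array([10_000, 20_000, 40_000, 60_000, 80_000], dtype=float)
        cms = bps * 1e-4
        gmap = fit_genetic_map(_markers("c", bps, cms))
        assert gmap.evaluate("c", 0) == pytest.approx(gmap.evaluate("c", 10_000))
        assert gmap.evaluate("c", -5_000) == pytest.approx(gmap.evaluate("c", 10_000))
        assert gmap.evaluate("c", 1e6) == pytest.approx(gmap.evaluate("c", 80_000))

    def test_nonmonotone_fit_repaired(self):
        rng = np.random.default_rng(0)
        bps = np.linspace(0, 100_000, 12)
        cms = np.sin(bps / 8000.0) * 10 + 12  # forces a wiggly quartic
        gmap = fit_genetic_map(_markers("c", bps, cms))
        grid = np.linspace(0, 100_000, 500)
        vals = gmap.evaluate("c", grid)
        assert (np.diff(vals) >= -1e-9).all()
        assert gmap.maps["c"].repaired

    def test_too_few_markers_rejected(self):
        with pytest.raises(ValueError, match="markers"):
            fit_genetic_map(_markers("c", [0.0, 1.0, 2.0, 3.0], [0, 1, 2, 3]))


class TestIdentityTracts:
    def test_identical_pair_spans_chromosome(self):
        am = make_analysis_matrix(
            np.array([[0, 0], [0, 0], [1, 1]]), pos=np.array([100, 200]), chrom_len=1000
        )
        tracts = pairwise_identity_tracts(am, (0, 1), linear_map(), chrom_lengths={"chr1": 1000})
        assert len(tracts) == 1
        assert (tracts[0].start, tracts[0].end) == (0, 1000)
        assert tracts[0].genetic_length == pytest.approx(1000.0)

    def test_boundaries_at_flanking_discordant_sites(self):
        am = make_analysis_matrix(
            np.array([[0, 0], [1, 1]]), pos=np.array([100, 200]), chrom_len=1000
        )
        tracts = pairwise_identity_tracts(am, (0, 1), linear_map(), chrom_lengths={"chr1": 1000})
        spans = [(t.start, t.end) for t in tracts]
        assert spans == [(0, 100), (100, 200), (200, 1000)]

    def test_missing_cluster_terminates(self):
        am = make_analysis_matrix(
            np.array([[0], [1]]), pos=np.array([100]), chrom_len=100_000
        )
        # callable everywhere except a 35 kb hole
        am.callable["chr1"] = np.array([[0, 40_000], [75_000, 100_000]])
        gmap = linear_map(length=100_000)
        tracts = pairwise_identity_tracts(
            am, (0, 1), gmap, miss_cluster_bp=30_000, chrom_lengths={"chr1": 100_000}
        )
        spans = [(t.start, t.end) for t in tracts]
        assert (40_000, 75_000) not in spans
        assert spans == [(0, 100), (100, 40_000), (75_000, 100_000)]

    def test_small_gap_does_not_terminate(self):
        am = make_analysis_matrix(np.array([[0], [1]]), pos=np.array([100]), chrom_len=100_000)
        am.callable["chr1"] = np.array([[0, 40_000], [60_000, 100_000]])  # 20 kb < 30 kb
        tracts = pairwise_identity_tracts(
            am, (0, 1), linear_map(length=100_000), chrom_lengths={"chr1": 100_000}
        )
        assert [(t.start, t.end) for t in tracts] == [(0, 100), (100, 100_000)]


class TestPairMoments:
    def test_mean_and_population_sd(self):
        mean, sd = pair_tract_moments(np.array([1.0, 3.0]))
        assert (mean, sd) == (2.0, 1.0)

    def test_single_tract_rejected(self):
        with pytest.raises(ValueError):
            pair_tract_moments(np.array([2.0]))

    def test_clone_pair_z_forced_zero(self):
        calls = np.array([[0, 0], [0, 0], [1, 0], [0, 1]])
        am = make_analysis_matrix(calls, pos=np.array([100, 200]), chrom_len=1000)
        state = _ScanState(am, linear_map(), chrom_lengths={"chr1": 1000})
        m = state.moments
        clone = (m.pair_i == 0) & (m.pair_j == 1)
        assert m.degenerate[clone].all()
        Z = state.z_matrix("chr1", np.array([100, 200]))
        assert (Z[clone] == 0).all()


# --- naive independent reimplementation --------------------------------------


def naive_phs(am, gmap, chrom, x, allele_idx, miss_cluster_bp=30_000, chrom_lengths=None):
    n = am.n_samples
    pairs = list(itertools.combinations(range(n), 2))

    def chrom_setup(c):
        iv = am.callable[c]
        L = (chrom_lengths or {}).get(c) or int(iv[-1, 1])
        gaps = []
        for k in range(iv.shape[0] - 1):
            if iv[k + 1, 0] - iv[k, 1] >= miss_cluster_bp:
                gaps.append((int(iv[k, 1]), int(iv[k + 1, 0])))
        return L, gaps

    def pair_tracts(i, j):
        lengths = []
        per_chrom = {}
        for c in am.chrom_names:
            L, gaps = chrom_setup(c)
            on = np.flatnonzero(am.chrom == c)
            disc = sorted(am.pos[on][am.calls[i, on] != am.calls[j, on]].tolist())
            cuts = sorted({0, L, *[g[0] for g in gaps], *[g[1] for g in gaps], *disc})
            gapset = set(gaps)
            tr = []
            for a, b in zip(cuts[:-1], cuts[1:]):
                if (a, b) in gapset:
                    continue
                tr.append((a, b, float(gmap.evaluate(c, b) - gmap.evaluate(c, a))))
            per_chrom[c] = (tr, set(disc))
            lengths.extend(t[2] for t in tr)
        return per_chrom, np.array(lengths)

    Z = {}
    for i, j in pairs:
        per_chrom, lengths = pair_tracts(i, j)
        if lengths.size < 2 or lengths.std() == 0:
            Z[(i, j)] = 0.0
            continue
        tr, disc = per_chrom[chrom]
        if x in disc:
            d = 0.0
        else:
            d = next(t[2] for t in tr if t[0] <= x < t[1])
        Z[(i, j)] = (d - lengths.mean()) / lengths.std()

    col = np.flatnonzero((am.chrom == chrom) & (am.pos == x))[0]
    carriers = set(np.flatnonzero(am.calls[:, col] == allele_idx).tolist())
    carrier_pairs = [p for p in pairs if set(p) <= carriers]
    nA = len(carriers)
    return sum(Z[p] for p in carrier_pairs) / (nA * (nA - 1) / 2) - sum(Z.values()) / len(pairs)


class TestPHSStatistic:
    def test_equal_z_cancellation(self):
        calls = np.array([[0], [0], [1], [1]])
        am = make_analysis_matrix(calls, pos=np.array([50]), chrom_len=100)
        v = phs_statistic(am, linear_map(length=100), "chr1", 50, 0)
        assert v == pytest.approx(0.0)

    def test_long_shared_carrier_haplotype_positive(self):
        rng = np.random.default_rng(8)
        S = 60
        pos = np.sort(rng.choice(100_000, size=S, replace=False)).astype(np.int64)
        calls = rng.integers(0, 2, size=(8, S)).astype(np.int16)
        # carriers 0-3 share one haplotype over the middle half
        mid = (pos >= 25_000) & (pos < 75_000)
        calls[1:4, mid] = calls[0, mid]
        center = pos[np.searchsorted(pos, 50_000) - 1]
        col = np.flatnonzero(pos == center)[0]
        calls[:4, col] = 1
        calls[4:, col] = 0
        am = make_analysis_matrix(calls, pos=pos, chrom_len=100_000)
        gmap = linear_map(slope=3e-4, length=100_000)
        v = phs_statistic(am, gmap, "chr1", int(center), 1)
        assert v > 0

    def test_matches_naive_on_small_instances(self):
        rng = np.random.default_rng(17)
        for rep in range(6):
            n = int(rng.integers(4, 7))
            S = int(rng.integers(10, 51))
            pos = np.sort(rng.choice(200_000, size=S, replace=False)).astype(np.int64)
            calls = rng.integers(0, 2, size=(n, S)).astype(np.int16)
            am = make_analysis_matrix(calls, pos=pos, chrom_len=200_000)
            if rep % 2:  # include a >=30 kb missing cluster sometimes
                lo = int(pos[S // 2]) + 1
                am.callable["chr1"] = np.array([[0, lo], [lo + 35_000, 200_000]])
                keep = (pos < lo) | (pos >= lo + 35_000)
                am = make_analysis_matrix(calls[:, keep], pos=pos[keep], chrom_len=200_000)
                am.callable["chr1"] = np.array([[0, lo], [lo + 35_000, 200_000]])
            gmap = linear_map(slope=2e-4, length=200_000)
            state = _ScanState(am, gmap, chrom_lengths={"chr1": 200_000})
            for col in rng.choice(am.n_snps, size=5, replace=False):
                x = int(am.pos[col])
                for allele in np.unique(am.calls[:, col]):
                    if (am.calls[:, col] == allele).sum() < 2:
                        continue
                    got = phs_statistic(
                        am, gmap, "chr1", x, int(allele), state=state
                    )
                    want = naive_phs(
                        am, gmap, "chr1", x, int(allele), chrom_lengths={"chr1": 200_000}
                    )
                    assert got == pytest.approx(want, abs=1e-10)

    def test_invariant_to_constant_cm_shift(self):
        rng = np.random.default_rng(21)
        S = 30
        pos = np.sort(rng.choice(50_000, size=S, replace=False)).astype(np.int64)
        calls = rng.integers(0, 2, size=(5, S)).astype(np.int16)
        am = make_analysis_matrix(calls, pos=pos, chrom_len=50_000)
        g0 = GeneticMap.from_polynomials({"chr1": (Polynomial([0.0, 2e-4]), 0.0, 50_000.0)})
        g1 = GeneticMap.from_polynomials({"chr1": (Polynomial([7.5, 2e-4]), 0.0, 50_000.0)})
        col = S // 2
        x = int(am.pos[col])
        allele = int(am.calls[0, col])
        if (am.calls[:, col] == allele).sum() >= 2:
            a = phs_statistic(am, g0, "chr1", x, allele)
            b = phs_statistic(am, g1, "chr1", x, allele)
            assert a == pytest.approx(b, abs=1e-10)


class TestPHSScan:
    def _random_am(self, seed=2, n=8, S=80, L=100_000):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(L, size=S, replace=False)).astype(np.int64)
        calls = rng.integers(0, 2, size=(n, S)).astype(np.int16)
        # keep every site polymorphic
        for s in range(S):
            if len(set(calls[:, s])) == 1:
                calls[s % n, s] = 1 - calls[s % n, s]
        return make_analysis_matrix(calls, pos=pos, chrom_len=L)

    def test_scan_matches_statistic(self):
        am = self._random_am()
        gmap = linear_map(slope=3e-4, length=100_000)
        scan = phs_scan(am, gmap, chrom_lengths={"chr1": 100_000})
        state = _ScanState(am, gmap, chrom_lengths={"chr1": 100_000})
        sub = scan.sample(10, random_state=1)
        for row in sub.itertuples():
            col = np.flatnonzero(am.pos == row.pos)[0]
            alleles = [am.ref[col]] + list(am.alts[col])
            v = phs_statistic(am, gmap, "chr1", row.pos, alleles.index(row.allele), state=state)
            assert row.phs == pytest.approx(v, abs=1e-10)

    def test_complement_alleles_both_reported_finite(self):
        am = self._random_am(seed=5)
        gmap = linear_map(slope=3e-4, length=100_000)
        scan = phs_scan(am, gmap, chrom_lengths={"chr1": 100_000})
        by_pos = scan.groupby("pos").size()
        # biallelic sites with both alleles at >=2 carriers yield 2 records
        assert (by_pos <= 2).all() and (by_pos >= 1).all()
        assert np.isfinite(scan["phs"]).all()

    def test_candidate_count_monotone_in_top_fraction(self):
        am = self._random_am(seed=9, n=10, S=120)
        gmap = linear_map(slope=3e-4, length=100_000)
        c1 = phs_scan(am, gmap, top_fraction=0.001)["candidate"].sum()
        c2 = phs_scan(am, gmap, top_fraction=0.002)["candidate"].sum()
        c3 = phs_scan(am, gmap, top_fraction=0.05)["candidate"].sum()
        assert c1 <= c2 <= c3

    def test_global_ranking_mode(self):
        am = self._random_am(seed=13)
        gmap = linear_map(slope=3e-4, length=100_000)
        scan = phs_scan(am, gmap, top_fraction=0.05, ranking="global")
        thr = np.quantile(scan["phs"], 0.95)
        assert set(scan[scan.candidate].index) == set(scan[scan.phs >= thr].index)
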