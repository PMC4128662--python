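"""Nei–Gojobori site/difference counting and functional site classification."""

import itertools

import numpy as np
import pytest

from haplopop import sites as hs
from haplopop.io import AnnotationSet, Feature, ReferenceGenome
from tests.conftest import make_analysis_matrix


# --- independent brute-force oracle -----------------------------------------

_TABLE = dict(hs._CODON_TABLE)
_STOPS = set(hs.STOP_CODONS)


def oracle_site_counts(codon):
    syn = 0.0
    aa = _TABLE[codon]
    for i, base in enumerate(codon):
        for b in "ACGT":
            if b == base:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut not in _STOPS and _TABLE.get(mut) == aa:
                syn += 1 / 3
    return syn, 3 - syn


def oracle_pair_diffs(a, b):
    """Enumerate all orderings of the differing positions, skipping stops."""
    pos = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in itertools.permutations(pos):
        cur, syn, nonsyn, ok = a, 0, 0, True
        for i in order:
            nxt = cur[:i] + b[i] + cur[i + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _TABLE[cur] == _TABLE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:
        return len(pos) / 2, len(pos) / 2
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestCodonSiteCounts:
    @pytest.mark.parametrize(
        "codon,syn", [("ATG", 0.0), ("TTT", 1 / 3), ("TGG", 0.0), ("GGG", 1.0)]
    )
    def test_known_codons(self, codon, syn):
        s, n = hs.codon_site_counts(codon)
        assert s == pytest.approx(syn, abs=1e-12)
        assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_fourfold_plus_first_position_arginine(self):
        s, _ = hs.codon_site_counts("CGG")  # CGN box + CGG<->AGG
        assert s > 1.0

    def test_all_sense_codons_sum_to_three(self):
        for codon in hs.SENSE_CODONS:
            s, n = hs.codon_site_counts(codon)
            assert s + n == pytest.approx(3.0, abs=1e-15)
            assert 0.0 <= s <= 3.0

    def test_matches_enumeration_oracle(self):
        for codon in hs.SENSE_CODONS:
            assert hs.codon_site_counts(codon) == pytest.approx(oracle_site_counts(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            hs.codon_site_counts("TAA")


class TestCodonPairDifferences:
    @pytest.mark.parametrize(
        "a,b,syn,nonsyn",
        [
            ("TTT", "TTC", 1.0, 0.0),  # Phe->Phe
            ("TTT", "TTA", 0.0, 1.0),  # Phe->Leu
            ("TTT", "TTT", 0.0, 0.0),
        ],
    )
    def test_single_changes(self, a, b, syn, nonsyn):
        d = hs.codon_pair_differences(a, b)
        assert (d.syn_diffs, d.nonsyn_diffs) == (syn, nonsyn)

    def test_two_position_pathway_average(self):
        d = hs.codon_pair_differences("TTT", "GTA")
        assert d.syn_diffs + d.nonsyn_diffs == pytest.approx(2.0)
        assert d.n_pathways <= 2

    def test_symmetry_and_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        codons = list(hs.SENSE_CODONS)
        for _ in range(500):
            a, b = rng.choice(codons, size=2)
            d = hs.codon_pair_differences(a, b)
            d_rev = hs.codon_pair_differences(b, a)
            assert (d.syn_diffs, d.nonsyn_diffs) == pytest.approx(
                (d_rev.syn_diffs, d_rev.nonsyn_diffs)
            )
            assert (d.syn_diffs, d.nonsyn_diffs) == pytest.approx(oracle_pair_diffs(a, b))
            n_diff = sum(x != y for x, y in zip(a, b))
            assert d.syn_diffs + d.nonsyn_diffs == pytest.approx(n_diff)

    def test_stop_input_rejected(self):
        with pytest.raises(ValueError):
            hs.codon_pair_differences("TAA", "TTT")


# --- classification ----------------------------------------------------------


def _gene_annotation(chrom_len=400, strand="+"):
    """One gene: UTR5 [20,80), CDS [80,140), intron [140,200), CDS [200,260), UTR3 [260,320)."""
    feats = [
        Feature("gene", "c", 20, 320, strand, id="g1"),
        Feature("five_prime_UTR" if strand == "+" else "three_prime_UTR", "c", 20, 80, strand,
                id="u5", parent="g1"),
        Feature("CDS", "c", 80, 140, strand, id="c1", parent="g1"),
        Feature("intron", "c", 140, 200, strand, id="i1", parent="g1"),
        Feature("CDS", "c", 200, 260, strand, id="c2", parent="g1"),
        Feature("three_prime_UTR" if strand == "+" else "five_prime_UTR", "c", 260, 320, strand,
                id="u3", parent="g1"),
    ]
    return AnnotationSet(feats)


def _reference_for_gene(strand="+", chrom_len=400, motif_offset=20):
    rng = np.random.default_rng(11)
    seq = list("".join(rng.choice(list("ACGT"), size=chrom_len)))
    sense_cds = "ATG" + "GGTGCAACC" * 12 + "GGTGCAACG"  # 120 bp, no stops
    intron = list("".join(rng.choice(list("ACGT"), size=60)))
    intron[0:2] = "GT"
    intron[-2:] = "AG"
    intron[motif_offset : motif_offset + 5] = "CTAAC"
    intron = "".join(intron)
    # scrub accidental CTAAC earlier in the intron
    if strand == "+":
        seq[80:140] = sense_cds[:60]
        seq[140:200] = intron
        seq[200:260] = sense_cds[60:]
    else:
        rc = lambda s: s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        # genomic order for a minus-strand gene: CDS2' = start of sense
        seq[200:260] = rc(sense_cds[:60])
        seq[140:200] = rc(intron)
        seq[80:140] = rc(sense_cds[60:])
    return ReferenceGenome(["c"], ["".join(seq)])


class TestClassifySites:
    def _classify(self, strand="+"):
        ref = _reference_for_gene(strand)
        ann = _gene_annotation(strand=strand)
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 390]), chrom="c", chrom_len=400
        )
        return hs.classify_sites(ann, ref, am), ref

    def test_classes_cover_and_are_exclusive(self):
        cmap, _ = self._classify()
        cls = cmap.classes["c"]
        assert cls.shape == (400,)
        # outside any feature -> intergenic
        assert cls[10] == hs.INTERGENIC and cls[390] == hs.INTERGENIC
        # UTRs painted
        assert (cls[20:80] == hs.UTR5).all()
        assert (cls[260:320] == hs.UTR3).all()

    def test_intron_restricted_to_branchpoint_window(self):
        cmap, _ = self._classify()
        cls = cmap.classes["c"]
        # intron [140,200), motif at offset 20: usable sense offsets 7..19
        assert (cls[147:160] == hs.INTRON).all()
        assert (cls[140:147] != hs.INTRON).all()
        assert (cls[160:200] != hs.INTRON).all()

    def test_minus_strand_intron_window_mirrored(self):
        cmap, _ = self._classify(strand="-")
        cls = cmap.classes["c"]
        # sense offset o maps to genomic end-1-o: offsets 7..19 -> 180..192
        assert (cls[181:193] == hs.INTRON).all()
        assert (cls[193:200] != hs.INTRON).all()

    def test_cds_fractions_defined_and_in_range(self):
        cmap, _ = self._classify()
        sf = cmap.syn_frac["c"]
        cds = np.r_[80:140, 200:260]
        assert np.isfinite(sf[cds]).all()
        assert ((sf[cds] >= 0) & (sf[cds] <= 1)).all()
        assert "g1" in cmap.gene_codons

    def test_minus_strand_cds_fractions_match_plus(self):
        cmap_p, _ = self._classify("+")
        cmap_m, _ = self._classify("-")
        # same sense CDS, so sorted per-codon fractions must agree
        sp = np.sort(cmap_p.syn_frac["c"][np.r_[80:140, 200:260]])
        sm = np.sort(cmap_m.syn_frac["c"][np.r_[80:140, 200:260]])
        assert sp == pytest.approx(sm)

    def test_short_element_excluded(self):
        ref = _reference_for_gene()
        ann = AnnotationSet([Feature("five_prime_UTR", "c", 50, 95, "+", id="u")])
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 390]), chrom="c", chrom_len=400
        )
        cmap = hs.classify_sites(ann, ref, am)
        assert (cmap.classes["c"][50:95] != hs.UTR5).all()  # 45 bp < 50 called

    def test_trna_and_pseudogene_excluded_not_intergenic(self):
        ref = _reference_for_gene()
        ann = AnnotationSet(
            [
                Feature("tRNA", "c", 50, 120, "+", id="t"),
                Feature("pseudogene", "c", 200, 280, "+", id="p"),
            ]
        )
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 390]), chrom="c", chrom_len=400
        )
        cmap = hs.classify_sites(ann, ref, am)
        assert (cmap.classes["c"][50:120] == hs.EXCLUDED).all()
        assert (cmap.classes["c"][200:280] == hs.EXCLUDED).all()

    def test_strict_intergenic_flank(self):
        ref = _reference_for_gene()
        ann = _gene_annotation()
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 390]), chrom="c", chrom_len=400
        )
        cmap = hs.classify_sites(ann, ref, am, strict_intergenic_flank=500)
        assert (cmap.classes["c"] != hs.INTERGENIC).all()

    def test_cds_not_multiple_of_three_warns_and_excludes(self):
        ref = _reference_for_gene()
        ann = AnnotationSet(
            [
                Feature("gene", "c", 80, 141, "+", id="g"),
                Feature("CDS", "c", 80, 141, "+", id="cd", parent="g"),
            ]
        )
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 390]), chrom="c", chrom_len=400
        )
        with pytest.warns(UserWarning, match="divisible"):
            cmap = hs.classify_sites(ann, ref, am)
        assert "g" not in cmap.gene_codons

    def test_noncallable_positions_excluded(self):
        from haplopop.qc import AnalysisMatrix

        ref = _reference_for_gene()
        ann = _gene_annotation()
        am = make_analysis_matrix(
            np.array([[0, 1], [1, 0]]), pos=np.array([10, 30]), chrom="c", chrom_len=400
        )
        am.callable["c"] = np.array([[0, 350]])  # tail not callable
        cmap = hs.classify_sites(ann, ref, am)
        assert (cmap.classes["c"][350:] == hs.EXCLUDED).all()
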