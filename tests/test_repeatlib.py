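import numpy as np
import pytest
from scipy import stats

from cenevol import repeatlib
from cenevol.repeatlib import (CentromereRegion, SatelliteMonomer,
                               SimilarityRecord)


def _mk_monomer(i, seq, chrom="1", start=1):
    return SatelliteMonomer(id=f"m{i}", strain="s", chromosome=chrom,
                            start=start, end=start + len(seq) - 1,
                            strand="+", sequence=seq)


class TestMonomerSimilarity:
    def test_identical(self):
        assert repeatlib.monomer_similarity("ACGTACGT", "ACGTACGT") == 1.0

    def test_one_mismatch(self):
        # 7 matched bases over min length 8
        assert repeatlib.monomer_similarity("ACGTACGT", "ACGTACTT") == 7 / 8

    def test_shorter_length_denominator(self):
        # perfect prefix: 6 matches / min(6, 12) = 1.0
        assert repeatlib.monomer_similarity("ACGTAC", "ACGTACGTACGT") == 1.0

    def test_symmetric(self):
        a, b = "ACGTTGCAACGT", "ACGTGCATACG"
        assert repeatlib.monomer_similarity(a, b) == \
            repeatlib.monomer_similarity(b, a)

    def test_range(self, rng):
        for _ in range(20):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
            s = repeatlib.monomer_similarity(a, b)
            assert 0.0 <= s <= 1.0

    def test_empty_operand_named(self):
        with pytest.raises(ValueError, match="first operand"):
            repeatlib.monomer_similarity("", "ACGT")
        with pytest.raises(ValueError, match="second operand"):
            repeatlib.monomer_similarity("ACGT", "")


class TestDecompose:
    def test_exact_tandem(self):
        template = "ACGTTACG"
        region = template * 10
        tiles = repeatlib.decompose_array(region, template)
        assert len(tiles) == 10
        assert all(e - s == 8 for s, e in tiles)

    def test_phase_offset_recovered(self):
        template = "ACGTTACGGA"
        region = template[4:] + template * 8
        tiles = repeatlib.decompose_array(region, template)
        full = [t for t in tiles if t[1] - t[0] == len(template)]
        assert len(full) >= 8
        assert full[0][0] == 6  # remaining partial head

    def test_partial_tail_kept_at_half(self):
        template = "ACGTACGTAC"  # length 10
        region = template * 3 + template[:5]
        tiles = repeatlib.decompose_array(region, template, min_fraction=0.5)
        assert tiles[-1] == (30, 35)

    def test_partial_tail_dropped_below_half(self):
        template = "ACGTACGTAC"
        region = template * 3 + template[:4]
        tiles = repeatlib.decompose_array(region, template, min_fraction=0.5)
        assert tiles[-1] == (20, 30)


class TestClustering:
    def test_threshold_boundary_joins_at_exact(self):
        base = "ACGTTGCAAC" * 4  # 40 bp
        # similarity exactly 0.90: 36 matches / 40
        variant = list(base)
        for i in range(4):
            variant[10 * i] = "T" if base[10 * i] != "T" else "A"
        variant = "".join(variant)
        mons = [_mk_monomer(0, base), _mk_monomer(1, variant)]
        assert repeatlib.monomer_similarity(base, variant) == 0.9
        clusters = repeatlib.cluster_monomers(mons, similarity_threshold=0.90)
        assert len(clusters) == 1

    def test_distinct_sequences_split(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        clusters = repeatlib.cluster_monomers(
            [_mk_monomer(0, a), _mk_monomer(1, b)])
        assert len(clusters) == 2

    def test_representative_only_above_ten_members(self):
        seq = "ACGTTGCAACGTTGCAACGT"
        for n, has_rep in ((10, False), (11, True)):
            mons = [_mk_monomer(i, seq) for i in range(n)]
            (cl,) = repeatlib.cluster_monomers(mons)
            assert (cl.representative is not None) == has_rep
            assert cl.size == n

    def test_representative_is_longest(self):
        long = "ACGTTGCAAC" * 5
        short = long[:-3]
        mons = [_mk_monomer(i, short) for i in range(10)] + [_mk_monomer(10, long)]
        (cl,) = repeatlib.cluster_monomers(mons)
        assert cl.representative == "m10"

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            repeatlib.cluster_monomers([], similarity_threshold=0.0)


class TestAssociations:
    def test_category_mapping(self):
        assert repeatlib._category("acro", "acro") == "AcroAcro"
        assert repeatlib._category("acro", "nonacro") == "AcroNonAcro"
        assert repeatlib._category("nonacro", "acro") == "AcroNonAcro"
        assert repeatlib._category("nonacro", "nonacro") == "NonAcroNonAcro"

    def test_best_match_is_cross_chromosome(self, rng):
        seqs = {}
        clusters = {}
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        for ci, chrom in enumerate("123"):
            s = list(base)
            for j in range(ci * 2):
                s[j * 7] = "ACGT"[(ci + j) % 4]
            seqs[f"rep{chrom}"] = "".join(s)
            clusters[chrom] = [repeatlib.MonomerCluster(
                id="cl0", members=[], representative=f"rep{chrom}", size=20)]
        records = repeatlib.best_match_associations(
            clusters, seqs, classes={"1": "acro", "2": "acro", "3": "nonacro"})
        assert len(records) == 3
        for r in records:
            ca = r.cluster_a.split("/")[0]
            cb = r.cluster_b.split("/")[0]
            assert ca != cb

    def test_single_chromosome_rejected(self):
        clusters = {"1": [repeatlib.MonomerCluster("cl0", [], "r", 20)]}
        with pytest.raises(ValueError):
            repeatlib.best_match_associations(clusters, {"r": "ACGT" * 10},
                                              {"1": "acro"})


class TestGroupComparison:
    def test_exact_p_matches_enumeration(self):
        # 3 vs 3 fully separated: one-sided exact rank-sum p = 1/C(6,3) = 0.05
        records = (
            [SimilarityRecord("a", "b", 0.5 + 0.01 * i, "NonAcroNonAcro")
             for i in range(3)]
            + [SimilarityRecord("c", "d", 0.9 + 0.01 * i, "AcroAcro")
               for i in range(3)]
            + [SimilarityRecord("e", "f", 0.8 + 0.01 * i, "AcroNonAcro")
               for i in range(3)])
        res = repeatlib.compare_similarity_groups(records)
        assert res["p_values"]["NonAcroNonAcro<AcroAcro"] == pytest.approx(0.05)
        assert res["medians"]["NonAcroNonAcro"] == pytest.approx(0.51)

    def test_agrees_with_scipy(self, rng):
        lo = rng.uniform(0.4, 0.7, 8)
        hi = rng.uniform(0.6, 0.95, 9)
        records = ([SimilarityRecord("a", "b", v, "NonAcroNonAcro") for v in lo]
                   + [SimilarityRecord("c", "d", v, "AcroAcro") for v in hi]
                   + [SimilarityRecord("e", "f", v, "AcroNonAcro") for v in hi])
        res = repeatlib.compare_similarity_groups(records)
        expect = stats.mannwhitneyu(lo, hi, alternative="less",
                                    method="exact").pvalue
        assert res["p_values"]["NonAcroNonAcro<AcroAcro"] == pytest.approx(expect)

    def test_too_few_records_rejected(self):
        records = [SimilarityRecord("a", "b", 0.5, "NonAcroNonAcro")]
        with pytest.raises(ValueError):
            repeatlib.compare_similarity_groups(records)


class TestRepresentativeScore:
    def test_clean_two_region_score(self, rng):
        mono = rng.integers(0, 4, 150).astype(np.uint8)
        regions = []
        for _ in range(2):
            r = rng.integers(0, 4, 4000).astype(np.uint8)
            r[1000:1150] = mono
            regions.append(r)
        score = repeatlib.representative_score(mono, regions)
        assert score == pytest.approx(2.0, abs=0.05)


class TestSatelliteFraction:
    def test_filters_strict(self, rng):
        mono = rng.integers(0, 4, 100).astype(np.uint8)
        good = np.tile(mono, 15)  # 1500 bp of pure satellite
        reads = [
            (good, 15.0),            # passes
            (good, 10.0),            # fails: qv not > 10
            (good[:1000], 15.0),     # fails: length not > 1000
        ]
        res = repeatlib.satellite_fraction(reads, mono, min_length=1000,
                                           min_qv=10)
        # only the first read passes both strict filters and is pure satellite
        assert res > 0.9

    def test_no_reads_pass(self):
        with pytest.raises(ValueError, match="no reads pass filters"):
            repeatlib.satellite_fraction([(np.zeros(10, np.uint8), 5.0)],
                                         np.zeros(5, np.uint8))


class TestTelomericRepeats:
    def test_forward_array_found(self):
        seq = "ACGT" * 10 + "TTAGGG" * 5 + "ACGT" * 10
        hits = repeatlib.find_telomeric_repeats(seq, min_copies=3)
        assert len(hits) == 1
        start, end, strand, copies = hits[0]
        assert (start, end) == (41, 70)  # 1-based closed
        assert strand == "+"
        assert copies == 5

    def test_reverse_complement_found(self):
        seq = "ACGT" * 10 + "CCCTAA" * 4 + "ACGT" * 10
        hits = repeatlib.find_telomeric_repeats(seq, min_copies=3)
        assert len(hits) == 1
        assert hits[0][2] == "-"

    def test_below_min_copies_ignored(self):
        seq = "ACGT" * 10 + "TTAGGG" * 2 + "ACGT" * 10
        assert repeatlib.find_telomeric_repeats(seq, min_copies=3) == []


class TestPositionClass:
    def test_acro_near_start(self):
        assert repeatlib.classify_centromere_position(
            1_000, 50_000, 1_000_000) == "acro"

    def test_acro_near_end(self):
        assert repeatlib.classify_centromere_position(
            960_000, 990_000, 1_000_000) == "acro"

    def test_interior_nonacro(self):
        assert repeatlib.classify_centromere_position(
            400_000, 500_000, 1_000_000) == "nonacro"

    def test_boundary_inclusive(self):
        # midpoint exactly at 15% of the length counts as acrocentric
        assert repeatlib.classify_centromere_position(
            100_000, 200_000, 1_000_000) == "acro"


class TestFamilyTree:
    def test_matches_scipy_ward(self, rng):
        from scipy.cluster import hierarchy as sch
        from scipy.spatial.distance import squareform

        reps = {}
        for i in range(5):
            reps[f"r{i}"] = "".join("ACGT"[j]
                                    for j in rng.integers(0, 4, 60))
        labels, Z = repeatlib.family_tree(reps)
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = 1 - repeatlib.monomer_similarity(
                    reps[labels[i]], reps[labels[j]])
        expect = sch.linkage(squareform(D, checks=False), method="ward")
        assert np.allclose(Z, expect)

    def test_cut_tree_sizes(self, rng):
        reps = {f"r{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 50))
                for i in range(6)}
        labels, Z = repeatlib.family_tree(reps)
        groups = repeatlib.cut_tree(Z, 3)
        assert len(set(groups)) == 3
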