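import numpy as np
import pytest

from cenevol import align, svkit
from cenevol.svkit import AlignmentChain, LocalAlignment, SVEvent


def _aln(qs, qe, ts, te, strand="+", score=100.0, identity=1.0):
    return LocalAlignment(query="q", qstart=qs, qend=qe, target="t",
                          tstart=ts, tend=te, strand=strand,
                          identity=identity, score=score)


class TestTypes:
    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            _aln(10, 5, 1, 6)

    def test_chain_overlap_rejected(self):
        with pytest.raises(ValueError):
            AlignmentChain([_aln(1, 100, 1, 100), _aln(90, 200, 101, 211)],
                           score=0.0, strand="+")

    def test_event_size_positive(self):
        with pytest.raises(ValueError):
            SVEvent(type="indel", carrier=None, chrom="1",
                    pos_query=1, pos_target=1, size=0)


class TestReciprocalBest:
    def test_mutual_best_kept(self):
        scores = {("a1", "b1"): 10, ("a1", "b2"): 5,
                  ("a2", "b2"): 8, ("a2", "b1"): 3}
        assert svkit.reciprocal_best_pairs(scores) == [("a1", "b1"),
                                                       ("a2", "b2")]

    def test_one_sided_best_dropped(self):
        scores = {("a1", "b1"): 10, ("a2", "b1"): 12}
        assert svkit.reciprocal_best_pairs(scores) == [("a2", "b1")]

    def test_tie_poisons_both(self):
        scores = {("a1", "b1"): 10, ("a1", "b2"): 10}
        assert svkit.reciprocal_best_pairs(scores) == []


class TestChaining:
    def test_single_alignment(self):
        chain = svkit.chain_alignments([_aln(1, 100, 1, 100)])
        assert len(chain.members) == 1
        assert chain.score == 100.0

    def test_colinear_pair_joined(self):
        a = _aln(1, 100, 1, 100)
        b = _aln(201, 300, 201, 300)
        chain = svkit.chain_alignments([a, b])
        assert len(chain.members) == 2
        # penalty 0.01 * (100 + 100)
        assert chain.score == pytest.approx(200 - 2.0)

    def test_crossing_alignment_excluded(self):
        a = _aln(1, 100, 1, 100)
        bad = _aln(150, 250, 10, 110, score=50.0)  # target goes backwards
        good = _aln(150, 250, 150, 250, score=80.0)
        chain = svkit.chain_alignments([a, bad, good])
        assert [m.qstart for m in chain.members] == [1, 150]
        assert chain.members[1].tstart == 150

    def test_strands_chained_separately(self):
        plus = [_aln(1, 100, 1, 100), _aln(101, 200, 101, 200)]
        minus = [_aln(300, 400, 900, 1000, strand="-", score=10.0)]
        chains = svkit.chain_per_strand(plus + minus)
        assert set(chains) == {"+", "-"}
        assert svkit.chain_alignments(plus + minus).strand == "+"

    def test_micro_overlap_trimmed_to_disjoint(self):
        a = _aln(1, 100, 1, 100)
        b = _aln(91, 200, 91, 200)   # 10-bp seed overlap
        chain = svkit.chain_alignments([a, b])
        assert chain.members[1].qstart == 101
        assert chain.members[1].tstart == 101

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            svkit.chain_alignments([])


class TestCallSVs:
    def test_query_gap_insertion_candidate(self):
        # 5 kb extra on the query, none on target
        chain = AlignmentChain([_aln(1, 1000, 1, 1000),
                                _aln(6001, 7000, 1001, 2000)],
                               score=0.0, strand="+")
        (ev,) = svkit.call_svs(chain)
        assert ev.type == "indel"
        assert ev.extra_in == "query"
        assert ev.size == 5000
        assert ev.pos_query == 1001
        assert ev.pos_target == 1001
        assert ev.size_class == "mid"

    def test_target_gap_candidate(self):
        chain = AlignmentChain([_aln(1, 1000, 1, 1000),
                                _aln(1001, 2000, 4001, 5000)],
                               score=0.0, strand="+")
        (ev,) = svkit.call_svs(chain)
        assert ev.extra_in == "target"
        assert ev.size == 3000
        assert ev.pos_target == 1001

    def test_below_threshold_ignored(self):
        chain = AlignmentChain([_aln(1, 1000, 1, 1000),
                                _aln(1901, 3000, 1001, 2100)],
                               score=0.0, strand="+")
        assert svkit.call_svs(chain) == []   # 900 < 1000

    def test_large_size_class(self):
        chain = AlignmentChain([_aln(1, 1000, 1, 1000),
                                _aln(61001, 62000, 1001, 2000)],
                               score=0.0, strand="+")
        (ev,) = svkit.call_svs(chain)
        assert ev.size_class == "large"

    def test_inversion_from_opposite_strand_block(self):
        chain = AlignmentChain([_aln(1, 1000, 1, 1000),
                                _aln(3001, 4000, 3001, 4000)],
                               score=0.0, strand="+")
        inv = _aln(1200, 2800, 1200, 2800, strand="-")
        evs = svkit.call_svs(chain, alignments=chain.members + [inv])
        types = [e.type for e in evs]
        assert types == ["inversion"]
        assert evs[0].size == 1601


class TestEndToEnd:
    def test_self_comparison_no_events(self, rng):
        s = rng.integers(0, 4, 100_000).astype(np.uint8)
        events = svkit.compare_pair_with_outgroup(s, s, s, chrom="1")
        assert events == []

    def test_planted_insertion_polarized(self, rng):
        anc = rng.integers(0, 4, 120_000).astype(np.uint8)
        ins = rng.integers(0, 4, 4_000).astype(np.uint8)
        a = np.concatenate([anc[:60_000], ins, anc[60_000:]])
        events = svkit.compare_pair_with_outgroup(a, anc, anc, chrom="1",
                                                  strain_a="A", strain_b="B")
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "insertion"
        assert ev.carrier == "A"
        assert abs(ev.size - 4_000) <= 50
        assert abs(ev.pos_query - 60_001) <= 50

    def test_planted_deletion_polarized(self, rng):
        anc = rng.integers(0, 4, 120_000).astype(np.uint8)
        b = np.concatenate([anc[:50_000], anc[56_000:]])  # B lost 6 kb
        events = svkit.compare_pair_with_outgroup(anc, b, anc, chrom="1",
                                                  strain_a="A", strain_b="B")
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "deletion"
        assert ev.carrier == "B"
        assert abs(ev.size - 6_000) <= 50

    def test_swap_antisymmetry(self, rng):
        anc = rng.integers(0, 4, 120_000).astype(np.uint8)
        ins = rng.integers(0, 4, 3_000).astype(np.uint8)
        a = np.concatenate([anc[:70_000], ins, anc[70_000:]])
        fwd = svkit.compare_pair_with_outgroup(a, anc, anc,
                                               strain_a="A", strain_b="B")
        rev = svkit.compare_pair_with_outgroup(anc, a, anc,
                                               strain_a="B", strain_b="A")
        assert [(e.type, e.carrier) for e in fwd] == \
            [(e.type, e.carrier) for e in rev]

    def test_planted_inversion_detected(self, rng):
        anc = rng.integers(0, 4, 120_000).astype(np.uint8)
        b = anc.copy()
        b[60_000:63_000] = align.revcomp(anc[60_000:63_000])
        events = svkit.compare_pair_with_outgroup(anc, b, anc, chrom="1")
        assert [e.type for e in events] == ["inversion"]
        assert abs(events[0].size - 3_000) <= 100

    def test_tandem_duplication_classified(self, rng):
        anc = rng.integers(0, 4, 120_000).astype(np.uint8)
        unit = anc[60_000:64_000].copy()
        # second copy diverged 2% so it is not collapsed by the aligner
        mut = rng.random(unit.size) < 0.02
        unit[mut] = (unit[mut] + 1) % 4
        a = np.concatenate([anc[:64_000], unit, anc[64_000:]])
        events = svkit.compare_pair_with_outgroup(a, anc, anc, chrom="1")
        assert len(events) == 1
        assert events[0].type == "duplication"


class TestMechanism:
    def test_planted_nahr(self, rng):
        rep = rng.integers(0, 4, 200).astype(np.uint8)
        left = rng.integers(0, 4, 2_000).astype(np.uint8)
        mid = rng.integers(0, 4, 3_000).astype(np.uint8)
        right = rng.integers(0, 4, 2_000).astype(np.uint8)
        # identical repeat copies sit just outside both breakpoints
        seq = np.concatenate([left, rep, mid, rep, right])
        start = left.size + rep.size + 1
        end = left.size + rep.size + mid.size
        assert svkit.classify_mechanism(seq, start, end) == "NAHR"

    def test_no_homology_nhej(self, rng):
        seq = rng.integers(0, 4, 8_000).astype(np.uint8)
        assert svkit.classify_mechanism(seq, 3_001, 5_000) == "NHEJ"

    def test_truncated_flank_unclassified(self, rng):
        seq = rng.integers(0, 4, 3_000).astype(np.uint8)
        assert svkit.classify_mechanism(seq, 100, 1_000) == "unclassified"


class TestPolarize:
    def test_clean_insertion_call(self, rng):
        # outgroup == lacking genome: flanks map adjacently
        lack = rng.integers(0, 4, 40_000).astype(np.uint8)
        call, dist = svkit.polarize_with_outgroup(lack, 20_000, 5_000, lack)
        assert call == "insertion"
        assert dist <= 50

    def test_clean_deletion_call(self, rng):
        og = rng.integers(0, 4, 40_000).astype(np.uint8)
        lack = np.concatenate([og[:20_000], og[25_000:]])  # lost 5 kb
        call, dist = svkit.polarize_with_outgroup(lack, 20_001, 5_000, og)
        assert call == "deletion"
        assert abs(dist - 5_000) <= 50

    def test_unmappable_flank_unclassified(self, rng):
        lack = rng.integers(0, 4, 40_000).astype(np.uint8)
        og = rng.integers(0, 4, 40_000).astype(np.uint8)
        call, dist = svkit.polarize_with_outgroup(lack, 20_000, 5_000, og)
        assert call == "unclassified"
        assert dist is None

    def test_short_flank_unclassified(self, rng):
        lack = rng.integers(0, 4, 4_000).astype(np.uint8)
        call, _ = svkit.polarize_with_outgroup(lack, 1_000, 5_000, lack)
        assert call == "unclassified"


class TestSummaryAndIO:
    def test_balance_counts(self):
        events = [
            SVEvent("insertion", "A", "1", 1, 1, 2_000),
            SVEvent("insertion", "A", "1", 1, 1, 3_000),
            SVEvent("deletion", "B", "1", 1, 1, 1_500),
            SVEvent("inversion", None, "1", 1, 1, 1_200),
        ]
        res = svkit.indel_balance_summary(events)
        assert res["insertion_deletion_ratio"] == pytest.approx(2.0)
        assert res["n_insertions"] == 2
        tab = res["table"].set_index(["strain", "type"])
        assert tab.loc[("A", "insertion"), "total_bp"] == 5_000

    def test_balance_empty_nan(self):
        res = svkit.indel_balance_summary([])
        assert np.isnan(res["insertion_deletion_ratio"])

    def test_alignment_roundtrip(self, tmp_path):
        alns = [_aln(1, 100, 5, 104), _aln(200, 300, 250, 350, strand="-")]
        path = tmp_path / "aln.tsv"
        svkit.write_alignments(alns, str(path))
        back = svkit.read_alignments(str(path))
        assert back == alns

    def test_events_frame_columns(self):
        df = svkit.events_to_frame([SVEvent("insertion", "A", "1", 5, 6, 2_000)])
        assert {"type", "carrier", "size", "pos_query"} <= set(df.columns)
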