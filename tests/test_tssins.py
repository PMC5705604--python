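import math
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from cenevol import tssins
from cenevol.tssins import InsertionAtTSS, TSSRecord, WindowStats


def _tss(strain="A", chrom="1", pos=10_000, strand="+", tags=5):
    return TSSRecord(strain=strain, chromosome=chrom, position=pos,
                     strand=strand, tag_count=tags)


def _ins(carrier="A", chrom="1", pos=1_000, size=2_000):
    return SimpleNamespace(type="insertion", carrier=carrier, chrom=chrom,
                           pos_query=pos, size=size)


class TestTypes:
    def test_bad_strand(self):
        with pytest.raises(ValueError):
            _tss(strand="x")

    def test_position_one_based(self):
        with pytest.raises(ValueError):
            _tss(pos=0)

    def test_insertion_size_bounds(self):
        with pytest.raises(ValueError, match="size"):
            InsertionAtTSS(tss=_tss(), insertion_start=1, insertion_end=500,
                           distance=10)
        with pytest.raises(ValueError, match="size"):
            InsertionAtTSS(tss=_tss(), insertion_start=1, insertion_end=20_000,
                           distance=10)

    def test_distance_bound(self):
        with pytest.raises(ValueError, match="distance"):
            InsertionAtTSS(tss=_tss(), insertion_start=1, insertion_end=2_000,
                           distance=150)

    def test_window_stats_range_checked(self):
        with pytest.raises(ValueError):
            WindowStats(gc_ratio=1.2, cpg_ratio=0.0,
                        unmethylated_fraction=0.0,
                        window_start=1, window_end=500)
        # NaN unmethylated fraction allowed
        WindowStats(gc_ratio=0.5, cpg_ratio=0.0,
                    unmethylated_fraction=float("nan"),
                    window_start=1, window_end=500)


class TestIntervalDistance:
    def test_strictly_between(self):
        assert tssins._interval_distance(100, 200, 250) == 49
        assert tssins._interval_distance(100, 200, 60) == 39
        assert tssins._interval_distance(100, 200, 150) == 0
        assert tssins._interval_distance(100, 200, 201) == 0


def _table(rows):
    return pd.DataFrame(rows, columns=["tss_id", "strain", "chrom", "pos",
                                       "strand", "tag_count"])


class TestPairing:
    def test_nearby_insertion_paired(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5),
                        ("t1", "B", "1", 10_000, "+", 4)])
        ins = [_ins(pos=10_051, size=2_000)]  # 50 bp downstream of the TSS
        with_ins, partners = tssins.find_insertion_tss_pairs(table, ins)
        assert len(with_ins) == 1 and len(partners) == 1
        assert with_ins[0].distance == 50
        assert with_ins[0].tss.strain == "A"
        assert partners[0].strain == "B"

    def test_far_insertion_skipped(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5),
                        ("t1", "B", "1", 10_000, "+", 4)])
        ins = [_ins(pos=10_151, size=2_000)]  # 150 bp away
        with_ins, _ = tssins.find_insertion_tss_pairs(table, ins)
        assert with_ins == []

    def test_oversized_insertion_skipped(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5),
                        ("t1", "B", "1", 10_000, "+", 4)])
        ins = [_ins(pos=10_050, size=12_000)]
        with_ins, _ = tssins.find_insertion_tss_pairs(table, ins)
        assert with_ins == []

    def test_both_strains_inserted_skipped(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5),
                        ("t1", "B", "1", 10_000, "+", 4)])
        ins = [_ins("A", pos=10_050), _ins("B", pos=10_050)]
        with_ins, _ = tssins.find_insertion_tss_pairs(table, ins)
        assert with_ins == []

    def test_missing_counterpart_skipped(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5)])
        with_ins, _ = tssins.find_insertion_tss_pairs(
            table, [_ins(pos=10_050)])
        assert with_ins == []

    def test_untagged_counterpart_skipped(self):
        table = _table([("t1", "A", "1", 10_000, "+", 5),
                        ("t1", "B", "1", 10_000, "+", 0)])
        with_ins, _ = tssins.find_insertion_tss_pairs(
            table, [_ins(pos=10_050)])
        assert with_ins == []


class TestWindowStats:
    def test_all_at_zero_ratios(self):
        ws = tssins.window_stats("A" * 1_200, _tss(pos=1_000))
        assert ws.gc_ratio == 0.0
        assert ws.cpg_ratio == 0.0
        assert math.isnan(ws.unmethylated_fraction)
        assert (ws.window_start, ws.window_end) == (500, 999)
        assert ws.clipped is False

    def test_cg_dinucleotide_window(self):
        # window = "CG" * 250: gc=1, cpg = 250/499
        genome = "A" * 500 + "CG" * 250 + "A" * 100
        ws = tssins.window_stats(genome, _tss(pos=1_001))
        assert ws.gc_ratio == 1.0
        assert ws.cpg_ratio == pytest.approx(250 / 499)

    def test_methylation_fraction(self):
        genome = "A" * 500 + "CG" * 250 + "A" * 100
        tss = _tss(pos=1_001)
        meth = {p: True for p in range(500, 1_000, 2)}  # all methylated
        ws = tssins.window_stats(genome, tss, methylation=meth)
        assert ws.unmethylated_fraction == 0.0
        meth[500] = False
        ws = tssins.window_stats(genome, tss, methylation=meth)
        assert ws.unmethylated_fraction == pytest.approx(1 / 250)

    def test_minus_strand_mirror(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3_000))
        from cenevol.align import decode, encode, revcomp
        rc = decode(revcomp(encode(seq)))
        p = 1_200
        ws_f = tssins.window_stats(seq, _tss(pos=p, strand="+"))
        ws_r = tssins.window_stats(rc, _tss(pos=len(seq) - p + 1, strand="-"))
        assert ws_f.gc_ratio == pytest.approx(ws_r.gc_ratio)
        assert ws_f.cpg_ratio == pytest.approx(ws_r.cpg_ratio)

    def test_clipped_flag(self):
        ws = tssins.window_stats("ACGT" * 200, _tss(pos=100))
        assert ws.clipped is True
        assert ws.window_start == 1

    def test_off_contig_rejected(self):
        with pytest.raises(ValueError):
            tssins.window_stats("ACGT" * 200, _tss(pos=1))

    def test_calls_to_lookup(self):
        calls = pd.DataFrame({"chrom": ["1", "1", "2"], "pos": [5, 9, 5],
                              "state": ["methylated", "unmethylated",
                                        "methylated"]})
        lk = tssins.calls_to_lookup(calls, chrom="1")
        assert lk == {5: True, 9: False}


def _ws(gc, cpg=0.1, unmeth=0.5):
    return WindowStats(gc_ratio=gc, cpg_ratio=cpg,
                       unmethylated_fraction=unmeth,
                       window_start=1, window_end=500)


class TestPairedTests:
    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            tssins.paired_increase_tests([_ws(0.5)] * 5, [_ws(0.4)] * 5)

    def test_all_zero_differences_nan(self):
        res = tssins.paired_increase_tests([_ws(0.5)] * 6, [_ws(0.5)] * 6)
        assert res["p_value"].isna().all()

    def test_exact_enumeration_six_pairs(self):
        # all six differences positive: one-sided exact p = 1 / 2^6
        w = [_ws(0.5 + 0.01 * i, 0.2 + 0.01 * i, 0.6 + 0.01 * i)
             for i in range(6)]
        wo = [_ws(0.4 + 0.01 * i, 0.1 + 0.01 * i, 0.5 + 0.01 * i)
              for i in range(6)]
        res = tssins.paired_increase_tests(w, wo).set_index("parameter")
        for param in tssins.PAIRED_PARAMETERS:
            assert res.loc[param, "p_value"] == pytest.approx(1 / 64)
            assert res.loc[param, "n_nonzero"] == 6

    def test_agrees_with_scipy(self, rng):
        a = rng.uniform(0.3, 0.9, 12)
        b = np.clip(a - rng.normal(0.05, 0.05, 12), 0, 1)
        w = [_ws(x) for x in a]
        wo = [_ws(x) for x in b]
        res = tssins.paired_increase_tests(w, wo).set_index("parameter")
        d = a - b
        d = d[d != 0]
        expect = sstats.wilcoxon(d, alternative="greater",
                                 zero_method="wilcox", method="exact").pvalue
        assert res.loc["gc_ratio", "p_value"] == pytest.approx(expect)

    def test_nan_pairs_dropped(self):
        w = [_ws(0.5, unmeth=float("nan"))] + [_ws(0.6)] * 6
        wo = [_ws(0.4)] * 7
        res = tssins.paired_increase_tests(w, wo).set_index("parameter")
        assert res.loc["unmethylated_fraction", "n_pairs"] == 6
        assert res.loc["gc_ratio", "n_pairs"] == 7


class TestTEClassify:
    def test_above_threshold_wins(self):
        fam = tssins.te_classify(1_000, [("LINE", 1, 400)])
        assert fam == "LINE"

    def test_exact_threshold_excluded(self):
        assert tssins.te_classify(1_000, [("LINE", 1, 300)]) is None

    def test_merged_overlaps_counted_once(self):
        # two overlapping intervals merge to 300 bp -> still not > 30%
        anns = [("LINE", 1, 200), ("LINE", 101, 300)]
        assert tssins.te_classify(1_000, anns) is None

    def test_largest_family_wins(self):
        anns = [("LINE", 1, 350), ("LTR", 1, 500)]
        assert tssins.te_classify(1_000, anns) == "LTR"

    def test_bad_length(self):
        with pytest.raises(ValueError):
            tssins.te_classify(0, [])


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=["tss_id", "strain", "replicate",
                                       "count"])


class TestExpressionScreen:
    def test_size_factors_scale(self):
        counts = np.array([[100.0, 200.0], [50.0, 100.0], [10.0, 20.0]])
        sf = tssins.size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_size_factors_need_expressed_locus(self):
        with pytest.raises(ValueError):
            tssins.size_factors(np.array([[0.0, 5.0], [5.0, 0.0]]))

    def _balanced(self, mult_first=1.0):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(30):
            base = rng.integers(50, 300)
            for strain in ("A", "B"):
                m = mult_first if (strain == "A" and i == 0) else 1.0
                for rep in (1, 2):
                    rows.append((f"t{i}", strain, rep,
                                 int(base * m) + int(rng.integers(0, 5))))
        return _counts_frame(rows)

    def test_identical_groups_null(self):
        res = tssins.expression_screen(self._balanced(), "A", "B")
        assert (res["p_value"].dropna() > 0.01).mean() >= 0.9
        assert np.nanmax(np.abs(res["log2_fold_change"])) < 0.5

    def test_strong_shift_detected(self):
        res = tssins.expression_screen(self._balanced(8.0), "A", "B")
        row = res[res["tss_id"] == "t0"].iloc[0]
        assert row["log2_fold_change"] > 2.0
        assert row["p_value"] < 1e-3

    def test_lfc_antisymmetric(self):
        df = self._balanced(4.0)
        ab = tssins.expression_screen(df, "A", "B").set_index("tss_id")
        ba = tssins.expression_screen(df, "B", "A").set_index("tss_id")
        assert np.allclose(ab["log2_fold_change"],
                           -ba.loc[ab.index, "log2_fold_change"])

    def test_novel_flag(self):
        rows = []
        for i in range(10):
            for strain in ("A", "B"):
                c = 0 if (strain == "B" and i == 0) else 100
                for rep in (1, 2):
                    rows.append((f"t{i}", strain, rep, c))
        res = tssins.expression_screen(_counts_frame(rows), "A", "B")
        assert res.set_index("tss_id")["novel"].loc["t0"]
        assert res["novel"].sum() == 1

    def test_all_zero_locus_nan(self):
        rows = []
        for i in range(5):
            for strain in ("A", "B"):
                c = 0 if i == 0 else 100
                for rep in (1, 2):
                    rows.append((f"t{i}", strain, rep, c))
        res = tssins.expression_screen(_counts_frame(rows), "A", "B")
        assert math.isnan(res.set_index("tss_id")["p_value"].loc["t0"])

    def test_missing_strain_rejected(self):
        with pytest.raises(ValueError):
            tssins.expression_screen(self._balanced(), "A", "Z")

    def test_null_calibration_bounded(self):
        """Wald p-values on a hard NB null stay near nominal (<= 3x)."""
        rng = np.random.default_rng(11)
        rows = []
        for i in range(400):
            mu = rng.uniform(50, 400)
            r = 1 / 0.1
            for strain in ("A", "B"):
                for rep in (1, 2, 3):
                    c = rng.negative_binomial(r, r / (r + mu))
                    rows.append((f"t{i}", strain, rep, int(c)))
        res = tssins.expression_screen(_counts_frame(rows), "A", "B")
        frac = float((res["p_value"].dropna() < 0.01).mean())
        assert frac <= 0.03


class TestStatsFrame:
    def test_columns(self):
        df = tssins.stats_to_frame([_ws(0.5)], [_tss()])
        assert {"strain", "pos", "gc_ratio", "cpg_ratio",
                "unmethylated_fraction", "clipped"} <= set(df.columns)
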