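import math

import numpy as np
import pandas as pd
import pytest

from oracles import bh_stepup, pearson_with_t_p, welch_t

from guidetag.rearrange import (anova_contrasts,
                                arcsine_transform, bh_adjust,
                                call_translocations, correlate,
                                deletion_spectrum, group_test,
                                predicted_junction)
from guidetag.seqio import GenomicInterval, revcomp


class TestArcsine:
    @pytest.mark.parametrize("p, expected", [
        (0.0, 0.0),
        (1.0, math.pi / 2),
        (0.25, math.asin(0.5)),
    ])
    def test_closed_forms(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.5)

    def test_range_property(self, rng):
        vals = arcsine_transform(rng.random(100))
        assert ((vals >= 0) & (vals <= math.pi / 2)).all()


class TestGroupTest:
    def test_identical_groups_p_one(self):
        res = group_test([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_matches_textbook_welch(self):
        treated = [0.10, 0.12, 0.11]
        control = [0.00, 0.00, 0.01]
        res = group_test(treated, control)
        x = np.arcsin(np.sqrt(treated))
        y = np.arcsin(np.sqrt(control))
        t, df, p = welch_t(x, y)
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(df)
        assert res.p == pytest.approx(p)

    def test_single_observation_untestable(self):
        res = group_test([0.1], [0.0])
        assert res.untestable

    def test_label_swap_flips_t_not_p(self):
        a, b = [0.2, 0.25, 0.22], [0.01, 0.02, 0.0]
        r1 = group_test(a, b)
        r2 = group_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p == pytest.approx(r2.p)


class TestAnovaContrasts:
    def test_contrast_matches_pooled_t_formula(self, rng):
        groups = {g: list(rng.random(4) * 0.2) for g in ("A", "B", "C")}
        out = anova_contrasts(groups, [("A", "C")], transform=False)
        a = np.asarray(groups["A"])
        b = np.asarray(groups["B"])
        c = np.asarray(groups["C"])
        mse = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3 + c.var(ddof=1) * 3) / 9
        t = (a.mean() - c.mean()) / math.sqrt(mse * (1 / 4 + 1 / 4))
        assert out["contrasts"][0].statistic == pytest.approx(t)
        assert out["anova_p"] <= 1.0

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_contrasts({"A": [1, 2], "B": [3, 4]}, [])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03])
        assert list(np.round(adj, 10)) == [0.03, 0.03, 0.03]

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_formula_oracle(self, rng):
        p = rng.random(25)
        assert bh_adjust(p) == pytest.approx(bh_stepup(list(p)))

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.random(15))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        # re-adjustment can only move values up, never below the fixed input
        assert (bh_adjust(adj) >= adj - 1e-12).all()

    def test_order_preserved_relative_to_input(self, rng):
        p = rng.random(20)
        adj = bh_adjust(p)
        assert (np.argsort(np.argsort(adj)) >= 0).all()
        # smaller raw p never yields a larger adjusted p
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(30)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestCorrelate:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = correlate(x, [2 * v for v in x])
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert correlate(x, [-v for v in x]).r == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        x = rng.random(10)
        y = 0.5 * x + rng.random(10) * 0.3
        res = correlate(x, y)
        r, p = pearson_with_t_p(x, y)
        assert res.r == pytest.approx(r)
        assert res.r_p == pytest.approx(p)

    def test_zero_variance_undefined(self):
        res = correlate([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
        assert res.undefined


class TestPredictedJunction:
    def test_manual_concatenation(self, toy_genome):
        cut_a, cut_b = 2_000, 9_000
        junc = predicted_junction(toy_genome, cut_a, "chrS1", "L",
                                  cut_b, "chrS2", "R", flank=20)
        ref_a = toy_genome["chrS1"]
        ref_b = toy_genome["chrS2"]
        assert junc == ref_a[1_980:2_000] + ref_b[9_000:9_020]
        assert len(junc) == 40

    def test_same_contig_join_is_deletion_junction(self, toy_genome):
        junc = predicted_junction(toy_genome, 2_000, "chrS1", "L",
                                  2_500, "chrS1", "R", flank=15)
        ref = toy_genome["chrS1"]
        assert junc == ref[1_985:2_000] + ref[2_500:2_515]

    def test_inverted_arm_revcomped(self, toy_genome):
        junc = predicted_junction(toy_genome, 2_000, "chrS1", "L",
                                  5_000, "chrS1", "L", flank=10)
        ref = toy_genome["chrS1"]
        assert junc == ref[1_990:2_000] + revcomp(ref[4_990:5_000])

    def test_self_join_rejected(self, toy_genome):
        with pytest.raises(ValueError):
            predicted_junction(toy_genome, 2_000, "chrS1", "L",
                               2_000, "chrS1", "R")


class TestDeletionSpectrum:
    def test_bins_and_summary(self):
        out = deletion_spectrum([60, 60, 200], samples=["S1", "S1", "S2"],
                                bins=[50, 100, 500, 2000])
        assert list(out["counts"]) == [2, 1, 0]
        s1 = out["per_sample"].set_index("sample").loc["S1"]
        assert s1["mean"] == 60 and s1["n"] == 2

    def test_empty(self):
        out = deletion_spectrum([])
        assert out["counts"].sum() == 0


class TestCallTranslocations:
    def _candidate(self, sample, contig, pos):
        from guidetag.align import Segment, SplitResult
        from guidetag.outcomes import Classification, EditClass
        seg1 = Segment(ref="chrA", strand="+", query_start=0, query_end=40,
                       ref_start=960, ref_end=1_000)
        seg2 = Segment(ref=contig, strand="+", query_start=40, query_end=80,
                       ref_start=pos, ref_end=pos + 40)
        split = SplitResult(segments=[seg1, seg2], junction_offset=40)
        return (sample, Classification(
            EditClass.translocation_candidate, split=split,
            partner=(contig, pos, "+")))

    @pytest.fixture
    def known_sites(self):
        return pd.DataFrame([
            {"contig": "chrB", "start": 5_000, "end": 5_020, "strand": "+",
             "name": "OT1"},
        ])

    def test_candidates_aggregate_per_partner(self, known_sites):
        anchor = GenomicInterval("chrA", 990, 1_010)
        cands = [self._candidate("S1", "chrB", 5_005) for _ in range(12)]
        events, novel = call_translocations(cands, known_sites, anchor,
                                            anchor_cut=1_000)
        assert len(events) == 1 and not novel
        assert events[0].umi_counts == {"S1": 12}

    def test_distant_partner_is_novel(self, known_sites):
        anchor = GenomicInterval("chrA", 990, 1_010)
        cands = [self._candidate("S1", "chrB", 5_500)]
        events, novel = call_translocations(cands, known_sites, anchor,
                                            anchor_cut=1_000)
        assert not events and len(novel) == 1

    def test_empty_candidates(self, known_sites):
        anchor = GenomicInterval("chrA", 990, 1_010)
        events, novel = call_translocations([], known_sites, anchor, 1_000)
        assert events == [] and novel == []
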