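"""Association statistics: exact values, identities, and model recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import tmbkit as tk
from tmbkit.errors import (
    ParameterError, SeparationError, UndefinedComparisonError,
)
from tmbkit.stats import horizon_auc, logistic_model, cox_model


class TestFisher:
    def test_balanced_table_is_null(self):
        r = tk.fisher_2x2([[1, 1], [1, 1]])
        assert r.effect == 1.0
        assert r.p_value == 1.0

    def test_zero_cell_sentinels(self):
        assert tk.fisher_2x2([[3, 0], [5, 10]]).effect == math.inf
        assert tk.fisher_2x2([[0, 3], [10, 5]]).effect == 0.0
        assert "Haldane" in tk.fisher_2x2([[3, 0], [5, 10]]).notes

    def test_negative_counts_rejected(self):
        with pytest.raises(ParameterError):
            tk.fisher_2x2([[1, -1], [2, 3]])

    @given(hst.lists(hst.integers(0, 12), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=60)
    def test_p_invariant_under_table_symmetries(self, cells):
        a, b, c, d = cells
        t = [[a + 1, b], [c, d + 1]]  # avoid the all-zero table
        p0 = tk.fisher_2x2(t).p_value
        transposed = [[t[0][0], t[1][0]], [t[0][1], t[1][1]]]
        swapped = [[t[1][1], t[1][0]], [t[0][1], t[0][0]]]
        assert tk.fisher_2x2(transposed).p_value == pytest.approx(p0, rel=1e-9)
        assert tk.fisher_2x2(swapped).p_value == pytest.approx(p0, rel=1e-9)

    def test_woolf_ci_brackets_or(self):
        r = tk.fisher_2x2([[19, 18], [5, 33]])
        assert r.ci_low < r.effect < r.ci_high


class TestMannWhitney:
    def test_exact_small_sample_p(self):
        # most extreme of the C(6,3)=20 labelings, two-sided: 2/20
        r = tk.mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.p_value == pytest.approx(0.1)

    def test_exhaustive_enumeration_oracle(self):
        x, y = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        pooled = x + y
        def u_of(subset):
            rest = [v for i, v in enumerate(pooled) if i not in subset]
            chosen = [pooled[i] for i in subset]
            return sum(1 for a in chosen for b in rest if a > b)
        observed = u_of((0, 1, 2))  # indices of x in pooled
        us = [u_of(s) for s in itertools.combinations(range(6), 3)]
        dev = abs(observed - 4.5)
        expected_p = sum(1 for u in us if abs(u - 4.5) >= dev - 1e-9) / len(us)
        r = tk.mann_whitney(x, y)
        assert r.p_value == pytest.approx(expected_p)

    def test_identical_samples_null(self):
        r = tk.mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert r.p_value == pytest.approx(1.0, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            tk.mann_whitney([], [1.0])


class TestROC:
    def test_perfect_separation(self):
        r = tk.roc_auc([1, 2, 10, 11], [0, 0, 1, 1])
        assert r.effect == 1.0

    def test_all_scores_equal_is_half(self):
        r = tk.roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.effect == 0.5

    def test_one_discordant_pair_gives_three_quarters(self):
        # positives score {2, 4}, negatives {1, 3}: 3 of 4 pairs concordant
        r = tk.roc_auc([1, 2, 3, 4], [0, 1, 0, 1])
        assert r.effect == pytest.approx(0.75)

    def test_one_class_rejected(self):
        with pytest.raises(ParameterError):
            tk.roc_auc([1, 2], [1, 1])

    @given(hst.lists(hst.floats(-50, 50), min_size=4, max_size=30),
           hst.data())
    @settings(deadline=None, max_examples=60)
    def test_auc_equals_scaled_u(self, scores, data):
        labels = data.draw(hst.lists(hst.integers(0, 1),
                                     min_size=len(scores),
                                     max_size=len(scores)))
        n1, n0 = sum(labels), len(labels) - sum(labels)
        if n1 == 0 or n0 == 0:
            return
        auc = tk.roc_auc(scores, labels).effect
        scores = np.asarray(scores)
        labels = np.asarray(labels)
        u = tk.mann_whitney(scores[labels == 1], scores[labels == 0]).effect
        assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestSpearman:
    def test_monotone_extremes(self):
        assert tk.spearman([1, 2, 3], [10, 20, 30]).effect == 1.0
        assert tk.spearman([1, 2, 3], [3, 2, 1]).effect == -1.0

    def test_hand_computed_rank_correlation(self):
        # ranks of y are 1,3,2,4: rho = 1 - 6*2/(4*15) = 0.8
        assert tk.spearman([1, 2, 3, 4], [1, 3, 2, 4]).effect == pytest.approx(0.8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            tk.spearman([1, 2, 3], [1, 2])


class TestSurvival:
    def test_identical_groups_are_null(self):
        t = [1, 2, 3, 4, 5] * 2
        e = [True] * 10
        g = ["a"] * 5 + ["b"] * 5
        comp = tk.survival_compare(t, e, g)
        assert comp.result.effect == pytest.approx(1.0)
        assert comp.result.p_value == pytest.approx(1.0)

    def test_direction_of_protection(self):
        # all events in group a at t=1; group b censored at t=2
        comp = tk.survival_compare([1, 1, 1, 2, 2, 2],
                                   [True, True, True, False, False, False],
                                   ["a", "a", "a", "b", "b", "b"],
                                   group_order=["b", "a"])
        assert comp.result.effect < 1.0  # censored group has lower hazard

    def test_reciprocal_under_group_swap(self, rng):
        t = rng.exponential(10, size=60)
        e = rng.random(60) < 0.8
        g = np.where(rng.random(60) < 0.5, "x", "y")
        if not e.any():
            e[0] = True
        ab = tk.survival_compare(t, e, g, group_order=["x", "y"]).result.effect
        ba = tk.survival_compare(t, e, g, group_order=["y", "x"]).result.effect
        assert ab == pytest.approx(1.0 / ba)

    def test_exponential_simulation_recovers_hr(self, rng):
        n = 500
        t1 = rng.exponential(1 / 0.4, size=n)   # hazard 0.4
        t2 = rng.exponential(1 / 1.0, size=n)   # hazard 1.0 -> true HR 0.4
        t = np.concatenate([t1, t2])
        cens = np.full(2 * n, 8.0)
        e = t <= cens
        time = np.minimum(t, cens)
        g = np.array(["high"] * n + ["low"] * n)
        comp = tk.survival_compare(time, e, g, group_order=["high", "low"])
        assert 0.32 <= comp.result.effect <= 0.50

    def test_km_curves_start_at_one(self):
        comp = tk.survival_compare([1, 2, 3, 4], [1, 1, 0, 1],
                                   ["a", "a", "b", "b"])
        for curve in comp.km_curves.values():
            assert curve["survival"].iloc[0] == pytest.approx(1.0)

    def test_no_events_rejected(self):
        with pytest.raises(UndefinedComparisonError):
            tk.survival_compare([1, 2], [False, False], ["a", "b"])


class TestTrendAndComposite:
    def test_matches_r_prop_trend_test(self):
        # frozen from R: prop.trend.test(c(2,9,15), c(20,30,25), score=0:2)
        labels = ["neither"] * 20 + ["one"] * 30 + ["both"] * 25
        succ = [1] * 2 + [0] * 18 + [1] * 9 + [0] * 21 + [1] * 15 + [0] * 10
        r = tk.chi_square_trend(labels, succ)
        assert r.effect == pytest.approx(12.5475936643, abs=1e-8)
        assert r.p_value == pytest.approx(0.0003967168405, rel=1e-6)

    def test_composite_label_rules(self):
        # PD-L1 positivity is inclusive (>=1%); TMB-high is strict (>median)
        tmb = [300, 158, 100, 400]
        pdl1 = [1.0, 0.0, 50.0, None]
        labels = tk.composite_groups(tmb, pdl1, tmb_threshold=158.0)
        assert labels == ["both", "neither", "one", None]

    def test_missing_pdl1_excluded_from_trend(self):
        labels = ["both"] * 10 + ["neither"] * 10 + [None] * 5
        succ = [1] * 8 + [0] * 2 + [1] * 1 + [0] * 9 + [1] * 5
        r = tk.chi_square_trend(labels, succ)
        assert r.n == 20


class TestGeneScan:
    def test_sentinel_or_for_exclusive_genes(self):
        mat = pd.DataFrame({
            "IFNGR1": [True] * 3 + [False] * 72,
            "STK11": [False] * 24 + [True] * 7 + [False] * 44,
            "NOWHERE": [False] * 75,
        })
        responder = [True] * 24 + [False] * 51
        # IFNGR1 mutated only in responders; STK11 only in non-responders
        scan = tk.gene_level_scan(mat, responder).set_index("gene")
        assert scan.loc["IFNGR1", "odds_ratio"] == math.inf
        assert scan.loc["STK11", "odds_ratio"] == 0.0
        assert scan.loc["NOWHERE", "skipped"] == "mutated in nobody"
        tested = scan[scan["skipped"] == ""]
        assert ((tested["q_value"] >= tested["p_value"] - 1e-12).all())

    def test_absent_gene_noted(self):
        mat = pd.DataFrame({"A": [True, False]})
        scan = tk.gene_level_scan(mat, [True, False], gene_list=["A", "B"])
        assert scan.set_index("gene").loc["B", "skipped"] == "absent from matrix"


class TestMultivariableModels:
    def _simulated(self, rng, n=2000):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        logit = -0.5 + 1.2 * x1 - 0.8 * x2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        return pd.DataFrame({"x1": x1, "x2": x2, "y": y.astype(int)})

    def test_logistic_recovers_known_coefficients(self, rng):
        df = self._simulated(rng)
        res, auc = logistic_model(df, "y", ["x1", "x2"])
        assert res["x1"].effect == pytest.approx(1.2, rel=0.10)
        assert res["x2"].effect == pytest.approx(-0.8, rel=0.10)
        assert 0.5 < auc.effect <= 1.0

    def test_single_covariate_matches_univariate(self, rng):
        df = self._simulated(rng, n=400)
        multi, _ = logistic_model(df, "y", ["x1"])
        import statsmodels.api as sm
        uni = sm.Logit(df["y"], sm.add_constant(df[["x1"]])).fit(disp=0)
        assert multi["x1"].effect == pytest.approx(uni.params["x1"], rel=1e-6)

    def test_constant_covariate_dropped(self, rng):
        df = self._simulated(rng, n=200)
        df["flat"] = 1.0
        res, _ = logistic_model(df, "y", ["x1", "flat"])
        assert "flat" not in res

    def test_perfect_separation_refused(self):
        df = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13],
                           "y": [0, 0, 0, 0, 1, 1, 1, 1]})
        with pytest.raises(SeparationError):
            logistic_model(df, "y", ["x"])

    def test_cox_recovers_sign(self, rng):
        n = 600
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.8 * x))
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        res = cox_model(df, "t", "e", ["x"])
        assert res["x"].effect == pytest.approx(0.8, rel=0.15)

    def test_horizon_auc_excludes_early_censored(self):
        df = pd.DataFrame({
            "score": [5.0, 4.0, 1.0, 2.0, 3.0],
            "t": [2.0, 3.0, 10.0, 4.0, 12.0],
            "e": [1, 1, 0, 0, 1],
        })
        # patient 4 (t=4, censored) is not evaluable at 6 months
        res = horizon_auc(df, "score", "t", "e", 6.0)
        assert res.n == 4
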