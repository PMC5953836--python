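"""CCF posterior inference against an independent brute-force oracle."""

import math

import numpy as np
import pytest

import tmbkit as tk
from tmbkit.clonality import (
    CCF_GRID, CLONAL, SUBCLONAL, UNRESOLVED,
    ccf_recovery_experiment, classify_variants,
)
from tmbkit.errors import ParameterError

import pandas as pd


def oracle_posterior(a, n, purity, cpn_normal=2.0, cpn_tumor=2.0):
    """Literal re-evaluation of the binomial pmf at every grid point.

    Deliberately independent of the implementation: log-pmf via lgamma,
    normalization by direct summation over shifted exponentials.
    """
    logs = []
    for k in range(1, 101):
        c = k / 100
        f = (purity * c) / (cpn_normal * (1 - purity) + purity * cpn_tumor)
        if f <= 0 or f >= 1:
            lp = -math.inf if (0 < a or f >= 1) else 0.0
        else:
            lp = (math.lgamma(n + 1) - math.lgamma(a + 1) - math.lgamma(n - a + 1)
                  + a * math.log(f) + (n - a) * math.log(1 - f))
        logs.append(lp)
    m = max(logs)
    w = [math.exp(l - m) for l in logs]
    total = sum(w)
    return [x / total for x in w]


class TestExpectedVAF:
    def test_pure_diploid_clonal_is_half(self):
        assert tk.expected_vaf(1.0, 1.0, 2, 2) == pytest.approx(0.5)

    def test_absent_mutation_is_zero(self):
        assert tk.expected_vaf(0.0, 0.7, 2, 2) == 0.0

    def test_half_purity_diploid(self):
        # p*c*m / (2(1-p) + 2p) = 0.5/2
        assert tk.expected_vaf(1.0, 0.5, 2, 2) == pytest.approx(0.25)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            ccf = rng.uniform(0, 1)
            p = rng.uniform(0.05, 1.0)
            cn_t = rng.integers(1, 6)
            v = tk.expected_vaf(ccf, p, 2, cn_t)
            assert 0.0 <= v <= 1.0


class TestCCFPosterior:
    def test_matches_bruteforce_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 500))
            a = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.1, 1.0))
            cn_t = float(rng.integers(1, 5))
            post = tk.ccf_posterior(a, n, p, 2.0, cn_t)
            expected = oracle_posterior(a, n, p, 2.0, cn_t)
            assert np.max(np.abs(post.posterior - expected)) < 1e-12

    def test_zero_alt_reads_mode_at_grid_bottom(self):
        post = tk.ccf_posterior(0, 100, 1.0)
        assert post.ccf_mode == pytest.approx(0.01)

    def test_half_vaf_pure_diploid_mode_at_one(self):
        post = tk.ccf_posterior(50, 100, 1.0)
        assert post.ccf_mode == pytest.approx(1.00)

    def test_posterior_normalized(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 2000))
            a = int(rng.integers(0, n + 1))
            post = tk.ccf_posterior(a, n, float(rng.uniform(0.1, 1.0)))
            assert post.posterior.sum() == pytest.approx(1.0, abs=1e-9)
            assert (post.posterior >= 0).all()

    def test_prob_mass_counts_grid_above_095(self):
        post = tk.ccf_posterior(480, 1000, 1.0)
        manual = post.posterior[CCF_GRID > 0.95].sum()
        assert post.prob_ccf_gt == pytest.approx(manual)
        assert np.count_nonzero(CCF_GRID > 0.95) == 5  # 0.96 ... 1.00

    def test_high_depth_stable(self):
        post = tk.ccf_posterior(50_000, 100_000, 1.0)
        assert post.ccf_mode == pytest.approx(1.00)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            tk.ccf_posterior(10, 5, 0.5)
        with pytest.raises(ParameterError):
            tk.ccf_posterior(1, 10, 0.0)
        with pytest.raises(ParameterError):
            tk.ccf_posterior(1, 10, 0.5, cpn_tumor_mut=0.5)


class TestClonalityCalls:
    def test_clearly_clonal(self):
        post = tk.ccf_posterior(500, 1000, 1.0)
        assert tk.classify_clonality(post) == CLONAL
        assert post.prob_ccf_gt > 0.5

    def test_clearly_subclonal(self):
        post = tk.ccf_posterior(100, 1000, 1.0)
        assert tk.classify_clonality(post) == SUBCLONAL
        assert post.prob_ccf_gt < 1e-6

    def test_exact_half_probability_is_subclonal(self):
        # the rule is strictly ">0.5": construct a posterior with mass
        # exactly 0.5 above the cut
        post = tk.CCFPosterior(
            grid=CCF_GRID.copy(),
            posterior=np.array([0.5] + [0.0] * 94 + [0.1] * 5),
            prob_ccf_gt=0.5, clonal=False, ccf_mode=0.01,
        )
        assert tk.classify_clonality(post) == SUBCLONAL

    def test_monotone_in_alt_reads(self):
        probs = [tk.ccf_posterior(a, 200, 0.8).prob_ccf_gt
                 for a in range(0, 201, 10)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_posterior_concentrates_at_high_depth(self, rng):
        # reads drawn at the expected VAF of a known CCF: mode ~ truth
        for c_star in (0.3, 0.6, 0.9):
            f = tk.expected_vaf(c_star, 0.9)
            a = int(rng.binomial(100_000, f))
            post = tk.ccf_posterior(a, 100_000, 0.9)
            assert abs(post.ccf_mode - c_star) <= 0.01

    def test_parameter_recovery_rate(self):
        # depth 1000, diploid purity-1 loci: expected recovery ~0.954
        rate = ccf_recovery_experiment(n_snvs=200, depth=1000, seed=0)
        assert rate >= 0.9


class TestClassifyVariants:
    def test_indels_and_missing_inputs_unresolved(self):
        table = pd.DataFrame({
            "patient_id": ["P1"] * 3,
            "mutation_key": ["m1", "m2", "m3"],
            "alt_count": [500, 100, 400],
            "depth": [1000, 1000, 1000],
            "purity": [1.0, 1.0, np.nan],
            "cpn_normal": [2, 2, 2],
            "cpn_tumor_mut": [2, 2, 2],
            "variant_type": ["SNV", "indel", "SNV"],
        })
        out = classify_variants(table)
        assert list(out["clonality"]) == [CLONAL, UNRESOLVED, UNRESOLVED]

    def test_forward_model_labels_recovered(self, rng):
        # simulate reads from the generator's forward model at depth 1000.
        # High-purity samples: the clonality rule is deliberately
        # conservative (strict P(CCF>0.95) > 0.5), so clonal mutations in
        # impure samples are systematically under-called and label accuracy
        # is only informative where CCF is well identified.
        n = 300
        clonal = rng.random(n) < 0.8
        ccf = np.where(clonal, 1.0, rng.uniform(0.1, 0.6, n))
        purity = rng.uniform(0.9, 1.0, n)
        f = purity * ccf / (2 * (1 - purity) + 2 * purity)
        depth = np.full(n, 1000)
        alt = rng.binomial(depth, f)
        table = pd.DataFrame({
            "patient_id": "P1", "mutation_key": [f"m{i}" for i in range(n)],
            "alt_count": alt, "depth": depth, "purity": purity,
            "cpn_normal": 2, "cpn_tumor_mut": 2, "variant_type": "SNV",
        })
        out = classify_variants(table)
        pred = out["clonality"] == CLONAL
        accuracy = np.mean(pred.to_numpy() == clonal)
        assert accuracy >= 0.9
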