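"""Statistical machinery against independent oracles.

The Fisher oracle enumerates all tables with the observed margins through
hypergeometric point probabilities; the BH oracle applies the step-up rule
directly.  Both stay independent of the implementation they check.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asecross.stats_core import (bh_adjust, estimate_size_factors,
                                 fisher_exact, nb_diff_test,
                                 nb_diff_test_matrix, pearson_corr,
                                 wilcoxon_rank_sum)


def fisher_enumeration_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over one margin."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = stats.hypergeom.pmf(x, n, r1, c1)
        if p_x <= p_obs * (1 + 1e-12):
            total += p_x
    return min(total, 1.0)


def bh_stepup_oracle(p):
    """Direct step-up: padj_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(estimate_size_factors(counts), [1, 1])

    def test_doubled_library_scales(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        factors = estimate_size_factors(counts)
        assert factors[1] / factors[0] == pytest.approx(2.0)
        assert np.prod(factors) == pytest.approx(1.0)

    def test_three_gene_hand_computation(self):
        # genes x libs: ratios to geometric means give medians by hand
        counts = np.array([[4.0, 16.0], [9.0, 9.0], [1.0, 25.0]])
        geo = np.exp(np.log(counts).mean(axis=1))
        expected = np.median(counts / geo[:, None], axis=0)
        expected /= np.exp(np.log(expected).mean())
        assert np.allclose(estimate_size_factors(counts), expected)

    def test_fallback_warns_without_all_positive_gene(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.warns(UserWarning, match="column-total"):
            factors = estimate_size_factors(counts)
        assert np.allclose(factors, [1, 1])


class TestNbDiffTest:
    def test_identical_groups_null(self):
        res = nb_diff_test([10, 10, 10], [10, 10, 10])
        assert res.log2_fold_change == 0
        assert res.p_value > 0.9

    def test_all_zero_gene(self):
        res = nb_diff_test([0, 0, 0], [0, 0, 0])
        assert res.p_value == 1.0 and res.log2_fold_change == 0.0

    def test_direction_follows_fold_change(self):
        res = nb_diff_test([100, 110, 90], [10, 12, 8])
        assert res.direction == 1 and res.log2_fold_change > 2.5

    def test_null_calibration(self):
        """Simulated null (phi = 0.1, n = 6 vs 6): rejection rate at 0.05
        stays near nominal, and p-values look uniform."""
        rng = np.random.default_rng(42)
        G = 2000
        lam = 2 ** rng.normal(8, 2, G)
        n = 1.0 / 0.1
        draw = lambda: rng.negative_binomial(n, n / (n + lam), (6, G)).T
        res = nb_diff_test_matrix(draw(), draw())
        rate = (res["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.08

    def test_reduces_to_poisson_variance_at_zero_dispersion(self):
        """With under-dispersed data the dispersion floors out and the Wald
        SE matches the Poisson form computed directly."""
        a = np.array([[50.0, 50.0, 50.0]])
        b = np.array([[30.0, 30.0, 30.0]])
        res = nb_diff_test_matrix(a, b)
        ma, mb = 50 + 0.5 / 3, 30 + 0.5 / 3
        se = np.sqrt(1 / (3 * ma) + 1 / (3 * mb))
        z = (np.log(ma) - np.log(mb)) / se
        expected = 2 * stats.t.sf(abs(z), df=2)
        assert res["p_value"].iloc[0] == pytest.approx(expected, rel=1e-6)

    def test_poisson_fallback_single_library(self):
        res = nb_diff_test([100], [100])
        assert res.p_value == pytest.approx(1.0, abs=0.1)
        res2 = nb_diff_test([200], [50])
        assert res2.p_value < 1e-10

    def test_size_factors_remove_depth(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=(200, 4)).astype(float)
        scaled = base * np.array([1.0, 2.0, 0.5, 1.5])
        res = nb_diff_test_matrix(
            scaled[:, :2], scaled[:, 2:],
            np.array([1.0, 2.0]), np.array([0.5, 1.5]))
        assert (res["p_value"] < 0.05).mean() < 0.1


class TestFisherExact:
    def test_homogeneous_table(self):
        assert fisher_exact([[10, 10], [10, 10]]) == 1.0

    def test_complete_separation_hand_enumeration(self):
        # C(10,5) = 252 tables; only the two extremes are as improbable
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_empty_margin_gives_one(self):
        assert fisher_exact([[0, 0], [3, 7]]) == 1.0
        assert fisher_exact([[0, 5], [0, 7]]) == 1.0

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            t = rng.integers(0, 9, size=(2, 2))
            assert fisher_exact(t) == pytest.approx(
                fisher_enumeration_oracle(t), abs=1e-10)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_applied_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            assert np.allclose(bh_adjust(p), bh_stepup_oracle(p), atol=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.random(100)
        perm = rng.permutation(100)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestWilcoxon:
    def test_identical_small_samples_central(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) > 0.9

    def test_complete_separation_exact(self):
        # all C(6,3) = 20 assignments; the 2 extremes are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_null_uniformity_large_sample(self):
        rng = np.random.default_rng(9)
        ps = [
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_corr(x, x) == pytest.approx(1.0)
        assert pearson_corr(x, -x) == pytest.approx(-1.0)

    def test_five_point_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert pearson_corr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_signaled(self):
        with pytest.raises(ValueError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
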