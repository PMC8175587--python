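import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from retroughness import datasets
from retroughness.stats import (
    correlation_matrix,
    fisher_variance_ratio,
    independent_t,
    ks_two_sample,
    mann_whitney_exact,
    paired_t,
    pearson_one_sided,
    proportions_z,
    shapiro_wilk,
)


def brute_force_mw_p(x, y, alternative):
    """Full enumeration of all labelings of the pooled sample (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)
    obs_u = sum(1 for a in x for b in y if a > b)
    us = []
    for idx in itertools.combinations(range(n), n1):
        first = pooled[list(idx)]
        second = np.delete(pooled, list(idx))
        us.append(sum(1 for a in first for b in second if a > b))
    us = np.array(us)
    n_max = n1 * (n - n1)
    if alternative == "greater":
        return (us >= obs_u).mean()
    if alternative == "less":
        return (us <= obs_u).mean()
    return min(1.0, 2 * min((us >= obs_u).mean(), (us <= obs_u).mean()))


class TestMannWhitneyExact:
    def test_textbook_example_p_one_sixth(self):
        res = mann_whitney_exact([1.0, 2.0], [3.0, 4.0], alternative="less")
        assert res.extra["U"] == 0
        assert res.p_value == pytest.approx(1 / 6)

    def test_identical_singletons_degenerate(self):
        res = mann_whitney_exact([5.0], [5.0], alternative="two-sided")
        assert res.p_value == pytest.approx(1.0)
        assert "ties" in res.extra["method"]

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(0)
        for n1 in range(1, 6):
            for n2 in range(1, 6):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2) + 0.5
                for alt in ("greater", "less", "two-sided"):
                    res = mann_whitney_exact(x, y, alternative=alt)
                    assert res.p_value == pytest.approx(
                        brute_force_mw_p(x, y, alt), abs=1e-12
                    )

    def test_matches_scipy_exact_at_study_sizes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=19)
        y = rng.normal(size=24)
        ours = mann_whitney_exact(x, y, alternative="greater")
        ref = sps.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert ours.extra["U"] == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        # and the normal approximation agrees to two decimals under the null
        approx = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert ours.p_value == pytest.approx(approx.pvalue, abs=0.01)

    @given(
        hst.lists(hst.integers(-50, 50), min_size=1, max_size=10),
        hst.lists(hst.integers(-50, 50), min_size=1, max_size=10),
    )
    @settings(max_examples=40, deadline=None)
    def test_rank_sum_u_identity(self, xs, ys):
        res = mann_whitney_exact(np.array(xs, float), np.array(ys, float))
        n1 = len(xs)
        assert res.extra["W"] - res.extra["U"] == pytest.approx(n1 * (n1 + 1) / 2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_exact([], [1.0])


class TestTTests:
    def test_paired_t_on_published_layer_means(self):
        res = paired_t(datasets.FD_MEAN_AD, datasets.FD_MEAN_CTL)
        assert res.df == 9
        assert res.statistic == pytest.approx(3.875, abs=1e-3)

    def test_equal_series_zero_variance_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(x, x)

    def test_independent_t_basic(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=23)
        res = independent_t(x, y)
        assert res.df == 41
        ref = sps.ttest_ind(x, y)
        assert res.statistic == pytest.approx(ref.statistic)

    def test_t_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = paired_t(x, y).statistic
        b = paired_t(100 + 7 * x, 100 + 7 * y).statistic
        assert a == pytest.approx(b)


class TestDistributionalChecks:
    def test_shapiro_on_normal_scores_near_one(self):
        scores = sps.norm.ppf((np.arange(1, 21) - 0.375) / (20 + 0.25))
        assert shapiro_wilk(scores).statistic > 0.99

    def test_shapiro_scale_invariance_and_range(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        assert shapiro_wilk(x).statistic == pytest.approx(
            shapiro_wilk(5 + 3 * x).statistic
        )
        with pytest.raises(ValueError):
            shapiro_wilk(x[:2])

    def test_fisher_f_on_published_layer_means(self):
        res = fisher_variance_ratio(datasets.FD_MEAN_AD, datasets.FD_MEAN_CTL)
        assert res.df == (9, 9)
        assert res.statistic == pytest.approx(0.79, abs=0.005)
        assert res.p_value == pytest.approx(0.73, abs=0.01)

    def test_ks_z_normalization(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=19), rng.normal(size=24)
        res = ks_two_sample(x, y)
        assert res.statistic == pytest.approx(
            res.extra["D"] * math.sqrt(19 * 24 / 43)
        )

    def test_proportions_z_symmetric(self):
        res = proportions_z(6, 19, 8, 24)
        assert abs(res.statistic) < 1.0  # similar sex ratios: no difference
        assert res.p_value > 0.5
        flipped = proportions_z(8, 24, 6, 19)
        assert flipped.statistic == pytest.approx(-res.statistic)


class TestCorrelationMatrix:
    @staticmethod
    def _table(n=40, seed=0, link=0.0):
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        data = {}
        for k in range(1, 11):
            data[f"fd_layer_{k}"] = 2.1 + 0.01 * (
                0.7 * latent + rng.normal(size=n)
            )
        import pandas as pd

        df = pd.DataFrame(data)
        df["group"] = ["AD"] * (n // 2) + ["CTL"] * (n - n // 2)
        df["mmse"] = 26 - link * latent + rng.normal(size=n)
        df["visual_acuity"] = 0.9 - 0.05 * link * latent + 0.1 * rng.normal(size=n)
        df["age"] = 77 + link * latent + 2 * rng.normal(size=n)
        return df

    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_one_sided(x, 2 * x, "greater")
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_shape_and_symmetry(self):
        cm = correlation_matrix(self._table())
        assert cm.r.shape == (13, 13)
        np.testing.assert_allclose(cm.r.values, cm.r.values.T)
        assert np.allclose(np.diag(cm.r), 1.0)

    def test_built_in_negative_mmse_link_recovered(self):
        cm = correlation_matrix(self._table(n=120, seed=1, link=3.0))
        sub = cm.r.loc[[f"fd_layer_{k}" for k in range(1, 11)], "mmse"]
        assert (sub < 0).all()
        sig = cm.significant.loc[[f"fd_layer_{k}" for k in range(1, 11)], "mmse"]
        assert sig.sum() >= 8

    def test_one_sided_false_positive_rate_calibrated(self):
        # independent columns: one-sided tests at alpha=.05 must reject ~5%
        rng = np.random.default_rng(6)
        n, reps, hits = 43, 400, 0
        for _ in range(reps):
            x, y = rng.normal(size=n), rng.normal(size=n)
            _, p = pearson_one_sided(x, y, "greater")
            hits += p < 0.05
        rate = hits / reps
        assert 0.03 < rate < 0.08

    def test_constant_column_flagged_undefined(self):
        df = self._table()
        df["age"] = 50.0
        cm = correlation_matrix(df)
        assert np.isnan(cm.r.loc["fd_layer_1", "age"])
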