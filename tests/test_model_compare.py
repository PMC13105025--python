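import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellskew.dist_models import FitResult, fit_mle, model_cdf, model_quantile
from cellskew.model_compare import (
    anova_oneway,
    bootstrap_r2m,
    compare_families,
    information_criteria,
    ks_statistic,
    pairwise_welch_holm,
    qq_points,
    r2_qq,
    select_best,
)
from cellskew.synthetic import SyntheticSpec, generate_sample


class TestInformationCriteria:
    def test_aic_formula(self):
        aic, _ = information_criteria(-100.0, k=2, n=50)
        assert aic == 204.0

    def test_bic_formula(self):
        _, bic = information_criteria(-100.0, k=2, n=100)
        assert bic == pytest.approx(2 * np.log(100) + 200)

    def test_delta_aic_invariant_to_common_loglik_shift(self):
        a1, _ = information_criteria(-100.0, 2, 10)
        a2, _ = information_criteria(-110.0, 3, 10)
        b1, _ = information_criteria(-100.0 + 7.0, 2, 10)
        b2, _ = information_criteria(-110.0 + 7.0, 3, 10)
        assert a2 - a1 == pytest.approx(b2 - b1)


def _brute_force_ks(x, family, params, grid_size=20_000):
    """Independent sup |ECDF - CDF| via a dense grid plus the jump points."""
    x = np.sort(x)
    grid = np.unique(
        np.concatenate([np.linspace(x[0] * 0.5, x[-1] * 1.5, grid_size), x])
    )
    ecdf_right = np.searchsorted(x, grid, side="right") / x.size
    ecdf_left = np.searchsorted(x, grid, side="left") / x.size
    f = model_cdf(family, params, grid)
    return max(np.max(np.abs(ecdf_right - f)), np.max(np.abs(ecdf_left - f)))


class TestKsStatistic:
    def test_data_at_midpoint_quantiles_gives_half_over_n(self):
        n = 20
        q = model_quantile("lognormal", [1.0, 0.5], (np.arange(1, n + 1) - 0.5) / n)
        assert ks_statistic(q, "lognormal", [1.0, 0.5]) == pytest.approx(0.5 / n)

    def test_disjoint_support_gives_one(self):
        assert ks_statistic(np.full(5, 10.0), "uniform", [0.0, 1.0]) == pytest.approx(1.0)

    def test_single_datum_at_median_gives_half(self):
        med = model_quantile("lognormal", [0.0, 1.0], [0.5])
        assert ks_statistic(med, "lognormal", [0.0, 1.0]) == pytest.approx(0.5)

    @given(
        mu=st.floats(-1.0, 3.0),
        sigma=st.floats(0.2, 2.0),
        n=st.integers(3, 100),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_sup(self, mu, sigma, n, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(mu, sigma, size=n))
        d = ks_statistic(x, "lognormal", [mu, sigma])
        assert d == pytest.approx(_brute_force_ks(x, "lognormal", [mu, sigma]), abs=1e-12)


class TestR2QQ:
    def test_perfect_model_gives_one(self):
        n = 50
        q = model_quantile("gamma", [2.0, 0.5], (np.arange(1, n + 1) - 0.5) / n)
        assert r2_qq(q, "gamma", [2.0, 0.5]) == pytest.approx(1.0, abs=1e-12)

    def test_lognormal_beats_truncated_gaussian_on_skewed_data(self):
        s = generate_sample(
            SyntheticSpec("lognormal", {"mu_log": 2.0, "sigma": 1.5}, n=10_000, seed=4)
        )
        ln = fit_mle(s, "lognormal")
        ga = fit_mle(s, "gaussian_trunc")
        assert ln.r2_qq > ga.r2_qq

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            r2_qq(np.full(5, 2.0), "lognormal", [0.0, 1.0])


class TestQQPoints:
    def test_perfect_model_lies_on_identity(self):
        n = 30
        q = model_quantile("lognormal", [0.0, 1.0], (np.arange(1, n + 1) - 0.5) / n)
        pts = qq_points(q, "lognormal", [0.0, 1.0])
        np.testing.assert_allclose(pts[:, 0], pts[:, 1], rtol=1e-10)

    def test_m_equal_n_means_no_subsampling(self, lognormal_sample):
        pts = qq_points(lognormal_sample, "lognormal", [2.0, 1.0], m=lognormal_sample.n_events)
        np.testing.assert_array_equal(pts[:, 1], np.sort(lognormal_sample.values))

    def test_subsampling_is_seed_deterministic(self, lognormal_sample):
        a = qq_points(lognormal_sample, "lognormal", [2.0, 1.0], m=100, seed=3)
        b = qq_points(lognormal_sample, "lognormal", [2.0, 1.0], m=100, seed=3)
        np.testing.assert_array_equal(a, b)


def _fit(family, aic, converged=True):
    return FitResult(family=family, params=np.array([1.0]), loglik=0.0, n=10,
                     converged=converged, aic=aic, bic=aic)


class TestSelectBest:
    def test_clear_winner_has_singleton_tie_set(self):
        t = select_best([_fit("lognormal", 100), _fit("gamma", 103), _fit("pareto", 104)])
        assert t.best_family == "lognormal"
        assert t.tie_set == ["lognormal"]

    def test_within_delta_models_tie(self):
        t = select_best([_fit("lognormal", 100), _fit("gamma", 101)])
        assert set(t.tie_set) == {"lognormal", "gamma"}

    def test_single_fit_is_best(self):
        assert select_best([_fit("gamma", 50)]).best_family == "gamma"

    def test_non_converged_fits_excluded(self):
        t = select_best([_fit("uniform", 10, converged=False), _fit("gamma", 50)])
        assert t.best_family == "gamma"
        with pytest.raises(ValueError, match="converged"):
            select_best([_fit("uniform", 10, converged=False)])

    def test_compare_families_picks_lognormal_for_lognormal_data(self, lognormal_sample):
        t = compare_families(lognormal_sample, ("lognormal", "gamma", "gaussian_trunc"))
        assert t.best_family == "lognormal"
        assert t.sample_id == "ln_ref"


class TestBootstrapR2m:
    def test_single_rep_equals_one_subsample_fit(self, lognormal_sample):
        mean_r2, _ = bootstrap_r2m([lognormal_sample], "lognormal", n_sub=500, reps=1, seed=7)
        rng = np.random.default_rng(7)
        sub = rng.choice(lognormal_sample.values, size=500, replace=False)
        fit = fit_mle(sub, "lognormal", compute_gof=False)
        assert mean_r2 == pytest.approx(r2_qq(sub, "lognormal", fit.params))

    def test_correct_model_pool_scores_high_at_moderate_skew(self):
        # at large sigma the extreme order statistics dominate SS_res and the
        # mean Q-Q r2 of even the true model drops well below 1
        s = generate_sample(
            SyntheticSpec("lognormal", {"mu_log": 2.0, "sigma": 0.5}, n=20_000, seed=11)
        )
        mean_r2, _ = bootstrap_r2m([s], "lognormal", n_sub=5_000, reps=20, seed=1)
        assert mean_r2 > 0.99

    def test_same_seed_reproduces_mean(self, lognormal_sample):
        a = bootstrap_r2m([lognormal_sample], "lognormal", n_sub=500, reps=5, seed=3)
        b = bootstrap_r2m([lognormal_sample], "lognormal", n_sub=500, reps=5, seed=3)
        assert a == b

    def test_pool_smaller_than_subsample_errors(self, lognormal_sample):
        with pytest.raises(ValueError, match="subsample"):
            bootstrap_r2m([lognormal_sample], "lognormal", n_sub=10**6, reps=1, seed=0)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, df1, df2, p = anova_oneway([[1.0, 2.0], [1.0, 2.0]])
        assert f == 0.0 and p == 1.0

    def test_hand_decomposition(self):
        f, df1, df2, p = anova_oneway([[0.0, 1.0], [2.0, 3.0]])
        assert (f, df1, df2) == (pytest.approx(8.0), 1, 2)
        from scipy import stats

        assert p == pytest.approx(float(stats.f.sf(8.0, 1, 2)))

    def test_shift_invariance(self):
        groups = [[0.1, 0.9, 0.4], [1.2, 0.8, 1.4]]
        f1 = anova_oneway(groups)[0]
        f2 = anova_oneway([[g + 5.0 for g in grp] for grp in groups])[0]
        assert f1 == pytest.approx(f2)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i, 1.0, size=8) for i in range(3)]
        from scipy import stats

        f, _, _, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0, 2.0]])
        with pytest.raises(ValueError, match="within-group"):
            anova_oneway([[1.0, 1.0], [2.0, 2.0]])


class TestPairwiseWelchHolm:
    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(i, 1.0, size=10) for i, k in enumerate("abc")}
        df = pairwise_welch_holm(groups)
        assert (df["p_holm"] >= df["p"] - 1e-15).all()
        assert len(df) == 3
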