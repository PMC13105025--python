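import numpy as np
import pytest
from scipy import stats

from cellskew.resp_sim import (
    BiasSurface,
    SimConfig,
    bias_surface,
    lognormal_mulog,
    mean_respiration,
    mm_respiration,
    quadrature_bias,
    quadrature_mean_respiration,
    respiration_bias,
    sample_gaussian_activity,
    sample_lognormal_activity,
)

SMALL = dict(n=100_000)


class TestGaussianBaseline:
    def test_zero_cv_gives_constant_activity(self):
        e = sample_gaussian_activity(SimConfig(n=100, cv=0.0, seed=0))
        np.testing.assert_array_equal(e, 1e5)

    def test_floored_fraction_matches_normal_tail(self):
        cfg = SimConfig(n=1_000_000, seed=1)
        e = sample_gaussian_activity(cfg)
        frac = np.mean(e == cfg.floor)
        # P(N(mu, 0.25 mu) <= 0) = Phi(-4) ~ 3.17e-5; allow Poisson scatter
        assert 1e-5 < frac < 6e-5
        assert np.all(e > 0)

    def test_sample_mean_within_clt_bound(self):
        cfg = SimConfig(n=1_000_000, seed=2)
        e = sample_gaussian_activity(cfg)
        assert abs(e.mean() - cfg.mu) < 3 * 0.25 * cfg.mu / 1e3


class TestLognormalActivity:
    def test_mulog_examples(self):
        assert lognormal_mulog(10.0, 0.0) == pytest.approx(np.log(10.0))
        assert lognormal_mulog(1e5, 2.0) == pytest.approx(5 * np.log(10) - 2.0)

    def test_analytic_mean_is_exactly_mu(self):
        for sigma in (0.01, 0.5, 1.0, 2.0, 3.5):
            mulog = lognormal_mulog(1e5, sigma)
            assert np.exp(mulog + sigma**2 / 2) == pytest.approx(1e5, rel=1e-12)

    @pytest.mark.parametrize("sigma,rel", [(0.01, 0.001), (1.0, None)])
    def test_sample_mean_preserved_within_mc_error(self, sigma, rel):
        cfg = SimConfig(n=1_000_000, seed=3)
        e = sample_lognormal_activity(cfg, sigma)
        if rel is not None:
            assert e.mean() == pytest.approx(cfg.mu, rel=rel)
        else:
            se = cfg.mu * np.sqrt(np.e - 1.0) / 1e3
            assert abs(e.mean() - cfg.mu) < 3 * se

    def test_median_below_mean_for_positive_sigma(self):
        cfg = SimConfig(n=100_000, seed=4)
        e = sample_lognormal_activity(cfg, 1.5)
        assert np.median(e) < cfg.mu
        assert np.median(e) == pytest.approx(np.exp(lognormal_mulog(cfg.mu, 1.5)), rel=0.02)


class TestMichaelisMenten:
    def test_half_saturation_point(self):
        assert mm_respiration(np.array([100.0]), 1.0, 100.0)[0] == 0.5

    def test_zero_and_saturation_limits(self):
        assert mm_respiration(np.array([0.0]), 1.0, 10.0)[0] == 0.0
        assert mm_respiration(np.array([1e12]), 1.0, 10.0)[0] == pytest.approx(1.0, abs=1e-6)

    def test_mean_respiration_basics(self):
        assert mean_respiration(np.full(5, 0.3)) == pytest.approx(0.3)
        assert mean_respiration(np.array([0.0, 1.0])) == 0.5
        rng = np.random.default_rng(0)
        r = rng.random(100)
        assert mean_respiration(r) == pytest.approx(mean_respiration(r[::-1]), rel=1e-14)


class TestRespirationBias:
    @pytest.mark.parametrize("sigma,km,tol", [
        (0.01, 1e2, 0.005),
        (2.0, 1e5, 0.02),
        (3.5, 1e5, 0.05),
    ])
    def test_matches_quadrature_oracle(self, sigma, km, tol):
        cfg = SimConfig(seed=5, **SMALL)
        _, _, ir = respiration_bias(cfg, sigma, km)
        expected = quadrature_bias(cfg.mu, cfg.cv, sigma, cfg.rmax, km, floor=cfg.floor)
        assert ir == pytest.approx(expected, rel=tol)

    def test_near_degenerate_sigma_gives_unit_ratio(self):
        cfg = SimConfig(seed=6, **SMALL)
        _, _, ir = respiration_bias(cfg, 0.01, 1e2)
        assert ir == pytest.approx(1.0, abs=0.005)


class TestBiasSurface:
    def test_single_cell_grid_equals_respiration_bias(self):
        cfg = SimConfig(n=10_000, km_values=[1e3], sigma_values=[1.0], seed=7)
        surf = bias_surface(cfg)
        assert len(surf.table) == 1
        r_ln, r_ga, ir = respiration_bias(cfg, 1.0, 1e3)
        assert surf.table.iloc[0]["ir"] == ir

    def test_ir_nonincreasing_in_sigma_at_fixed_km(self):
        cfg = SimConfig(sigma_values=[0.01, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5],
                        km_values=[1e3, 1e5], seed=8, **SMALL)
        surf = bias_surface(cfg)
        mc_se = 3.0 / np.sqrt(cfg.n)  # generous bound on MC jitter of the ratio
        for km, grp in surf.table.groupby("km"):
            ir = grp.sort_values("sigma")["ir"].to_numpy()
            assert np.all(np.diff(ir) <= mc_se)

    def test_bias_larger_at_high_km_for_strong_skew(self):
        cfg = SimConfig(sigma_values=[1.0, 2.0, 3.0], km_values=[1e2, 1e5], seed=9, **SMALL)
        t = bias_surface(cfg).table
        for sigma in cfg.sigma_values:
            lo = t[(t.km == 1e2) & (t.sigma == sigma)]["pct_bias"].iloc[0]
            hi = t[(t.km == 1e5) & (t.sigma == sigma)]["pct_bias"].iloc[0]
            assert hi > lo

    def test_jensen_upper_bound_on_mean_respiration(self):
        cfg = SimConfig(sigma_values=[0.5, 2.0], km_values=[1e3, 1e5], seed=10, **SMALL)
        t = bias_surface(cfg).table
        for _, row in t.iterrows():
            bound = cfg.rmax * cfg.mu / (row.km + cfg.mu)
            assert row.mean_r_lognormal < bound + 3.0 / np.sqrt(cfg.n)
            assert row.mean_r_gaussian < bound + 3.0 / np.sqrt(cfg.n)

    def test_same_seed_gives_bit_identical_surfaces(self):
        cfg = SimConfig(n=10_000, sigma_values=[0.5, 1.5], km_values=[1e3], seed=11)
        a, b = bias_surface(cfg), bias_surface(cfg)
        assert a.table.equals(b.table)

    def test_grid_refinement_leaves_existing_cells_unchanged(self):
        coarse = SimConfig(n=10_000, sigma_values=[0.5, 1.5], km_values=[1e3], seed=12)
        fine = SimConfig(n=10_000, sigma_values=[0.5, 1.0, 1.5], km_values=[1e3], seed=12)
        a = bias_surface(coarse).table.set_index("sigma")
        b = bias_surface(fine).table.set_index("sigma")
        for sigma in (0.5, 1.5):
            assert a.loc[sigma, "ir"] == b.loc[sigma, "ir"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(mu=-1.0)
        with pytest.raises(ValueError):
            SimConfig(km_values=[0.0])


class TestQuadratureOracle:
    def test_sigma_to_zero_limit_is_point_mass_response(self):
        r = quadrature_mean_respiration("lognormal", 1e5, 1e-8, 1.0, 1e4)
        assert r == pytest.approx(1e5 / (1e4 + 1e5), rel=1e-9)

    def test_joint_scaling_of_mu_and_km_is_invariant(self):
        a = quadrature_mean_respiration("lognormal", 1e5, 1.5, 1.0, 1e4)
        b = quadrature_mean_respiration("lognormal", 2e5, 1.5, 1.0, 2e4)
        assert a == pytest.approx(b, rel=1e-9)

    def test_gaussian_oracle_matches_explicit_integral(self):
        mu, cv, km = 1e5, 0.25, 1e3
        sd = cv * mu
        dist = stats.norm(mu, sd)
        from scipy.integrate import quad

        val, _ = quad(lambda e: dist.pdf(e) * e / (km + e), 0, mu + 10 * sd, limit=200)
        val += dist.cdf(0.0) * 0.1 / (km + 0.1)
        r = quadrature_mean_respiration("gaussian_trunc", mu, cv, 1.0, km)
        assert r == pytest.approx(val, rel=1e-8)

    def test_monte_carlo_agrees_over_spot_grid(self):
        cfg = SimConfig(seed=13, **SMALL)
        for km in (1e2, 1e4, 1e5):
            for sigma in (0.5, 1.5, 3.0):
                e = sample_lognormal_activity(cfg, sigma, None)
                # direct draw (not the per-cell substream) is fine: compare means
                r_mc = mean_respiration(mm_respiration(e, cfg.rmax, km))
                r_q = quadrature_mean_respiration("lognormal", cfg.mu, sigma, cfg.rmax, km)
                mc_se = np.std(mm_respiration(e, cfg.rmax, km)) / np.sqrt(cfg.n)
                assert abs(r_mc - r_q) < 4 * mc_se
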