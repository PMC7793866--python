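"""ACF/FRAP fitting: round trips, model selection, and FRAP normalization."""

import numpy as np
import pytest

from fcsfrap import (
    ACFParams1C,
    ACFParams2C,
    CorrelationCurve,
    FitConfig,
    FRAPParams,
    fit_acf,
    fit_frap,
    frap_model,
    generate_analytic_acf,
    normalize_frap,
    select_model,
)
from fcsfrap.fitting import ONE_COMPONENT, TWO_COMPONENT


class TestFitACF:
    def test_noiseless_two_component_round_trip(self, geom, lag_grid):
        truth = ACFParams2C(n_particles=1.0, f1=0.73, tau_d1=135.8e-6, tau_d2=4.043e-3)
        curve, _ = generate_analytic_acf(truth, geom, lag_grid)
        fit = fit_acf(curve, TWO_COMPONENT, geom)
        assert fit.converged
        p = fit.params
        assert p.n_particles == pytest.approx(truth.n_particles, rel=1e-3)
        assert p.f1 == pytest.approx(truth.f1, rel=1e-3)
        assert p.tau_d1 == pytest.approx(truth.tau_d1, rel=1e-3)
        assert p.tau_d2 == pytest.approx(truth.tau_d2, rel=1e-3)
        assert fit.slow_fraction_pct == pytest.approx(27.0, abs=0.1)

    def test_round_trip_sweep_of_random_parameter_sets(self, geom, lag_grid):
        rng = np.random.default_rng(20)
        for _ in range(25):
            truth = ACFParams1C(
                n_particles=rng.uniform(0.3, 30), tau_d=10 ** rng.uniform(-5, -2.5)
            )
            curve, _ = generate_analytic_acf(truth, geom, lag_grid)
            p = fit_acf(curve, ONE_COMPONENT, geom).params
            assert p.n_particles == pytest.approx(truth.n_particles, rel=1e-3)
            assert p.tau_d == pytest.approx(truth.tau_d, rel=1e-3)
        for _ in range(25):
            t1 = 10 ** rng.uniform(-4.5, -3.5)
            truth = ACFParams2C(
                n_particles=rng.uniform(0.3, 30),
                f1=rng.uniform(0.3, 0.9),
                tau_d1=t1,
                tau_d2=t1 * rng.uniform(15, 100),
            )
            curve, _ = generate_analytic_acf(truth, geom, lag_grid)
            p = fit_acf(curve, TWO_COMPONENT, geom).params
            assert p.f1 == pytest.approx(truth.f1, rel=1e-3)
            assert p.tau_d1 == pytest.approx(truth.tau_d1, rel=1e-3)
            assert p.tau_d2 == pytest.approx(truth.tau_d2, rel=1e-3)

    def test_two_component_fit_of_one_component_data_is_nested(self, geom, lag_grid):
        truth = ACFParams1C(n_particles=2.0, tau_d=2e-4)
        curve, _ = generate_analytic_acf(truth, geom, lag_grid)
        fit1 = fit_acf(curve, ONE_COMPONENT, geom)
        fit2 = fit_acf(curve, TWO_COMPONENT, geom)
        p = fit2.params
        assert p.f1 >= 0.999 or p.tau_d2 / p.tau_d1 < 1.1
        assert fit2.sse <= fit1.sse + 1e-20

    def test_flat_zero_curve_flags_nonconvergence(self, geom, lag_grid):
        curve = CorrelationCurve(lags=lag_grid, g=np.zeros_like(lag_grid))
        fit = fit_acf(curve, ONE_COMPONENT, geom)
        assert not fit.converged
        assert fit.params is None

    def test_fit_respects_minimum_lag_cutoff(self, geom):
        # points below 0.01 ms are corrupted; the fit must ignore them
        lags = np.geomspace(1e-7, 1.0, 300)
        truth = ACFParams1C(n_particles=1.5, tau_d=2e-4)
        curve, _ = generate_analytic_acf(truth, geom, lags)
        g = curve.g.copy()
        g[lags < 1e-5] += 5.0  # gross afterpulsing-like artifact
        corrupted = CorrelationCurve(lags=lags, g=g)
        p = fit_acf(corrupted, ONE_COMPONENT, geom).params
        assert p.tau_d == pytest.approx(truth.tau_d, rel=1e-6)

    def test_unit_invariance_of_the_lag_axis(self, geom, lag_grid):
        # a curve exported in ms and converted back to s fits identically
        truth = ACFParams2C(n_particles=1.0, f1=0.6, tau_d1=1e-4, tau_d2=5e-3)
        curve, _ = generate_analytic_acf(truth, geom, lag_grid)
        roundtrip = CorrelationCurve(lags=(curve.lags * 1e3) / 1e3, g=curve.g)
        a = fit_acf(curve, TWO_COMPONENT, geom).params
        b = fit_acf(roundtrip, TWO_COMPONENT, geom).params
        assert a.tau_d1 == pytest.approx(b.tau_d1, rel=1e-12)

    def test_insufficient_lags_rejected(self, geom):
        curve = CorrelationCurve(lags=np.geomspace(1e-5, 1e-4, 5), g=np.ones(5))
        with pytest.raises(ValueError, match="lags"):
            fit_acf(curve, ONE_COMPONENT, geom)


class TestSelectModel:
    def test_two_component_data_selected_under_noise(self, geom, lag_grid):
        truth = ACFParams2C(n_particles=1.0, f1=0.7, tau_d1=1.3e-4, tau_d2=30 * 1.3e-4)
        curve, _ = generate_analytic_acf(
            truth, geom, lag_grid, "multiplicative_gaussian", 0.01, rng_seed=5
        )
        model_id, fit = select_model(curve, geom)
        assert model_id == TWO_COMPONENT

    def test_one_component_data_selected_under_noise(self, geom, lag_grid):
        truth = ACFParams1C(n_particles=1.0, tau_d=2e-4)
        curve, _ = generate_analytic_acf(
            truth, geom, lag_grid, "multiplicative_gaussian", 0.01, rng_seed=6
        )
        model_id, _ = select_model(curve, geom)
        assert model_id == ONE_COMPONENT

    def test_parsimony_on_noiseless_single_component(self, geom, lag_grid):
        curve, _ = generate_analytic_acf(ACFParams1C(1.0, 2e-4), geom, lag_grid)
        model_id, _ = select_model(curve, geom)
        assert model_id == ONE_COMPONENT

    def test_runs_test_criterion_also_detects_two_components(self, geom, lag_grid):
        truth = ACFParams2C(n_particles=1.0, f1=0.7, tau_d1=1.3e-4, tau_d2=4e-3)
        curve, _ = generate_analytic_acf(
            truth, geom, lag_grid, "multiplicative_gaussian", 0.01, rng_seed=7
        )
        config = FitConfig(model_selection_criterion="aic_plus_runs_test")
        model_id, _ = select_model(curve, geom, config)
        assert model_id == TWO_COMPONENT


class TestNormalizeFRAP:
    def test_equal_bleach_and_cell_signals_give_unity(self):
        t = np.arange(1.0, 21.0)
        ic = 900.0 * np.exp(-0.01 * t) + 50
        out = normalize_frap(t, ic, ic, np.full_like(t, 30.0))
        np.testing.assert_allclose(out, 1.0, rtol=1e-12)

    def test_construction_inverts_exactly_despite_bleaching(self):
        p = FRAPParams(fd=0.1, fi=1.0, m=2.0, alpha=1.0)
        t = np.arange(1.0, 61.0)
        bg = 10.0
        ic = 1000.0 * np.exp(-t / 200.0) + bg
        ib = bg + (ic - bg) * frap_model(t, p)
        out = normalize_frap(t, ib, ic, np.full_like(t, bg))
        f = frap_model(t, p)
        # plateau max: 3-frame moving average over the last 20% of frames
        window = f[-12:]
        peak = np.max(np.convolve(window, np.ones(3) / 3, mode="valid"))
        np.testing.assert_allclose(out, f / peak, rtol=1e-10)

    def test_background_exceeding_cell_signal_names_the_frame(self):
        t = np.arange(1.0, 11.0)
        ic = np.full_like(t, 100.0)
        ic[4] = 5.0
        with pytest.raises(ValueError, match="frame 4"):
            normalize_frap(t, ic, ic, np.full_like(t, 30.0))


class TestFitFRAP:
    def test_noiseless_round_trip(self):
        p = FRAPParams(fd=0.1, fi=1.0, m=2.0, alpha=1.0)
        t = np.arange(1.0, 61.0)
        fit = fit_frap(t, frap_model(t, p))
        assert fit.converged
        assert fit.t_half == pytest.approx(2.0, rel=5e-3)
        assert fit.params.fd == pytest.approx(0.1, abs=1e-3)
        assert fit.params.alpha == pytest.approx(1.0, rel=1e-3)

    def test_median_half_time_error_under_noise(self):
        # sampling must resolve the half-time: several frames before t = m
        p = FRAPParams(fd=0.1, fi=0.95, m=2.0, alpha=1.0)
        t = np.arange(0.2, 60.0, 0.2)
        truth = frap_model(t, p)
        config = FitConfig(multistart_count=3)
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_frap(t, truth + rng.normal(0, 0.02, t.size), config)
            errors.append(abs(fit.t_half - p.m) / p.m)
        assert np.median(errors) <= 0.05

    def test_noisy_fit_reaches_the_global_optimum_at_coarse_sampling(self):
        # with 1 s frames and m = 2 s the half-time is weakly identified, but
        # the fit must still land at (or below) the SSE of the true parameters
        p = FRAPParams(fd=0.1, fi=0.95, m=2.0, alpha=1.0)
        t = np.arange(1.0, 61.0)
        truth = frap_model(t, p)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = truth + rng.normal(0, 0.02, t.size)
            fit = fit_frap(t, y, FitConfig(multistart_count=3))
            assert fit.sse <= float(np.sum((y - truth) ** 2)) + 1e-12

    def test_flat_curve_has_zero_mobile_fraction(self):
        t = np.arange(1.0, 31.0)
        fit = fit_frap(t, np.full_like(t, 0.4))
        assert fit.mobile_fraction_pct == pytest.approx(0.0, abs=1.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            fit_frap(np.arange(1.0, 6.0), np.linspace(0.2, 0.8, 5))
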