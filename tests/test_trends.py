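"""Penalized-spline and beta-response smooths, back-transformed curves."""

import numpy as np
import pytest
from scipy.special import expit

from glycoda.coda import GP_COLUMNS, close, ilr, ilr_inverse
from glycoda.simulate import (BASELINE_GP_PERCENT, GeneratorConfig,
                              generate_cohort, trend_matrix)
from glycoda.trends import (bspline_basis, fit_beta_smooth, fit_psmooth,
                            fit_sexwise_ilr_trends, predict_composition_curve,
                            sex_difference_windows)


def cox_de_boor(x, t, i, k):
    """Independent recursive B-spline evaluation (oracle)."""
    if k == 0:
        return float(t[i] <= x < t[i + 1])
    out = 0.0
    if t[i + k] > t[i]:
        out += (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    if t[i + k + 1] > t[i + 1]:
        out += (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * \
            cox_de_boor(x, t, i + 1, k - 1)
    return out


class TestBsplineBasis:
    def test_partition_of_unity(self, rng):
        x = rng.uniform(0, 10, 200)
        b = bspline_basis(x, n_basis=12, degree=3)
        assert np.abs(b.sum(axis=1) - 1).max() < 1e-12

    def test_degree_zero_is_indicator(self):
        x = np.array([0.1, 1.1, 2.1, 3.1])
        b = bspline_basis(x, n_basis=4, degree=0, domain=(0, 4))
        assert np.allclose(b, np.eye(4))

    def test_matches_cox_de_boor_oracle(self):
        x = np.linspace(0, 1, 17)
        degree, n_basis = 3, 8
        b = bspline_basis(x, n_basis, degree)
        t = np.linspace(-0.6, 1.6, 12)  # uniform knots, 5 segments on [0,1]
        for xi, row in zip(x[:-1], b[:-1]):  # oracle is half-open at 1
            oracle = [cox_de_boor(xi, t, i, degree) for i in range(n_basis)]
            assert np.allclose(row, oracle, atol=1e-12)

    def test_too_few_basis_functions(self):
        with pytest.raises(ValueError):
            bspline_basis(np.linspace(0, 1, 10), n_basis=2, degree=3)


class TestFitPsmooth:
    def test_constant_reproduced(self, rng):
        x = rng.uniform(0, 50, 100)
        fit = fit_psmooth(x, np.full(100, 3.7))
        assert np.abs(fit.predict(np.linspace(0, 50, 20)) - 3.7).max() < 1e-8

    def test_line_in_penalty_null_space(self, rng):
        x = rng.uniform(0, 50, 100)
        y = 2.0 + 0.5 * x
        fit = fit_psmooth(x, y, lambda_grid=[1e6])
        grid = np.linspace(x.min(), x.max(), 20)
        assert np.abs(fit.predict(grid) - (2.0 + 0.5 * grid)).max() < 1e-6

    def test_sin_recovery(self, rng):
        x = rng.uniform(0, 100, 500)
        y = np.sin(x / 10) + rng.normal(0, 0.1, 500)
        fit = fit_psmooth(x, y, n_basis=20)
        grid = np.linspace(0, 100, 200)
        rmse = np.sqrt(np.mean((fit.predict(grid) - np.sin(grid / 10)) ** 2))
        assert rmse < 0.05

    def test_gcv_lambda_larger_for_pure_noise(self, rng):
        x = rng.uniform(0, 100, 400)
        signal = np.sin(x / 8)
        lam_signal = fit_psmooth(x, signal + rng.normal(0, 0.1, 400)).lam
        lam_noise = fit_psmooth(x, rng.normal(0, 0.1, 400)).lam
        assert lam_noise > lam_signal

    def test_deterministic_refit(self, rng):
        x = rng.uniform(0, 10, 60)
        y = rng.normal(size=60)
        a = fit_psmooth(x, y)
        b = fit_psmooth(x, y)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lam == b.lam

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="20"):
            fit_psmooth(np.arange(10.0), np.arange(10.0))


class TestCompositionCurves:
    def test_noise_free_recovery_and_closure(self):
        cfg = GeneratorConfig(n_subjects=700, noise_sd=0.0, factor_sd=0.0,
                              delta_cluster=np.zeros(45), seed=21)
        sim = generate_cohort(cfg)
        fits = fit_sexwise_ilr_trends(sim.cohort_table)
        grid = np.linspace(22, 87, 25)
        for sex, is_f in (("M", False), ("F", True)):
            curves = predict_composition_curve(fits, sex, grid, n_draws=200,
                                               seed=0)
            mean = np.column_stack([c.mean for c in curves])
            truth = ilr_inverse(
                ilr(close(BASELINE_GP_PERCENT))[None, :]
                + trend_matrix(cfg, grid, np.full(grid.size, is_f)))
            assert np.abs(mean - truth).max() < 0.5
            assert np.abs(mean.sum(axis=1) - 100).max() < 0.1
            for c in curves:
                assert np.all(c.lower95 <= c.mean + 1e-9)
                assert np.all(c.mean <= c.upper95 + 1e-9)

    def test_band_width_monotone_in_noise(self):
        widths = []
        for noise in (0.05, 0.25, 0.6):
            cfg = GeneratorConfig(n_subjects=400, noise_sd=noise,
                                  factor_sd=0.0, delta_cluster=np.zeros(45),
                                  seed=31)
            sim = generate_cohort(cfg)
            fits = fit_sexwise_ilr_trends(sim.cohort_table)
            curves = predict_composition_curve(fits, "F",
                                               np.linspace(25, 85, 15),
                                               n_draws=200, seed=0)
            widths.append(np.mean([np.mean(c.upper95 - c.lower95)
                                   for c in curves]))
        assert widths[0] < widths[1] < widths[2]

    def test_draw_floor(self, small_cohort):
        fits = fit_sexwise_ilr_trends(small_cohort.cohort_table)
        with pytest.raises(ValueError, match="n_draws"):
            predict_composition_curve(fits, "F", np.linspace(20, 80, 5),
                                      n_draws=50)


class TestBetaSmooth:
    def test_constant_fraction(self, rng):
        x = rng.uniform(0, 80, 300)
        y = np.clip(0.3 + rng.normal(0, 1e-3, 300), 1e-6, 1 - 1e-6)
        fit = fit_beta_smooth(x, y)
        grid = np.linspace(0, 80, 30)
        mu, se = fit.predict(grid, se=True)
        mu_resp = expit(mu)
        assert np.abs(mu_resp - 0.3).max() < 0.01
        lo = expit(mu - 1.96 * se)
        hi = expit(mu + 1.96 * se)
        assert np.all((lo <= 0.3) & (0.3 <= hi))

    def test_parameter_recovery(self, rng):
        x = rng.uniform(0, 100, 800)
        mu = expit(-1 + x / 50)
        y = rng.beta(mu * 50, (1 - mu) * 50)
        fit = fit_beta_smooth(x, y)
        grid = np.linspace(0, 100, 100)
        rmse = np.sqrt(np.mean((fit.predict_response(grid)
                                - expit(-1 + grid / 50)) ** 2))
        assert rmse < 0.02

    def test_fitted_mean_strictly_inside_unit_interval(self, rng):
        x = rng.uniform(0, 50, 200)
        y = rng.beta(2, 30, 200)
        fit = fit_beta_smooth(x, y)
        mu = fit.predict_response(np.linspace(0, 50, 40))
        assert np.all((mu > 0) & (mu < 1))

    def test_boundary_values_nudged_with_warning(self, rng):
        x = rng.uniform(0, 50, 200)
        y = rng.beta(2, 10, 200)
        y[0] = 0.0
        with pytest.warns(UserWarning, match="nudged"):
            fit_beta_smooth(x, y)


class TestSexDifferenceWindows:
    def test_label_swap_gives_identical_windows(self, rng):
        x = rng.uniform(18, 90, 400)
        y_m = 0.5 * np.sin(x / 15) + rng.normal(0, 0.2, 400)
        y_f = rng.normal(0, 0.2, 400)
        fit_m = fit_psmooth(x, y_m)
        fit_f = fit_psmooth(x, y_f)
        grid = np.linspace(20, 88, 50)
        assert sex_difference_windows(fit_m, fit_f, grid) == \
            sex_difference_windows(fit_f, fit_m, grid)

    def test_null_trends_rarely_flagged(self):
        cfg = GeneratorConfig(n_subjects=1000, delta_cluster=np.zeros(45),
                              factor_sd=0.0, seed=41)
        # force identical sex trends
        amps = cfg.age_trend_amplitudes
        amps["lin_amp"][:, 1] = amps["lin_amp"][:, 0]
        amps["sin_amp"][:, 1] = amps["sin_amp"][:, 0]
        amps["sex_offset"][:] = 0.0
        sim = generate_cohort(cfg)
        fits = fit_sexwise_ilr_trends(sim.cohort_table)
        grid = np.linspace(22, 87, 40)
        flagged = 0
        for j in range(45):
            for lo, hi in sex_difference_windows(fits[(j, "M")],
                                                 fits[(j, "F")], grid):
                flagged += np.sum((grid >= lo) & (grid <= hi))
        assert flagged / (45 * grid.size) <= 0.10

    def test_injected_divergence_after_age_50_detected(self):
        cfg = GeneratorConfig(n_subjects=1500, delta_cluster=np.zeros(45),
                              factor_sd=0.0, seed=43)
        sim = generate_cohort(cfg)
        tab = sim.cohort_table.copy()
        z = ilr(tab[GP_COLUMNS].to_numpy())
        bump = np.maximum(tab["age"].to_numpy() - 50.0, 0.0) / 40.0
        z[:, 10] += bump * (tab["sex"] == "F").to_numpy()
        tab[GP_COLUMNS] = ilr_inverse(z)
        fits = fit_sexwise_ilr_trends(tab)
        grid = np.linspace(20, 90, 70)
        windows = sex_difference_windows(fits[(10, "M")], fits[(10, "F")], grid)
        assert any(hi > 60 and lo > 45 for lo, hi in windows)
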