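"""Backfitting, the local-linear smoother, and the reference-model zoo."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from svcpois import (
    DegenerateDesignWarning,
    ReferenceModel,
    SVCPoissonRegressor,
    SimConfig,
    build_design,
    fit_parametric_given_alpha,
    fit_reference_model,
    local_linear_alpha,
    select_bandwidth,
    simulate_calls,
    validate_series,
)
from svcpois.data_model import DesignMatrices
from svcpois.estimation import _kernel_weights, _qp_irls

from conftest import make_table


def brute_force_local_linear(t, d, R, h, kernel, var_w=None):
    """Independent oracle: solve each target's 2x2 weighted normal equations."""
    out = np.empty(len(t))
    vw = np.ones_like(d) if var_w is None else var_w
    for i, t0 in enumerate(t):
        w = _kernel_weights((t - t0) / h, kernel) * vw
        A = np.column_stack([d, d * (t - t0)])
        M = A.T @ (A * w[:, None])
        rhs = A.T @ (w * R)
        out[i] = np.linalg.solve(M, rhs)[0]
    return out


def _toy_design(n, seed=0, tarp_scale=3.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(5, 60, size=n)
    tq = rng.random(n) * tarp_scale
    tn = rng.random(n) * tarp_scale
    series = validate_series(make_table(y, tarp_quit=tq, tarp_nrt=tn))
    return series, build_design(series)


class TestLocalLinearAlpha:
    @pytest.mark.parametrize("n", [8, 12, 15])
    @pytest.mark.parametrize("kernel", ["epanechnikov", "gaussian"])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_normal_equations(self, n, kernel, weighted):
        series, design = _toy_design(n + 1, seed=n)
        rng = np.random.default_rng(n + 99)
        beta = rng.normal(scale=0.05, size=6)
        gamma = rng.normal(scale=0.5, size=8)
        mu = design.y_resp + 1.0 if weighted else None
        h = 4.0
        got = local_linear_alpha(series, design, beta, gamma, h, kernel, mu=mu)
        R = design.y_resp - design.y_prev * (design.X @ beta) - design.Z @ gamma
        var_w = None if mu is None else 1.0 / mu
        want = brute_force_local_linear(
            design.t, design.y_prev, R, h, kernel, var_w
        )
        assert np.allclose(got, want, atol=1e-8, rtol=1e-8)

    @pytest.mark.parametrize("bandwidth", [2.0, 6.0, 50.0])
    def test_exact_on_constant_carryover(self, bandwidth):
        # Y_j = 2 * Y_{j-1} exactly; beta = gamma = 0 -> alpha = 2 everywhere
        y = 2 ** np.arange(10)
        series = validate_series(make_table(y))
        design = build_design(series)
        a = local_linear_alpha(series, design, np.zeros(6), np.zeros(8), bandwidth)
        assert np.allclose(a, 2.0, atol=1e-10)

    @pytest.mark.parametrize("bandwidth", [3.0, 8.0])
    def test_reproduces_linear_coefficient_exactly(self, bandwidth):
        # local-linear smoothing preserves a coefficient linear in time
        rng = np.random.default_rng(5)
        d = rng.integers(3, 30, size=20).astype(float)
        t = np.arange(1.0, 21.0)
        a_true = 0.5 + 0.03 * t
        R = d * a_true
        design = DesignMatrices(
            X=np.zeros((20, 6)),
            Z=np.zeros((20, 8)),
            y_prev=d,
            y_resp=R,
            dates=pd.date_range("2000-08-07", periods=20),
            t=t,
        )
        a = local_linear_alpha(None, design, np.zeros(6), np.zeros(8), bandwidth)
        assert np.allclose(a, a_true, atol=1e-9)

    def test_sparse_local_support_widens_and_warns(self):
        # all but two previous-day counts are zero: most windows are empty
        y = [0, 0, 0, 4, 5, 0, 0, 0, 0, 0]
        series = validate_series(make_table(y))
        design = build_design(series)
        with pytest.warns(DegenerateDesignWarning, match="widening"):
            a = local_linear_alpha(series, design, np.zeros(6), np.zeros(8), 1.5)
        assert np.all(np.isfinite(a))


class TestParametricStep:
    def test_recovers_truth_on_noiseless_data(self):
        series, truth = _noiseless_unit_alpha_series()
        design = build_design(series)
        beta, gamma = fit_parametric_given_alpha(series, design, np.ones(design.n))
        assert np.allclose(beta, 0.0, atol=1e-8)
        assert np.allclose(gamma, truth, atol=1e-8)

    def test_score_equations_hold_at_solution(self, sim360):
        series, truth = sim360
        design = build_design(series)
        beta, gamma = fit_parametric_given_alpha(series, design, truth.alpha)
        mu = design.y_prev * (truth.alpha + design.X @ beta) + design.Z @ gamma
        D = np.column_stack([design.y_prev[:, None] * design.X, design.Z])
        score = D.T @ ((design.y_resp - mu) / mu)
        assert np.abs(score).max() < 1e-6

    def test_unit_weights_reduce_to_ols(self, sim360):
        series, truth = sim360
        design = build_design(series)
        beta, gamma = fit_parametric_given_alpha(
            series, design, truth.alpha, variance_weighting=False
        )
        D = np.column_stack([design.y_prev[:, None] * design.X, design.Z])
        resp = design.y_resp - design.y_prev * truth.alpha
        ols = np.linalg.lstsq(D, resp, rcond=None)[0]
        assert np.allclose(np.concatenate([beta, gamma]), ols, atol=1e-8)

    def test_irls_matches_statsmodels_identity_poisson(self):
        # independent oracle for the quasi-Poisson solver on a benign design
        rng = np.random.default_rng(3)
        n = 300
        x1 = rng.random(n) * 10
        x2 = rng.random(n) * 5
        mu_true = 20 + 2.0 * x1 + 1.0 * x2
        y = rng.poisson(mu_true).astype(float)
        D = np.column_stack([np.ones(n), x1, x2])
        theta, conv = _qp_irls(y, D, names=["c", "x1", "x2"])
        glm = sm.GLM(
            y, D, family=sm.families.Poisson(link=sm.families.links.Identity())
        ).fit(start_params=theta)
        assert conv
        assert np.allclose(theta, glm.params, rtol=1e-6)


def _noiseless_unit_alpha_series(n=60):
    """Integer-valued data exactly satisfying the recursion with alpha'=1.

    gamma day effects are integers and the TARP effects act on even TARP
    values, so Y_j = Y_{j-1} + Z_j'gamma stays integral and noiseless.
    """
    gamma = np.array([5, 3, 4, 2, 6, 1, 0.5, 0.25])
    dates = pd.date_range("2000-08-06", periods=n, freq="D")
    wd = dates.weekday.to_numpy()
    rng = np.random.default_rng(11)
    tq = 2.0 * rng.integers(0, 4, size=n)
    tn = 4.0 * rng.integers(0, 3, size=n)
    y = np.empty(n, dtype=np.int64)
    y[0] = 20
    for j in range(1, n):
        day_effect = gamma[wd[j]] if wd[j] < 6 else 0.0
        y[j] = y[j - 1] + day_effect + 0.5 * tq[j] + 0.25 * tn[j]
    series = validate_series(make_table(y, tarp_quit=tq, tarp_nrt=tn))
    return series, gamma


class TestFitSVCM:
    def test_recovers_parameters_on_one_dataset(self, sim360, fit360):
        _, truth = sim360
        assert fit360.converged_
        assert np.abs(fit360.beta_ - truth.beta).max() < 0.2
        assert np.abs(fit360.gamma_[:6] - truth.gamma[:6]).max() < 8.0
        assert abs(fit360.gamma_[6] - truth.gamma[6]) < 0.1
        assert np.abs(fit360.alpha_ - truth.alpha).mean() < 0.1

    def test_mu_recomputable_from_params(self, fit360):
        from svcpois import conditional_mean

        mu = conditional_mean(fit360.params_, fit360.design_)
        assert np.allclose(mu, fit360.mu_, rtol=1e-10)
        assert np.all(fit360.mu_ > 0)

    def test_large_bandwidth_collapses_to_constant_alpha_model(self):
        # on exactly-noiseless data the smoother's slope is exactly zero and
        # the huge-bandwidth fit coincides with the constant-alpha Model 3
        series, _ = _noiseless_unit_alpha_series()
        est = SVCPoissonRegressor(
            bandwidth=1e6, variance_weighting=True
        ).fit(series)
        ref = ReferenceModel(model_id=3).fit(series)
        alpha_const = ref.params_[0]
        theta_ref = ref.params_[1:]
        assert np.allclose(est.alpha_, alpha_const, atol=1e-4)
        assert np.allclose(
            est.params_.theta, theta_ref, atol=1e-4 * (1 + np.abs(theta_ref))
        )

    def test_large_bandwidth_near_model3_on_noisy_data(self):
        series, _ = simulate_calls(SimConfig(alpha_fn="constant"), seed=21)
        est = SVCPoissonRegressor(bandwidth=1e6).fit(series)
        ref = ReferenceModel(model_id=3).fit(series)
        rel = np.abs(est.gamma_ - ref.params_[7:]) / (np.abs(ref.params_[7:]) + 1.0)
        assert rel.max() < 1e-2

    def test_zero_tarp_column_is_an_error(self):
        with pytest.raises(ValueError, match="tarp_nrt"):
            SVCPoissonRegressor().fit(
                make_table([5] * 40, tarp_quit=np.ones(40))
            )

    def test_constant_counts_flagged_as_degenerate(self):
        # constant y makes y_prev*X collinear with X: rank-deficient design
        with pytest.warns(DegenerateDesignWarning):
            est = SVCPoissonRegressor(bandwidth=10).fit(
                make_table(
                    [7] * 40,
                    tarp_quit=np.linspace(1, 4, 40),
                    tarp_nrt=np.linspace(2, 3, 40),
                )
            )
        assert np.all(np.isfinite(est.params_.theta))

    def test_short_series_warns(self):
        with pytest.warns(UserWarning, match="response days"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                SVCPoissonRegressor(bandwidth=4).fit(
                    make_table(
                        [9, 12, 10, 14, 9, 6, 5, 8, 11, 13],
                        tarp_quit=np.arange(10) % 3 + 1.0,
                        tarp_nrt=np.arange(10) % 2 + 1.0,
                    )
                )

    def test_wrss_descends_nearly_monotonically(self, fit360):
        h = np.asarray(fit360.wrss_history_)
        assert h[-1] <= h[0]
        if len(h) > 1:
            assert np.diff(h).max() <= 1e-3 * h[0]


class TestSelectBandwidth:
    def test_singleton_grid_returned_with_note(self, sim360):
        series, _ = sim360
        with pytest.warns(UserWarning, match="single candidate"):
            assert select_bandwidth(series, grid=[7.0]) == 7.0

    def test_selected_bandwidth_minimizes_cv(self):
        series, _ = simulate_calls(SimConfig(n_days=150), seed=31)
        h, scores = select_bandwidth(
            series, grid=[7.0, 14.0, 28.0], return_scores=True
        )
        assert scores[h] <= min(scores.values()) * (1 + 1e-12)

    def test_constant_alpha_prefers_largest_bandwidth(self):
        series, _ = simulate_calls(
            SimConfig(n_days=240, alpha_fn="constant"), seed=17
        )
        h = select_bandwidth(series, grid=[7.0, 14.0, 28.0])
        assert h == 28.0


class TestReferenceModels:
    def test_model1_perfect_plane_has_zero_mse(self):
        n = 12
        rng = np.random.default_rng(2)
        tq = rng.integers(0, 5, size=n).astype(float)
        tn = rng.integers(0, 5, size=n).astype(float)
        y = (10 + 2 * tq + 3 * tn).astype(int)
        fit = fit_reference_model(
            make_table(y, tarp_quit=tq, tarp_nrt=tn), model_id=1
        )
        assert np.allclose(fit.mu, y[1:], atol=1e-8)

    def test_model1_matches_closed_form_ols_on_toy_table(self):
        y = np.array([30, 42, 55, 38, 61, 47, 33, 52, 44])
        tq = np.array([0.0, 5, 10, 2, 12, 7, 1, 9, 6])
        tn = np.array([3.0, 1, 4, 2, 6, 3, 0, 5, 2])
        fit = fit_reference_model(
            make_table(y, tarp_quit=tq, tarp_nrt=tn), model_id=1
        )
        A = np.column_stack([np.ones(8), tq[1:], tn[1:]])
        want = np.linalg.solve(A.T @ A, A.T @ y[1:])
        assert np.allclose(fit.params, want, atol=1e-10)

    def test_models_nest_in_sample_mse(self, sim360):
        from svcpois import mse

        series, _ = sim360
        design = build_design(series)
        fits = {m: fit_reference_model(series, m, bandwidth=14.0) for m in (3, 4)}
        full = SVCPoissonRegressor(bandwidth=14.0).fit(series)
        m5 = mse(design.y_resp, full.mu_)
        m4 = mse(design.y_resp, fits[4].mu)
        m3 = mse(design.y_resp, fits[3].mu)
        # the full model nests both restricted conditional models
        assert m5 <= m4 + 1e-6
        assert m5 <= m3 + 1e-6

    def test_unknown_model_id_rejected(self, sim360):
        with pytest.raises(ValueError, match="model_id"):
            fit_reference_model(sim360[0], model_id=7)
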