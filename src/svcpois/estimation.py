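"""Fitting the semi-varying coefficient conditional Poisson model.

The conditional mean

    mu_j = Y_{j-1} * (alpha(t_j) + X_j' beta) + Z_j' gamma

mixes a smooth curve ``alpha(t)`` with parametric coefficients ``(beta,
gamma)``.  Estimation is profile backfitting:

* given ``(beta, gamma)``, the curve is estimated by local-linear kernel
  smoothing of the partial residual ``R_j = Y_j - Y_{j-1} X_j'beta -
  Z_j'gamma`` against time, with the previous-day count entering the local
  design (the curve multiplies ``Y_{j-1}``) and optional quasi-Poisson
  variance weights ``1/mu_j``;
* given ``alpha``, the parametric part solves the identity-link quasi-Poisson
  estimating equations (IRLS with weights ``1/mu_j`` and offset
  ``Y_{j-1} alpha_j``).

The two half-steps alternate until the parameters stop moving.  The public
face is :class:`SVCPoissonRegressor`, a scikit-learn style estimator; the
module functions below it are thin wrappers kept for scripting convenience.
Four simpler reference models (ordinary least squares on TARPs, identity-link
Poisson on TARPs, constant-``alpha``, and varying-``alpha`` without the
day-of-week carryover) are available through :class:`ReferenceModel` for
MSE comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .data_model import (
    DAY_LABELS,
    DailySeries,
    DesignMatrices,
    PositivityError,
    SVCParams,
    build_design,
    conditional_mean,
    validate_series,
    _mean_no_check,
)

__all__ = [
    "SVCPoissonRegressor",
    "ReferenceModel",
    "ConvergenceWarning",
    "DegenerateDesignWarning",
    "SingularDesignError",
    "DEFAULT_BANDWIDTH_GRID",
    "PARAM_NAMES",
    "fit_svcm",
    "local_linear_alpha",
    "fit_parametric_given_alpha",
    "select_bandwidth",
    "fit_reference_model",
]

DEFAULT_BANDWIDTH_GRID = (7.0, 10.0, 14.0, 21.0, 30.0)

#: Coefficient names in reporting order (carryover modifiers, then immigration).
PARAM_NAMES = tuple(f"beta{i + 1} ({d})" for i, d in enumerate(DAY_LABELS)) + tuple(
    f"gamma{i + 1} ({lab})"
    for i, lab in enumerate(DAY_LABELS + ("TARPs Quit", "TARPs NRT"))
)


class ConvergenceWarning(UserWarning):
    pass


class DegenerateDesignWarning(UserWarning):
    pass


class SingularDesignError(np.linalg.LinAlgError):
    """Weighted cross-product matrix is singular; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular weighted cross-product; collinear column(s): "
            + ", ".join(self.columns)
        )


def _kernel_weights(u: np.ndarray, kernel: str) -> np.ndarray:
    if kernel == "epanechnikov":
        return 0.75 * np.clip(1.0 - u * u, 0.0, None)
    if kernel == "gaussian":
        return np.exp(-0.5 * u * u)
    raise ValueError(f"unknown kernel {kernel!r}; use 'epanechnikov' or 'gaussian'")


def clipped_mean(alpha, beta, gamma, design: DesignMatrices, eps: float = 1e-8):
    """Conditional mean clipped below at eps — used inside iterative solvers only."""
    return np.clip(_mean_no_check(alpha, beta, gamma, design), eps, None)


# ---------------------------------------------------------------------------
# quasi-Poisson IRLS (identity link, offset)
# ---------------------------------------------------------------------------


def _collinear_columns(D: np.ndarray, names) -> list:
    # pick out columns whose singular direction loads them heavily
    _, s, vt = np.linalg.svd(D, full_matrices=False)
    null = vt[s < max(s.max(), 1.0) * 1e-10] if s.size else vt
    if null.size == 0:
        return list(names)
    load = np.abs(null).max(axis=0)
    return [n for n, l in zip(names, load) if l > 0.1]


def _wls(D, resp, w, names, on_singular):
    A = D.T @ (D * w[:, None])
    b = D.T @ (w * resp)
    try:
        # the weighted Gram matrix is PD iff the design has full column rank;
        # a Cholesky solve detects (near-)singularity cheaply
        L = np.linalg.cholesky(A)
        theta = sla.cho_solve((L, True), b)
        if not np.all(np.isfinite(theta)):
            raise np.linalg.LinAlgError
        return theta
    except np.linalg.LinAlgError:
        if on_singular == "raise":
            raise SingularDesignError(_collinear_columns(D * np.sqrt(w)[:, None], names))
        warnings.warn(
            "rank-deficient parametric design; returning a minimum-norm "
            "(pseudo-inverse) solution",
            DegenerateDesignWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(A) @ b


def _qp_irls(
    y,
    D,
    offset=0.0,
    *,
    names=None,
    theta0=None,
    eps=1e-8,
    tol=1e-10,
    max_iter=50,
    variance_weighting=True,
    on_singular="raise",
    w_floor=None,
):
    """Identity-link quasi-Poisson IRLS: solve sum_j (y_j - mu_j)/mu_j d_j = 0.

    mu = offset + D theta; weights 1/max(mu, w_floor) are refreshed each
    sweep.  The weight floor guards against the identity link wandering
    negative mid-iteration (a clipped mean of eps would otherwise hand a
    single day a weight of 1/eps and capsize the solve); it defaults to 1%
    of the mean response.  With ``variance_weighting=False`` this is a
    single ordinary least-squares solve on the offset-adjusted response.
    """
    y = np.asarray(y, dtype=float)
    D = np.asarray(D, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), y.shape)
    names = list(names) if names is not None else [f"col{i}" for i in range(D.shape[1])]
    resp = y - offset
    if not variance_weighting:
        return _wls(D, resp, np.ones_like(y), names, on_singular), True
    if w_floor is None:
        w_floor = max(eps, 0.01 * float(y.mean()))
    if theta0 is None:
        theta = _wls(D, resp, 1.0 / np.clip(y, 1.0, None), names, on_singular)
    else:
        theta = np.asarray(theta0, dtype=float).copy()
    converged = False
    for _ in range(max_iter):
        mu = np.clip(offset + D @ theta, w_floor, None)
        new = _wls(D, resp, 1.0 / mu, names, on_singular)
        delta = np.max(np.abs(new - theta)) / max(1.0, np.max(np.abs(theta)))
        theta = new
        if delta < tol:
            converged = True
            break
    return theta, converged


# ---------------------------------------------------------------------------
# local-linear smoothing of the varying coefficient
# ---------------------------------------------------------------------------


def _local_linear_core(t, d, R, h, kernel, var_w=None, targets=None, warn=True):
    """Local-linear estimate of a(t0) in R_j ~ d_j*(a + b(t_j - t0)).

    Vectorised over targets: weighted moment sums are matrix products against
    the (m, n) kernel weight matrix.  Points with d_j = 0 carry zero weight by
    construction.  Targets whose effective local sample (kernel support with
    d_j > 0) is below 2, or whose 2x2 normal matrix is numerically singular,
    get a progressively widened window (h doubling), with a warning.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    R = np.asarray(R, dtype=float)
    targets = t if targets is None else np.atleast_1d(np.asarray(targets, dtype=float))
    vw = np.ones_like(d) if var_w is None else np.asarray(var_w, dtype=float)
    d2v = d * d * vw
    dRv = d * R * vw

    def moments(h_, rows=None):
        tg = targets if rows is None else targets[rows]
        U = t[None, :] - tg[:, None]
        W = _kernel_weights(U / h_, kernel)
        S0 = W @ d2v
        WU = W * U
        S1 = WU @ d2v
        S2 = (WU * U) @ d2v
        T0 = W @ dRv
        T1 = WU @ dRv
        eff = ((W > 0) & (d > 0)[None, :]).sum(axis=1)
        return S0, S1, S2, T0, T1, eff

    def solve(S0, S1, S2, T0, T1, eff):
        det = S0 * S2 - S1 * S1
        scale = np.abs(S0 * S2) + S1 * S1 + 1e-300
        ok = (eff >= 2) & (det > 1e-10 * scale)
        a = np.full(S0.shape, np.nan)
        a[ok] = (S2[ok] * T0[ok] - S1[ok] * T1[ok]) / det[ok]
        return a, ok

    a, ok = solve(*moments(h))
    if not np.all(ok):
        if warn:
            warnings.warn(
                f"{(~ok).sum()} smoothing target(s) had fewer than 2 effective "
                "local observations; widening the window there",
                DegenerateDesignWarning,
                stacklevel=3,
            )
        span = max(t.max() - t.min(), 1.0)
        rows = np.nonzero(~ok)[0]
        h_ = float(h)
        while rows.size and h_ < 8.0 * span:
            h_ *= 2.0
            a_w, ok_w = solve(*moments(h_, rows))
            a[rows[ok_w]] = a_w[ok_w]
            rows = rows[~ok_w]
        if rows.size:
            # nothing identifiable anywhere (e.g. y_prev == 0 throughout):
            # fall back to a local-constant value, 0 if even that is empty
            S0, _, _, T0, _, _ = moments(8.0 * span, rows)
            with np.errstate(invalid="ignore", divide="ignore"):
                lc = np.where(S0 > 0, T0 / np.where(S0 > 0, S0, 1.0), 0.0)
            a[rows] = lc
    return a


class _SmootherCache:
    """Kernel moment matrices for repeated alpha half-steps at fixed (t, h).

    The (n, n) kernel matrices depend only on the time grid, bandwidth and
    kernel, so backfit iterations (and bootstrap refits) reduce to a handful
    of matrix-vector products.  Targets with a degenerate local problem fall
    back to the widening path of :func:`_local_linear_core`.
    """

    def __init__(self, t, h, kernel):
        self.t = np.asarray(t, dtype=float)
        self.h = float(h)
        self.kernel = kernel
        U = self.t[None, :] - self.t[:, None]
        self.W = _kernel_weights(U / self.h, kernel)
        self.WU = self.W * U
        self.WUU = self.WU * U
        self.Wpos = (self.W > 0).astype(float)

    def alpha(self, d, R, vw=None):
        d2v = d * d if vw is None else d * d * vw
        dRv = d * R if vw is None else d * R * vw
        S0 = self.W @ d2v
        S1 = self.WU @ d2v
        S2 = self.WUU @ d2v
        T0 = self.W @ dRv
        T1 = self.WU @ dRv
        det = S0 * S2 - S1 * S1
        scale = np.abs(S0 * S2) + S1 * S1 + 1e-300
        eff = self.Wpos @ (d > 0).astype(float)
        ok = (eff >= 2) & (det > 1e-10 * scale)
        a = np.empty(len(S0))
        a[ok] = (S2[ok] * T0[ok] - S1[ok] * T1[ok]) / det[ok]
        if not np.all(ok):
            full = _local_linear_core(
                self.t, d, R, self.h, self.kernel, vw, warn=False
            )
            a[~ok] = full[~ok]
        return a


def _loo_alpha(t, d, R, h, kernel, var_w=None):
    """Leave-one-out alpha at each observation's own time point.

    At target t_j the left-out point sits at u = 0, so only the S0/T0 moment
    sums change: subtract the point's own kernel-weighted contribution.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    vw = np.ones_like(d) if var_w is None else np.asarray(var_w, dtype=float)
    d2v = d * d * vw
    dRv = d * R * vw
    U = t[None, :] - t[:, None]
    W = _kernel_weights(U / h, kernel)
    # the left-out point sits at u = 0: only the S0/T0 sums lose its
    # contribution, with self-weight K(0) (vw is already folded into d2v/dRv)
    k0 = float(_kernel_weights(np.zeros(1), kernel)[0])
    S0 = W @ d2v - k0 * d2v
    WU = W * U
    S1 = WU @ d2v
    S2 = (WU * U) @ d2v
    T0 = W @ dRv - k0 * dRv
    T1 = WU @ dRv
    det = S0 * S2 - S1 * S1
    scale = np.abs(S0 * S2) + S1 * S1 + 1e-300
    ok = det > 1e-10 * scale
    a = np.full(len(t), np.nan)
    a[ok] = (S2[ok] * T0[ok] - S1[ok] * T1[ok]) / det[ok]
    if np.any(~ok):  # fall back to the in-sample estimate where LOO is degenerate
        a_in = _local_linear_core(t, d, np.asarray(R, float), h, kernel, var_w, warn=False)
        a[~ok] = a_in[~ok]
    return a


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class SVCPoissonRegressor(BaseEstimator):
    """Semi-varying coefficient conditional Poisson regressor.

    Parameters
    ----------
    bandwidth : float or "auto", default 14.0
        Kernel bandwidth in days.  "auto" selects from ``bandwidth_grid`` by
        leave-one-out cross-validation of the one-step prediction error.
    kernel : {"epanechnikov", "gaussian"}
        Epanechnikov (compact support) is the default.
    bandwidth_grid : sequence of float
        Candidates for "auto"; defaults to {7, 10, 14, 21, 30} days, the
        scale of the trend features (advertising flights, holiday surges).
    max_backfit_iter, tol : backfitting control.  Convergence is declared
        when the largest change across (alpha, beta, gamma), relative to the
        largest current magnitude, drops below ``tol``.
    variance_weighting : bool
        Weight both half-steps by 1/mu (quasi-Poisson).  Off gives plain
        least squares in both half-steps.
    include_day_carryover : bool
        With False, drops the X'beta carryover modifiers (reference Model 4).
    eps : float
        Positivity clip for means inside the solvers.

    Attributes (after fit)
    ----------------------
    alpha_, beta_, gamma_ : estimated curve (length J-1) and coefficients.
    params_ : SVCParams bundle.
    mu_ : fitted conditional means, response days 2..J.
    bandwidth_ : resolved bandwidth in days.
    converged_, n_iter_, wrss_history_ : backfitting diagnostics.
    series_, design_ : the fitted data.
    """

    def __init__(
        self,
        bandwidth=14.0,
        kernel="epanechnikov",
        bandwidth_grid=DEFAULT_BANDWIDTH_GRID,
        max_backfit_iter=100,
        tol=1e-6,
        variance_weighting=True,
        include_day_carryover=True,
        eps=1e-8,
    ):
        self.bandwidth = bandwidth
        self.kernel = kernel
        self.bandwidth_grid = bandwidth_grid
        self.max_backfit_iter = max_backfit_iter
        self.tol = tol
        self.variance_weighting = variance_weighting
        self.include_day_carryover = include_day_carryover
        self.eps = eps
        # one IRLS sweep per backfit iteration: the outer alternation supplies
        # the remaining sweeps, and a single sweep keeps the composite map a
        # plain coordinate update (empirically monotone in the weighted RSS)
        self._irls_sweeps = 1

    # -- internals ---------------------------------------------------------

    def _coerce(self, series) -> DailySeries:
        if isinstance(series, DailySeries):
            return series
        return validate_series(series)

    def _parametric_design(self, design: DesignMatrices):
        if self.include_day_carryover:
            D = np.column_stack([design.y_prev[:, None] * design.X, design.Z])
            names = list(PARAM_NAMES)
        else:
            D = design.Z
            names = [n for n in PARAM_NAMES if n.startswith("gamma")]
        return D, names

    def _split_theta(self, theta):
        if self.include_day_carryover:
            return theta[:6], theta[6:]
        return np.zeros(6), theta

    def _check_design(self, design: DesignMatrices):
        for k, name in ((6, "tarp_quit"), (7, "tarp_nrt")):
            if np.all(design.Z[:, k] == 0.0):
                raise ValueError(
                    f"degenerate design: column {name} is identically zero; "
                    "the advertising effect is not identifiable"
                )

    def _initial_fit(self, design, on_singular):
        # joint constant-alpha fit: the curve enters as one more column y_prev
        D, names = self._parametric_design(design)
        D0 = np.column_stack([design.y_prev, D])
        theta, _ = _qp_irls(
            design.y_resp,
            D0,
            names=["alpha(const)"] + names,
            eps=self.eps,
            variance_weighting=self.variance_weighting,
            on_singular=on_singular,
        )
        beta, gamma = self._split_theta(theta[1:])
        return float(theta[0]), beta, gamma

    def _backfit(self, design, h, alpha, beta, gamma, max_iter, tol, on_singular):
        # The parametric half-step solves for a constant alpha-shift c jointly
        # with (beta, gamma) — design column y_prev, offset y_prev*alpha — and
        # folds c back into the curve.  Without this the constant direction of
        # alpha (partially confounded with the y_prev*X carryover columns)
        # is the slowest backfitting mode and convergence crawls.
        D, names = self._parametric_design(design)
        Dc = np.column_stack([design.y_prev, D])
        names_c = ["alpha(shift)"] + names
        cache = self._smoother(design.t, h)
        wrss_history = []
        converged = False
        n_iter = 0
        w_floor = max(self.eps, 0.01 * float(design.y_resp.mean()))
        for n_iter in range(1, max_iter + 1):
            old = np.concatenate([np.atleast_1d(alpha) * np.ones(design.n), beta, gamma])
            mu = clipped_mean(alpha, beta, gamma, design, w_floor)
            var_w = 1.0 / mu if self.variance_weighting else None
            R = design.y_resp - design.y_prev * (design.X @ beta) - design.Z @ gamma
            if n_iter == 1:
                # first pass goes through the widening/warning path
                alpha = _local_linear_core(
                    design.t, design.y_prev, R, h, self.kernel, var_w=var_w
                )
            else:
                alpha = cache.alpha(design.y_prev, R, var_w)
            offset = design.y_prev * alpha
            theta0 = np.concatenate(
                [[0.0], np.concatenate([beta, gamma]) if self.include_day_carryover else gamma]
            )
            theta, _ = _qp_irls(
                design.y_resp,
                Dc,
                offset=offset,
                names=names_c,
                theta0=theta0,
                eps=self.eps,
                max_iter=self._irls_sweeps,
                variance_weighting=self.variance_weighting,
                on_singular=on_singular,
            )
            alpha = alpha + theta[0]
            beta, gamma = self._split_theta(theta[1:])
            mu = clipped_mean(alpha, beta, gamma, design, self.eps)
            resid2 = (design.y_resp - mu) ** 2
            # track the criterion each half-step actually descends: Pearson-
            # weighted under quasi-Poisson weighting, plain RSS otherwise
            wrss_history.append(
                float(np.sum(resid2 / mu)) if self.variance_weighting
                else float(np.sum(resid2))
            )
            new = np.concatenate([alpha, beta, gamma])
            delta = np.max(np.abs(new - old)) / max(1.0, np.max(np.abs(old)))
            if delta < tol:
                converged = True
                break
        return alpha, beta, gamma, converged, n_iter, wrss_history

    def _smoother(self, t, h) -> _SmootherCache:
        cached = getattr(self, "_smoother_cache", None)
        if (
            cached is not None
            and cached.h == float(h)
            and cached.kernel == self.kernel
            and cached.t.shape == np.shape(t)
            and np.array_equal(cached.t, t)
        ):
            return cached
        self._smoother_cache = _SmootherCache(t, h, self.kernel)
        return self._smoother_cache

    # -- API ---------------------------------------------------------------

    def fit(self, series, y=None, *, warm_start_params=None, _on_singular="pinv"):
        """Fit the model to a DailySeries (or a raw 4-column table).

        ``y`` is ignored (the response lives inside the series); it is
        accepted for scikit-learn API compatibility.
        """
        series = self._coerce(series)
        design = build_design(series)
        self._check_design(design)
        if design.n < 20:
            warnings.warn(
                f"only {design.n} response days; at least 20 are recommended",
                UserWarning,
            )
        if self.bandwidth == "auto":
            h = select_bandwidth(series, grid=self.bandwidth_grid, base=self)
        else:
            h = float(self.bandwidth)
            if h <= 0:
                raise ValueError("bandwidth must be positive")
        if warm_start_params is not None:
            alpha0 = warm_start_params.alpha
            beta0 = warm_start_params.beta
            gamma0 = warm_start_params.gamma
        else:
            alpha0, beta0, gamma0 = self._initial_fit(design, _on_singular)
        alpha, beta, gamma, converged, n_iter, wrss = self._backfit(
            design, h, alpha0, beta0, gamma0,
            self.max_backfit_iter, self.tol, _on_singular,
        )
        if not converged:
            warnings.warn(
                f"backfitting did not converge in {n_iter} iterations "
                f"(tol={self.tol:g}); returning the last iterate",
                ConvergenceWarning,
            )
        self.params_ = SVCParams(alpha=alpha, beta=beta, gamma=gamma)
        self.alpha_, self.beta_, self.gamma_ = alpha, beta, gamma
        try:
            self.mu_ = conditional_mean(self.params_, design)
            self.positive_ = True
        except PositivityError as err:
            warnings.warn(
                f"fitted mean non-positive at response index {err.index}; "
                "values clipped at eps in mu_",
                ConvergenceWarning,
            )
            self.mu_ = clipped_mean(alpha, beta, gamma, design, self.eps)
            self.positive_ = False
        self.bandwidth_ = h
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.wrss_history_ = wrss
        self.series_ = series
        self.design_ = design
        return self

    def predict(self, series=None):
        """In-sample fitted conditional means (response days 2..J)."""
        if series is not None:
            raise NotImplementedError(
                "out-of-sample prediction requires an alpha(t) value beyond "
                "the fitted range; refit on the extended series instead"
            )
        return self.mu_


# ---------------------------------------------------------------------------
# reference models (MSE comparison zoo)
# ---------------------------------------------------------------------------


@dataclass
class ReferenceFit:
    """Lightweight result of a reference-model fit (see ReferenceModel)."""

    model_id: int
    params: np.ndarray
    param_names: list
    mu: np.ndarray


class ReferenceModel(BaseEstimator):
    """The four comparison models, plus the full model as id 5.

    1. ordinary least squares of Y_j on (1, TARP_quit, TARP_nrt)
    2. identity-link Poisson, same mean
    3. constant-alpha conditional model (full beta, gamma)
    4. varying alpha with immigration but no day-of-week carryover
    5. the full semi-varying coefficient model

    All models are fitted (and should be scored) on the common response
    window, days 2..J.
    """

    def __init__(self, model_id=1, bandwidth=14.0, kernel="epanechnikov", eps=1e-8):
        self.model_id = model_id
        self.bandwidth = bandwidth
        self.kernel = kernel
        self.eps = eps

    def fit(self, series, y=None):
        series = series if isinstance(series, DailySeries) else validate_series(series)
        design = build_design(series)
        mid = int(self.model_id)
        if mid in (1, 2):
            D = np.column_stack([np.ones(design.n), design.Z[:, 6], design.Z[:, 7]])
            names = ["alpha", "gamma7 (TARPs Quit)", "gamma8 (TARPs NRT)"]
            if mid == 1:
                res = sm.OLS(design.y_resp, D).fit()
                params = np.asarray(res.params)
                mu = np.asarray(res.fittedvalues)
            else:
                params, _ = _qp_irls(design.y_resp, D, names=names, eps=self.eps)
                mu = D @ params
        elif mid == 3:
            D = np.column_stack(
                [design.y_prev, design.y_prev[:, None] * design.X, design.Z]
            )
            names = ["alpha"] + list(PARAM_NAMES)
            params, _ = _qp_irls(design.y_resp, D, names=names, eps=self.eps)
            mu = D @ params
        elif mid in (4, 5):
            est = SVCPoissonRegressor(
                bandwidth=self.bandwidth,
                kernel=self.kernel,
                include_day_carryover=(mid == 5),
                eps=self.eps,
            ).fit(series)
            self.estimator_ = est
            params = est.params_.theta
            names = list(PARAM_NAMES)
            mu = est.mu_
        else:
            raise ValueError(f"model_id must be in 1..5, got {self.model_id}")
        self.result_ = ReferenceFit(mid, np.asarray(params), list(names), np.asarray(mu))
        self.params_ = self.result_.params
        self.mu_ = self.result_.mu
        self.series_ = series
        self.design_ = design
        return self

    def predict(self, series=None):
        if series is not None:
            raise NotImplementedError("in-sample fitted values only")
        return self.mu_


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_svcm(series, spec=None, **kwargs) -> SVCPoissonRegressor:
    """Fit the full model; ``spec`` may be a dict of estimator parameters."""
    params = dict(spec or {})
    params.update(kwargs)
    return SVCPoissonRegressor(**params).fit(series)


def local_linear_alpha(
    series,
    design: DesignMatrices,
    beta,
    gamma,
    bandwidth,
    kernel="epanechnikov",
    mu=None,
    eps=1e-8,
):
    """One alpha half-step: local-linear smooth of the partial residual.

    With ``mu`` given, weights are additionally divided by max(mu, eps)
    (quasi-Poisson variance weighting).
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    R = design.y_resp - design.y_prev * (design.X @ beta) - design.Z @ gamma
    var_w = None if mu is None else 1.0 / np.clip(np.asarray(mu, float), eps, None)
    return _local_linear_core(design.t, design.y_prev, R, float(bandwidth), kernel, var_w)


def fit_parametric_given_alpha(
    series, design: DesignMatrices, alpha, *, variance_weighting=True, eps=1e-8
):
    """One (beta, gamma) half-step: quasi-Poisson IRLS with offset y_prev*alpha.

    With ``variance_weighting=False`` this is ordinary least squares on the
    offset-adjusted response.  Raises SingularDesignError on collinearity.
    """
    offset = design.y_prev * np.broadcast_to(np.atleast_1d(alpha), (design.n,))
    D = np.column_stack([design.y_prev[:, None] * design.X, design.Z])
    theta, _ = _qp_irls(
        design.y_resp,
        D,
        offset=offset,
        names=list(PARAM_NAMES),
        eps=eps,
        variance_weighting=variance_weighting,
        on_singular="raise",
    )
    return theta[:6], theta[6:]


def select_bandwidth(series, spec=None, *, grid=None, base=None, return_scores=False):
    """Leave-one-out cross-validated bandwidth over a candidate grid.

    For each candidate the full backfit runs (warm-started from the previous
    candidate's solution); the CV score is the sum of squared one-step
    prediction errors with alpha(t_j) re-estimated leaving day j out of the
    smoothing step (beta, gamma and the variance weights frozen — the
    parametric part has 14 parameters against hundreds of days, so its LOO
    perturbation is negligible).  Ties break toward the larger (smoother)
    bandwidth.
    """
    series = series if isinstance(series, DailySeries) else validate_series(series)
    params = dict(spec or {})
    if base is not None:
        params = {**base.get_params(), **params}
    grid = tuple(grid if grid is not None else params.pop("bandwidth_grid", DEFAULT_BANDWIDTH_GRID))
    params.pop("bandwidth", None)
    params.pop("bandwidth_grid", None)
    if not grid:
        raise ValueError("bandwidth grid is empty")
    if len(grid) == 1:
        warnings.warn(
            f"bandwidth grid has a single candidate ({grid[0]}); returning it "
            "without cross-validation",
            UserWarning,
        )
        return (float(grid[0]), {float(grid[0]): np.nan}) if return_scores else float(grid[0])
    design = build_design(series)
    scores = {}
    warm = None
    for h in sorted(float(g) for g in grid):
        est = SVCPoissonRegressor(bandwidth=h, **params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(series, warm_start_params=warm)
        warm = est.params_
        mu = est.mu_
        var_w = 1.0 / np.clip(mu, est.eps, None) if est.variance_weighting else None
        R = (
            design.y_resp
            - design.y_prev * (design.X @ est.beta_)
            - design.Z @ est.gamma_
        )
        a_loo = _loo_alpha(design.t, design.y_prev, R, h, est.kernel, var_w)
        mu_loo = (
            design.y_prev * (a_loo + design.X @ est.beta_) + design.Z @ est.gamma_
        )
        scores[h] = float(np.sum((design.y_resp - mu_loo) ** 2))
    best = None
    best_score = np.inf
    for h in sorted(scores):  # ascending: a tie hands the win to the larger h
        if scores[h] <= best_score * (1.0 + 1e-12):
            best, best_score = h, min(scores[h], best_score)
    return (best, scores) if return_scores else best


def fit_reference_model(series, model_id, **kwargs) -> ReferenceFit:
    """Fit one of the comparison models and return its ReferenceFit."""
    return ReferenceModel(model_id=model_id, **kwargs).fit(series).result_
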