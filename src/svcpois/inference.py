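"""Overdispersion-adjusted residual bootstrap inference.

No closed form is available for the standard errors of the parametric
coefficients (beta, gamma), so they are bootstrapped.  Because daily call
counts are typically overdispersed (conditional variance phi * mu with
phi > 1), a plain parametric Poisson bootstrap would understate the noise;
instead the modified Pearson residuals

    r*_j = (y_j - mu_hat_j) / sqrt(phi_hat * mu_hat_j)

are computed with phi_hat chosen so that they have unit second moment,
re-centred, resampled with replacement, and pseudo-responses

    y^b_j = mu_hat_j + r*^b_j * sqrt(phi_hat * mu_hat_j)

are refitted with the bandwidth frozen at the original fit's value (the
bootstrap targets the parametric component; re-selecting the bandwidth per
replicate would mix smoothing variability into the standard errors).
Pseudo-responses are left un-rounded — the quasi-likelihood refit needs only
first and second moments — and negatives are truncated at zero (counted).
Day 1 is held fixed throughout.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import PARAM_NAMES, SVCPoissonRegressor

__all__ = [
    "BootstrapResult",
    "AlphaBand",
    "estimate_dispersion",
    "bootstrap_se",
    "alpha_band",
    "wald_table",
]


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate draws and derived standard errors for the 14 coefficients."""

    phi: float
    B: int
    draws: np.ndarray          # (B, 14) replicate (beta, gamma)
    se: np.ndarray             # (14,)
    z: np.ndarray
    p: np.ndarray
    seed: int | None
    estimate: np.ndarray       # original (beta, gamma)
    names: tuple
    alpha_draws: np.ndarray    # (B, J-1) replicate alpha curves
    n_failed: int              # replicates that raised and were redrawn
    n_truncated: int           # pseudo-responses truncated at zero


@dataclass(frozen=True)
class AlphaBand:
    lower: np.ndarray
    upper: np.ndarray
    level: float
    alpha_hat: np.ndarray
    dates: object = None


def estimate_dispersion(y, mu) -> float:
    """Moment estimator phi_hat = (1/n) sum (y - mu)^2 / mu.

    This is the value that gives the modified Pearson residuals unit second
    moment.  A (near-)zero value is flagged: data that sit exactly on the
    fitted means cannot carry Poisson noise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have equal length")
    if np.any(mu <= 0):
        raise ValueError("all means must be strictly positive")
    phi = float(np.mean((y - mu) ** 2 / mu))
    if phi < 1e-12:
        warnings.warn(
            "dispersion estimate is 0: residuals vanish, the data cannot be "
            "Poisson-noisy around these means",
            UserWarning,
        )
    return phi


def _refit_design(fit: SVCPoissonRegressor, yb, max_iter, tol):
    """Refit the model on a pseudo-response vector (bandwidth frozen).

    This is a conditional (fixed-design) residual bootstrap: the regressors —
    including the previous-day counts Y_{j-1}, which the model conditions
    on — stay at their observed values and only the responses are perturbed.
    Lagging the pseudo-responses into y_prev instead would hand the refit a
    noisy regressor the response does not react to and inflate the carryover
    coefficients' spread (errors-in-variables).  Warm-started at the original
    solution.
    """
    d = fit.design_
    design_b = dataclasses.replace(d, y_resp=yb)
    alpha, beta, gamma, _, _, _ = fit._backfit(
        design_b,
        fit.bandwidth_,
        fit.alpha_,
        fit.beta_,
        fit.gamma_,
        max_iter,
        tol,
        "raise",
    )
    return alpha, beta, gamma


def bootstrap_se(
    fit: SVCPoissonRegressor,
    B: int = 5000,
    seed: int | None = None,
    *,
    phi: float | None = None,
    refit_max_iter: int = 30,
    refit_tol: float = 1e-5,
) -> BootstrapResult:
    """Overdispersion-adjusted nonparametric residual bootstrap.

    Parameters
    ----------
    fit : a fitted SVCPoissonRegressor.
    B : number of replicates (5000 is the conventional reporting default).
    seed : governs all resampling; same seed + same B reproduce bit-identically.
    phi : optional dispersion override (e.g. 1.0 for an unadjusted Poisson
        bootstrap); by default phi is estimated from the fit by
        :func:`estimate_dispersion`.
    refit_max_iter, refit_tol : backfitting control for the replicate refits,
        which warm-start at the original solution and need few iterations.

    Raises
    ------
    RuntimeError
        If more than 10% of replicates raise during refitting.
    """
    if B < 2:
        raise ValueError("need at least B=2 bootstrap replicates")
    if not fit.converged_:
        warnings.warn(
            "bootstrapping a non-converged fit; standard errors may be unreliable",
            UserWarning,
        )
    y = fit.design_.y_resp
    mu = fit.mu_
    n = len(y)
    # residuals are always standardized by the data's own dispersion; the
    # (possibly overridden) phi enters only the reconstruction scale.  With
    # phi=1 the pseudo-responses carry Poisson-scale noise (the unadjusted
    # bootstrap); the default phi_hat restores the empirical dispersion.
    phi_data = estimate_dispersion(y, mu)
    phi_hat = phi_data if phi is None else float(phi)
    std = np.sqrt(np.clip(phi_data, 0.0, None) * mu)
    scale = np.sqrt(np.clip(phi_hat, 0.0, None) * mu)
    with np.errstate(invalid="ignore", divide="ignore"):
        rstar = np.where(std > 0, (y - mu) / np.where(std > 0, std, 1.0), 0.0)
    rstar = rstar - rstar.mean()  # remove O(1/n) mean bias in the pseudo-data

    rng = np.random.default_rng(seed)
    draws = np.empty((B, 14))
    alpha_draws = np.empty((B, n))
    n_failed = 0
    n_truncated = 0
    max_failures = max(int(0.1 * B), 1)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        yb = mu + rstar[idx] * scale
        neg = yb < 0
        n_truncated += int(neg.sum())
        yb = np.where(neg, 0.0, yb)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                alpha_b, beta_b, gamma_b = _refit_design(
                    fit, yb, refit_max_iter, refit_tol
                )
        except Exception:
            n_failed += 1
            if n_failed > max_failures:
                raise RuntimeError(
                    f"{n_failed} of {b + n_failed} bootstrap refits failed; "
                    "the fit is too fragile to bootstrap"
                )
            continue
        draws[b] = np.concatenate([beta_b, gamma_b])
        alpha_draws[b] = alpha_b
        b += 1

    estimate = fit.params_.theta
    se = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimate / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return BootstrapResult(
        phi=phi_hat,
        B=B,
        draws=draws,
        se=se,
        z=z,
        p=p,
        seed=seed,
        estimate=estimate,
        names=PARAM_NAMES,
        alpha_draws=alpha_draws,
        n_failed=n_failed,
        n_truncated=n_truncated,
    )


def alpha_band(
    fit: SVCPoissonRegressor,
    boot: BootstrapResult,
    level: float = 0.95,
    method: str = "percentile",
) -> AlphaBand:
    """Pointwise confidence band for the varying coefficient.

    ``method="percentile"`` (default) takes pointwise quantiles of the
    replicate alpha curves; ``method="normal"`` is alpha_hat ± z * sd(alpha^b).
    The band is expanded, where necessary, to contain the point estimate.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must be in (0, 1), got {level}")
    a = fit.alpha_
    if method == "percentile":
        lo = np.quantile(boot.alpha_draws, (1.0 - level) / 2.0, axis=0)
        hi = np.quantile(boot.alpha_draws, 1.0 - (1.0 - level) / 2.0, axis=0)
    elif method == "normal":
        zq = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
        sd = boot.alpha_draws.std(axis=0, ddof=1)
        lo, hi = a - zq * sd, a + zq * sd
    else:
        raise ValueError("method must be 'percentile' or 'normal'")
    return AlphaBand(
        lower=np.minimum(lo, a),
        upper=np.maximum(hi, a),
        level=level,
        alpha_hat=a,
        dates=fit.design_.dates,
    )


def wald_table(fit: SVCPoissonRegressor, boot: BootstrapResult) -> pd.DataFrame:
    """Coefficient table (name, estimate, se, z, p) in reporting order."""
    if boot.draws.shape[1] != len(boot.estimate):
        raise ValueError("bootstrap result does not match the fit")
    return pd.DataFrame(
        {
            "name": list(boot.names),
            "estimate": boot.estimate,
            "se": boot.se,
            "z": boot.z,
            "p": boot.p,
        }
    )
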