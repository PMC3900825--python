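"""Domain types and design construction for the conditional Poisson call-count model.

The observed record is a daily series: a calendar date, the number of calls
``Y_j`` received that day, and the television advertising weight (TARPs,
target audience rating points) of two campaigns running that day.  The model
conditions each day on the previous one,

    E(Y_j | F_{j-1}) = Y_{j-1} * (alpha_j + X_j' beta) + Z_j' gamma,

where ``X_j`` holds six day-of-week indicators (Monday..Saturday, Sunday is
the reference and codes as the all-zero row), ``Z_j = [X_j, TARP_quit_j,
TARP_nrt_j]``, ``alpha_j`` is a smooth time-varying carryover rate and
``gamma`` is the mean number of "immigrant" callers (people who call without
having been in the previous day's at-risk pool).  Day 1 is conditioning-only:
all per-day vectors produced here are aligned to the response days
``j = 2..J``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DAY_LABELS",
    "Z_COLUMN_LABELS",
    "DailySeries",
    "DesignMatrices",
    "SVCParams",
    "PositivityError",
    "read_series_csv",
    "validate_series",
    "build_design",
    "conditional_mean",
]

#: Day-of-week indicator order (Sunday is the omitted reference category).
DAY_LABELS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat")

#: Column order of the immigration design Z.
Z_COLUMN_LABELS = DAY_LABELS + ("TARPs Quit", "TARPs NRT")

REQUIRED_COLUMNS = ("date", "calls", "tarp_quit", "tarp_nrt")


class PositivityError(ValueError):
    """A conditional mean came out non-positive.

    Attributes
    ----------
    index : int
        Zero-based position within the response days (j = 2..J) of the first
        offending mean.
    """

    def __init__(self, index: int, value: float):
        self.index = int(index)
        self.value = float(value)
        super().__init__(
            f"conditional mean is non-positive (mu={value:.6g}) at response "
            f"day index {index}; an identity-link Poisson mean must be > 0"
        )


@dataclass(frozen=True)
class DailySeries:
    """A validated run of consecutive daily observations.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly consecutive calendar days, length ``J >= 8``.
    y : ndarray of int
        Daily call counts, all ``>= 0``.
    tarp_quit, tarp_nrt : ndarray of float
        Daily advertising weight of the two campaigns, all ``>= 0``.
    """

    dates: pd.DatetimeIndex
    y: np.ndarray
    tarp_quit: np.ndarray
    tarp_nrt: np.ndarray

    def __post_init__(self):
        dates = pd.DatetimeIndex(self.dates)
        y = np.asarray(self.y)
        tq = np.asarray(self.tarp_quit, dtype=float)
        tn = np.asarray(self.tarp_nrt, dtype=float)
        J = len(dates)
        if J < 8:
            raise ValueError(f"need at least 8 consecutive days, got J={J}")
        if not (len(y) == len(tq) == len(tn) == J):
            raise ValueError("dates, y, tarp_quit and tarp_nrt must share a length")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        gaps = np.nonzero(deltas != 1)[0]
        if gaps.size:
            k = gaps[0]
            raise ValueError(
                f"dates must advance by exactly one day; gap between "
                f"{dates[k].date()} and {dates[k + 1].date()}"
            )
        if not np.issubdtype(y.dtype, np.integer):
            yf = y.astype(float)
            if not np.all(np.isfinite(yf)) or np.any(yf != np.round(yf)):
                raise ValueError("call counts must be finite integers")
            y = yf.astype(np.int64)
        if np.any(y < 0):
            k = int(np.argmax(y < 0))
            raise ValueError(f"negative call count {y[k]} on {dates[k].date()}")
        for name, arr in (("tarp_quit", tq), ("tarp_nrt", tn)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "y", y.astype(np.int64))
        object.__setattr__(self, "tarp_quit", tq)
        object.__setattr__(self, "tarp_nrt", tn)

    @property
    def J(self) -> int:
        """Number of observed days (the fit uses the J-1 response days)."""
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "calls": self.y,
                "tarp_quit": self.tarp_quit,
                "tarp_nrt": self.tarp_nrt,
            }
        )


@dataclass(frozen=True)
class DesignMatrices:
    """Model matrices aligned to response days j = 2..J.

    ``X`` is (J-1) x 6 day-of-week indicators (Sunday = all-zero row), ``Z``
    is (J-1) x 8 = [X | tarp_quit | tarp_nrt], ``y_prev[k] = Y_{j-1}`` and
    ``y_resp[k] = Y_j``.  ``t`` is the time coordinate in days since the
    first observation (so 1..J-1 for a gap-free series).
    """

    X: np.ndarray
    Z: np.ndarray
    y_prev: np.ndarray
    y_resp: np.ndarray
    dates: pd.DatetimeIndex
    t: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class SVCParams:
    """Model parameters: varying coefficient plus the parametric effects.

    ``alpha`` has one value per response day (dimensionless carryover rate),
    ``beta`` the six day-of-week modifiers of the carryover, ``gamma`` the
    eight immigration effects (six day-of-week effects in calls/day, then
    calls per TARP unit for the two campaigns).
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        b = np.asarray(self.beta, dtype=float).reshape(-1)
        g = np.asarray(self.gamma, dtype=float).reshape(-1)
        if b.shape != (6,):
            raise ValueError(f"beta must have length 6, got {b.shape}")
        if g.shape != (8,):
            raise ValueError(f"gamma must have length 8, got {g.shape}")
        for name, arr in (("alpha", a), ("beta", b), ("gamma", g)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "gamma", g)

    @property
    def theta(self) -> np.ndarray:
        """The 14 parametric coefficients, (beta, gamma) concatenated."""
        return np.concatenate([self.beta, self.gamma])


def read_series_csv(path) -> DailySeries:
    """Read and validate the standard input CSV (date, calls, tarp_quit, tarp_nrt)."""
    return validate_series(pd.read_csv(path))


def validate_series(raw_table: pd.DataFrame) -> DailySeries:
    """Validate a raw table into a :class:`DailySeries`.

    Raises
    ------
    ValueError
        On missing columns, calendar gaps, negative or non-integer counts,
        or non-numeric TARP values.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in raw_table.columns]
    if missing:
        raise ValueError(f"input table is missing column(s): {', '.join(missing)}")
    dates = pd.to_datetime(raw_table["date"])
    for col in ("tarp_quit", "tarp_nrt"):
        vals = pd.to_numeric(raw_table[col], errors="coerce")
        if vals.isna().any():
            bad = raw_table[col][vals.isna()].iloc[0]
            raise ValueError(f"non-numeric value {bad!r} in column {col}")
    return DailySeries(
        dates=pd.DatetimeIndex(dates),
        y=np.asarray(pd.to_numeric(raw_table["calls"])),
        tarp_quit=np.asarray(pd.to_numeric(raw_table["tarp_quit"]), dtype=float),
        tarp_nrt=np.asarray(pd.to_numeric(raw_table["tarp_nrt"]), dtype=float),
    )


def build_design(series: DailySeries) -> DesignMatrices:
    """Construct the design matrices for response days j = 2..J.

    Day-of-week is taken from the calendar date (pandas: Monday=0), so
    arbitrary start days and partial weeks are handled; Sunday rows of X are
    all zero.
    """
    resp_dates = series.dates[1:]
    weekday = resp_dates.weekday.to_numpy()  # Mon=0 .. Sun=6
    n = series.J - 1
    X = np.zeros((n, 6))
    for col in range(6):  # Sunday (6) left as the all-zero reference row
        X[weekday == col, col] = 1.0
    Z = np.column_stack([X, series.tarp_quit[1:], series.tarp_nrt[1:]])
    t = (resp_dates - series.dates[0]).days.to_numpy().astype(float)
    return DesignMatrices(
        X=X,
        Z=Z,
        y_prev=series.y[:-1].astype(float),
        y_resp=series.y[1:].astype(float),
        dates=resp_dates,
        t=t,
    )


def conditional_mean(params: SVCParams, design: DesignMatrices) -> np.ndarray:
    """Evaluate mu_j = Y_{j-1} (alpha_j + X_j' beta) + Z_j' gamma per response day.

    Raises
    ------
    PositivityError
        If any mean is <= 0 (carries the offending index).  Iterative solvers
        clip instead (see :func:`svcpois.estimation.clipped_mean`); the public
        contract is strict.
    """
    mu = _mean_no_check(params.alpha, params.beta, params.gamma, design)
    bad = np.nonzero(mu <= 0)[0]
    if bad.size:
        raise PositivityError(bad[0], mu[bad[0]])
    return mu


def _mean_no_check(alpha, beta, gamma, design: DesignMatrices) -> np.ndarray:
    alpha = np.broadcast_to(np.atleast_1d(alpha), (design.n,))
    return design.y_prev * (alpha + design.X @ beta) + design.Z @ gamma
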