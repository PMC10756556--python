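"""Longitudinal statistics: OLS trends, the limb x parameter R^2 matrix, and
recovery time/rate estimators.

Conventions follow the gait-monitoring literature: R^2 >= 0.49 is read as a
strong and >= 0.81 as a very strong correlation; significance is flagged at
p < 0.01 (two-sided t test on the slope); recovery rates are reported per month
of 30.44 days (calendar average).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, InsufficientDataError, ValidationError
from .io import LIMBS

#: Average calendar month length used for rate conversions (days).
DAYS_PER_MONTH = 30.44

#: R^2 thresholds for the qualitative strength labels.
R2_STRONG = 0.49
R2_VERY_STRONG = 0.81

#: Significance level for correlation-matrix flags.
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class RegressionFit:
    """Simple-OLS summary: y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def strength(self) -> str:
        """Qualitative label: none (<0.49), strong (>=0.49), very strong (>=0.81)."""
        if self.r_squared >= R2_VERY_STRONG:
            return "very strong"
        if self.r_squared >= R2_STRONG:
            return "strong"
        return "none"


def ols_fit(x, y) -> RegressionFit:
    """Least-squares line fit with R^2 and a two-sided slope t test (n-2 df).

    A constant response is a legal degenerate case (slope 0, R^2 0, p 1); a
    constant predictor is not.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points for a finite p-value, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor x is constant")
    if np.ptp(y) == 0:
        # SS_tot = SS_res = 0; define R^2 = 0, p = 1 for the null fit.
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=n)
    res = sps.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
        n=n,
    )


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise R^2 grid over (limb, parameter) variables plus time.

    ``r_squared`` is symmetric with unit diagonal; cells with fewer than the
    minimum number of paired observations are NaN and never significant.
    """

    r_squared: pd.DataFrame
    significant: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def labels(self) -> list[str]:
        return list(self.r_squared.index)


def correlation_matrix(
    daily: pd.DataFrame,
    parameters: tuple[str, ...] = ("grf_peak_pct", "grf_mean_pct", "t_c_s", "imp_abs_pct_s"),
    limbs: tuple[str, ...] = LIMBS,
    include_day: bool = True,
    alpha: float = DEFAULT_ALPHA,
    min_pairs: int = 3,
    bonferroni: bool = False,
) -> CorrelationMatrix:
    """Build the limb x parameter determination-coefficient matrix.

    Observations are per-animal daily means pooled across animals (animal as
    replicate), matched by (animal, day).  Each off-diagonal cell is the R^2 of
    the simple OLS between the two variables (invariant to which one is treated
    as response), flagged significant when the slope p-value is below ``alpha``
    (optionally Bonferroni-corrected over the upper triangle).  ``include_day``
    adds the measurement day ("time") as a pseudo-variable.
    """
    wide = daily.pivot_table(
        index=["animal_id", "day_postop"],
        columns=["limb", "parameter"],
        values="mean",
        aggfunc="first",
    )
    columns: dict[str, np.ndarray] = {}
    if include_day:
        columns["time"] = wide.index.get_level_values("day_postop").to_numpy(dtype=float)
    for limb in limbs:
        for param in parameters:
            if (limb, param) in wide.columns:
                columns[f"{limb}.{param}"] = wide[(limb, param)].to_numpy(dtype=float)
    labels = list(columns)
    k = len(labels)
    r2 = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    npairs = pd.DataFrame(0, index=labels, columns=labels)
    n_tests = k * (k - 1) // 2
    thr = alpha / n_tests if (bonferroni and n_tests) else alpha
    for a, b in itertools.combinations(labels, 2):
        xa, xb = columns[a], columns[b]
        ok = np.isfinite(xa) & np.isfinite(xb)
        n = int(ok.sum())
        npairs.loc[a, b] = npairs.loc[b, a] = n
        if n < min_pairs or np.ptp(xa[ok]) == 0 or np.ptp(xb[ok]) == 0:
            r2.loc[a, b] = r2.loc[b, a] = np.nan
            continue
        fit = ols_fit(xa[ok], xb[ok])
        r2.loc[a, b] = r2.loc[b, a] = fit.r_squared
        sig.loc[a, b] = sig.loc[b, a] = bool(fit.p_value < thr)
    return CorrelationMatrix(r_squared=r2, significant=sig, n_pairs=npairs)


def recovery_time(
    days, values, control_ref: float, tolerance_frac: float = 0.05
) -> float | None:
    """First persistent entry of a daily-mean series into the control band.

    Returns the smallest measurement day from which the series stays within
    ``tolerance_frac`` (relative) of ``control_ref`` for that day and all later
    days; ``None`` if it never settles.  The persistence clause prevents a
    single noisy crossing from counting as recovery.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if days.size == 0:
        raise InsufficientDataError("empty series")
    if days.shape != values.shape:
        raise ValidationError("days and values must have equal length")
    if not control_ref > 0:
        raise ValidationError("control_ref must be positive")
    order = np.argsort(days, kind="stable")
    days, values = days[order], values[order]
    in_band = np.abs(values - control_ref) <= tolerance_frac * control_ref
    # suffix-AND: persistent[i] true iff in_band from i onward
    persistent = np.logical_and.accumulate(in_band[::-1])[::-1]
    idx = np.flatnonzero(persistent)
    return float(days[idx[0]]) if idx.size else None


def recovery_rate(days, values, window: tuple[float, float] | None = None) -> float:
    """Linear recovery rate in parameter units per month (30.44 days).

    OLS slope of the daily-mean series against the measurement day, restricted
    to ``window`` (inclusive day range) when given; requires at least 3 points.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is not None:
        lo, hi = window
        keep = (days >= lo) & (days <= hi)
        days, values = days[keep], values[keep]
    if days.size < 3:
        raise InsufficientDataError(f"need >= 3 points in window, got {days.size}")
    if np.ptp(values) == 0:
        return 0.0
    return ols_fit(days, values).slope * DAYS_PER_MONTH
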