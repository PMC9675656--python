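"""Cosinor (harmonic) regression for monthly seasonality.

The cosinor model regresses a periodic outcome on a sine and cosine of
known period by ordinary least squares:

    y_t = b0 + bs * sin(2*pi*t/P) + bc * cos(2*pi*t/P) + e_t

Amplitude ``sqrt(bs^2 + bc^2)`` is the seasonality effect size, and the
acrophase ``atan2(bs, bc)`` maps to the peak month of the fitted
sinusoid.  Seasonality is decided by the joint F-test of both harmonic
coefficients; the sine-term t-test is reported alongside for
comparability with conventional "sinw" tables.

Month index ``t`` is the integer month-of-year (Jan = 1); multiple years
pool on month-of-year with each year-month contributing one observation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CosinorRegressor",
    "CosinorFit",
    "fit_cosinor",
    "peak_difference",
    "seasonality_test",
    "SeasonalityDecision",
]


class CosinorRegressor(BaseEstimator, RegressorMixin):
    """Least-squares cosinor regression with a single harmonic.

    Parameters
    ----------
    period : float, default 12
        Cycle length in the units of the time index (months).

    Attributes
    ----------
    intercept_, coef_sin_, coef_cos_ : float
        OLS coefficients of the harmonic design ``[1, sin, cos]``.
    se_intercept_, se_sin_, se_cos_ : float
        Classical (Gaussian) standard errors.
    t_sin_, p_sin_ : float
        t statistic and two-sided p-value of the sine coefficient.
    f_joint_, p_joint_ : float
        Joint F statistic and p-value for both harmonic terms being zero.
    amplitude_ : float
        ``sqrt(coef_sin_^2 + coef_cos_^2)``.
    phase_rad_ : float
        Acrophase ``atan2(coef_sin_, coef_cos_)`` in radians.
    peak_month_ : float
        Time (in [1, 1 + period)) at which the fitted sinusoid peaks.
    n_obs_, residual_df_ : int
        Observations used and residual degrees of freedom.
    """

    def __init__(self, period: float = 12.0):
        self.period = period

    def _design(self, t: np.ndarray) -> np.ndarray:
        w = 2.0 * np.pi * t / self.period
        return np.column_stack([np.ones_like(t), np.sin(w), np.cos(w)])

    def fit(self, t, y, sample_weight=None):
        """Fit the cosinor to observations ``y`` at time points ``t``.

        Missing (NaN) observations are dropped.  Requires at least four
        usable points whose time values span at least half a period.
        """
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("t and y must have the same length")
        mask = np.isfinite(t) & np.isfinite(y)
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float).ravel()[mask]
        t, y = t[mask], y[mask]
        if t.size < 4:
            raise ValueError(
                f"cosinor needs >= 4 non-missing observations, got {t.size}"
            )
        phase = np.mod(t, self.period)
        if phase.max() - phase.min() < self.period / 2:
            raise ValueError(
                "observations span less than half a period; the harmonic "
                "design is ill-conditioned"
            )
        X = self._design(t)
        if sample_weight is not None:
            sw = np.sqrt(sample_weight)
            Xw, yw = X * sw[:, None], y * sw
        else:
            Xw, yw = X, y
        if np.linalg.matrix_rank(Xw) < 3:
            raise ValueError("degenerate cosinor design (rank-deficient)")
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        df = t.size - 3
        sigma2 = float(resid @ resid) / df if df > 0 else np.nan
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se = np.sqrt(np.diag(cov))

        self.intercept_, self.coef_sin_, self.coef_cos_ = map(float, beta)
        self.se_intercept_, self.se_sin_, self.se_cos_ = map(float, se)
        # joint F for bs = bc = 0: compare against weighted-mean-only model
        ybar = (yw @ (Xw[:, 0])) / float(Xw[:, 0] @ Xw[:, 0])
        rss0 = float(((yw - ybar * Xw[:, 0]) ** 2).sum())
        rss1 = float(resid @ resid)
        # a numerically constant series carries no seasonal information
        constant = rss0 <= 1e-20 * max(1.0, float(yw @ yw))
        if constant:
            self.t_sin_, self.p_sin_ = 0.0, 1.0
            self.f_joint_, self.p_joint_ = 0.0, 1.0
        else:
            if se[1] > 0:
                self.t_sin_ = self.coef_sin_ / self.se_sin_
            else:  # perfect fit: zero residual variance
                self.t_sin_ = 0.0 if self.coef_sin_ == 0 else np.inf
            self.p_sin_ = (
                float(2 * stats.t.sf(abs(self.t_sin_), df)) if df > 0 else np.nan
            )
            if df > 0 and rss1 > 0:
                self.f_joint_ = ((rss0 - rss1) / 2.0) / (rss1 / df)
                self.p_joint_ = float(stats.f.sf(self.f_joint_, 2, df))
            else:  # perfect fit: overwhelming evidence for the harmonic
                self.f_joint_, self.p_joint_ = np.inf, 0.0
        self.amplitude_ = float(np.hypot(self.coef_sin_, self.coef_cos_))
        self.phase_rad_ = float(np.arctan2(self.coef_sin_, self.coef_cos_))
        peak = (self.phase_rad_ * self.period / (2 * np.pi)) % self.period
        self.peak_month_ = float(peak if peak >= 1.0 else peak + self.period)
        self.n_obs_ = int(t.size)
        self.residual_df_ = int(df)
        return self

    def predict(self, t):
        check_is_fitted(self, "intercept_")
        t = np.asarray(t, dtype=float).ravel()
        return self._design(t) @ np.array(
            [self.intercept_, self.coef_sin_, self.coef_cos_]
        )


@dataclass(frozen=True)
class CosinorFit:
    """Flat summary of a fitted cosinor (see :class:`CosinorRegressor`)."""

    intercept: float
    coef_sin: float
    coef_cos: float
    se_intercept: float
    se_sin: float
    se_cos: float
    t_sin: float
    p_sin: float
    f_joint: float
    p_joint: float
    amplitude: float
    phase_rad: float
    peak_month: float
    n_months: int
    residual_df: int
    period: float = 12.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def fit_cosinor(
    y, t=None, period: float = 12.0, sample_weight=None
) -> CosinorFit:
    """Fit a cosinor to monthly values and return a flat summary.

    ``y`` may be a Period-indexed Series (month-of-year is taken from the
    index) or an array with explicit time points ``t``.
    """
    if t is None:
        if not isinstance(y, pd.Series):
            raise ValueError("provide t, or a Period-indexed Series for y")
        idx = y.index
        if isinstance(idx, pd.PeriodIndex):
            t = idx.month.to_numpy(dtype=float)
        else:
            t = np.asarray(idx, dtype=float)
        y = y.to_numpy(dtype=float)
    est = CosinorRegressor(period=period).fit(t, y, sample_weight=sample_weight)
    return CosinorFit(
        intercept=est.intercept_,
        coef_sin=est.coef_sin_,
        coef_cos=est.coef_cos_,
        se_intercept=est.se_intercept_,
        se_sin=est.se_sin_,
        se_cos=est.se_cos_,
        t_sin=est.t_sin_,
        p_sin=est.p_sin_,
        f_joint=est.f_joint_,
        p_joint=est.p_joint_,
        amplitude=est.amplitude_,
        phase_rad=est.phase_rad_,
        peak_month=est.peak_month_,
        n_months=est.n_obs_,
        residual_df=est.residual_df_,
        period=period,
    )


def _peak_of(fit) -> float:
    if isinstance(fit, CosinorFit):
        return fit.peak_month
    if isinstance(fit, CosinorRegressor):
        return fit.peak_month_
    return float(fit)


def peak_difference(fit_a, fit_b, period: float = 12.0) -> float:
    """Signed circular displacement between two seasonal peaks, in months.

    Returns the minimal displacement of peak(a) relative to peak(b) on
    the circle of length ``period``, in (-period/2, period/2]; positive
    when b's peak precedes a's (b leads).  Accepts fitted cosinors or
    bare peak-month numbers.
    """
    pa, pb = _peak_of(fit_a), _peak_of(fit_b)
    if isinstance(fit_a, CosinorFit) and isinstance(fit_b, CosinorFit):
        if fit_a.period != fit_b.period:
            raise ValueError("fits have different periods")
        period = fit_a.period
    d = (pa - pb) % period
    if d > period / 2:
        d -= period
    return float(round(d, 10))


@dataclass(frozen=True)
class SeasonalityDecision:
    """Joint-test verdict on the presence of a seasonal component."""

    p_joint: float
    p_sin: float
    alpha: float
    seasonal: bool


def seasonality_test(fit: CosinorFit, alpha: float = 0.05) -> SeasonalityDecision:
    """Decide seasonality from the joint harmonic F-test at level alpha.

    The per-term sine t-test p-value is carried along for reporting; the
    verdict rests on the joint test, which is phase-invariant.
    """
    return SeasonalityDecision(
        p_joint=fit.p_joint,
        p_sin=fit.p_sin,
        alpha=alpha,
        seasonal=bool(fit.p_joint < alpha),
    )
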