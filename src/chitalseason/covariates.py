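"""Monthly covariate table: lagged rainfall, daylength, year.

Rainfall enters the conception and antler models at lags of 0, 1, 3 and
6 months.  Two lag conventions are supported: ``cumulative`` (default)
sums rainfall over the window from ``lag`` months before a month up to
and including that month; ``single`` takes rainfall in the single month
``lag`` months earlier.  Missing rainfall months raise rather than being
zero-filled, since a silent zero would masquerade as drought.

Daylength defaults to the astronomical mean day length for the month at
a configurable latitude (solar declination + hour-angle formula); a
user-supplied 12-value monthly table takes precedence when given.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STUDY_LATITUDE = -20.08  # Charters Towers region, degrees

__all__ = [
    "lagged_rainfall",
    "daylength",
    "build_covariate_table",
    "STUDY_LATITUDE",
]


def _as_period(month) -> pd.Period:
    return pd.Period(month, freq="M")


def _rain_lookup(series: pd.Series) -> pd.Series:
    s = pd.Series(series).copy()
    if not isinstance(s.index, pd.PeriodIndex):
        s.index = pd.PeriodIndex(s.index, freq="M")
    if (s < 0).any():
        raise ValueError("rainfall cannot be negative")
    return s.sort_index()


def lagged_rainfall(
    series: pd.Series,
    month,
    lag: int,
    convention: str = "cumulative",
) -> float:
    """Rainfall (mm) for ``month`` at the given lag.

    ``cumulative``: total over months ``month-lag .. month`` inclusive.
    ``single``: rainfall of the single month ``month-lag``.
    Any required month absent from the series raises, naming the gap.
    """
    if convention not in ("cumulative", "single"):
        raise ValueError(f"unknown lag convention {convention!r}")
    if lag < 0:
        raise ValueError("lag must be non-negative")
    s = _rain_lookup(series)
    m = _as_period(month)
    if convention == "single":
        wanted = [m - lag]
    else:
        wanted = [m - i for i in range(lag + 1)]
    missing = [str(w) for w in wanted if w not in s.index]
    if missing:
        raise ValueError(
            f"rainfall series is missing month(s) {', '.join(missing)} "
            f"required for lag {lag} at {m}"
        )
    return float(s.loc[wanted].sum()) if convention == "cumulative" else float(
        s.loc[wanted[0]]
    )


def daylength(month, latitude_deg: float) -> float:
    """Mean astronomical day length (hours) over the days of a month.

    Standard solar-declination formula: declination
    delta = 23.44 deg * sin(2*pi*(284 + n)/365) for day-of-year n, day
    length 24/pi * arccos(-tan(phi) tan(delta)).  Valid only between the
    polar circles.
    """
    if not -66.5 < latitude_deg < 66.5:
        raise ValueError(
            f"latitude {latitude_deg} outside supported range (-66.5, 66.5)"
        )
    m = _as_period(month)
    days = pd.date_range(m.start_time, m.end_time, freq="D")
    n = days.dayofyear.to_numpy()
    decl = np.deg2rad(23.44) * np.sin(2 * np.pi * (284 + n) / 365.0)
    phi = np.deg2rad(latitude_deg)
    cos_h = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    hours = 24.0 / np.pi * np.arccos(cos_h)
    return float(hours.mean())


def build_covariate_table(
    rainfall: pd.Series,
    months: Sequence,
    latitude_deg: float = STUDY_LATITUDE,
    convention: str = "cumulative",
    lags: Sequence[int] = (0, 1, 3, 6),
    daylength_table: Mapping[int, float] | None = None,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One covariate row per requested month.

    Parameters
    ----------
    rainfall : Series
        Monthly rainfall totals (mm), Period-indexable; must cover the
        maximum lag before the first requested month.
    months : sequence
        Months to build rows for (anything ``pd.Period`` accepts).
    daylength_table : mapping month-number (1-12) -> hours, optional
        Overrides the astronomical computation exactly when supplied.
    extra : DataFrame, optional
        Additional monthly columns (e.g. temperature), Period-indexed;
        joined through on ``year_month``.

    Returns
    -------
    DataFrame indexed by ``year_month`` with ``rain_lag{L}`` for each
    requested lag, ``daylength_h``, and ``year``.
    """
    idx = pd.PeriodIndex([_as_period(m) for m in months], name="year_month")
    rows: dict[str, list[float]] = {f"rain_lag{L}": [] for L in lags}
    for m in idx:
        for L in lags:
            rows[f"rain_lag{L}"].append(lagged_rainfall(rainfall, m, L, convention))
    out = pd.DataFrame(rows, index=idx)
    if daylength_table is not None:
        if sorted(daylength_table) != list(range(1, 13)):
            raise ValueError("daylength_table must map all months 1..12")
        out["daylength_h"] = [daylength_table[m.month] for m in idx]
    else:
        out["daylength_h"] = [daylength(m, latitude_deg) for m in idx]
    out["year"] = [m.year for m in idx]
    if extra is not None:
        ex = extra.copy()
        if not isinstance(ex.index, pd.PeriodIndex):
            ex.index = pd.PeriodIndex(ex.index, freq="M")
        out = out.join(ex, how="left")
    out.attrs["lag_convention"] = convention
    return out
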