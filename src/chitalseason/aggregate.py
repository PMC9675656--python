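"""Monthly aggregation of antler observations and conceptions.

Camera-trap triggers are thinned to independent detections (consecutive
triggers from the same camera less than 60 minutes apart are treated as
one event), antler states are pooled per calendar month into a
hard-antler numerator over a sampled-males denominator, and conception
records are pooled per month over an "at risk" denominator: the number
of culled females whose gestation window covers that month, i.e. the
females in which a conception that month could have been detected.

Months without data are reported as missing (NaN), never as zeros, and
are expected to be dropped from downstream model fits.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

ANTLER_STATES = ("hard", "velvet", "cast")

__all__ = [
    "dedupe_camera_triggers",
    "monthly_hard_antler",
    "at_risk_denominator",
    "monthly_conceptions",
]


def dedupe_camera_triggers(
    observations: pd.DataFrame, window_minutes: float = 60.0
) -> pd.DataFrame:
    """Drop camera triggers within ``window_minutes`` of the last kept one.

    Greedy per-camera thinning: within each camera the first trigger is
    kept, and each subsequent trigger is kept iff it falls at least
    ``window_minutes`` after the most recently *kept* trigger (so the
    rule is idempotent).  A gap of exactly ``window_minutes`` is kept.
    Incidental observations pass through untouched.

    Parameters
    ----------
    observations : DataFrame
        Columns ``timestamp`` (datetime-like), ``source``
        ("camera"/"incidental"), ``camera_id``, ``antler_state``.
    """
    if observations.empty:
        return observations.copy()
    df = observations.reset_index(drop=True).copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    camera = df[df["source"] == "camera"]
    other = df[df["source"] != "camera"]

    keep_idx: list = []
    window = pd.Timedelta(minutes=window_minutes)
    for _, grp in camera.sort_values("timestamp").groupby("camera_id", sort=False):
        last_kept = None
        for idx, ts in zip(grp.index, grp["timestamp"]):
            if last_kept is None or ts - last_kept >= window:
                keep_idx.append(idx)
                last_kept = ts
    kept = pd.concat([other, camera.loc[keep_idx]]) if keep_idx else other
    return kept.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _to_period(x) -> pd.PeriodIndex:
    return pd.PeriodIndex(pd.to_datetime(x), freq="M")


def monthly_hard_antler(observations: pd.DataFrame) -> pd.DataFrame:
    """Monthly hard-antler counts from (deduplicated) observations.

    Records whose antler state is not one of ``hard``/``velvet``/``cast``
    (uncertain or unknown stages) are excluded from both numerator and
    denominator.

    Returns
    -------
    DataFrame indexed by ``year_month`` (monthly Period) with columns
    ``n_sampled``, ``n_hard``, ``prop_hard``.  Calendar months inside the
    observed span with no usable records appear with NaN counts (missing,
    not zero).
    """
    usable = observations[observations["antler_state"].isin(ANTLER_STATES)]
    if usable.empty:
        return pd.DataFrame(
            columns=["n_sampled", "n_hard", "prop_hard"],
            index=pd.PeriodIndex([], freq="M", name="year_month"),
        )
    ym = _to_period(usable["timestamp"])
    grouped = pd.DataFrame(
        {"ym": ym, "hard": (usable["antler_state"] == "hard").to_numpy()}
    ).groupby("ym")
    out = grouped.agg(n_sampled=("hard", "size"), n_hard=("hard", "sum"))
    full = pd.period_range(out.index.min(), out.index.max(), freq="M")
    out = out.reindex(full)
    out.index.name = "year_month"
    out["prop_hard"] = out["n_hard"] / out["n_sampled"]
    return out


def at_risk_denominator(
    cull_dates: Iterable, gestation_days: float = 229.0
) -> pd.Series:
    """Per-month count of culled females that could have been pregnant.

    Every culled female (pregnant or not) contributes one count to each
    calendar month intersecting her gestation window, the half-open
    interval ``(cull_date - gestation_days, cull_date]``: a conception is
    detectable at cull only if it happened within one gestation before it.

    Returns a Series indexed by monthly Period covering the full span,
    with zero for covered-span months no window touches.
    """
    dates = pd.to_datetime(pd.Series(list(cull_dates)))
    if dates.empty:
        raise ValueError("at_risk_denominator requires at least one cull")
    gest = pd.Timedelta(days=int(round(gestation_days)))
    starts = _to_period(dates - gest + pd.Timedelta(days=1))
    ends = _to_period(dates)
    span = pd.period_range(starts.min(), ends.max(), freq="M")
    counts = pd.Series(0, index=span, dtype=int)
    for s, e in zip(starts, ends):
        counts.loc[s:e] += 1
    counts.index.name = "year_month"
    counts.name = "n_at_risk"
    return counts


def monthly_conceptions(
    conception_dates: Iterable, at_risk: pd.Series
) -> pd.DataFrame:
    """Monthly conception counts, denominators and percentages.

    Parameters
    ----------
    conception_dates : iterable of dates
        Back-calculated conception dates of pregnant females.
    at_risk : Series
        Monthly at-risk denominators from :func:`at_risk_denominator`,
        computed from the same cull set.

    Returns
    -------
    DataFrame indexed by ``year_month`` with ``n_conceived``,
    ``n_at_risk``, ``pct_conceived`` (= 100 * n_conceived / n_at_risk).
    Months with zero denominator are flagged missing (NaN percentage).
    """
    dates = list(conception_dates)
    if dates:
        months = _to_period(dates)
        n_conceived = pd.Series(months).value_counts().sort_index()
    else:
        n_conceived = pd.Series(dtype=int)
    out = pd.DataFrame({"n_at_risk": at_risk})
    out["n_conceived"] = n_conceived.reindex(out.index).fillna(0).astype(int)
    orphans = n_conceived.index.difference(out.index)
    if len(orphans) or (
        (out["n_at_risk"] == 0) & (out["n_conceived"] > 0)
    ).any():
        raise ValueError(
            "conception recorded in a month with zero at-risk denominator; "
            "conceptions and denominators must come from the same cull set"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * out["n_conceived"] / out["n_at_risk"]
    out["pct_conceived"] = pct.where(out["n_at_risk"] > 0)
    out.index.name = "year_month"
    return out[["n_conceived", "n_at_risk", "pct_conceived"]]
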