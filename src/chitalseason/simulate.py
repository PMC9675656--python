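"""Synthetic field data with known seasonal truth.

Emulates the observational design of a tropical-savanna deer study so
the whole pipeline can be exercised end to end against planted truth:

* **Rainfall** — yearly totals are gamma-distributed around a 689 mm
  mean with a 47% between-year CV, apportioned to months by a Dirichlet
  whose expectation puts 75% of the year's rain in November–March (the
  wet season).
* **Antler observations** — per month, a fixed number of stag records
  whose hard-antler probability follows a sinusoid over the year;
  a fraction arrive via camera traps, some in bursts of triggers less
  than an hour apart so deduplication has something to do.
* **Culls** — females culled on a fixed calendar of occasions.  A
  female can be detectably pregnant only if she conceived within one
  gestation (229 d) before her cull; within that window her conception
  month follows intensities proportional to ``exp(rain_effect * lagged
  rainfall)``, and her overall chance of being pregnant comes from the
  complement of per-month base-rate hazards.  Foetal mass is the
  forward growth model at the planted age times multiplicative
  lognormal noise, capped at birth mass.

Everything is driven by one integer seed; a fixed seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .covariates import lagged_rainfall
from .growth import GrowthModelParams, mass_from_age

WET_MONTHS = (11, 12, 1, 2, 3)

__all__ = [
    "SimulationTruth",
    "gen_rainfall",
    "gen_antler_observations",
    "gen_culls",
    "generate_dataset",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Planted parameters of one synthetic dataset.

    Defaults mirror the study conditions: 689 mm mean annual rain with
    CV 47% and ~75% falling Nov–Mar; hard-antler probability 0.6 with a
    0.25-amplitude peak in June; conception hazard 0.12 per
    female-month at average rainfall, boosted by cumulative rainfall
    over the three months preceding conception; eight cull occasions of
    30 females spanning October 2014 to March 2018.
    """

    seed: int = 0
    years: int = 6
    start_year: int = 2013
    annual_rain_mm: float = 689.0
    wet_fraction: float = 0.75
    rain_cv: float = 0.47
    rain_concentration: float = 30.0
    antler_baseline: float = 0.6
    antler_amplitude: float = 0.25
    antler_peak_month: float = 6.0
    conception_base_rate: float = 0.12
    rain_effect: float = 0.004
    rain_lag: int = 3
    lag_convention: str = "cumulative"
    n_females_culled: int = 30
    cull_months: tuple[str, ...] = (
        "2014-10", "2015-03", "2015-10", "2016-03",
        "2016-10", "2016-11", "2017-11", "2018-03",
    )
    n_antler_obs_per_month: int = 200
    obs_start: str = "2014-01"
    obs_end: str = "2018-12"
    camera_fraction: float = 0.3
    n_cameras: int = 20
    burst_prob: float = 0.25
    mass_noise_sd: float = 0.1
    growth: GrowthModelParams = field(default_factory=GrowthModelParams)

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for name in ("annual_rain_mm", "rain_cv", "rain_concentration",
                     "conception_base_rate", "n_females_culled",
                     "n_antler_obs_per_month"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.wet_fraction < 1:
            raise ValueError("wet_fraction must be in (0, 1)")
        for name in ("antler_baseline", "camera_fraction", "burst_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mass_noise_sd < 0 or self.antler_amplitude < 0:
            raise ValueError("noise/amplitude parameters cannot be negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cull_months"] = list(self.cull_months)
        return d

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def gen_rainfall(truth: SimulationTruth, rng=None) -> pd.Series:
    """Monthly rainfall series (mm), Period-indexed, for the study years."""
    rng = rng or truth.rng(1)
    shape = 1.0 / truth.rain_cv**2
    totals = rng.gamma(shape, truth.annual_rain_mm / shape, size=truth.years)
    wet_each = truth.wet_fraction / len(WET_MONTHS)
    dry_each = (1.0 - truth.wet_fraction) / (12 - len(WET_MONTHS))
    alpha = truth.rain_concentration * np.array(
        [wet_each if m in WET_MONTHS else dry_each for m in range(1, 13)]
    )
    values = []
    for total in totals:
        values.extend(total * rng.dirichlet(alpha))
    idx = pd.period_range(
        f"{truth.start_year}-01", periods=12 * truth.years, freq="M"
    )
    return pd.Series(values, index=idx, name="rain_mm")


def hard_antler_probability(month_of_year, truth: SimulationTruth) -> np.ndarray:
    """Planted P(hard antler) for month-of-year (sinusoid, clipped to [0,1])."""
    m = np.asarray(month_of_year, dtype=float)
    wave = np.cos(2 * np.pi * (m - truth.antler_peak_month) / 12.0)
    return np.clip(truth.antler_baseline + truth.antler_amplitude * wave, 0, 1)


def gen_antler_observations(truth: SimulationTruth, rng=None) -> pd.DataFrame:
    """Antler-state records, a mix of incidental and camera-trap sources.

    Camera records may arrive in bursts of triggers < 60 min apart
    (duplicated detections of the same stag); deduplication should thin
    each burst back to one record.
    """
    rng = rng or truth.rng(2)
    months = pd.period_range(truth.obs_start, truth.obs_end, freq="M")
    n = truth.n_antler_obs_per_month
    frames = []
    for m in months:
        p_hard = float(hard_antler_probability(m.month, truth))
        start = m.start_time
        span_s = (m.end_time - start).total_seconds()
        hard = rng.random(n) < p_hard
        velvet = rng.random(n) < 0.6
        state = np.where(hard, "hard", np.where(velvet, "velvet", "cast"))
        ts = start + pd.to_timedelta(rng.uniform(0, span_s, size=n), unit="s")
        is_cam = rng.random(n) < truth.camera_fraction
        cam_ids = rng.integers(truth.n_cameras, size=n)
        df = pd.DataFrame(
            {
                "timestamp": ts,
                "source": np.where(is_cam, "camera", "incidental"),
                "camera_id": np.where(
                    is_cam, np.char.add("cam", cam_ids.astype(str)), ""
                ),
                "antler_state": state,
            }
        )
        frames.append(df)
        # burst duplicates: extra camera triggers < 60 min after the original
        burst = is_cam & (rng.random(n) < truth.burst_prob)
        if burst.any():
            reps = rng.integers(1, 3, size=int(burst.sum()))
            dup = df.loc[np.repeat(np.flatnonzero(burst), reps)].copy()
            dup["timestamp"] = dup["timestamp"] + pd.to_timedelta(
                rng.uniform(1, 59, size=len(dup)), unit="m"
            )
            frames.append(dup)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _lagged_table(truth, rainfall) -> dict:
    """Lagged rainfall for every month with full lag coverage."""
    return {
        m: lagged_rainfall(rainfall, m, truth.rain_lag, truth.lag_convention)
        for m in rainfall.index
        if (m - truth.rain_lag) in rainfall.index
    }


def gen_culls(
    truth: SimulationTruth, rainfall: pd.Series, rng=None
) -> pd.DataFrame:
    """Cull records with gestation-window-truncated conceptions.

    Returns a DataFrame ``cull_date, pregnant, foetal_mass_g,
    true_conception_date`` (the last column is the planted truth and is
    dropped before the data reach the pipeline).
    """
    rng = rng or truth.rng(3)
    gest = int(round(truth.growth.gestation_days))
    lagged = _lagged_table(truth, rainfall)
    if not lagged:
        raise ValueError(
            f"rainfall series too short to support lag {truth.rain_lag}"
        )
    rain_ref = float(np.mean(list(lagged.values())))
    rows = []
    for cm in truth.cull_months:
        period = pd.Period(cm, freq="M")
        for _ in range(truth.n_females_culled):
            cull = period.start_time + pd.Timedelta(
                days=int(rng.integers(0, period.days_in_month))
            )
            window_start = cull - pd.Timedelta(days=gest)  # exclusive
            months = pd.period_range(
                (window_start + pd.Timedelta(days=1)).to_period("M"),
                cull.to_period("M"),
                freq="M",
            )
            # per-month hazard at the planted base rate and rainfall boost
            try:
                lag_vals = np.array([lagged[m] for m in months])
            except KeyError as exc:
                raise ValueError(
                    f"rainfall series does not cover lag {truth.rain_lag} "
                    f"before window month {exc.args[0]}"
                ) from None
            boost = np.exp(truth.rain_effect * (lag_vals - rain_ref))
            weights = boost / boost.max()
            hazard = np.clip(truth.conception_base_rate * boost, 0.0, 1.0)
            # usable day-span of each window month (at least 1 d before cull)
            spans = []
            for m in months:
                lo = max(m.start_time, window_start + pd.Timedelta(days=1))
                hi = min(m.end_time.normalize(), cull - pd.Timedelta(days=1))
                spans.append((lo, max(0, (hi - lo).days + 1)))
            days = np.array([s[1] for s in spans], dtype=float)
            probs = weights * (days > 0)
            p_pregnant = 1.0 - float(np.prod(1.0 - hazard[days > 0]))
            if probs.sum() > 0 and rng.random() < p_pregnant:
                j = int(rng.choice(len(months), p=probs / probs.sum()))
                lo, span = spans[j]
                conc = lo + pd.Timedelta(days=int(rng.integers(0, span)))
                age = (cull - conc).days
                mass = mass_from_age(float(age), truth.growth)
                if truth.mass_noise_sd > 0:
                    mass *= float(
                        np.exp(rng.normal(0.0, truth.mass_noise_sd))
                    )
                mass = min(mass, truth.growth.birth_mass)
                rows.append((cull, True, mass, conc))
            else:
                rows.append((cull, False, np.nan, pd.NaT))
    df = pd.DataFrame(
        rows,
        columns=["cull_date", "pregnant", "foetal_mass_g",
                 "true_conception_date"],
    )
    return df.reset_index(drop=True)


def generate_dataset(truth: SimulationTruth) -> dict:
    """Generate the full synthetic dataset for one seed.

    Returns a dict with ``rainfall`` (Series), ``observations`` and
    ``culls`` (DataFrames) and ``truth`` (the parameter record).
    """
    rainfall = gen_rainfall(truth)
    observations = gen_antler_observations(truth)
    culls = gen_culls(truth, rainfall)
    return {
        "rainfall": rainfall,
        "observations": observations,
        "culls": culls,
        "truth": truth,
    }
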