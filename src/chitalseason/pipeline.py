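"""End-to-end male and female seasonality analyses.

The male analysis: deduplicate camera triggers, pool antler states per
month, fit a cosinor to the monthly hard-antler proportion, and explain
the monthly hard-antler count (offset: stags sampled) with Poisson
models over daylength, lagged rainfall, year and a year-rainfall
interaction, AICc-ranked and model-averaged.

The female analysis: back-calculate conception dates from foetal
masses, build gestation-window at-risk denominators, fit a cosinor to
the monthly conception proportion, and explain the monthly conception
count (offset: females at risk) with Poisson models over lagged
rainfall, year, daylength, a year-daylength interaction and optionally
the male hard-antler proportion.

Asynchrony is the signed circular displacement between the two fitted
seasonal peaks, flagged advisory when either cosinor is non-seasonal at
the configured level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import (
    at_risk_denominator,
    dedupe_camera_triggers,
    monthly_conceptions,
    monthly_hard_antler,
)
from .cosinor import CosinorFit, fit_cosinor, peak_difference, seasonality_test
from .covariates import STUDY_LATITUDE
from .glmselect import (
    AveragedModelResult,
    ModelConstraints,
    enumerate_models,
    fit_poisson_glm,
    rank_and_average,
)
from .growth import GrowthModelParams, back_calculate_table

logger = logging.getLogger("chitalseason")

RAIN_LAG_TERMS = ("rain_lag0", "rain_lag1", "rain_lag3", "rain_lag6")

__all__ = [
    "AnalysisConfig",
    "SexAnalysis",
    "AsynchronyResult",
    "run_male_analysis",
    "run_female_analysis",
    "asynchrony",
    "build_report",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the study design."""

    dedup_window_min: float = 60.0
    latitude_deg: float = STUDY_LATITUDE
    lag_convention: str = "cumulative"
    alpha: float = 0.05
    top_delta: float = 2.0
    renormalize_top_weights: bool = True
    year_categorical: bool = True
    male_terms: tuple[str, ...] = (
        "daylength_h",
        *RAIN_LAG_TERMS,
        "year",
        *(f"year:{t}" for t in RAIN_LAG_TERMS),
    )
    female_terms: tuple[str, ...] = (
        "daylength_h",
        *RAIN_LAG_TERMS,
        "year",
        "year:daylength_h",
        "prop_hard",
    )
    exclusive_groups: tuple[tuple[str, ...], ...] = (
        ("daylength_h", "temperature_c"),
    )
    growth: GrowthModelParams = field(default_factory=GrowthModelParams)

    @property
    def detection_window_days(self) -> int:
        """At-risk window length for the conception denominator.

        The ceiling of the growth curve's age at birth mass (~234 d)
        rather than the nominal 229-day gestation: back-calculated ages
        can reach the curve's own maximum, and every datable conception
        must fall inside its female's at-risk window.
        """
        return math.ceil(self.growth.max_age)

    @property
    def constraints(self) -> ModelConstraints:
        return ModelConstraints(
            one_of_groups=(RAIN_LAG_TERMS,),
            exclusive_groups=self.exclusive_groups,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SexAnalysis:
    """Monthly series, cosinor fit and averaged GLM for one sex."""

    monthly: pd.DataFrame
    cosinor: CosinorFit
    averaged: AveragedModelResult
    n_model_rows: int


def _glm_rows(monthly, covariates, count_col, offset_col):
    joined = monthly.join(covariates, how="inner")
    rows = joined.dropna(subset=[count_col, offset_col])
    rows = rows[rows[offset_col] > 0]
    return rows


def _average_over(rows, counts, offsets, terms, config):
    models = enumerate_models(terms, config.constraints)
    categorical = ("year",) if config.year_categorical else ()
    fits = []
    for m in models:
        try:
            fits.append(
                fit_poisson_glm(
                    counts, offsets, design=rows, terms=m,
                    categorical=categorical,
                )
            )
        except (ValueError, KeyError) as exc:
            logger.info("skipping model %s: %s", m or ("1",), exc)
    return rank_and_average(
        fits, top_delta=config.top_delta,
        renormalize_top=config.renormalize_top_weights,
    )


def run_male_analysis(
    observations: pd.DataFrame,
    covariates: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> SexAnalysis:
    """Antler seasonality: cosinor + model-averaged Poisson rate model."""
    config = config or AnalysisConfig()
    n_raw = len(observations)
    deduped = dedupe_camera_triggers(observations, config.dedup_window_min)
    logger.info(
        "dedup: %d observations in, %d kept (%d dropped)",
        n_raw, len(deduped), n_raw - len(deduped),
    )
    monthly = monthly_hard_antler(deduped)
    with_data = monthly.dropna(subset=["n_sampled"])
    logger.info(
        "monthly antler series: %d months with data (of %d spanned)",
        len(with_data), len(monthly),
    )
    cos_fit = fit_cosinor(with_data["prop_hard"])
    terms = tuple(
        t for t in config.male_terms
        if all(p in covariates.columns or p == "year"
               for p in t.split(":"))
    )
    rows = _glm_rows(with_data, covariates, "n_hard", "n_sampled")
    averaged = _average_over(
        rows, rows["n_hard"], rows["n_sampled"], terms, config
    )
    return SexAnalysis(
        monthly=monthly, cosinor=cos_fit, averaged=averaged,
        n_model_rows=len(rows),
    )


def run_female_analysis(
    culls: pd.DataFrame,
    covariates: pd.DataFrame,
    config: AnalysisConfig | None = None,
    male_monthly: pd.DataFrame | None = None,
) -> SexAnalysis:
    """Conception seasonality: cosinor + model-averaged Poisson rate model.

    ``male_monthly`` (the monthly antler table) must be supplied when the
    hard-antler-proportion term is among the candidates.
    """
    config = config or AnalysisConfig()
    conceptions = back_calculate_table(culls, config.growth)
    if conceptions.empty:
        raise ValueError(
            "no pregnant females in the cull table; conception seasonality "
            "cannot be estimated"
        )
    logger.info(
        "back-calculated %d conception dates from %d culls",
        len(conceptions), len(culls),
    )
    at_risk = at_risk_denominator(
        culls["cull_date"], config.detection_window_days
    )
    monthly = monthly_conceptions(conceptions["conception_date"], at_risk)
    with_data = monthly[monthly["n_at_risk"] > 0]
    cos_fit = fit_cosinor(with_data["pct_conceived"] / 100.0)

    covs = covariates
    terms = config.female_terms
    if "prop_hard" in {p for t in terms for p in t.split(":")}:
        if male_monthly is None:
            terms = tuple(
                t for t in terms
                if "prop_hard" not in t.split(":")
            )
            logger.info(
                "male monthly series not supplied; dropping prop_hard term"
            )
        else:
            covs = covariates.join(male_monthly[["prop_hard"]], how="left")
    terms = tuple(
        t for t in terms
        if all(p in covs.columns or p == "year" for p in t.split(":"))
    )
    rows = _glm_rows(with_data, covs, "n_conceived", "n_at_risk")
    needed = sorted({p for t in terms for p in t.split(":") if p != "year"})
    rows = rows.dropna(subset=[c for c in needed if c in rows.columns])
    averaged = _average_over(
        rows, rows["n_conceived"], rows["n_at_risk"], terms, config
    )
    return SexAnalysis(
        monthly=monthly, cosinor=cos_fit, averaged=averaged,
        n_model_rows=len(rows),
    )


@dataclass(frozen=True)
class AsynchronyResult:
    """Signed circular peak displacement between the sexes, months.

    Positive when the female conception peak precedes the male
    hard-antler peak.  ``advisory`` is set when either cosinor is
    non-seasonal at the configured level, in which case the displacement
    is reported but should not be over-read.
    """

    months: float
    male_peak_month: float
    female_peak_month: float
    male_seasonal: bool
    female_seasonal: bool
    advisory: bool
    synchronous: bool


def asynchrony(
    male_fit: CosinorFit, female_fit: CosinorFit, alpha: float = 0.05
) -> AsynchronyResult:
    """Circular peak difference male-vs-female with significance gating."""
    male_dec = seasonality_test(male_fit, alpha)
    female_dec = seasonality_test(female_fit, alpha)
    months = peak_difference(male_fit, female_fit)
    return AsynchronyResult(
        months=months,
        male_peak_month=male_fit.peak_month,
        female_peak_month=female_fit.peak_month,
        male_seasonal=male_dec.seasonal,
        female_seasonal=female_dec.seasonal,
        advisory=not (male_dec.seasonal and female_dec.seasonal),
        synchronous=abs(months) < 0.5,
    )


def _monthly_records(monthly: pd.DataFrame) -> list[dict]:
    out = monthly.reset_index()
    out["year_month"] = out["year_month"].astype(str)
    return out.replace({np.nan: None}).to_dict(orient="records")


def build_report(
    male: SexAnalysis,
    female: SexAnalysis,
    config: AnalysisConfig,
    provenance: dict | None = None,
) -> dict:
    """JSON-serialisable report of both analyses plus their asynchrony."""
    asym = asynchrony(male.cosinor, female.cosinor, config.alpha)
    return {
        "male": {
            "cosinor": male.cosinor.to_dict(),
            "model_average": male.averaged.to_dict(),
            "monthly": _monthly_records(male.monthly),
            "n_model_rows": male.n_model_rows,
        },
        "female": {
            "cosinor": female.cosinor.to_dict(),
            "model_average": female.averaged.to_dict(),
            "monthly": _monthly_records(female.monthly),
            "n_model_rows": female.n_model_rows,
        },
        "asynchrony": asdict(asym),
        "config": config.to_dict(),
        "provenance": {"version": __version__, **(provenance or {})},
    }
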