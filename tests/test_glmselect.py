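"""Poisson rate models, AICc ranking and full model averaging."""

import numpy as np
import pandas as pd
import pytest

from chitalseason import (
    GLMFit,
    ModelConstraints,
    PoissonGLM,
    enumerate_models,
    fit_poisson_glm,
    rank_and_average,
)
from chitalseason.glmselect import aicc


@pytest.fixture
def month_data(rng):
    n = 48
    design = pd.DataFrame(
        {
            "rain": rng.uniform(0, 400, n),
            "daylength_h": 12 + 1.2 * np.sin(2 * np.pi * np.arange(n) / 12),
        }
    )
    offsets = rng.integers(20, 60, n).astype(float)
    eta = -2.0 + 0.003 * design["rain"].to_numpy()
    counts = rng.poisson(offsets * np.exp(eta))
    counts = np.minimum(counts, offsets)
    return design, counts.astype(float), offsets


class TestPoissonGLM:
    def test_intercept_only_closed_form(self, month_data):
        design, counts, offsets = month_data
        fit = fit_poisson_glm(counts, offsets)
        assert fit.coefficients[0] == pytest.approx(
            np.log(counts.sum() / offsets.sum()), abs=1e-10
        )

    def test_matches_statsmodels_oracle(self, month_data):
        import statsmodels.api as sm

        design, counts, offsets = month_data
        fit = fit_poisson_glm(counts, offsets, design, ("rain", "daylength_h"))
        X = sm.add_constant(design[["rain", "daylength_h"]].to_numpy())
        ref = sm.GLM(
            counts, X, family=sm.families.Poisson(), offset=np.log(offsets)
        ).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_parameter_recovery_over_replicates(self, rng):
        """Mean estimate of a planted rate effect is within MC error of truth."""
        n, beta_true = 48, 0.003
        rain = rng.uniform(0, 400, n)
        offsets = np.full(n, 40.0)
        design = pd.DataFrame({"rain": rain})
        estimates = []
        for _ in range(200):
            mu = offsets * np.exp(-2.0 + beta_true * rain)
            counts = rng.poisson(mu).astype(float)
            fit = fit_poisson_glm(counts, offsets, design, ("rain",))
            estimates.append(fit.coefficients[1])
        est = np.array(estimates)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - beta_true) < 4 * mc_se

    def test_zero_offset_rejected(self, month_data):
        design, counts, offsets = month_data
        offsets = offsets.copy()
        offsets[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_poisson_glm(counts, offsets)

    def test_counts_above_exposure_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            fit_poisson_glm([5.0, 1.0], [4.0, 2.0])

    def test_aicc_definition(self):
        assert aicc(-100.0, 3, 40) == pytest.approx(
            200 + 6 + 2 * 3 * 4 / (40 - 4)
        )
        with pytest.raises(ValueError):
            aicc(-100.0, 10, 11)

    def test_estimator_interface(self, month_data):
        design, counts, offsets = month_data
        est = PoissonGLM().fit(
            design[["rain"]].to_numpy(), counts, offset=np.log(offsets)
        )
        assert est.converged_ and est.coef_.shape == (2,)
        mu = est.predict(design[["rain"]].to_numpy(), offset=np.log(offsets))
        assert mu.shape == counts.shape and (mu > 0).all()


class TestEnumeration:
    def test_one_lag_constraint_model_count(self):
        models = enumerate_models(
            ("daylength", "rain0", "rain3"),
            ModelConstraints(one_of_groups=(("rain0", "rain3"),)),
        )
        assert sorted(models) == sorted(
            [(), ("daylength",), ("rain0",), ("rain3",),
             ("daylength", "rain0"), ("daylength", "rain3")]
        )

    def test_empty_candidates_gives_null_model(self):
        assert enumerate_models(()) == [()]

    def test_exclusive_pair_never_cooccurs(self):
        models = enumerate_models(
            ("daylength", "temperature"),
            ModelConstraints(exclusive_groups=(("daylength", "temperature"),)),
        )
        assert all(
            not {"daylength", "temperature"} <= set(m) for m in models
        )

    def test_interaction_requires_both_mains(self):
        models = enumerate_models(("a", "b", "a:b"))
        with_int = [m for m in models if "a:b" in m]
        assert with_int == [("a", "b", "a:b")]


def _fit(terms, beta, var, ll, k=2, n=40):
    names = ("Intercept", *terms)
    return GLMFit(
        terms=terms,
        coef_names=names,
        coefficients=np.array([0.0, *([beta] * len(terms))]),
        standard_errors=np.sqrt(np.array([0.0, *([var] * len(terms))])),
        log_likelihood=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        converged=True,
        iterations=5,
    )


class TestAveraging:
    def test_single_top_model_passes_through(self):
        fits = [_fit(("x",), 0.4, 0.01, -50.0), _fit((), 0.0, 0.0, -80.0, k=1)]
        result = rank_and_average(fits)
        assert result.top_set == (("x",),)
        assert result.estimates.loc["x", "estimate"] == pytest.approx(0.4)
        assert result.estimates.loc["x", "se_unconditional"] == pytest.approx(0.1)

    def test_zero_substitution_hand_example(self):
        # two models with equal AICc; term only in the first
        fits = [_fit(("x",), 0.4, 0.01, -50.0), _fit((), 0.0, 0.0, -50.0, k=2)]
        result = rank_and_average(fits)
        row = result.estimates.loc["x"]
        assert row["estimate"] == pytest.approx(0.2)
        assert row["se_unconditional"] ** 2 == pytest.approx(0.045)

    def test_weights_sum_to_one(self):
        fits = [
            _fit(("x",), 0.4, 0.01, -50.0),
            _fit(("z",), 0.1, 0.02, -51.0),
            _fit((), 0.0, 0.0, -60.0, k=1),
        ]
        result = rank_and_average(fits)
        assert result.model_table["akaike_weight"].sum() == pytest.approx(1.0)

    def test_ranking_invariant_to_loglik_shift(self):
        fits = [_fit(("x",), 0.4, 0.01, -50.0), _fit(("z",), 0.1, 0.02, -52.0)]
        shifted = [
            _fit(f.terms, f.coefficients[1] if f.terms else 0.0,
                 f.standard_errors[1] ** 2 if f.terms else 0.0,
                 f.log_likelihood + 7.5)
            for f in fits
        ]
        r1, r2 = rank_and_average(fits), rank_and_average(shifted)
        np.testing.assert_allclose(
            r1.model_table["delta_aicc"], r2.model_table["delta_aicc"]
        )
        np.testing.assert_allclose(
            r1.model_table["akaike_weight"], r2.model_table["akaike_weight"]
        )

    def test_term_shared_by_all_top_models_is_unchanged(self):
        fits = [
            _fit(("x",), 0.4, 0.01, -50.0, k=2),
            _fit(("x", "z"), 0.4, 0.01, -49.5, k=3),
        ]
        result = rank_and_average(fits)
        assert result.estimates.loc["x", "estimate"] == pytest.approx(0.4)

    def test_all_nonconverged_rejected(self):
        bad = GLMFit(
            terms=(), coef_names=("Intercept",),
            coefficients=np.array([0.0]), standard_errors=np.array([0.1]),
            log_likelihood=-10.0, k=1, n=20, aicc=22.0,
            converged=False, iterations=100,
        )
        with pytest.raises(ValueError, match="converged"):
            rank_and_average([bad])

    def test_matches_independent_averaging_oracle(self, month_data, rng):
        """Full averaging agrees with a formula-level oracle on statsmodels fits."""
        import statsmodels.api as sm

        design, counts, offsets = month_data
        candidates = [(), ("rain",), ("daylength_h",), ("rain", "daylength_h")]
        fits = [
            fit_poisson_glm(counts, offsets, design, m) for m in candidates
        ]
        result = rank_and_average(fits, top_delta=np.inf, renormalize_top=True)

        # oracle: independent fits + direct transcription of the formulas
        oracle = {}
        for m in candidates:
            X = sm.add_constant(
                design[list(m)].to_numpy() if m else np.empty((len(counts), 0))
            )
            r = sm.GLM(counts, X, family=sm.families.Poisson(),
                       offset=np.log(offsets)).fit()
            k = len(r.params)
            a = -2 * r.llf + 2 * k + 2 * k * (k + 1) / (len(counts) - k - 1)
            oracle[m] = (r, a)
        aiccs = np.array([oracle[m][1] for m in candidates])
        w = np.exp(-(aiccs - aiccs.min()) / 2)
        w /= w.sum()
        for j, name in enumerate(["Intercept", "rain", "daylength_h"]):
            betas, varis = [], []
            for m in candidates:
                r, _ = oracle[m]
                cols = ["Intercept", *m]
                if name in cols:
                    i = cols.index(name)
                    betas.append(r.params[i])
                    varis.append(r.bse[i] ** 2)
                else:
                    betas.append(0.0)
                    varis.append(0.0)
            betas, varis = np.array(betas), np.array(varis)
            bbar = w @ betas
            se_u = np.sqrt(w @ (varis + (betas - bbar) ** 2))
            assert result.estimates.loc[name, "estimate"] == pytest.approx(
                bbar, abs=1e-6
            )
            assert result.estimates.loc[name, "se_unconditional"] == pytest.approx(
                se_u, abs=1e-6
            )
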