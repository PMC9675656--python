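"""Poisson rate models with offsets, AICc ranking and model averaging.

Monthly event counts (stags in hard antler; females conceiving) are
modelled as Poisson with a log link and the log of the monthly exposure
(stags sampled; females at risk) as an offset, so coefficients act on
the event *rate*.  Candidate models are all additive subsets of the
covariate terms subject to three constraints: at most one rainfall-lag
term per model (the lags are alternative measurements of one quantity),
interactions only alongside both main effects, and mutually exclusive
groups (e.g. photoperiod vs temperature, which are too collinear to fit
together) never co-occurring.

Models are ranked by AICc.  When several models fall within a small
AICc distance of the best, coefficients are combined by full (zero
substitution) model averaging with unconditional standard errors:

    beta_bar = sum_i w_i beta_i          (beta_i = 0 where term absent)
    var_u    = sum_i w_i (var_i + (beta_i - beta_bar)^2)

with Akaike weights w_i renormalised over the top set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PoissonGLM",
    "GLMFit",
    "ModelConstraints",
    "AveragedModelResult",
    "fit_poisson_glm",
    "enumerate_models",
    "rank_and_average",
    "build_design",
]


class PoissonGLM(BaseEstimator):
    """Poisson log-link regression fit by iteratively reweighted least squares.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column to the design.
    tol : float, default 1e-8
        Convergence threshold on the relative change in deviance.
    max_iter : int, default 100

    Attributes
    ----------
    coef_ : ndarray
        Coefficients (intercept first when ``fit_intercept``).
    se_ : ndarray
        Standard errors from the inverse Fisher information.
    loglik_ : float
        Poisson log-likelihood at the MLE (including the ``log y!`` term).
    deviance_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8,
                 max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, offset=None):
        """Fit to counts ``y`` with optional log-exposure ``offset``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        n = y.size
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError("y must be non-negative counts")
        offset = np.zeros(n) if offset is None else np.asarray(offset, float).ravel()
        if self.fit_intercept:
            X = np.column_stack([np.ones(n), X])
        p = X.shape[1]
        if n <= p:
            raise ValueError(f"need more observations ({n}) than parameters ({p})")

        # mean-response start, as in standard GLM practice
        mu = y + 0.5
        eta = np.log(mu)
        beta = np.zeros(p)
        dev = self._deviance(y, mu)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            w = mu  # Poisson log-link working weights
            z = eta - offset + (y - mu) / mu
            wx = X * w[:, None]
            beta_new, *_ = np.linalg.lstsq(wx.T @ X, wx.T @ z, rcond=None)
            eta = X @ beta_new + offset
            eta = np.clip(eta, -30, 30)  # guard against separation blow-up
            mu = np.exp(eta)
            dev_new = self._deviance(y, mu)
            beta = beta_new
            if abs(dev_new - dev) / (abs(dev_new) + 0.1) < self.tol:
                converged = True
                dev = dev_new
                break
            dev = dev_new

        info = (X * mu[:, None]).T @ X
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
            converged = False
        self.coef_ = beta
        self.se_ = se
        self.cov_ = cov
        self.deviance_ = float(dev)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = y * np.log(mu) - mu - [math.lgamma(v + 1.0) for v in y]
        self.loglik_ = float(np.sum(ll))
        self.converged_ = bool(converged)
        self.n_iter_ = it
        self.n_obs_ = n
        self.n_params_ = p
        return self

    @staticmethod
    def _deviance(y, mu):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(y > 0, y * np.log(y / mu), 0.0)
        return float(2.0 * np.sum(term - (y - mu)))

    def predict(self, X, offset=None):
        """Expected counts for a design matrix (and optional offset)."""
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        offset = 0.0 if offset is None else np.asarray(offset, float).ravel()
        return np.exp(X @ self.coef_ + offset)


@dataclass(frozen=True)
class GLMFit:
    """A fitted Poisson rate model plus its AICc bookkeeping."""

    terms: tuple[str, ...]
    coef_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    k: int
    n: int
    aicc: float
    converged: bool
    iterations: int

    @property
    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.coef_names, self.coefficients))

    @property
    def var_dict(self) -> dict[str, float]:
        return dict(zip(self.coef_names, np.square(self.standard_errors)))


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def build_design(
    table: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    categorical: tuple[str, ...] = ("year",),
) -> pd.DataFrame:
    """Expand term names into numeric design columns.

    Plain terms map to their column; terms listed in ``categorical`` are
    dummy-coded (first level dropped); ``a:b`` builds the element-wise
    products of the expansions of ``a`` and ``b``.
    """
    blocks: list[pd.DataFrame] = []
    for term in terms:
        blocks.append(_expand_term(table, term, categorical))
    if not blocks:
        return pd.DataFrame(index=table.index)
    return pd.concat(blocks, axis=1)


def _expand_term(table, term, categorical):
    if ":" in term:
        parts = [p.strip() for p in term.split(":")]
        mats = [_expand_term(table, p, categorical) for p in parts]
        out = mats[0]
        for nxt in mats[1:]:
            cols = {}
            for a in out.columns:
                for b in nxt.columns:
                    cols[f"{a}:{b}"] = out[a].to_numpy() * nxt[b].to_numpy()
            out = pd.DataFrame(cols, index=table.index)
        return out
    if term not in table.columns:
        raise KeyError(f"unknown covariate term {term!r}")
    if term in categorical:
        dummies = pd.get_dummies(table[term], prefix=term, drop_first=True)
        return dummies.astype(float)
    return table[[term]].astype(float)


def fit_poisson_glm(
    counts,
    offset_counts,
    design: pd.DataFrame | None = None,
    terms: tuple[str, ...] = (),
    categorical: tuple[str, ...] = ("year",),
) -> GLMFit:
    """Fit one Poisson rate model and return it with its AICc.

    Parameters
    ----------
    counts : array-like
        Monthly event counts.
    offset_counts : array-like
        Monthly exposures (> 0, elementwise >= counts); enter the model
        as a fixed log offset.
    design : DataFrame, optional
        Covariate table; ``terms`` are expanded against it.  Omit both
        for the intercept-only model.
    """
    y = np.asarray(counts, dtype=float).ravel()
    expo = np.asarray(offset_counts, dtype=float).ravel()
    if np.any(expo <= 0):
        raise ValueError("offset exposures must be strictly positive")
    if np.any(y > expo):
        raise ValueError("counts cannot exceed their exposures")
    if design is not None and terms:
        Xdf = build_design(design, terms, categorical)
        X = Xdf.to_numpy(dtype=float)
        coef_names = ("Intercept", *Xdf.columns)
    else:
        X = np.empty((y.size, 0))
        coef_names = ("Intercept",)
        terms = ()
    est = PoissonGLM().fit(X, y, offset=np.log(expo))
    return GLMFit(
        terms=tuple(terms),
        coef_names=coef_names,
        coefficients=est.coef_,
        standard_errors=est.se_,
        log_likelihood=est.loglik_,
        k=est.n_params_,
        n=est.n_obs_,
        aicc=aicc(est.loglik_, est.n_params_, est.n_obs_),
        converged=est.converged_,
        iterations=est.n_iter_,
    )


@dataclass(frozen=True)
class ModelConstraints:
    """Constraints on the candidate model set.

    one_of_groups : groups (e.g. the rainfall lags) from which at most
        one member may enter any single model.
    exclusive_groups : pairs/groups of terms that never co-occur
        (collinear alternatives such as photoperiod and temperature).
    """

    one_of_groups: tuple[tuple[str, ...], ...] = ()
    exclusive_groups: tuple[tuple[str, ...], ...] = ()

    def allows(self, terms: tuple[str, ...]) -> bool:
        base = set()
        for t in terms:
            base.update(p.strip() for p in t.split(":"))
        for group in self.one_of_groups:
            if len(base & set(group)) > 1:
                return False
        for group in self.exclusive_groups:
            if len(base & set(group)) > 1:
                return False
        mains = {t for t in terms if ":" not in t}
        for t in terms:
            if ":" in t and any(
                p.strip() not in mains for p in t.split(":")
            ):
                return False
        return True


def enumerate_models(
    candidate_terms,
    constraints: ModelConstraints | None = None,
) -> list[tuple[str, ...]]:
    """All additive subsets of the candidate terms obeying the constraints.

    Always includes the intercept-only model ``()``.  Interaction terms
    (``a:b``) are admitted only when both main effects are present.
    """
    constraints = constraints or ModelConstraints()
    terms = list(candidate_terms)
    models = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            if constraints.allows(combo):
                models.append(tuple(combo))
    return models


@dataclass(frozen=True)
class AveragedModelResult:
    """Full model-averaged coefficients with unconditional uncertainty."""

    estimates: pd.DataFrame       # per coefficient: estimate, se, z, ci
    model_table: pd.DataFrame     # per model: terms, k, aicc, delta, weights
    top_set: tuple[tuple[str, ...], ...]
    top_delta: float

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.reset_index().to_dict(orient="records"),
            "model_table": self.model_table.to_dict(orient="records"),
            "top_set": [list(m) for m in self.top_set],
            "top_delta": self.top_delta,
        }


def rank_and_average(
    fits: list[GLMFit],
    top_delta: float = 2.0,
    renormalize_top: bool = True,
    z_crit: float = 1.959963984540054,
) -> AveragedModelResult:
    """Rank fitted models by AICc and full-average the top set.

    Akaike weights are computed over the whole converged candidate set
    for the model table; averaging uses the models with AICc within
    ``top_delta`` of the best, with weights renormalised over that set
    (set ``renormalize_top=False`` to keep full-set weights).  Averaging
    is "full": a coefficient is zero, with zero within-model variance,
    in models that exclude its term.
    """
    usable = [f for f in fits if f.converged]
    if not usable:
        raise ValueError("no converged model fits to average")
    aiccs = np.array([f.aicc for f in usable])
    delta = aiccs - aiccs.min()
    raw_w = np.exp(-delta / 2.0)
    weights_all = raw_w / raw_w.sum()

    order = np.argsort(delta, kind="stable")
    table = pd.DataFrame(
        {
            "terms": [" + ".join(usable[i].terms) or "1" for i in order],
            "k": [usable[i].k for i in order],
            "aicc": aiccs[order],
            "delta_aicc": delta[order],
            "akaike_weight": weights_all[order],
        }
    )

    top_idx = [i for i in order if delta[i] < top_delta]
    w_top = np.array([weights_all[i] for i in top_idx])
    if renormalize_top:
        w_top = w_top / w_top.sum()
    top_fits = [usable[i] for i in top_idx]

    coef_names: list[str] = []
    for f in top_fits:
        for name in f.coef_names:
            if name not in coef_names:
                coef_names.append(name)
    rows = {}
    for name in coef_names:
        betas = np.array([f.coef_dict.get(name, 0.0) for f in top_fits])
        varis = np.array([f.var_dict.get(name, 0.0) for f in top_fits])
        beta_bar = float(w_top @ betas)
        var_u = float(w_top @ (varis + (betas - beta_bar) ** 2))
        se_u = math.sqrt(var_u)
        rows[name] = {
            "estimate": beta_bar,
            "se_unconditional": se_u,
            "z_value": abs(beta_bar) / se_u if se_u > 0 else np.inf,
            "ci_low": beta_bar - z_crit * se_u,
            "ci_high": beta_bar + z_crit * se_u,
        }
    estimates = pd.DataFrame.from_dict(rows, orient="index")
    estimates.index.name = "term"
    return AveragedModelResult(
        estimates=estimates,
        model_table=table.reset_index(drop=True),
        top_set=tuple(f.terms for f in top_fits),
        top_delta=top_delta,
    )
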