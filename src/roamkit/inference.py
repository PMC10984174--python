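"""Gamma GLM of home-range size with two-stage AICc model selection.

Home-range areas are strictly positive and right-skewed, so candidate
models are gamma GLMs with a log link (multiplicative covariate effects).
Model selection is all-subsets within two stages — intrinsic predictors
(sex, age, neuroticism) first, then extrinsic predictors (road density,
major-road presence, ordinal start date) with any retained intrinsic
predictor carried into every stage-2 candidate. Support is judged by the
small-sample-corrected information criterion

    AICc = −2·logL + 2k + 2k(k+1)/(n−k−1),

where k counts the intercept, the slopes and the gamma shape parameter.
A predictor is retained when it appears in at least one model within
ΔAICc of the cut (default 2) *and* its Wald CI (default 85 %, the
AIC-consistent level) in the best model containing it excludes zero.
Coefficients are combined across the ΔAICc window by full
(zero-substitution) model averaging with renormalised Akaike weights and
Buckland unconditional standard errors.

Coefficients come from iteratively reweighted least squares (via
statsmodels); the gamma shape is re-estimated by maximum likelihood for
each candidate so that log-likelihoods, and hence AICc values, are
coherent across models. Wald standard errors use the Pearson dispersion
(the convention of mainstream GLM software).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)

INTRINSIC = ("sex", "age", "neuroticism")
EXTRINSIC = ("road_density", "major_road", "start_ordinal_date")


# ---------------------------------------------------------------------------
# Single-model fit
# ---------------------------------------------------------------------------

@dataclass
class FittedGlm:
    predictors: tuple[str, ...]  # predictor names (not design columns)
    params: pd.Series  # coefficients incl. Intercept, link scale
    bse: pd.Series
    loglik: float  # at the ML shape estimate
    shape: float  # gamma shape (ML)
    k: int  # intercept + slopes + shape
    n: int
    columns: dict[str, list[str]] = field(default_factory=dict)


def _ml_gamma_shape(y: np.ndarray, mu: np.ndarray) -> float:
    """ML estimate of the gamma shape given fitted means.

    Solves log k − ψ(k) + 1 + mean(log(y/μ) − y/μ) = 0; the mean term is
    ≤ −1 with equality only for a perfect fit, where k → ∞ (capped).
    """
    m = float(np.mean(np.log(y / mu) - y / mu))
    if m >= -1.0 - 1e-12:
        return 1e8

    def g(k):
        return math.log(k) - special.digamma(k) + 1.0 + m

    return float(optimize.brentq(g, 1e-8, 1e10, xtol=1e-12, rtol=1e-12))


def _gamma_loglik(y: np.ndarray, mu: np.ndarray, shape: float) -> float:
    return float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))


def design_matrix(table: pd.DataFrame,
                  predictors: tuple[str, ...]) -> tuple[pd.DataFrame, dict]:
    """Design columns for the named predictors.

    Categorical sex becomes a single male contrast ``sex_M`` (animals of
    unknown sex must be dropped upstream); everything else enters as-is.
    """
    cols = {}
    out = {}
    for p in predictors:
        if p == "sex":
            out["sex_M"] = (table["sex"].astype(str) == "M").astype(float)
            cols[p] = ["sex_M"]
        else:
            out[p] = table[p].astype(float)
            cols[p] = [p]
    X = pd.DataFrame(out, index=table.index)
    return X, cols


def fit_gamma_glm(response: pd.Series, design: pd.DataFrame,
                  predictors: tuple[str, ...] | None = None,
                  columns: dict | None = None,
                  maxiter: int = 100) -> FittedGlm:
    """Gamma GLM (log link) by IRLS, gamma shape by profile ML."""
    y = np.asarray(response, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma GLM response must be strictly positive")
    preds_in = tuple(predictors if predictors is not None
                     else design.columns)
    if design.shape[1] == 0:
        # intercept-only: ML mean is the sample mean in closed form
        mu = np.full_like(y, y.mean())
        shape = _ml_gamma_shape(y, mu)
        # Pearson-dispersion Wald SE, matching the slope models' convention
        phi = float(np.sum(((y - mu) / mu) ** 2)) / max(len(y) - 1, 1)
        se0 = math.sqrt(phi / len(y))
        return FittedGlm(
            predictors=preds_in,
            params=pd.Series({"Intercept": math.log(y.mean())}),
            bse=pd.Series({"Intercept": se0}),
            loglik=_gamma_loglik(y, mu, shape),
            shape=shape, k=2, n=len(y),
            columns=dict(columns or {}),
        )
    X = sm.add_constant(design.astype(float), has_constant="add")
    model = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Log()))
    try:
        res = model.fit(maxiter=maxiter, tol=1e-8)
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"gamma GLM failed to converge: {err}") from err
    if not res.converged:
        # IRLS can enter a shallow limit cycle; polish with a quasi-Newton
        # step from the IRLS iterate before declaring failure
        res2 = model.fit(start_params=np.asarray(res.params),
                         method="lbfgs", maxiter=200, disp=0)
        if np.all(np.isfinite(np.asarray(res2.params))):
            res = res2
        else:
            raise RuntimeError(
                f"gamma GLM did not converge in {maxiter} IRLS iterations; "
                f"deviance trace ends at {res.deviance:.4g}"
            )
    mu = np.asarray(res.fittedvalues)
    shape = _ml_gamma_shape(y, mu)
    llf = _gamma_loglik(y, mu, shape)
    preds = tuple(predictors if predictors is not None else design.columns)
    return FittedGlm(
        predictors=preds,
        params=res.params.rename({"const": "Intercept"}),
        bse=res.bse.rename({"const": "Intercept"}),
        loglik=llf,
        shape=shape,
        k=len(res.params) + 1,
        n=len(y),
        columns=dict(columns or {p: [p] for p in preds}),
    )


# ---------------------------------------------------------------------------
# AICc bookkeeping
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined: need n > k + 1 (n={n}, k={k})")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class ModelSet:
    """All candidate models of one stage, ranked by AICc."""

    table: pd.DataFrame  # model, df, AICc, delta_aicc, weight (sorted)
    fits: dict[tuple[str, ...], FittedGlm]

    @property
    def best(self) -> FittedGlm:
        return self.fits[self.table.iloc[0]["model"]]

    def within(self, delta_cut: float) -> pd.DataFrame:
        return self.table[self.table["delta_aicc"] < delta_cut]


def rank_models(fits: list[FittedGlm]) -> ModelSet:
    rows = []
    for f in fits:
        rows.append({"model": f.predictors, "df": f.k,
                     "AICc": aicc(f.loglik, f.k, f.n)})
    tab = pd.DataFrame(rows).sort_values("AICc", kind="mergesort")
    tab["delta_aicc"] = tab["AICc"] - tab["AICc"].min()
    rel = np.exp(-0.5 * tab["delta_aicc"].to_numpy())
    tab["weight"] = rel / rel.sum()
    tab = tab.reset_index(drop=True)
    return ModelSet(tab, {f.predictors: f for f in fits})


def all_subsets(table: pd.DataFrame, response: pd.Series,
                stage_predictors: tuple[str, ...],
                carried: tuple[str, ...] = ()) -> ModelSet:
    """Fit every subset of the stage predictors (carried predictors are in
    every candidate, including the stage's null model)."""
    needed = list(dict.fromkeys(carried + stage_predictors))
    usable = table.dropna(subset=[c for c in needed if c in table.columns])
    if "sex" in needed:
        usable = usable[usable["sex"].isin(["M", "F"])]
    dropped = len(table) - len(usable)
    if dropped:
        logger.info("%d animal(s) dropped for missing covariates", dropped)
    max_k = len(needed) + 3  # largest candidate: slopes + intercept + shape
    if len(usable) <= max_k + 1:
        raise ValueError(
            f"only {len(usable)} animal(s) have complete covariates "
            f"({needed}); AICc needs n > k + 1 = {max_k + 1}"
        )
    y = response.loc[usable.index]

    fits = []
    for r in range(len(stage_predictors) + 1):
        for combo in itertools.combinations(stage_predictors, r):
            preds = tuple(carried) + combo
            X, cols = design_matrix(usable, preds)
            fits.append(fit_gamma_glm(y, X, predictors=preds, columns=cols))
    return rank_models(fits)


# ---------------------------------------------------------------------------
# Retention and model averaging
# ---------------------------------------------------------------------------

def wald_ci(fit: FittedGlm, column: str, level: float
            ) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2.0)
    est, se = float(fit.params[column]), float(fit.bse[column])
    return est - z * se, est + z * se


def retain_predictors(model_set: ModelSet, stage_predictors,
                      delta_cut: float = 2.0,
                      ci_level: float = 0.85) -> tuple[str, ...]:
    """Predictors supported by the stage: present in a ΔAICc<cut model and
    with a zero-excluding Wald CI in the best model containing them."""
    top = model_set.within(delta_cut)
    retained = []
    for p in stage_predictors:
        in_top = any(p in m for m in top["model"])
        if not in_top:
            continue
        best_with = next(m for m in model_set.table["model"] if p in m)
        fit = model_set.fits[best_with]
        excludes = False
        for col in fit.columns[p]:
            lo, hi = wald_ci(fit, col, ci_level)
            if lo > 0 or hi < 0:
                excludes = True
        if excludes:
            retained.append(p)
    return tuple(retained)


def model_average(model_set: ModelSet, delta_cut: float = 2.0,
                  ci_level: float = 0.85,
                  conditional: bool = False) -> pd.DataFrame:
    """Average coefficients over the ΔAICc window.

    Full (zero-substitution) averaging by default: a model that excludes a
    coefficient contributes zero with zero variance. Unconditional SEs use
    the weight-combined (Buckland) formula
    se = Σ wᵢ·√(seᵢ² + (βᵢ − β̄)²).
    """
    top = model_set.within(delta_cut)
    if top.empty:
        raise ValueError("no models within the AICc window")
    w = top["weight"].to_numpy()
    w = w / w.sum()
    fits = [model_set.fits[m] for m in top["model"]]

    columns: list[str] = []
    for f in fits:
        for c in f.params.index:
            if c not in columns:
                columns.append(c)
    rows = []
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    for col in columns:
        est = np.array([float(f.params.get(col, 0.0)) for f in fits])
        se = np.array([float(f.bse.get(col, 0.0)) for f in fits])
        present = np.array([col in f.params.index for f in fits])
        if conditional:
            wc = w[present] / w[present].sum()
            beta = float(np.sum(wc * est[present]))
            use = float(np.sum(
                wc * np.sqrt(se[present] ** 2 + (est[present] - beta) ** 2)))
        else:
            beta = float(np.sum(w * est))
            use = float(np.sum(w * np.sqrt(se**2 + (est - beta) ** 2)))
        rows.append({"coefficient": col, "estimate": beta, "se": use,
                     "ci_lower": beta - z * use, "ci_upper": beta + z * use})
    return pd.DataFrame(rows).set_index("coefficient")


# ---------------------------------------------------------------------------
# Two-stage driver
# ---------------------------------------------------------------------------

@dataclass
class TwoStageResult:
    intrinsic: ModelSet
    retained_intrinsic: tuple[str, ...]
    extrinsic: ModelSet
    retained_extrinsic: tuple[str, ...]
    averaged: pd.DataFrame


def run_two_stage(table: pd.DataFrame, response: pd.Series,
                  delta_cut: float = 2.0, ci_level: float = 0.85,
                  intrinsic: tuple[str, ...] = INTRINSIC,
                  extrinsic: tuple[str, ...] = EXTRINSIC) -> TwoStageResult:
    """Intrinsic stage, carry supported predictors, extrinsic stage,
    then model averaging over the final ΔAICc window."""
    stage1 = all_subsets(table, response, intrinsic)
    carried = retain_predictors(stage1, intrinsic, delta_cut, ci_level)
    stage2 = all_subsets(table, response, extrinsic, carried=carried)
    retained2 = retain_predictors(stage2, carried + extrinsic, delta_cut,
                                  ci_level)
    averaged = model_average(stage2, delta_cut, ci_level)
    return TwoStageResult(stage1, carried, stage2, retained2, averaged)
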