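"""Breeding-success regression: 2-SD standardization, AICc all-subsets
model selection, full-model averaging, and relative importance.

The analysis asks which of four predictors — age, average weight, and the
two standardized heterozygosities (genome-wide and MHC) — best explain
whether an adult bred, and, among breeders, how many offspring it produced.
Sexes are modeled separately.  Binary breeding success uses a binomial GLM
(optionally with one random intercept, fitted by adaptive Gauss-Hermite
quadrature); offspring counts use a Poisson GLM for males and, for females
— biologically capped at four young — a binomial response of successes
(offspring) out of four.

Predictors are standardized by centring and dividing by twice the sample
standard deviation, which puts binary and continuous effects on a
comparable scale.  All subsets of the global predictor set are fitted and
ranked by AICc; models within a fixed AICc distance of the best form the
top set, whose renormalized Akaike weights drive full-model averaging
(absent predictors contribute zero) with unconditional standard errors.
Relative importance (RI) of a predictor is the proportion of top-set models
that include it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .glmm import ConvergenceError, fit_glmm

__all__ = [
    "ModelSpec",
    "FitResult",
    "AveragedModel",
    "Standardization",
    "standardize_2sd",
    "two_sd_constants",
    "standardize_within_group",
    "fit_glm",
    "model_average",
    "fitted_probabilities",
    "aicc",
    "SeparationError",
]

FAMILIES = ("binomial", "poisson", "binomial_out_of_4")


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation detected in a binomial fit."""


@dataclass(frozen=True)
class Standardization:
    """Constants of one predictor's 2-SD standardization, kept for back-transforms."""

    mean: float
    sd: float  # sample SD (ddof=1)
    minimum: float
    maximum: float

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / (2.0 * self.sd)


def two_sd_constants(values: Sequence[float], name: str = "predictor") -> Standardization:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(np.unique(v)) < 2:
        raise ValueError(f"{name}: cannot standardize a constant (zero SD)")
    return Standardization(float(v.mean()), float(v.std(ddof=1)), float(v.min()), float(v.max()))


def standardize_2sd(values: Sequence[float], name: str = "predictor") -> np.ndarray:
    """Centre and divide by twice the sample SD: (x - mean) / (2 * SD)."""
    return two_sd_constants(values, name).apply(values)


def standardize_within_group(
    data: pd.DataFrame,
    predictors: Sequence[str],
    group_cols: Sequence[str] = ("enclosure_year_id", "sex"),
    prefix: str = "z_",
) -> pd.DataFrame:
    """Relative (within enclosure-year × sex) 2-SD standardization.

    Returns a copy of ``data`` with ``prefix + predictor`` columns holding
    each value's difference from its group mean divided by twice the group
    SD.  A group in which a predictor has zero spread gets relative value 0
    for that predictor (with a warning): every member is average for its
    group.
    """
    out = data.copy()
    for pred in predictors:
        zcol = np.full(len(data), np.nan)
        for key, idx in data.groupby(list(group_cols)).groups.items():
            v = data.loc[idx, pred].to_numpy(dtype=float)
            if len(v) < 2:
                raise ValueError(f"group {key}: needs at least 2 members to standardize {pred!r}")
            sd = v.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                warnings.warn(
                    f"group {key}: zero SD for {pred!r}; relative values set to 0",
                    stacklevel=2,
                )
                zcol[data.index.get_indexer(idx)] = 0.0
            else:
                zcol[data.index.get_indexer(idx)] = (v - v.mean()) / (2.0 * sd)
        out[prefix + pred] = zcol
    return out


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response family, predictor subset, optional random intercept."""

    response: str  # column holding the response (binary or count)
    family: str  # binomial | poisson | binomial_out_of_4
    predictors: tuple[str, ...]
    random_intercept: str | None = None  # grouping column, or None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: dict[str, float]  # "(Intercept)" plus included predictors
    standard_errors: dict[str, float]
    loglik: float
    k: int  # intercept + slopes + random-intercept variance (if fitted)
    n: int
    aicc: float
    random_intercept_var: float | None = None
    delta_aicc: float = field(default=np.nan)
    weight: float = field(default=np.nan)


@dataclass
class AveragedModel:
    """Full-average coefficients over the AICc top set."""

    estimates: dict[str, float]
    unconditional_se: dict[str, float]
    relative_importance: dict[str, float]
    top_models: list[FitResult]
    all_models: list[FitResult]
    global_spec: ModelSpec
    delta_threshold: float
    method: str  # "full" or "conditional"


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k} parameters")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _response_arrays(spec: ModelSpec, data: pd.DataFrame):
    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == "binomial":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError(f"{spec.response}: binomial response must be 0/1")
        return y, 1
    if spec.family == "binomial_out_of_4":
        if ((y < 0) | (y > 4)).any():
            raise ValueError(f"{spec.response}: counts must lie in 0..4")
        return y, 4
    if (y < 0).any():
        raise ValueError(f"{spec.response}: Poisson response must be non-negative")
    return y, None


def _check_separation(coefs: np.ndarray, names: Sequence[str]) -> None:
    big = np.abs(coefs) > 15.0
    if big.any():
        which = [n for n, b in zip(names, big) if b]
        raise SeparationError(
            f"coefficients {which} diverged (|estimate| > 15 on the standardized scale); "
            "likely complete separation"
        )


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit one candidate model by maximum likelihood.

    Fixed-effects families go through iteratively reweighted least squares
    (relative deviance change < 1e-8, at most 100 iterations); a requested
    random intercept switches to the adaptive Gauss-Hermite marginal
    likelihood (15 nodes).
    """
    cols = list(spec.predictors)
    sub = data.dropna(subset=[spec.response, *cols, *( [spec.random_intercept] if spec.random_intercept else [] )])
    n = len(sub)
    y, trials = _response_arrays(spec, sub)
    X = np.column_stack([np.ones(n)] + [sub[c].to_numpy(dtype=float) for c in cols])
    names = ["(Intercept)", *cols]
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small to fit {len(cols)} predictors")

    if spec.random_intercept is None:
        if spec.family == "poisson":
            model = sm.GLM(y, X, family=sm.families.Poisson())
        elif spec.family == "binomial_out_of_4":
            model = sm.GLM(np.column_stack([y, 4 - y]), X, family=sm.families.Binomial())
        else:
            model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=100, tol=1e-8)
        if not res.converged:
            raise ConvergenceError(f"IRLS failed to converge in 100 iterations for {names}")
        coefs = np.asarray(res.params)
        _check_separation(coefs, names)
        ll = float(res.llf)
        k = len(names)
        ses = np.asarray(res.bse)
        rvar = None
    else:
        groups = sub[spec.random_intercept].to_numpy()
        fam = "poisson" if spec.family == "poisson" else "binomial"
        glmm = fit_glmm(y, X, groups, family=fam, trials=trials if trials else 1)
        coefs = glmm.beta
        _check_separation(coefs, names)
        ll = glmm.loglik
        k = len(names) + 1  # + random-intercept variance
        ses = glmm.se_beta
        rvar = glmm.sigma**2
    return FitResult(
        spec=spec,
        coefficients=dict(zip(names, map(float, coefs))),
        standard_errors=dict(zip(names, map(float, ses))),
        loglik=ll,
        k=k,
        n=n,
        aicc=aicc(ll, k, n),
        random_intercept_var=rvar,
    )


def model_average(
    global_spec: ModelSpec,
    data: pd.DataFrame,
    delta_threshold: float = 2.0,
    method: str = "full",
) -> AveragedModel:
    """All-subsets AICc selection and model averaging over the top set.

    Fits every subset of the global predictor set (including the
    intercept-only model), keeps models within ``delta_threshold`` AICc of
    the best, renormalizes their Akaike weights, and averages.  ``method =
    "full"`` substitutes zero where a predictor is absent (shrinking
    uncertain effects toward zero); ``"conditional"`` averages only over the
    models containing the predictor.
    """
    if method not in ("full", "conditional"):
        raise ValueError(f"unknown averaging method {method!r}")
    preds = global_spec.predictors
    fits: list[FitResult] = []
    for r in range(len(preds) + 1):
        for subset in combinations(preds, r):
            spec = ModelSpec(global_spec.response, global_spec.family, subset, global_spec.random_intercept)
            try:
                fits.append(fit_glm(spec, data))
            except (ConvergenceError, SeparationError) as exc:
                warnings.warn(f"subset {subset}: excluded ({exc})", stacklevel=2)
    if not fits:
        raise RuntimeError("no candidate model converged")
    best = min(f.aicc for f in fits)
    for f in fits:
        f.delta_aicc = f.aicc - best
    top = sorted((f for f in fits if f.delta_aicc <= delta_threshold), key=lambda f: f.aicc)
    raw_w = np.exp([-0.5 * f.delta_aicc for f in top])
    w = raw_w / raw_w.sum()
    for f, wi in zip(top, w):
        f.weight = float(wi)

    terms = ["(Intercept)", *preds]
    estimates: dict[str, float] = {}
    unc_se: dict[str, float] = {}
    ri: dict[str, float] = {}
    for term in terms:
        betas = np.array([f.coefficients.get(term, 0.0) for f in top])
        ses = np.array([f.standard_errors.get(term, 0.0) for f in top])
        present = np.array([term in f.coefficients for f in top])
        if method == "conditional" and term != "(Intercept)":
            if not present.any():
                estimates[term] = 0.0
                unc_se[term] = 0.0
                ri[term] = 0.0
                continue
            wc = w[present] / w[present].sum()
            bc, sc = betas[present], ses[present]
            est = float(np.sum(wc * bc))
            var = float(np.sum(wc * (sc**2 + (bc - est) ** 2)))
        else:
            est = float(np.sum(w * betas))
            var = float(np.sum(w * (ses**2 + (betas - est) ** 2)))
        estimates[term] = est
        unc_se[term] = float(np.sqrt(var))
        if term != "(Intercept)":
            ri[term] = float(present.mean())
    return AveragedModel(
        estimates=estimates,
        unconditional_se=unc_se,
        relative_importance=ri,
        top_models=top,
        all_models=sorted(fits, key=lambda f: f.aicc),
        global_spec=global_spec,
        delta_threshold=delta_threshold,
        method=method,
    )


@dataclass(frozen=True)
class FittedProbability:
    probability: float
    linear_predictor: float
    uncertain_predictors: tuple[str, ...]  # RI < 1: averaged estimate is shrunken


def fitted_probabilities(
    avg: AveragedModel,
    profile: Mapping[str, float],
    standardizations: Mapping[str, Standardization],
) -> FittedProbability:
    """Back-transform the averaged model to a breeding probability for a raw
    covariate profile.

    ``profile`` gives raw covariate values (e.g. age in years);
    ``standardizations`` the constants used at fit time.  Predictors with
    RI < 1 are included (full-average coefficients) but flagged, since their
    averaged estimates are shrunken by model-selection uncertainty.  A
    profile value outside the fitted covariate range triggers an
    extrapolation warning.
    """
    eta = avg.estimates["(Intercept)"]
    flagged = []
    for pred in avg.global_spec.predictors:
        if pred not in profile:
            raise KeyError(f"profile is missing predictor {pred!r}")
        std = standardizations[pred]
        x = float(profile[pred])
        if x < std.minimum or x > std.maximum:
            warnings.warn(
                f"{pred}={x} lies outside the fitted range "
                f"[{std.minimum}, {std.maximum}]; extrapolating",
                stacklevel=2,
            )
        eta += avg.estimates[pred] * float(std.apply(x))
        if avg.relative_importance.get(pred, 0.0) < 1.0:
            flagged.append(pred)
    return FittedProbability(
        probability=float(expit(eta)),
        linear_predictor=float(eta),
        uncertain_predictors=tuple(flagged),
    )


def averaged_table(avg: AveragedModel) -> pd.DataFrame:
    """Results table in the conventional layout: predictor, estimate
    (unconditional SE), RI."""
    rows = []
    for term, est in avg.estimates.items():
        rows.append(
            {
                "predictor": term,
                "estimate": est,
                "unconditional_se": avg.unconditional_se[term],
                "relative_importance": avg.relative_importance.get(term, np.nan),
            }
        )
    return pd.DataFrame(rows)
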