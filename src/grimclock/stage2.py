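"""Stage 2: penalized Cox mortality clock, year-scale calibration, published
model, age acceleration, and deviance-residual mortality scores.

The clock is the linear predictor of an elastic-net Cox regression of
time-to-death on DNAm surrogate biomarkers plus age and sex, linearly
rescaled so that its mean and variance over the training cohort match those
of chronological age.  Ties are handled with the Breslow approximation
throughout, the standard convention for penalized Cox software.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .core_data import ClockModel
from .stage1 import ElasticNetSpec

#: Published 12-covariate mortality-clock coefficients (Cox log-hazard scale).
#: The ten DNAm components are surrogate biomarkers of plasma proteins
#: (adrenomedullin, beta-2-microglobulin, cystatin C, GDF-15, leptin, log CRP,
#: log hemoglobin A1C, PAI-1, TIMP-1) and smoking pack-years; the clock also
#: uses chronological age and a female indicator.
PUBLISHED_GRIMAGE2_COEFFICIENTS = {
    "DNAmADM": 0.00609,
    "DNAmB2M": 2.79e-07,
    "DNAmCystatin C": 4.08e-06,
    "DNAmGDF-15": 0.00035,
    "DNAmLeptin": -2.03e-05,
    "DNAmlogCRP": 1.90266,
    "DNAmlogA1C": 0.40359,
    "DNAmPAI-1": 0.02941,
    "DNAmTIMP-1": 3.67e-06,
    "DNAmPACKYRS": 0.00014,
    "Age": 0.02676,
    "Female": -0.14212,
}

#: Published year-scale calibration: clock = intercept + slope * (X @ beta).
PUBLISHED_GRIMAGE2_CALIBRATION = (-61.03936, 8.271105)


@dataclass
class CoxFit:
    """Elastic-net Cox fit: coefficients over all candidates (zeros allowed)."""

    coefficients: dict[str, float]
    lambda_: float
    alpha: float
    ties_method: str = "breslow"
    converged: bool = True


@dataclass
class Calibration:
    """Affine map putting a Cox linear predictor on the scale of age (years)."""

    intercept: float
    slope: float
    train_age_mean: float
    train_age_sd: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be positive")


def breslow_partial_loglik(time, event, lp) -> float:
    """Cox partial log-likelihood with Breslow handling of tied event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    ll = 0.0
    exp_lp = np.exp(lp)
    for t in np.unique(time[event == 1]):
        at_event = (time == t) & (event == 1)
        risk = time >= t
        ll += lp[at_event].sum() - at_event.sum() * np.log(exp_lp[risk].sum())
    return float(ll)


def _as_surv(time, event):
    return Surv.from_arrays(
        event=np.asarray(event, dtype=bool), time=np.asarray(time, dtype=float)
    )


def fit_cox_elastic_net(
    X: pd.DataFrame, time, event, spec: ElasticNetSpec | None = None
) -> CoxFit:
    """Fit an elastic-net penalized Cox model of time-to-event on ``X``.

    lambda is chosen (unless fixed in the spec) by k-fold cross-validation
    maximizing the held-out partial-likelihood contribution
    ``ll_all(beta_-k) - ll_train(beta_-k)`` summed over folds (the grouped
    deviance used by glmnet-style software).  Covariates are standardized
    internally; coefficients are reported on the original scale.  lambda = 0
    falls back to an unpenalized Newton fit.
    """
    spec = spec or ElasticNetSpec()
    X = pd.DataFrame(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no events; cannot fit a Cox model")
    Xv = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xv)):
        raise ValueError("non-finite covariate values")
    names = list(X.columns)
    y = _as_surv(time, event)

    grid = spec.lambda_grid
    if np.isscalar(grid) and not isinstance(grid, str) and float(grid) == 0.0:
        est = CoxPHSurvivalAnalysis(alpha=0.0, ties="breslow", n_iter=200)
        est.fit(X, y)
        coefs = dict(zip(names, map(float, est.coef_)))
        return CoxFit(coefficients=coefs, lambda_=0.0, alpha=spec.alpha)

    l1 = max(spec.alpha, 1e-16)  # coxnet requires l1_ratio > 0
    if np.isscalar(grid) and not isinstance(grid, str):
        alphas = np.asarray([float(grid)])
    elif isinstance(grid, str):
        path = CoxnetSurvivalAnalysis(
            l1_ratio=l1, alpha_min_ratio=0.01, n_alphas=50, normalize=True
        )
        path.fit(X, y)
        alphas = np.asarray(path.alphas_)
    else:
        alphas = np.sort(np.asarray(grid, dtype=float))[::-1]

    full = CoxnetSurvivalAnalysis(
        l1_ratio=l1, alphas=alphas, normalize=True, fit_baseline_model=False
    )
    full.fit(X, y)
    fitted_alphas = np.asarray(full.alphas_)

    if len(fitted_alphas) == 1:
        best_idx = 0
    else:
        cv = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        scores = np.zeros(len(fitted_alphas))
        counts = np.zeros(len(fitted_alphas), dtype=int)
        for train_idx, _test_idx in cv.split(Xv):
            sub = CoxnetSurvivalAnalysis(
                l1_ratio=l1, alphas=fitted_alphas, normalize=True
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub.fit(X.iloc[train_idx], y[train_idx])
            coef_path = sub.coef_  # (p, n_alphas actually fit)
            # a fold may terminate its path early; match by alpha value
            for k, a in enumerate(np.asarray(sub.alphas_)):
                j = int(np.argmin(np.abs(fitted_alphas - a)))
                lp_all = Xv @ coef_path[:, k]
                ll_all = breslow_partial_loglik(time, event, lp_all)
                ll_train = breslow_partial_loglik(
                    time[train_idx], event[train_idx], lp_all[train_idx]
                )
                scores[j] += ll_all - ll_train
                counts[j] += 1
        # only alphas scored in every fold are comparable
        valid = counts == counts.max()
        scores[~valid] = -np.inf
        best_idx = int(np.argmax(scores))

    coefs = dict(zip(names, map(float, full.coef_[:, best_idx])))
    return CoxFit(
        coefficients=coefs, lambda_=float(fitted_alphas[best_idx]), alpha=spec.alpha
    )


def linear_predictor(model: ClockModel | CoxFit, X: pd.DataFrame) -> np.ndarray:
    """Sum of coefficient * covariate per sample (no intercept; Cox has none)."""
    coefs = model.coefficients
    missing = [c for c in coefs if c not in X.columns]
    if missing:
        raise ValueError(f"missing covariates: {missing}")
    names = list(coefs)
    beta = np.array([coefs[c] for c in names])
    return X[names].to_numpy(dtype=float) @ beta


def calibrate_to_age(lp_train, age_train) -> Calibration:
    """Affine calibration matching the mean and SD of chronological age.

    slope = sd(age)/sd(lp) and intercept = mean(age) - slope * mean(lp), both
    with n-1 denominators, so the calibrated training values have exactly the
    mean and SD of the training ages.
    """
    lp = np.asarray(lp_train, dtype=float)
    age = np.asarray(age_train, dtype=float)
    sd_lp = lp.std(ddof=1)
    sd_age = age.std(ddof=1)
    if sd_lp == 0 or sd_age == 0:
        raise ValueError(
            "zero variance in linear predictor or age (a fully shrunk Cox fit "
            "has no spread to calibrate; refit with a smaller penalty or more events)"
        )
    slope = sd_age / sd_lp
    intercept = age.mean() - slope * lp.mean()
    return Calibration(
        intercept=float(intercept),
        slope=float(slope),
        train_age_mean=float(age.mean()),
        train_age_sd=float(sd_age),
    )


def make_clock_model(fit: CoxFit, calibration: Calibration) -> ClockModel:
    """Package a Cox fit and its calibration as a reusable clock model."""
    return ClockModel(
        covariate_names=list(fit.coefficients),
        coefficients=dict(fit.coefficients),
        calib_intercept=calibration.intercept,
        calib_slope=calibration.slope,
    )


def apply_clock(model: ClockModel, X: pd.DataFrame) -> pd.Series:
    """Evaluate the clock in years: calib_intercept + calib_slope * (X @ beta)."""
    lp = linear_predictor(model, X)
    values = model.calib_intercept + model.calib_slope * lp
    index = X.index if isinstance(X, pd.DataFrame) else None
    return pd.Series(values, index=index, name="DNAmClock")


def published_grimage2_model() -> ClockModel:
    """The published 12-covariate mortality clock with its year calibration.

    Users supply the ten DNAm component values (computed from their own
    CpG-weight files) plus Age and Female; the per-CpG weights behind the
    components were never published and are not bundled.
    """
    intercept, slope = PUBLISHED_GRIMAGE2_CALIBRATION
    return ClockModel(
        covariate_names=list(PUBLISHED_GRIMAGE2_COEFFICIENTS),
        coefficients=dict(PUBLISHED_GRIMAGE2_COEFFICIENTS),
        calib_intercept=intercept,
        calib_slope=slope,
    )


def age_acceleration(dnam_measure, age) -> np.ndarray:
    """Residuals of the DNAm measure regressed on chronological age (OLS).

    Positive values mean the measure is higher than expected for the
    person's age.  Residuals have mean zero and zero sample covariance
    with age.
    """
    y = np.asarray(dnam_measure, dtype=float)
    a = np.asarray(age, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if a.std() == 0:
        raise ValueError("age is constant; acceleration undefined")
    A = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    if isinstance(dnam_measure, pd.Series):
        return pd.Series(resid, index=dnam_measure.index, name="AgeAccel")
    return resid


def mortality_res(time, event, lp) -> np.ndarray:
    """Deviance residuals from a Cox model with given linear predictors.

    The Breslow cumulative baseline hazard is estimated from (time, event,
    lp); the martingale residual is ``m_i = event_i - Lambda0(t_i) *
    exp(lp_i)`` and the deviance residual is ``sign(m) * sqrt(-2 * [m +
    event * log(event - m)])``.  A sample's residual measures its excess
    mortality relative to the model baseline.  With no events at all the
    baseline hazard is identically zero and a zero vector is returned with a
    warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    lp = np.asarray(lp, dtype=float)
    if not (len(time) == len(event) == len(lp)):
        raise ValueError("time, event, lp must have equal length")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    if event.sum() == 0:
        warnings.warn("all observations censored; residuals are identically zero")
        return np.zeros(len(time))

    exp_lp = np.exp(lp)
    event_times = np.unique(time[event == 1])
    increments = np.array(
        [
            ((time == t) & (event == 1)).sum() / exp_lp[time >= t].sum()
            for t in event_times
        ]
    )
    cumhaz = np.cumsum(increments)
    # Lambda0 at each sample's own time (right-continuous step function)
    idx = np.searchsorted(event_times, time, side="right") - 1
    lam0 = np.where(idx >= 0, cumhaz[np.clip(idx, 0, None)], 0.0)

    mart = event - lam0 * exp_lp
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = mart + np.where(event == 1, event * np.log(event - mart), 0.0)
    dev = np.sign(mart) * np.sqrt(-2.0 * inner)
    return dev
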