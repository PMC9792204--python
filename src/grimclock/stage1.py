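"""Stage 1: elastic-net DNAm surrogates of winsorized, log-scale plasma analytes.

Each surrogate regresses an analyte (after upper-tail winsorization at a
scaled-value threshold and natural-log transformation) on all CpG beta
columns plus chronological age and a female indicator, with an elastic-net
penalty.  The penalty strength lambda is chosen by k-fold cross-validation;
the mixing parameter alpha defaults to 0.5 (midpoint of ridge and lasso, the
convention in earlier methylation-clock work, since no single value is
canonical).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .core_data import MethylationMatrix, PhenotypeTable, SurrogateModel

#: Published winsorization bounds for the two analytes the flagship clock
#: added, in their native units (CRP in mg/L, A1C in %).
PUBLISHED_CRP_BOUNDS = (0.14, 54.01)
PUBLISHED_A1C_BOUNDS = (4.7, 10.0)


@dataclass
class ElasticNetSpec:
    """Tuning configuration for elastic-net fits (both stages).

    alpha       : L1/L2 mixing parameter in [0, 1] (1 = lasso).
    n_folds     : cross-validation folds for selecting lambda.
    lambda_grid : "auto" for a data-driven descending grid, a sequence of
                  positive values to search, or a single float to fix lambda
                  (0 means unpenalized).
    seed        : governs the shuffled fold assignment.
    standardize : standardize predictors internally; coefficients are always
                  reported on the original scale.
    """

    alpha: float = 0.5
    n_folds: int = 10
    lambda_grid: object = "auto"
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def winsorize_by_scaled_threshold(x, z_max: float = 6.0):
    """Cap the upper tail at the largest raw value whose scaled value is <= z_max.

    Scaled values are z = (x - mean) / sd computed on the raw input (SD with
    n-1 denominator).  The cap ``hi`` is the maximum raw value with z <= z_max;
    raw values with z > z_max are replaced by ``hi``.  The lower tail is left
    untouched (both target analytes are right-skewed); ``lo`` is the observed
    minimum, stored so prediction-time inputs can be clamped to the training
    range.  Returns ``(winsorized, lo, hi)``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 3:
        raise ValueError("need at least 3 values")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    if sd == 0:
        return arr.copy(), float(arr[0]), float(arr[0])
    z = (arr - mean) / sd
    inside = z <= z_max
    if not inside.any():  # pragma: no cover - impossible for z_max > 0
        raise ValueError("no values at or below the scaled threshold")
    hi = float(arr[inside].max())
    lo = float(arr.min())
    out = np.where(z > z_max, hi, arr)
    return out, lo, hi


def apply_bounds(x, lo: float, hi: float) -> np.ndarray:
    """Clamp values to stored training bounds [lo, hi]."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) exceeds hi ({hi})")
    return np.clip(np.asarray(x, dtype=float), lo, hi)


def log_transform(x) -> np.ndarray:
    """Natural log, elementwise; errors name the first offending sample."""
    arr = np.asarray(x, dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        if isinstance(x, pd.Series):
            name = x.index[bad][0]
        else:
            name = int(np.argwhere(bad)[0][0])
        raise ValueError(f"non-positive value at sample {name!r}; cannot log-transform")
    return np.log(arr)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def _fit_enet_gaussian(
    X: np.ndarray, y: np.ndarray, spec: ElasticNetSpec
) -> tuple[np.ndarray, float, float]:
    """Solve the penalized least-squares problem; returns (beta, intercept, lambda).

    Objective: MSE/2 + lambda * [alpha*||b||_1 + (1-alpha)*||b||_2^2 / 2],
    i.e. scikit-learn's parameterization with its ``alpha`` = lambda and
    ``l1_ratio`` = the mixing parameter.  Predictors are standardized
    internally when requested; coefficients are returned on the original
    scale.  lambda = 0 falls back to the least-squares solution.
    """
    if spec.standardize:
        Xs, x_mean, x_sd = _standardize(X)
    else:
        Xs, x_mean, x_sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])

    grid = spec.lambda_grid
    if np.isscalar(grid) and not isinstance(grid, str):
        lam = float(grid)
        if lam == 0.0:
            A = np.column_stack([np.ones(len(Xs)), Xs])
            coef_full, *_ = np.linalg.lstsq(A, y, rcond=None)
            b_std, icpt = coef_full[1:], coef_full[0]
        else:
            # l1_ratio=0 (pure ridge) is supported by coordinate descent too
            est = ElasticNet(alpha=lam, l1_ratio=spec.alpha, max_iter=50_000)
            est.fit(Xs, y)
            b_std, icpt = est.coef_, est.intercept_
    else:
        lam = None
        if len(y) < spec.n_folds:
            raise ValueError("n_folds exceeds the number of samples")
        cv = KFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
        alphas = 100 if isinstance(grid, str) else np.asarray(grid, dtype=float)
        est = ElasticNetCV(
            l1_ratio=spec.alpha,
            alphas=alphas,
            eps=1e-3,
            cv=cv,
            max_iter=50_000,
        )
        est.fit(Xs, y)
        b_std, icpt, lam = est.coef_, est.intercept_, float(est.alpha_)
    beta = b_std / x_sd
    intercept = float(icpt - np.dot(b_std, x_mean / x_sd))
    return beta, intercept, lam


def fit_surrogate(
    m: MethylationMatrix,
    pheno: PhenotypeTable,
    target: str,
    spec: ElasticNetSpec | None = None,
    *,
    winsorize: bool = True,
    winsor_z: float = 6.0,
    log: bool = True,
) -> SurrogateModel:
    """Train a DNAm surrogate for ``target`` on all CpGs plus age and sex.

    The target column is winsorized (upper tail, scaled-value threshold) and
    natural-log transformed when configured, then regressed on every CpG
    column together with ``age`` and ``female`` under the elastic-net penalty.
    Age and sex enter as penalized candidates alongside the CpGs.  Samples
    missing the target or any predictor are dropped listwise.  The returned
    model stores the winsorization bounds, per-CpG training means (for
    imputation at prediction time) and the mean/SD of the in-sample
    predictions (the per-SD scaling basis).
    """
    spec = spec or ElasticNetSpec()
    m, pheno = _restrict(m, pheno)
    if target not in pheno.data.columns:
        raise ValueError(f"target column {target!r} not in phenotype table")
    for col in ("age", "female"):
        if col not in pheno.data.columns:
            raise ValueError(f"phenotype table lacks required column {col!r}")

    df = pd.concat(
        [m.data, pheno.data[["age", "female", target]]], axis=1
    ).dropna()
    if len(df) < 3:
        raise ValueError("too few complete samples to fit")
    y_raw = df[target].to_numpy(dtype=float)
    if np.all(y_raw == y_raw[0]):
        raise ValueError("target is constant; nothing to fit")

    lo = hi = None
    y = y_raw
    if winsorize:
        y, lo, hi = winsorize_by_scaled_threshold(y, winsor_z)
    if log:
        y = log_transform(y)

    cpg_ids = m.cpg_ids
    X = df[cpg_ids + ["age", "female"]].to_numpy(dtype=float)
    beta, intercept, lam = _fit_enet_gaussian(X, y, spec)

    cpg_beta = beta[: len(cpg_ids)]
    nonzero = {cid: float(b) for cid, b in zip(cpg_ids, cpg_beta) if b != 0.0}
    preds = intercept + X @ beta
    train_sd = float(np.std(preds, ddof=1))
    if train_sd == 0:
        # intercept-only fit (e.g. full shrinkage): keep a unit scale so the
        # model remains serializable; scaled values are then centered only
        train_sd = 1.0
    model = SurrogateModel(
        name=target,
        cpg_weights=nonzero,
        age_weight=float(beta[len(cpg_ids)]),
        female_weight=float(beta[len(cpg_ids) + 1]),
        intercept=float(intercept),
        log_transformed=bool(log),
        train_mean=float(np.mean(preds)),
        train_sd=train_sd,
        winsor_lo=lo,
        winsor_hi=hi,
        cpg_means={cid: float(v) for cid, v in df[cpg_ids].mean().items()},
    )
    model.lambda_ = lam  # selected penalty, on scikit-learn's per-sample scale
    return model


def _restrict(m, pheno):
    from .core_data import align_samples

    if m.sample_ids == pheno.sample_ids:
        return m, pheno
    return align_samples(m, pheno)


def predict_surrogate(
    model: SurrogateModel, m: MethylationMatrix, pheno: PhenotypeTable
) -> pd.Series:
    """Apply a fitted surrogate: intercept + CpG weights + age/sex terms.

    CpGs absent from the matrix (or missing for a sample) are imputed from
    the per-CpG training means stored in the model; if those are unavailable
    the call fails listing the unresolvable CpGs.
    """
    m, pheno = _restrict(m, pheno)
    needed = list(model.cpg_weights)
    missing_cols = [c for c in needed if c not in m.data.columns]
    means = model.cpg_means or {}
    unresolvable = [c for c in missing_cols if c not in means]
    if unresolvable:
        raise ValueError(f"unresolvable CpGs (no stored training mean): {unresolvable}")
    block = pd.DataFrame(index=m.data.index)
    for c in needed:
        if c in m.data.columns:
            col = m.data[c]
            if col.isna().any():
                if c not in means:
                    raise ValueError(f"missing values in CpG {c!r} and no stored mean")
                col = col.fillna(means[c])
            block[c] = col
        else:
            block[c] = means[c]
    w = np.array([model.cpg_weights[c] for c in needed])
    score = (
        model.intercept
        + block.to_numpy(dtype=float) @ w
        + model.age_weight * pheno.data["age"].to_numpy(dtype=float)
        + model.female_weight * pheno.data["female"].to_numpy(dtype=float)
    )
    return pd.Series(score, index=m.data.index, name=f"DNAm{model.name}")


def scale_surrogate(x, model: SurrogateModel) -> np.ndarray:
    """Express surrogate values in training-SD units: (x - mean) / sd."""
    if not model.train_sd > 0:
        raise ValueError("train_sd must be positive")
    return (np.asarray(x, dtype=float) - model.train_mean) / model.train_sd
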