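"""Validation battery: robust correlation, stratified association models,
fixed-effect and Stouffer meta-analysis, EWAS screens, and phenotype utilities.

Association analyses follow the pattern used to validate methylation clocks
across epidemiological cohorts: fit the model within each stratum (cohort x
race x sex), then pool the per-stratum estimates across strata — by
inverse-variance fixed-effect weighting for effect sizes, or by Stouffer's
sqrt(n)-weighted Z combination when covariates cannot be harmonized across
cohorts.  Pedigree or repeated-measure correlation is handled with
cluster-robust sandwich standard errors keyed on a cluster column rather
than explicit mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .core_data import MetaResult, MethylationMatrix, mask_extreme_values


@dataclass
class StratumAssociation:
    """A single stratum's estimate: log HR, log OR, beta, or Fisher-z."""

    label: str
    estimate: float
    se: float
    n: int
    kind: str  # cox | logistic | linear | bicor

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.n < 3:
            raise ValueError("n must be >= 3")

    @property
    def ratio(self) -> float:
        """exp(estimate): hazard or odds ratio for cox/logistic kinds."""
        return float(np.exp(self.estimate))


# ---------------------------------------------------------------------------
# robust correlation
# ---------------------------------------------------------------------------


def bicor(x, y, c: float = 9.0) -> float:
    """Biweight midcorrelation: a median/MAD-weighted robust correlation.

    Each observation is downweighted by ``(1 - u^2)^2`` with
    ``u = (x - median) / (c * MAD)`` (raw median absolute deviation, no
    consistency constant) and dropped entirely when ``|u| >= 1``, making the
    estimate insensitive to gross outliers.  When the MAD of a variable is
    zero it is replaced by the standard deviation, with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired non-missing values")

    def weights(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError("constant vector; correlation undefined")
            warnings.warn("MAD is zero; falling back to standard deviation")
            mad = sd
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return v - med, w

    dx, wx = weights(x)
    dy, wy = weights(y)
    num = np.sum(wx * wy * dx * dy)
    den = np.sqrt(np.sum((wx * dx) ** 2) * np.sum((wy * dy) ** 2))
    return float(np.clip(num / den, -1.0, 1.0))


def fisher_z(r: float, n: int) -> tuple[float, float]:
    """Fisher transform of a correlation: (atanh(r), variance 1/(n-3))."""
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    return float(np.arctanh(r)), 1.0 / (n - 3)


def bicor_stratum(x, y, label: str, c: float = 9.0) -> StratumAssociation:
    """bicor within one stratum, expressed on the Fisher-z scale for pooling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    n = int(keep.sum())
    r = bicor(x[keep], y[keep], c)
    z, var = fisher_z(r, n)
    return StratumAssociation(label=label, estimate=z, se=float(np.sqrt(var)), n=n, kind="bicor")


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


def fixed_effect_meta(strata: list[StratumAssociation]) -> MetaResult:
    """Inverse-variance fixed-effect pooling across strata.

    Correlation (``bicor``) strata are pooled on the Fisher-z scale (their
    ``estimate`` is already atanh(r) with se 1/sqrt(n-3)) and the pooled
    estimate is back-transformed to a correlation for reporting; ``se``, ``z``
    and ``p`` then refer to the z scale.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    if any(s.se <= 0 for s in strata):
        raise ValueError("all strata must have positive se")
    est = np.array([s.estimate for s in strata])
    w = np.array([1.0 / s.se**2 for s in strata])
    pooled = float(np.sum(w * est) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    report = pooled
    if all(s.kind == "bicor" for s in strata):
        report = float(np.tanh(pooled))
    return MetaResult(
        estimate=report,
        se=se,
        z=float(z),
        p=max(p, np.nextafter(0, 1)),
        strata=[(s.label, s.estimate, s.se) for s in strata],
    )


def stouffer_meta(z_scores, ns) -> tuple[float, float]:
    """Stouffer combination of per-stratum Z scores weighted by sqrt(n)."""
    z = np.asarray(z_scores, dtype=float)
    n = np.asarray(ns, dtype=float)
    if z.size == 0:
        raise ValueError("empty input")
    if len(z) != len(n):
        raise ValueError("z_scores and ns must have equal length")
    if (n < 1).any():
        raise ValueError("sample sizes must be >= 1")
    Z = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    p = float(2 * stats.norm.sf(abs(Z)))
    return Z, max(p, np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# stratum-level association models
# ---------------------------------------------------------------------------


def cox_association(
    time,
    event,
    exposure,
    covariates: pd.DataFrame | None = None,
    cluster=None,
    label: str = "stratum",
) -> StratumAssociation:
    """Proportional-hazards association of an exposure with time-to-event.

    Returns the log hazard ratio per unit exposure with model-based standard
    error, or a cluster-robust (Huber sandwich) standard error when cluster
    labels are supplied (pedigrees, repeated measures).
    """
    df = pd.DataFrame(
        {"time": np.asarray(time, float), "event": np.asarray(event, int)}
    )
    df["exposure"] = np.asarray(exposure, float)
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        df = pd.concat([df, cov], axis=1)
    if cluster is not None:
        df["_cluster"] = np.asarray(cluster)
    if df["event"].sum() < 1:
        raise ValueError("no events in stratum")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if cluster is not None:
                cph.fit(df, duration_col="time", event_col="event", cluster_col="_cluster")
            else:
                cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # separation / non-convergence
        raise RuntimeError(f"Cox fit failed in stratum {label!r}: {exc}") from exc
    est = float(cph.params_["exposure"])
    se = float(cph.standard_errors_["exposure"])
    return StratumAssociation(label=label, estimate=est, se=se, n=len(df), kind="cox")


def logistic_association(
    outcome, exposure, covariates: pd.DataFrame | None = None, label: str = "stratum"
) -> StratumAssociation:
    """Logistic regression: log odds ratio per unit exposure with its SE."""
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    x = np.asarray(exposure, dtype=float)
    if x.std() == 0:
        raise ValueError("exposure is constant; effect not identifiable")
    X = pd.DataFrame({"exposure": x})
    if covariates is not None:
        X = pd.concat([X, pd.DataFrame(covariates).reset_index(drop=True)], axis=1)
    X = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0)
    est = float(fit.params["exposure"])
    se = float(fit.bse["exposure"])
    return StratumAssociation(label=label, estimate=est, se=se, n=len(y), kind="logistic")


# ---------------------------------------------------------------------------
# EWAS screens
# ---------------------------------------------------------------------------


def ewas_numeric_trait(
    m: MethylationMatrix, trait, min_pairs: int = 10, mask_z: float = 6.0
) -> pd.DataFrame:
    """Per-CpG correlation screen against a numeric trait.

    Each CpG column is first cleaned of extreme values (more than ``mask_z``
    SDs from its mean), then correlated (Pearson) with the trait; the p-value
    is from the Student-t reference with n-2 degrees of freedom and Z is the
    Fisher-transformed correlation times sqrt(n-3).  CpGs with fewer than
    ``min_pairs`` complete pairs are emitted with missing statistics.
    Returns a table ordered by CpG ID with columns cpg, r, z, p, n.
    """
    t = np.asarray(trait, dtype=float)
    if len(t) != m.n_samples:
        raise ValueError("trait length must match the number of samples")
    rows = []
    for cpg in sorted(m.cpg_ids):
        x = m.data[cpg].to_numpy(dtype=float)
        try:
            x = mask_extreme_values(x, mask_z)
        except ValueError:
            pass
        keep = np.isfinite(x) & np.isfinite(t)
        n = int(keep.sum())
        if n < min_pairs or np.std(x[keep]) == 0 or np.std(t[keep]) == 0:
            rows.append((cpg, np.nan, np.nan, np.nan, n))
            continue
        r, p = stats.pearsonr(x[keep], t[keep])
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(max(n - 3, 1))
        rows.append((cpg, float(r), float(z), float(p), n))
    return pd.DataFrame(rows, columns=["cpg", "r", "z", "p", "n"])


#: Canonical names for the seven imputed blood-cell covariates of Model III.
BLOOD_CELL_COLUMNS = (
    "cd8_naive",
    "cd8pcd28ncd45ran",
    "plasmablast",
    "cd4t",
    "nk",
    "monocytes",
    "granulocytes",
)


def ewas_cox(
    m: MethylationMatrix,
    time,
    event,
    model: str,
    covariates: pd.DataFrame,
    cell_columns=BLOOD_CELL_COLUMNS,
    mask_z: float = 6.0,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Per-CpG Cox screen of a censored trait under nested adjustment models.

    Model I adjusts for age and sex; Model II additionally for smoking
    pack-years; Model III additionally for seven imputed blood-cell
    composition covariates.  Each CpG column is cleaned of >6-SD extremes
    before its own Cox fit.  Returns a table with columns cpg, loghr, se, p, n.
    """
    required = {"I": ["age", "female"]}
    required["II"] = required["I"] + ["packyrs"]
    required["III"] = required["I"] + list(cell_columns)
    if model not in required:
        raise ValueError(f"model must be one of {sorted(required)}, got {model!r}")
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    missing = [c for c in required[model] if c not in cov.columns]
    if missing:
        raise ValueError(f"Model {model} requires covariate columns: {missing}")
    cov = cov[required[model]]

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    for cpg in sorted(m.cpg_ids):
        x = m.data[cpg].to_numpy(dtype=float)
        try:
            x = mask_extreme_values(x, mask_z)
        except ValueError:
            pass
        df = cov.copy()
        df["cpg"] = x
        df["time"] = time
        df["event"] = event
        df = df.dropna()
        n = len(df)
        if n < min_pairs or df["event"].sum() < 2 or df["cpg"].std() == 0:
            rows.append((cpg, np.nan, np.nan, np.nan, n))
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
            rows.append(
                (
                    cpg,
                    float(cph.params_["cpg"]),
                    float(cph.standard_errors_["cpg"]),
                    float(cph.summary.loc["cpg", "p"]),
                    n,
                )
            )
        except Exception:
            rows.append((cpg, np.nan, np.nan, np.nan, n))
    return pd.DataFrame(rows, columns=["cpg", "loghr", "se", "p", "n"])


# ---------------------------------------------------------------------------
# phenotype utilities
# ---------------------------------------------------------------------------


def comorbidity_index(conditions: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Total number of age-related conditions per sample.

    ``conditions`` holds 0/1 indicator columns (arthritis, cataract, cancer,
    ...); missing indicators are excluded from the sum.  Returns the rowwise
    count and the number of non-missing indicators that contributed.
    """
    df = pd.DataFrame(conditions)
    vals = df.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if not np.all(np.isin(vals[finite], (0.0, 1.0))):
        raise ValueError("condition indicators must be 0/1 or missing")
    count = pd.Series(np.nansum(vals, axis=1).astype(int), index=df.index, name="comorbidity")
    contributing = pd.Series(finite.sum(axis=1), index=df.index, name="n_conditions")
    return count, contributing


def homa_ir(fpi, fpg):
    """HOMA-IR insulin-resistance score: (FPI [mU/l] x FPG [mmol/l]) / 22.5."""
    fpi = np.asarray(fpi, dtype=float)
    fpg = np.asarray(fpg, dtype=float)
    if (fpi < 0).any() or (fpg < 0).any():
        raise ValueError("FPI and FPG must be non-negative")
    out = fpi * fpg / 22.5
    return float(out) if out.ndim == 0 else out


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Optional multiple-testing adjustment (bh or bonferroni) for EWAS tables."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
        out[ok] = multipletests(p[ok], method=key)[1]
    return out
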