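"""Core containers and I/O: methylation matrices, phenotype tables, model files.

A :class:`MethylationMatrix` is an (samples x CpGs) array of beta values in
[0, 1] with unique sample and CpG identifiers; a :class:`PhenotypeTable`
carries per-sample demographics, survival outcome, plasma analytes and
arbitrary covariate columns.  Fitted models (Stage-1 surrogates and Stage-2
mortality clocks) serialize to a small JSON dialect so that trained weights
can be exchanged and re-applied to new cohorts.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("grimclock")

_CPG_PATTERN = re.compile(r"^cg\d+$")

_SEP = {"csv": ",", "tsv": "\t"}


def _infer_dialect(path) -> str:
    return "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """Samples x CpGs beta-value matrix.

    ``data`` is indexed by sample ID with CpG IDs as columns.  Beta values
    must lie in [0, 1]; NaN marks missing measurements.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate CpG ID: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at sample {idx[i]!r}, CpG {cols[j]!r}: "
                f"{values[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.data.shape[1]


#: columns of PhenotypeTable with a fixed meaning; everything else is treated
#: as an analyte / covariate column.
RESERVED_PHENOTYPE_COLUMNS = ("age", "female", "time", "event", "packyrs", "stratum")


@dataclass
class PhenotypeTable:
    """Per-sample phenotype table indexed by sample ID.

    Recognized columns: ``age`` (years, > 0), ``female`` (0/1), ``time``
    (follow-up years, >= 0), ``event`` (0/1 death indicator), ``packyrs``
    (smoking pack-years, >= 0) and ``stratum`` (cohort/race label).  Any other
    column is carried along as an analyte or covariate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        d = self.data
        if "age" in d and (d["age"].dropna() <= 0).any():
            raise ValueError("age must be positive")
        for col in ("female", "event"):
            if col in d:
                vals = d[col].dropna().unique()
                if not set(vals) <= {0, 1}:
                    raise ValueError(f"{col} must be coded 0/1, got {sorted(vals)}")
        if "time" in d and (d["time"].dropna() < 0).any():
            raise ValueError("follow-up time must be non-negative")
        if "time" in d and "event" in d:
            bad = (d["event"] == 1) & ~(d["time"] > 0)
            if bad.any():
                raise ValueError(
                    f"event with non-positive time for sample {idx[bad.to_numpy()][0]!r}"
                )
        if "packyrs" in d and (d["packyrs"].dropna() < 0).any():
            raise ValueError("packyrs must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SurrogateModel:
    """Stage-1 DNAm surrogate of a (possibly log-scale) plasma analyte.

    The prediction is ``intercept + sum(w_cpg * beta) + age_weight * age +
    female_weight * female``.  ``train_mean``/``train_sd`` are the mean and SD
    of the in-sample predictions and define the per-SD scaling used when the
    surrogate enters downstream association models.  ``cpg_means`` optionally
    stores training-set mean betas used to impute missing CpGs at prediction
    time.
    """

    name: str
    cpg_weights: dict[str, float]
    age_weight: float
    female_weight: float
    intercept: float
    log_transformed: bool
    train_mean: float
    train_sd: float
    winsor_lo: float | None = None
    winsor_hi: float | None = None
    cpg_means: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.train_sd > 0:
            raise ValueError("train_sd must be positive")


@dataclass
class ClockModel:
    """Stage-2 mortality clock: Cox coefficients plus year-scale calibration.

    The clock value in years is ``calib_intercept + calib_slope * (X @ beta)``.
    """

    covariate_names: list[str]
    coefficients: dict[str, float]
    calib_intercept: float
    calib_slope: float

    def __post_init__(self) -> None:
        if set(self.covariate_names) != set(self.coefficients):
            raise ValueError("coefficients must cover exactly the covariate names")
        if len(self.covariate_names) != len(set(self.covariate_names)):
            raise ValueError("duplicate covariate name")
        if not self.calib_slope > 0:
            raise ValueError("calib_slope must be positive")


@dataclass
class MetaResult:
    """Pooled association across strata (inverse-variance fixed effect)."""

    estimate: float
    se: float
    z: float
    p: float
    strata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("pooled se must be positive")
        if not (0 < self.p <= 1):
            raise ValueError("p must be in (0, 1]")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def read_methylation(path, dialect: str | None = None) -> MethylationMatrix:
    """Read a samples x CpGs beta matrix from delimited text.

    First column = sample IDs, header row = CpG IDs.  Values outside [0, 1]
    are rejected; empty cells become missing.  A first column that looks like
    CpG identifiers (``cg`` followed by digits) triggers an error suggesting
    the matrix is transposed.
    """
    sep = _SEP[dialect or _infer_dialect(path)]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    first_ids = raw.index[: min(20, len(raw.index))]
    if len(first_ids) and all(_CPG_PATTERN.match(s) for s in first_ids):
        raise ValueError(
            "first column holds CpG IDs; the matrix appears transposed "
            "(expected samples as rows, CpGs as columns)"
        )
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ValueError(f"non-numeric value at row {row!r}, column {col!r}")
        numeric[col] = converted
    return MethylationMatrix(numeric)


def write_methylation(m: MethylationMatrix, path, dialect: str | None = None) -> None:
    sep = _SEP[dialect or _infer_dialect(path)]
    m.data.to_csv(path, sep=sep, index_label="sample_id")


def read_phenotypes(path, dialect: str | None = None) -> PhenotypeTable:
    """Read a phenotype table (first column = sample ID) from delimited text."""
    sep = _SEP[dialect or _infer_dialect(path)]
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotypes(p: PhenotypeTable, path, dialect: str | None = None) -> None:
    sep = _SEP[dialect or _infer_dialect(path)]
    p.data.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# alignment and preprocessing
# ---------------------------------------------------------------------------


def align_samples(
    m: MethylationMatrix, p: PhenotypeTable
) -> tuple[MethylationMatrix, PhenotypeTable]:
    """Restrict both inputs to their shared samples, in matrix order.

    Raises if the intersection is empty; logs how many samples were dropped
    from each side.
    """
    shared = [s for s in m.sample_ids if s in set(p.sample_ids)]
    if not shared:
        raise ValueError("no shared sample IDs between methylation and phenotypes")
    dropped_m = m.n_samples - len(shared)
    dropped_p = len(p.sample_ids) - len(shared)
    if dropped_m or dropped_p:
        logger.info(
            "align_samples: dropped %d methylation and %d phenotype samples",
            dropped_m,
            dropped_p,
        )
    return (
        MethylationMatrix(m.data.loc[shared]),
        PhenotypeTable(p.data.loc[shared]),
    )


def mask_extreme_values(x, z_max: float = 6.0):
    """Set values more than ``z_max`` SDs from the mean to missing.

    Single pass: the mean and SD (n-1 denominator) are computed once over the
    non-missing input; values with ``|x - mean| / sd > z_max`` become NaN.
    If the SD is zero the input is returned unchanged.  Re-running on the
    output with recomputed moments may mask further values; the one-pass
    semantics here are deliberate.
    """
    arr = np.asarray(x, dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mean = arr[finite].mean()
    sd = arr[finite].std(ddof=1)
    if sd == 0:
        return x
    out = arr.copy()
    out[finite & (np.abs(arr - mean) / sd > z_max)] = np.nan
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index, name=x.name)
    return out


# ---------------------------------------------------------------------------
# model JSON dialect
# ---------------------------------------------------------------------------

_SURROGATE_REQUIRED = {
    "name",
    "cpg_weights",
    "age_weight",
    "female_weight",
    "intercept",
    "log_transformed",
    "train_mean",
    "train_sd",
}
_SURROGATE_OPTIONAL = {"winsor_lo", "winsor_hi", "cpg_means"}
_CLOCK_REQUIRED = {"covariate_names", "coefficients", "calib_intercept", "calib_slope"}


def save_model(model: SurrogateModel | ClockModel, path) -> None:
    """Serialize a fitted model to the package's JSON dialect."""
    if isinstance(model, SurrogateModel):
        payload = {
            "model_type": "surrogate",
            "name": model.name,
            "cpg_weights": model.cpg_weights,
            "age_weight": model.age_weight,
            "female_weight": model.female_weight,
            "intercept": model.intercept,
            "log_transformed": model.log_transformed,
            "train_mean": model.train_mean,
            "train_sd": model.train_sd,
            "winsor_lo": model.winsor_lo,
            "winsor_hi": model.winsor_hi,
            "cpg_means": model.cpg_means,
        }
    elif isinstance(model, ClockModel):
        payload = {
            "model_type": "clock",
            "covariate_names": model.covariate_names,
            "coefficients": model.coefficients,
            "calib_intercept": model.calib_intercept,
            "calib_slope": model.calib_slope,
        }
    else:  # pragma: no cover - guarded by type hints
        raise TypeError(f"unsupported model type: {type(model)!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> SurrogateModel | ClockModel:
    """Parse a model file; unknown fields warn, missing required fields error."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    kind = payload.pop("model_type", None)
    if kind == "surrogate":
        required, optional = _SURROGATE_REQUIRED, _SURROGATE_OPTIONAL
        cls = SurrogateModel
    elif kind == "clock":
        required, optional = _CLOCK_REQUIRED, set()
        cls = ClockModel
    else:
        raise ValueError(f"model file {path} lacks a valid 'model_type'")
    missing = required - payload.keys()
    if missing:
        raise ValueError(f"model file {path} missing fields: {sorted(missing)}")
    unknown = payload.keys() - required - optional
    if unknown:
        warnings.warn(f"ignoring unknown model fields: {sorted(unknown)}")
    kwargs = {k: payload[k] for k in payload.keys() & (required | optional)}
    return cls(**kwargs)
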