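"""Two-stage convenience pipeline: surrogates, mortality clock, calibration.

Glue around the stage-1 and stage-2 primitives for the common end-to-end
run: train DNAm surrogates for each analyte, assemble the Stage-2 covariate
table (per-SD-scaled surrogates plus Age and Female), fit the penalized Cox
clock, and calibrate its linear predictor to the scale of chronological age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import MethylationMatrix, PhenotypeTable
from .stage1 import ElasticNetSpec, fit_surrogate, predict_surrogate, scale_surrogate
from .stage2 import (
    Calibration,
    CoxFit,
    calibrate_to_age,
    fit_cox_elastic_net,
    linear_predictor,
    make_clock_model,
)


def run_two_stage(
    m: MethylationMatrix,
    pheno: PhenotypeTable,
    targets: tuple[str, ...] = ("CRP", "A1C"),
    stage1_spec: ElasticNetSpec | None = None,
    stage2_spec: ElasticNetSpec | None = None,
) -> dict:
    """Train surrogates for ``targets``, fit the Cox clock, calibrate to years.

    Returns a dict with the fitted surrogate models, the Stage-2 covariate
    table, the Cox fit, the calibration, the packaged clock model and the
    calibrated per-sample clock values (years).
    """
    stage1_spec = stage1_spec or ElasticNetSpec()
    stage2_spec = stage2_spec or ElasticNetSpec()

    surrogates = {}
    X = pd.DataFrame(index=pheno.data.index)
    for t in targets:
        model = fit_surrogate(m, pheno, t, stage1_spec)
        pred = predict_surrogate(model, m, pheno)
        X[f"DNAmlog{t}"] = scale_surrogate(pred, model)
        surrogates[t] = model
    X["Age"] = pheno.data["age"].to_numpy(dtype=float)
    X["Female"] = pheno.data["female"].to_numpy(dtype=float)

    fit: CoxFit = fit_cox_elastic_net(
        X, pheno.data["time"], pheno.data["event"], stage2_spec
    )
    lp = linear_predictor(fit, X)
    if np.std(lp) == 0:
        raise RuntimeError("Cox fit fully shrunk; cannot calibrate the clock")
    calib: Calibration = calibrate_to_age(lp, pheno.data["age"])
    clock = make_clock_model(fit, calib)
    years = pd.Series(
        calib.intercept + calib.slope * lp, index=pheno.data.index, name="clock_years"
    )
    return {
        "surrogates": surrogates,
        "covariates": X,
        "cox_fit": fit,
        "calibration": calib,
        "clock_model": clock,
        "clock_years": years,
    }
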