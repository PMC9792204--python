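"""Synthetic cohort generator with the statistical structure both clock
stages assume, plus ground truth for recovery tests.

The generator emulates a training cohort of older adults: CpG beta values
that load linearly (on the logit scale) on age and on latent analyte
factors, plasma analytes that are linear in their causal CpGs plus age and
sex with a right-skewed (exponentiated) CRP-like analyte, zero-inflated
smoking pack-years, and a proportional-hazards mortality process driven by
the analytes, age, sex and smoking with a Weibull baseline and independent
uniform censoring.  The default scenario mirrors the scale of the cohort the
flagship clock was trained on: n = 1833, age 66.1 +/- 9.06 years, roughly
13% deaths over follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import MethylationMatrix, PhenotypeTable

#: Default training-scale scenario (sample size, age distribution, death rate).
FHS_LIKE = {
    "n": 1833,
    "p": 1030,
    "age_mean": 66.1,
    "age_sd": 9.06,
    "censor_rate": 0.87,
}


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    causal_cpgs: dict  # analyte -> (list of CpG IDs, weight array)
    cox_beta: dict  # covariate -> log-hazard coefficient
    baseline_shape: float
    baseline_scale: float
    censor_rate: float
    seed: int
    log_scale_analytes: tuple = ()
    lp: np.ndarray | None = None  # true mortality linear predictor
    analyte_signal: dict = field(default_factory=dict)  # analyte -> latent signal

    def __post_init__(self) -> None:
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


DEFAULT_COX_BETA = {
    "logCRP_true": 0.35,
    "logA1C_true": 0.35,
    "age": 0.09,
    "female": -0.3,
    "packyrs": 0.012,
}


def simulate_cohort(
    n: int = 1833,
    p: int = 1030,
    *,
    age_mean: float = 66.1,
    age_sd: float = 9.06,
    n_causal: int = 20,
    signal_r2: float = 0.8,
    censor_rate: float = 0.87,
    baseline_shape: float = 1.5,
    baseline_scale: float = 80.0,
    cox_beta: dict | None = None,
    seed: int = 1,
) -> tuple[MethylationMatrix, PhenotypeTable, SimTruth]:
    """Simulate a cohort of ``n`` samples over ``p`` CpGs with known truth.

    Ages are drawn normal then affinely standardized so the empirical mean
    and SD equal the requested values exactly.  Each of two analytes (a
    right-skewed CRP-like marker in mg/L and an A1C-like percentage) has
    ``n_causal`` causal CpGs whose logits share a latent factor; the analyte
    signal is a linear combination of those CpG betas plus age and sex, with
    Gaussian noise sized so the structural part explains ``signal_r2`` of the
    variance.  Mortality follows a Weibull proportional-hazards model whose
    log hazard is linear in the true (log-scale) analyte signals, age, sex
    and pack-years.  Everything is reproducible from ``seed``.
    """
    if n < 50 or p < 10:
        raise ValueError("need n >= 50 and p >= 10")
    if 2 * n_causal > p:
        raise ValueError("not enough CpGs for the requested causal sets")
    rng = np.random.default_rng(seed)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    cpg_ids = [f"cg{i:08d}" for i in range(p)]

    age = rng.normal(size=n)
    age = (age - age.mean()) / age.std(ddof=1)  # exact empirical standardization
    age_std = age.copy()
    age = age_mean + age_sd * age_std
    female = rng.binomial(1, 0.5, size=n).astype(float)

    analytes = ("CRP", "A1C")
    causal: dict[str, tuple[list[str], np.ndarray]] = {}
    latent = {a: rng.normal(size=n) for a in analytes}

    logits = rng.normal(0.0, 1.2, size=p)[None, :] + np.zeros((n, p))
    age_load = rng.normal(0.0, 0.15, size=p)
    logits += age_std[:, None] * age_load[None, :]
    logits += rng.normal(0.0, 0.3, size=(n, p))

    pos = 0
    for a in analytes:
        idx = np.arange(pos, pos + n_causal)
        pos += n_causal
        load = rng.uniform(0.6, 1.2, size=n_causal) * rng.choice([-1, 1], n_causal)
        logits[:, idx] += latent[a][:, None] * load[None, :]
        causal[a] = ([cpg_ids[j] for j in idx], load)

    if np.mean(np.abs(logits) > 8) > 0.05:
        raise ValueError(
            "effect sizes saturate the beta scale (logits beyond +/-8); "
            "reduce loadings or noise"
        )
    betas = 1.0 / (1.0 + np.exp(-logits))

    # analyte = linear combination of causal CpG betas + age + sex + noise
    signal = {}
    pheno = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    pheno["age"] = age
    pheno["female"] = female
    log_scale = []
    for a in analytes:
        ids, load = causal[a]
        cols = [cpg_ids.index(c) for c in ids]
        w = load / np.abs(load).sum()  # recover the latent factor direction
        s = betas[:, cols] @ w
        s = (s - s.mean()) / s.std(ddof=1)
        core = s + 0.2 * age_std + 0.15 * female
        noise_sd = np.sqrt(core.var(ddof=1) * (1 - signal_r2) / signal_r2)
        y = core + rng.normal(0.0, noise_sd, size=n)
        signal[a] = s
        if a == "CRP":
            pheno["CRP"] = np.exp(0.5 + 1.0 * y)  # right-skewed, mg/L scale
            log_scale.append("CRP")
        else:
            pheno["A1C"] = 5.6 + 0.45 * y  # percent scale
    smoker = rng.binomial(1, 0.5, size=n)
    pheno["packyrs"] = np.round(smoker * rng.gamma(2.0, 10.0, size=n), 1)

    beta_map = dict(cox_beta if cox_beta is not None else DEFAULT_COX_BETA)
    drivers = {
        "logCRP_true": np.log(pheno["CRP"].to_numpy()),
        "logA1C_true": np.log(pheno["A1C"].to_numpy()),
        "age": age,
        "female": female,
        "packyrs": pheno["packyrs"].to_numpy(),
    }
    lp = np.zeros(n)
    for name, b in beta_map.items():
        v = drivers[name]
        lp += b * (v - v.mean()) / v.std(ddof=1)

    truth = SimTruth(
        causal_cpgs=causal,
        cox_beta=beta_map,
        baseline_shape=baseline_shape,
        baseline_scale=baseline_scale,
        censor_rate=censor_rate,
        seed=seed,
        log_scale_analytes=tuple(log_scale),
        lp=lp,
        analyte_signal=signal,
    )
    time, event = simulate_survival(lp, truth, rng=rng)
    pheno["time"] = time
    pheno["event"] = event
    pheno["stratum"] = "sim"

    matrix = MethylationMatrix(
        pd.DataFrame(betas, index=pheno.index, columns=cpg_ids)
    )
    return matrix, PhenotypeTable(pheno), truth


def simulate_survival(
    lp, truth: SimTruth, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from a Weibull proportional-hazards model.

    Event times satisfy ``T = scale * (-log U / exp(lp))^(1/shape)``; an
    independent uniform censoring time ``C = c_max * V`` is tuned by bisection
    on ``c_max`` so the realized event fraction matches ``1 - censor_rate``.
    ``censor_rate = 0`` yields all events.
    """
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictor")
    if truth.censor_rate >= 1:
        raise ValueError("censor_rate must be < 1")
    rng = rng if rng is not None else np.random.default_rng(truth.seed + 1)
    u = rng.uniform(size=len(lp))
    T = truth.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / truth.baseline_shape)
    T = np.maximum(T, 1e-8)
    if truth.censor_rate == 0:
        return T, np.ones(len(lp), dtype=int)

    v = rng.uniform(size=len(lp))
    target = 1.0 - truth.censor_rate
    lo_c, hi_c = 1e-6, float(T.max()) * 10
    for _ in range(200):
        mid = 0.5 * (lo_c + hi_c)
        frac = np.mean(T <= mid * v)
        if frac < target:
            lo_c = mid
        else:
            hi_c = mid
    c = hi_c * v
    event = (T <= c).astype(int)
    time = np.minimum(T, c)
    time = np.maximum(time, 1e-8)
    return time, event
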