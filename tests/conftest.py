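import warnings

import numpy as np
import pytest

import grimclock as gc
from grimclock.pipeline import run_two_stage

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """Modest simulated cohort reused across unit tests (n=300, p=60)."""
    return gc.simulate_cohort(n=300, p=60, n_causal=12, seed=11)


@pytest.fixture(scope="session")
def fhs_like_run():
    """Full two-stage fit on a training-scale cohort with ages at mean 66, SD 9."""
    m, p, truth = gc.simulate_cohort(n=1833, p=200, age_mean=66.0, age_sd=9.0, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_two_stage(
            m,
            p,
            stage1_spec=gc.ElasticNetSpec(seed=11),
            stage2_spec=gc.ElasticNetSpec(seed=12),
        )
    return m, p, truth, result


# ---------------------------------------------------------------------------
# independent oracles (direct textbook formulas, no package code)
# ---------------------------------------------------------------------------


def ols_normal_equations(X, y):
    """Least squares with intercept via the normal equations."""
    A = np.column_stack([np.ones(len(X)), np.asarray(X, float)])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))


def newton_cox_breslow(X, time, event, n_iter=100, tol=1e-12):
    """Unpenalized Cox partial-likelihood Newton-Raphson solver (Breslow ties)."""
    X = np.asarray(X, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        w = np.exp(X @ beta)
        grad = np.zeros_like(beta)
        hess = np.zeros((len(beta), len(beta)))
        for t in np.unique(time[event == 1]):
            D = (time == t) & (event == 1)
            R = time >= t
            s0 = w[R].sum()
            s1 = (w[R, None] * X[R]).sum(axis=0)
            s2 = np.einsum("i,ij,ik->jk", w[R], X[R], X[R])
            xbar = s1 / s0
            grad += X[D].sum(axis=0) - D.sum() * xbar
            hess += D.sum() * (s2 / s0 - np.outer(xbar, xbar))
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def deviance_residuals_direct(time, event, lp):
    """Deviance residuals from first principles: Breslow baseline hazard,
    martingale residuals, then the signed square-root transform."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.exp(np.asarray(lp, float))
    lam0 = np.zeros(len(time))
    for i in range(len(time)):
        total = 0.0
        for t in np.unique(time[event == 1]):
            if t <= time[i]:
                d = np.sum((time == t) & (event == 1))
                total += d / risk[time >= t].sum()
        lam0[i] = total
    mart = event - lam0 * risk
    dev = np.zeros(len(time))
    for i in range(len(time)):
        inner = mart[i]
        if event[i] == 1:
            inner += np.log(1.0 - mart[i])
        dev[i] = np.sign(mart[i]) * np.sqrt(-2.0 * inner)
    return mart, dev


def bicor_direct(x, y, c=9.0):
    """Biweight midcorrelation evaluated term by term."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def uw(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return v - med, w

    dx, wx = uw(x)
    dy, wy = uw(y)
    num = sum(wx[i] * wy[i] * dx[i] * dy[i] for i in range(len(x)))
    den = np.sqrt(
        sum((wx[i] * dx[i]) ** 2 for i in range(len(x)))
        * sum((wy[i] * dy[i]) ** 2 for i in range(len(y)))
    )
    return num / den
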