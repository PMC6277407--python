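"""Risk-score survival analysis for a multigene expression panel.

The per-patient risk score is the linear combination

    risk = Σ_i  β_i · expr_i

with β_i the Cox proportional-hazards regression coefficient of gene i.
Patients are dichotomized at the cohort median risk score (ties go to the
low-risk group) and the two groups are compared with Kaplan–Meier curves
and a log-rank test.

The Cox partial likelihood is maximized in-package with damped Newton
iterations and Breslow handling of tied event times; either one
multivariate fit or per-gene univariate fits can supply the coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank

COX_TOL = 1e-8
COX_MAX_ITER = 100


@dataclass
class CoxFit:
    """Cox proportional-hazards fit result."""

    coefficients: pd.Series
    log_likelihood: float
    converged: bool
    iterations: int
    gradient_norm: float


def _breslow_loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood with gradient and Hessian.

    Patients sorted by descending time; risk sets accumulate as cumulative
    sums, ties at one event time share the same risk-set denominator.
    """
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    n, p = x.shape
    eta = x @ beta
    # guard against overflow in exp for extreme steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        ev = np.flatnonzero(event[i : j + 1]) + i
        d = len(ev)
        if d:
            denom0 = s0[j]
            denom1 = s1[j] / denom0
            loglik += eta[ev].sum() - d * np.log(denom0)
            grad += x[ev].sum(axis=0) - d * denom1
            hess -= d * (s2[j] / denom0 - np.outer(denom1, denom1))
        i = j + 1
    return loglik, grad, hess


def fit_cox(
    cohort: pd.DataFrame,
    gene_cols: list[str],
    time_col: str = "time",
    event_col: str = "event",
    mode: str = "multivariate",
) -> CoxFit:
    """Maximize the Cox partial likelihood (Breslow ties, damped Newton).

    ``mode='multivariate'`` fits one model over all genes;
    ``mode='univariate'`` fits each gene alone and assembles the
    coefficient vector from the per-gene fits (both usages are found in
    risk-score practice).  Convergence: max |score| < 1e-8 within 100
    iterations.  Raises on zero events or collinear covariates.
    """
    if mode == "univariate":
        parts = [
            fit_cox(cohort, [g], time_col, event_col, mode="multivariate")
            for g in gene_cols
        ]
        return CoxFit(
            coefficients=pd.Series(
                [f.coefficients.iloc[0] for f in parts], index=gene_cols
            ),
            log_likelihood=float(sum(f.log_likelihood for f in parts)),
            converged=all(f.converged for f in parts),
            iterations=max(f.iterations for f in parts),
            gradient_norm=max(f.gradient_norm for f in parts),
        )
    if mode != "multivariate":
        raise ValueError(f"unknown mode {mode!r}")

    x = cohort[gene_cols].to_numpy(dtype=float)
    time = cohort[time_col].to_numpy(dtype=float)
    event = cohort[event_col].to_numpy(dtype=int)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    if event.sum() == 0:
        raise ValueError("cohort has no events; Cox fit undefined")
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < x.shape[1]:
        raise ValueError("collinear covariates; Cox fit not identifiable")

    beta = np.zeros(x.shape[1])
    loglik, grad, hess = _breslow_loglik_grad_hess(beta, x, time, event)
    converged = False
    iterations = 0
    for iterations in range(1, COX_MAX_ITER + 1):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < COX_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, -grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular Hessian; covariates degenerate") from exc
        # damped update: halve the step until the likelihood does not drop
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = _breslow_loglik_grad_hess(cand, x, time, event)
            if ll_new >= loglik - 1e-12:
                break
            factor /= 2.0
        beta, loglik, grad, hess = cand, ll_new, g_new, h_new
    gnorm = float(np.max(np.abs(grad)))
    converged = converged or gnorm < COX_TOL
    return CoxFit(
        coefficients=pd.Series(beta, index=gene_cols),
        log_likelihood=float(loglik),
        converged=bool(converged),
        iterations=iterations,
        gradient_norm=gnorm,
    )


def risk_scores(
    cohort: pd.DataFrame, coefficients: pd.Series | dict[str, float]
) -> pd.DataFrame:
    """Per-patient risk score and median-split group.

    risk = Σ coef_i × expression_i; a patient is high-risk iff the score
    strictly exceeds the cohort median (ties at the median → low).
    """
    coefs = pd.Series(coefficients, dtype=float)
    missing = [g for g in coefs.index if g not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks expression columns: {missing}")
    scores = cohort[list(coefs.index)].to_numpy(dtype=float) @ coefs.to_numpy()
    median = float(np.median(scores))
    out = cohort.copy()
    out["risk_score"] = scores
    out["risk_group"] = np.where(scores > median, "high", "low")
    out.attrs["median_risk"] = median
    return out


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate; columns time, survival, at_risk."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no observations")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": table["at_risk"].reindex(surv.index).to_numpy(dtype=float),
        }
    ).reset_index(drop=True)


def logrank_test(
    times_a: np.ndarray,
    events_a: np.ndarray,
    times_b: np.ndarray,
    events_b: np.ndarray,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p).

    With no events in either group the test is undefined and (0, 1) is
    returned by convention.
    """
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be nonempty")
    if int(np.sum(events_a)) + int(np.sum(events_b)) == 0:
        return 0.0, 1.0
    res = _lifelines_logrank(times_a, times_b, events_a, events_b)
    return float(res.test_statistic), float(res.p_value)


def risk_score_analysis(
    cohort: pd.DataFrame,
    gene_cols: list[str],
    time_col: str = "time",
    event_col: str = "event",
    coefficients: pd.Series | dict[str, float] | None = None,
    mode: str = "multivariate",
) -> dict:
    """End-to-end: fit (or take) coefficients, score, split, KM + log-rank."""
    if coefficients is None:
        fit = fit_cox(cohort, gene_cols, time_col, event_col, mode=mode)
        coefficients = fit.coefficients
    else:
        fit = None
        coefficients = pd.Series(coefficients, dtype=float)
    scored = risk_scores(cohort, coefficients)
    high = scored[scored["risk_group"] == "high"]
    low = scored[scored["risk_group"] == "low"]
    chi2, p = logrank_test(
        high[time_col].to_numpy(),
        high[event_col].to_numpy(),
        low[time_col].to_numpy(),
        low[event_col].to_numpy(),
    )
    return {
        "fit": fit,
        "coefficients": coefficients,
        "scored": scored,
        "km_high": kaplan_meier(high[time_col], high[event_col]),
        "km_low": kaplan_meier(low[time_col], low[event_col]),
        "logrank_chi2": chi2,
        "logrank_p": p,
    }
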