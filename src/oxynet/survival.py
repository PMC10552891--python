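"""Kaplan-Meier estimation, log-rank testing, Cox regression and screens.

The Cox model is fitted by Newton-Raphson on the partial likelihood with
the Efron tie correction (Breslow optional). Monotone likelihood (complete
separation) is detected and flagged rather than silently reported as a
finite estimate. Feature-wide screens dichotomize expression (median split,
or any-vs-none when the median is zero), run one log-rank test per feature
and adjust with BH across the screen.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, OxynetError
from .corrnet import bh_adjust
from .preprocess import dichotomize_expression

logger = logging.getLogger("oxynet.survival")


def _check_times(time: np.ndarray, event: np.ndarray) -> None:
    if (time <= 0).any():
        raise OxynetError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise OxynetError("event flags must be 0/1")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimate(time: Sequence[float], event: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct event time with the risk-set size, number
    of events and the survival estimate after that time. Censored times
    reduce the risk set only. S(0) = 1 and S is non-increasing.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise OxynetError("km_estimate needs >=1 sample")
    _check_times(time, event)
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = len(time)
    for t in np.unique(time[event == 1]):
        at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": t, "at_risk": at_risk, "events": d, "survival": s})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

def logrank_test(time: Sequence[float], event: Sequence[int],
                 group: Sequence) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    _check_times(time, event)
    levels = np.unique(group)
    if len(levels) != 2:
        raise OxynetError(f"log-rank test needs exactly 2 groups, got {len(levels)}")
    if event.sum() == 0:
        raise OxynetError("log-rank test needs >=1 event")
    g1 = group == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    """Fitted Cox model for the first covariate of interest."""

    beta: np.ndarray          # all coefficients
    se: np.ndarray
    hr: float                 # exp(beta[0])
    ci_low: float
    ci_high: float
    p: float                  # Wald p for beta[0]
    n: int
    n_events: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta, "se": self.se,
            "HR": np.exp(self.beta),
            "ci_low": np.exp(self.beta - 1.959963984540054 * self.se),
            "ci_high": np.exp(self.beta + 1.959963984540054 * self.se),
        })


def _cox_loglik(beta: np.ndarray, time: np.ndarray, event: np.ndarray,
                X: np.ndarray, ties: str):
    """Partial log-likelihood, score and information (Efron or Breslow)."""
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="mergesort")  # decreasing time
    time_o, event_o, X_o, w_o = time[order], event[order], X[order], w[order]
    p = X.shape[1]
    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    # running risk-set sums over decreasing time
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    n = len(time_o)
    while i < n:
        t = time_o[i]
        j = i
        while j < n and time_o[j] == t:
            s0 += w_o[j]
            s1 += w_o[j] * X_o[j]
            s2 += w_o[j] * np.outer(X_o[j], X_o[j])
            j += 1
        d_idx = [k for k in range(i, j) if event_o[k] == 1]
        d = len(d_idx)
        if d:
            xd = X_o[d_idx]
            wd = w_o[d_idx]
            ll += eta[order][d_idx].sum()
            if ties == "breslow":
                for _ in range(d):
                    ll -= np.log(s0)
                score += xd.sum(axis=0) - d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
            else:  # efron
                wd_sum = wd.sum()
                s1_d = (wd[:, None] * xd).sum(axis=0)
                s2_d = (wd[:, None, None] * np.einsum("ki,kj->kij", xd, xd)).sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s0 - f * wd_sum
                    num1 = s1 - f * s1_d
                    num2 = s2 - f * s2_d
                    ll -= np.log(denom)
                    score -= num1 / denom
                    info += num2 / denom - np.outer(num1, num1) / denom ** 2
                score += xd.sum(axis=0)
        i = j
    return ll, score, info


def cox_fit(time: Sequence[float], event: Sequence[int], covariates,
            ties: str = "efron", max_iter: int = 50,
            tol: float = 1e-8) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``covariates`` is a 1-D array (single covariate) or a samples x p
    array/DataFrame; the reported HR, CI and Wald p refer to the first
    column. Convergence requires max |score| < ``tol``; monotone likelihood
    (diverging coefficients / complete separation) yields
    ``converged=False``, never a silent finite estimate.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(covariates, float)
    if X.ndim == 1:
        X = X[:, None]
    _check_times(time, event)
    if event.sum() == 0:
        raise OxynetError("cox_fit needs >=1 event")
    if np.any(X.std(axis=0) == 0):
        raise OxynetError("constant covariate in Cox model")
    center = X.mean(axis=0)
    Xc = X - center
    p = X.shape[1]
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        ll, score, info = _cox_loglik(beta, time, event, Xc, ties)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving to keep the likelihood finite
        if np.max(np.abs(step)) > 5.0:
            step = step * (5.0 / np.max(np.abs(step)))
        beta = beta + step
        if np.max(np.abs(beta)) > 50:
            logger.warning("Cox fit diverging (|beta|>50): monotone likelihood "
                           "/ complete separation suspected")
            break
    if converged and np.max(np.abs(beta)) > 15:
        # likelihood plateau at an absurd coefficient: monotone likelihood
        logger.warning("Cox fit reached |beta|=%.1f: monotone likelihood / "
                       "complete separation; flagged as non-converged",
                       float(np.max(np.abs(beta))))
        converged = False
    _, _, info = _cox_loglik(beta, time, event, Xc, ties)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    z975 = 1.959963984540054
    wald_p = float(2 * stats.norm.sf(abs(beta[0] / se[0]))) if se[0] > 0 else np.nan
    with np.errstate(over="ignore"):
        hr = float(np.exp(beta[0]))
        ci_low = float(np.exp(beta[0] - z975 * se[0]))
        ci_high = float(np.exp(beta[0] + z975 * se[0]))
    return CoxResult(
        beta=beta, se=se, hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=wald_p, n=len(time), n_events=int(event.sum()),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# feature-wide survival screen
# ---------------------------------------------------------------------------

def screen_features(expression: ExpressionMatrix, clinical: pd.DataFrame,
                    endpoint: str = "OS") -> pd.DataFrame:
    """One log-rank test per feature after expression dichotomization.

    Expression is split high/low by the median (any-vs-none when the median
    is zero); undichotomizable (constant) features are skipped with a
    warning. Unadjusted p and BH q across the screen are both reported.
    """
    if endpoint not in ("OS", "DFS"):
        raise OxynetError(f"endpoint must be OS or DFS, got {endpoint!r}")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns else clinical
    shared = [s for s in expression.sample_ids if s in clin.index]
    sub = clin.loc[shared]
    usable = sub[tcol].notna() & sub[ecol].notna() & (pd.to_numeric(sub[tcol]) > 0)
    ids = sub.index[usable]
    time = pd.to_numeric(sub.loc[ids, tcol]).to_numpy()
    event = sub.loc[ids, ecol].astype(int).to_numpy()
    rows = []
    for fid in expression.feature_ids:
        values = expression.values.loc[fid, ids]
        try:
            labels, mode = dichotomize_expression(values)
            chi2, pval = logrank_test(time, event, labels.to_numpy())
        except OxynetError as exc:
            logger.warning("screen (%s): skipping %s: %s", endpoint, fid, exc)
            continue
        rows.append({"feature": fid, "grouping": mode, "chi2": chi2, "p": pval,
                     "n": len(ids), "n_events": int(event.sum())})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy(), family=f"survival_screen_{endpoint}")
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    logger.info("survival screen (%s): %d features tested, %d samples, %d events",
                endpoint, len(out), len(ids), int(event.sum()))
    return out
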