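"""Two-group survival comparison: Kaplan–Meier, log-rank, Cox.

The Kaplan–Meier product-limit estimator and the standard two-group
log-rank test (hypergeometric variance, chi-square with one degree of
freedom) are delegated to lifelines. The two-group Cox proportional-hazards
fit is implemented here as a one-dimensional Breslow partial likelihood
(binary covariate), with a Wald 95% interval on the log-hazard scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .config import InputError


@dataclass(frozen=True)
class KMCurve:
    """Step-function survival estimate: survival drops at event times,
    censoring only depletes the at-risk count."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    log_partial_likelihood: float
    diverged: bool = False


def _check(records: pd.DataFrame, need_groups: bool = True) -> pd.DataFrame:
    for col in ("time_days", "event"):
        if col not in records.columns:
            raise InputError(f"missing survival column {col!r}")
    if (records["time_days"] <= 0).any():
        raise InputError("survival times must be strictly positive")
    if need_groups:
        levels = records["group"].unique()
        if len(levels) != 2:
            raise InputError(
                f"exactly two group levels required, got {sorted(map(str, levels))}"
            )
    return records


def km_estimate(records: pd.DataFrame, by_group: bool = True):
    """Product-limit estimate, per group (dict) or pooled (single curve)."""
    _check(records, need_groups=by_group)
    if not by_group:
        return _km_single(records)
    return {
        str(g): _km_single(sub)
        for g, sub in records.groupby("group", sort=True)
    }


def _km_single(records: pd.DataFrame) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_days"], records["event"])
    event_times = np.sort(records.loc[records["event"] == 1, "time_days"].unique())
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array(
        [(records["time_days"] >= t).sum() for t in event_times], dtype=int
    )
    return KMCurve(times=event_times.astype(float), survival=surv, at_risk=at_risk)


def logrank_test(records: pd.DataFrame) -> LogRankResult:
    """Standard two-group log-rank chi-square (df=1)."""
    _check(records)
    g0, g1 = sorted(records["group"].unique(), key=str)
    a = records[records["group"] == g0]
    b = records[records["group"] == g1]
    if len(a) == 0 or len(b) == 0:
        raise InputError("one group is empty")
    if int(records["event"].sum()) == 0:
        return LogRankResult(0.0, 1.0, degenerate=True)
    res = _ll_logrank(
        a["time_days"], b["time_days"], a["event"], b["event"]
    )
    stat = float(res.test_statistic)
    return LogRankResult(stat, float(chi2.sf(stat, df=1)))


def _breslow_parts(records: pd.DataFrame, group1=None):
    g0, g1 = sorted(records["group"].unique(), key=str)
    if group1 is not None:
        if group1 not in (g0, g1):
            raise InputError(f"group1={group1!r} is not a group level")
        if group1 == g0:
            g0, g1 = g1, g0
    order = np.argsort(records["time_days"].to_numpy(), kind="mergesort")
    t = records["time_days"].to_numpy()[order]
    e = records["event"].to_numpy()[order].astype(bool)
    x = (records["group"].to_numpy()[order] == g1).astype(float)
    # risk set of subject i = everyone with time >= t_i (ties share risk set)
    first_idx = np.searchsorted(t, t, side="left")
    suffix_all = np.cumsum(np.ones_like(x)[::-1])[::-1]
    suffix_x = np.cumsum(x[::-1])[::-1]
    return t, e, x, first_idx, suffix_all, suffix_x, (g0, g1)


def _breslow_loglik(beta: float, e, x, first_idx, suffix_all, suffix_x) -> float:
    eb = np.exp(beta)
    # S0 over risk set: n0 + n1 * e^beta
    s0 = (suffix_all - suffix_x) + suffix_x * eb
    return float(beta * x[e].sum() - np.log(s0[first_idx[e]]).sum())


def cox_two_group(records: pd.DataFrame, group1=None) -> CoxResult:
    """Maximum Breslow partial-likelihood hazard ratio for a binary group
    covariate, with a Wald 95% CI on the log scale. The level coded 1 is
    ``group1`` when given, else the second level in sorted order. A group
    with no events yields a monotone likelihood; the fit is flagged
    diverged with a one-sided bound."""
    _check(records)
    t, e, x, first_idx, suffix_all, suffix_x, (g0, g1) = _breslow_parts(
        records, group1
    )
    events_g1 = int(e[x == 1].sum())
    events_g0 = int(e[x == 0].sum())
    if events_g0 == 0 or events_g1 == 0:
        hr = 0.0 if events_g1 == 0 else np.inf
        return CoxResult(hr, 0.0, np.inf,
                         _breslow_loglik(0.0, e, x, first_idx, suffix_all, suffix_x),
                         diverged=True)

    res = minimize_scalar(
        lambda b: -_breslow_loglik(b, e, x, first_idx, suffix_all, suffix_x),
        bounds=(-15.0, 15.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    beta = float(res.x)
    if abs(beta) > 14.0:
        # monotone likelihood from time-ordered separation: the maximizer
        # sits at the boundary even though both groups have events
        hr = 0.0 if beta < 0 else np.inf
        return CoxResult(hr, 0.0, np.inf, float(-res.fun), diverged=True)
    # observed information: sum over events of p(1-p), p = share of group-1
    # hazard in the risk set
    eb = np.exp(beta)
    s0 = (suffix_all - suffix_x) + suffix_x * eb
    p = suffix_x[first_idx[e]] * eb / s0[first_idx[e]]
    info = float((p * (1.0 - p)).sum())
    se = np.sqrt(1.0 / info) if info > 0 else np.inf
    zcrit = norm.ppf(0.975)
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        log_partial_likelihood=float(-res.fun),
        diverged=False,
    )


def cox_loglik_grid(records: pd.DataFrame, lo=-5.0, hi=5.0, step=1e-4) -> float:
    """Brute-force grid maximizer of the Breslow log partial likelihood
    over log-HR; an independent oracle for :func:`cox_two_group`."""
    _check(records)
    _, e, x, first_idx, suffix_all, suffix_x, _ = _breslow_parts(records)
    betas = np.arange(lo, hi + step / 2, step)
    lls = np.array(
        [_breslow_loglik(b, e, x, first_idx, suffix_all, suffix_x) for b in betas]
    )
    return float(betas[np.argmax(lls)])
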