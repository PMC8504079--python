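"""Kaplan-Meier estimation and log-rank comparison of classifier calls.

A biomarker call is clinically useful if it separates survival curves.
This module compares the prognostic separation achieved by two *sources*
of calls — e.g. pathologists' consensus calls on one subject set versus
model-predicted calls on a disjoint subject set (the subjects whose
status the pathologists never assigned) — by running one log-rank test
per source, each on its own subjects only.

Estimators are implemented from the standard formulas: the product-limit
survival estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i), and the K-group
log-rank test from observed-vs-expected event counts with hypergeometric
variance, chi-square distributed with K-1 degrees of freedom.  Ties
between events and censorings at the same time follow the usual
convention: subjects censored at t are still at risk for events at t.
No multiple-comparison correction is applied to reported p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLabelsError, DesignError, ValidationError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_estimate",
    "logrank_test",
    "compare_call_sources",
]


@dataclass
class KMCurve:
    """Product-limit curve: survival evaluated at the distinct event times."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray     # n_i at each event time
    n_events: np.ndarray    # d_i at each event time
    n_total: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time ``t``."""
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "survival": self.survival,
            "at_risk": self.at_risk,
            "events": self.n_events,
        })


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    group_sizes: dict | None = None


def _check_times(times: np.ndarray, events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValidationError("times and events must be equal-length vectors")
    if np.any(t < 0):
        raise ValidationError("survival times must be >= 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValidationError("event indicators must be 0 or 1")
    return t, e


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    With no events the curve is identically 1.  Subjects censored exactly
    at an event time count as at risk for that event.
    """
    t, e = _check_times(times, events)
    if t.size == 0:
        raise ValidationError("need at least one record")
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    d_list = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_list.append(d_i)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_list, dtype=int),
        n_total=int(t.size),
    )


def logrank_test(times: np.ndarray, events: np.ndarray,
                 groups: np.ndarray) -> LogRankResult:
    """K-group log-rank test.

    At each distinct event time the observed events per group are
    compared with the expectation under a common hazard; the statistic is
    the quadratic form of the summed (O - E) vector (one group dropped)
    against the summed hypergeometric variance-covariance matrix, which
    for two groups reduces to (sum(O - E))^2 / sum(V).
    """
    t, e = _check_times(times, events)
    grp = np.asarray(groups)
    if grp.shape != t.shape:
        raise ValidationError("groups must align with times")
    if pd.isna(grp).any():
        raise ValidationError("group labels must be non-missing")
    levels, g_idx = np.unique(grp, return_inverse=True)
    k = levels.size
    if k < 2:
        raise DegenerateLabelsError("log-rank needs >= 2 groups")
    if e.sum() == 0:
        raise DegenerateLabelsError("log-rank needs >= 1 event")

    event_times = np.unique(t[e == 1])
    u = np.zeros(k - 1)               # summed O - E, last group dropped
    v = np.zeros((k - 1, k - 1))      # summed covariance
    for et in event_times:
        at_risk = t >= et
        n = int(at_risk.sum())
        d = int(np.sum((t == et) & (e == 1)))
        n_j = np.bincount(g_idx[at_risk], minlength=k).astype(float)
        d_j = np.bincount(g_idx[(t == et) & (e == 1)], minlength=k).astype(float)
        exp_j = d * n_j / n
        u += (d_j - exp_j)[: k - 1]
        if n > 1:
            frac = n_j / n
            scale = d * (n - d) / (n - 1)
            cov = scale * (np.diag(frac) - np.outer(frac, frac))
            v += cov[: k - 1, : k - 1]
    # pseudo-inverse guards the degenerate all-tied case
    chi2 = float(u @ np.linalg.pinv(v) @ u)
    chi2 = max(chi2, 0.0)
    df = k - 1
    sizes = {lv: int(np.sum(grp == lv)) for lv in levels}
    return LogRankResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        group_sizes=sizes,
    )


def compare_call_sources(
    records_ref: pd.DataFrame,
    records_model: pd.DataFrame,
    time_col: str = "survival_days",
    event_col: str = "event",
    group_col: str = "group",
) -> dict[str, LogRankResult]:
    """Paired log-rank tests for reference calls vs model calls.

    ``records_ref`` holds subjects with reference (e.g. pathologist)
    calls, ``records_model`` subjects with model-predicted calls; each
    DataFrame needs time/event/group columns and is indexed by sample id.
    The two subject sets must be disjoint — the comparison is only fair
    when no subject contributes to both tests.
    """
    overlap = records_ref.index.intersection(records_model.index)
    if len(overlap):
        raise DesignError(
            f"subject sets overlap ({len(overlap)} shared ids, e.g. "
            f"{list(overlap[:3])})"
        )
    out = {}
    for name, rec in (("reference", records_ref), ("model", records_model)):
        out[name] = logrank_test(
            rec[time_col].to_numpy(dtype=float),
            rec[event_col].to_numpy(dtype=int),
            rec[group_col].to_numpy(),
        )
    return out
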