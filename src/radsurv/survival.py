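"""Concordance index, Kaplan-Meier estimation, log-rank test, calibration.

The concordance index is computed from the definition
AUC(tau) = P(P_i > P_j | T_i < T_j, T_i < tau): a pair (i, j) is comparable
when the earlier time belongs to an observed event (and precedes tau, when
an observe period is given); the pair is concordant when the earlier
failure carries the higher predicted risk, with tied risks credited 0.5.
With tau = +inf this is Harrell's C.  Kaplan-Meier curves and the
two-sample log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ConcordanceResult",
    "SurvivalCurve",
    "CalibrationPoint",
    "concordance_index",
    "kaplan_meier",
    "logrank_test",
    "calibration_at",
]


@dataclass
class ConcordanceResult:
    c_index: float
    n_comparable: int
    n_concordant: float  # ties counted 0.5
    tau: float  # observe period (inf = Harrell's convention)

    def __float__(self) -> float:
        return self.c_index


def concordance_index(
    risk, time, event, tau: float | None = None
) -> ConcordanceResult:
    """Concordance between predicted risk and observed survival.

    Comparable pairs: time_i < time_j, event_i = 1, and time_i < tau.
    Tied event times are not comparable; tied risks score 0.5.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not (risk.shape == time.shape == event.shape):
        raise ValueError("risk, time, event must have equal length")
    if tau is None:
        tau = math.inf
    earlier = (time[:, None] < time[None, :]) & (event[:, None] == 1)
    earlier &= time[:, None] < tau
    n_comparable = int(earlier.sum())
    if n_comparable == 0:
        raise ValueError("no comparable pairs (no observed events before tau)")
    higher = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    n_concordant = float(higher[earlier].sum()) + 0.5 * float(tied[earlier].sum())
    return ConcordanceResult(
        c_index=n_concordant / n_comparable,
        n_comparable=n_comparable,
        n_concordant=n_concordant,
        tau=tau,
    )


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with risk-set bookkeeping."""

    times: np.ndarray  # distinct observed times, increasing
    survival: np.ndarray  # S(t) at those times, non-increasing
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def last_time(self) -> float:
        return float(self.times[-1])


def kaplan_meier(time, event) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate (via lifelines)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    mask = table.index.to_numpy(float) > 0  # drop the t=0 bookkeeping row
    times = table.index.to_numpy(float)[mask]
    surv = np.array([float(kmf.predict(t)) for t in times])
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(int)[mask],
        events=table["observed"].to_numpy(int)[mask],
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi2, p) with 1 df."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    if len(set(group.tolist())) < 2:
        raise ValueError("log-rank test needs two non-empty groups")
    if event.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    g = group == group.max()
    res = _ll_logrank(time[~g], time[g], event[~g], event[g])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CalibrationPoint:
    horizon: float
    predicted: float  # mean model-predicted survival probability
    observed: float  # Kaplan-Meier estimate at the horizon
    gap: float
    extrapolated: bool = False  # horizon beyond the last observed time


def calibration_at(
    model, term_values, time, event, horizons=(730.0, 1825.0)
) -> list[CalibrationPoint]:
    """Compare mean predicted survival against the Kaplan-Meier estimate at
    fixed horizons (defaults: 2 and 5 years in days).

    ``model`` must carry a baseline-hazard estimate (Breslow); the
    per-case prediction is S_0(t) ** exp(linear predictor).
    """
    X = np.asarray(term_values, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if model.baseline_times is None:
        raise ValueError("model has no baseline-hazard estimate; refit required")
    lp = X @ model.coefficients if X.size else np.zeros(len(time))
    km = kaplan_meier(time, event)
    out = []
    for h in horizons:
        if h <= 0:
            out.append(CalibrationPoint(horizon=h, predicted=1.0, observed=1.0, gap=0.0))
            continue
        extrapolated = h > km.last_time
        observed = km.survival_at(min(h, km.last_time))
        s0 = model.baseline_survival(h)
        predicted = float(np.mean(s0 ** np.exp(lp)))
        out.append(
            CalibrationPoint(
                horizon=h,
                predicted=predicted,
                observed=observed,
                gap=predicted - observed,
                extrapolated=extrapolated,
            )
        )
    return out
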