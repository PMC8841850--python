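"""Feature screening, candidate-set construction, stepwise Cox selection.

The high-dimensional feature panel is reduced in three stages:

1. Univariate concordance screening — each transformed feature is fitted
   alone in a Cox model and ranked by the training C-index of its risk
   score; the top k survive, with the selection extended through every
   feature tied at the boundary C-index value (so a request for 200 can
   return 203 when ranks 199-203 share one value).
2. Candidate-set construction — each screened feature contributes a main
   effect and an interaction with each augmented feature; the two
   augmented features enter as main effects too: 3m + 2 candidates
   (611 for m = 203).
3. Forward-stepwise selection with likelihood-ratio entry/removal tests
   (defaults 0.05 / 0.10), deterministic tie-breaks by candidate order,
   and a step cap guarding against cycling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cox import CoxModel, PredictorTerm, fit_cox, term_design_matrix
from .survival import concordance_index

__all__ = [
    "ScreeningResult",
    "select_top_k",
    "univariate_screen",
    "build_candidate_set",
    "stepwise_select",
]

log = logging.getLogger(__name__)


@dataclass
class ScreeningResult:
    ranked: list[tuple[str, float]]  # (feature, univariate C-index), descending
    selected: list[str]
    k_requested: int
    k_effective: int
    fallback_features: list[str]  # univariate fits that did not converge


def select_top_k(names, scores, k: int) -> list:
    """Top-k by score, extended through all ties at the boundary value.

    Order among distinct scores is descending; ties preserve input order
    (stable sort), and every name sharing the k-th ranked score is
    included, so the effective count can exceed k.
    """
    scores = np.asarray(scores, float)
    names = list(names)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(names) != scores.size:
        raise ValueError("names and scores must have equal length")
    order = np.argsort(-scores, kind="stable")
    if k >= len(names):
        return [names[i] for i in order]
    boundary = scores[order[k - 1]]
    j = k
    while j < len(names) and scores[order[j]] == boundary:
        j += 1
    return [names[i] for i in order[:j]]


def univariate_screen(Z: pd.DataFrame, time, event, k: int) -> ScreeningResult:
    """Rank features by the C-index of their univariate Cox risk score.

    A non-converged univariate fit falls back to the raw transformed
    feature as the risk score for ranking (logged); the ranking itself is
    tie-inclusive at the boundary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    names = [str(c) for c in Z.columns]
    cs = np.empty(len(names))
    fallback: list[str] = []
    for i, name in enumerate(names):
        x = Z[name].to_numpy(float)
        try:
            fit = fit_cox(x[:, None], time, event)
            risk = x * fit.coefficients[0]
            if not fit.converged:
                raise RuntimeError("non-converged")
        except (RuntimeError, np.linalg.LinAlgError):
            fallback.append(name)
            log.warning("univariate Cox fit failed for %s; ranking by raw values", name)
            risk = x
        cs[i] = concordance_index(risk, time, event).c_index
    order = np.argsort(-cs, kind="stable")
    ranked = [(names[i], float(cs[i])) for i in order]
    selected = select_top_k(names, cs, k)
    return ScreeningResult(
        ranked=ranked,
        selected=selected,
        k_requested=k,
        k_effective=len(selected),
        fallback_features=fallback,
    )


def build_candidate_set(
    selected: list[str], include_augmented: bool = True
) -> list[PredictorTerm]:
    """Main effects, z'_1- and z'_2-interactions for each screened feature,
    plus (optionally) the two augmented main effects: 3m + 2 terms."""
    if len(selected) < 1:
        raise ValueError("need at least one screened feature")
    if len(set(selected)) != len(selected):
        raise ValueError("duplicate feature names in screened set")
    terms = [PredictorTerm("main", name) for name in selected]
    terms += [PredictorTerm("interaction", name, "z1") for name in selected]
    terms += [PredictorTerm("interaction", name, "z2") for name in selected]
    if include_augmented:
        terms += [PredictorTerm("main", "z1"), PredictorTerm("main", "z2")]
    return terms


def _safe_fit(M, cols, time, event, ties):
    """Fit on a column subset; None when the fit is unusable for an LR test."""
    try:
        fit = fit_cox(M[:, cols], time, event, ties=ties)
    except (ValueError, np.linalg.LinAlgError):
        return None
    if not fit.converged:
        return None
    return fit


def stepwise_select(
    candidates: list[PredictorTerm],
    Z: pd.DataFrame,
    aug,
    time,
    event,
    p_entry: float = 0.05,
    p_removal: float = 0.10,
    ties: str = "breslow",
) -> CoxModel:
    """Forward-stepwise Cox selection with likelihood-ratio criteria.

    Each step adds the candidate with the smallest LR p-value if it is
    below ``p_entry``, then removes included terms whose LR p-value
    exceeds ``p_removal``, iterating to a fixed point.  Ties in p-value
    break by candidate order; total steps are capped at twice the number
    of candidates.  The empty model is a valid outcome.
    """
    if not candidates:
        raise ValueError("need at least one candidate term")
    if not p_entry < p_removal:
        raise ValueError("p_entry must be smaller than p_removal")
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    M = term_design_matrix(candidates, Z, aug)
    current: list[int] = []
    ll_null = fit_cox(M[:, []], time, event, ties=ties).log_partial_likelihood
    ll_current = ll_null
    steps = 0
    changed = True
    while changed and steps < 2 * len(candidates):
        changed = False
        steps += 1
        # forward
        best_p, best_j, best_fit = np.inf, None, None
        for j in range(len(candidates)):
            if j in current:
                continue
            fit = _safe_fit(M, current + [j], time, event, ties)
            if fit is None:
                continue
            lr = max(0.0, 2.0 * (fit.log_partial_likelihood - ll_current))
            p = chi2.sf(lr, df=1)
            if p < best_p:  # strict: first minimal candidate wins ties
                best_p, best_j, best_fit = p, j, fit
        if best_j is not None and best_p < p_entry:
            current.append(best_j)
            ll_current = best_fit.log_partial_likelihood
            changed = True
        # backward
        while len(current) > 0:
            worst_p, worst_pos = -np.inf, None
            for pos in range(len(current)):
                reduced = current[:pos] + current[pos + 1 :]
                fit = _safe_fit(M, reduced, time, event, ties)
                if fit is None:
                    continue
                lr = max(0.0, 2.0 * (ll_current - fit.log_partial_likelihood))
                p = chi2.sf(lr, df=1)
                if p > worst_p:  # strict: first maximal candidate wins ties
                    worst_p, worst_pos = p, pos
            if worst_pos is not None and worst_p > p_removal:
                del current[worst_pos]
                refit = _safe_fit(M, current, time, event, ties)
                ll_current = (
                    refit.log_partial_likelihood if refit is not None else ll_null
                )
                changed = True
            else:
                break
    chosen = [candidates[j] for j in current]
    final = fit_cox(M[:, current], time, event, terms=chosen, ties=ties)
    return final
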