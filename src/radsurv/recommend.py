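"""Counterfactual adjuvant-therapy recommendation and benefit comparison.

The augmented features z'_1, z'_2 are actionable: with a case's radiomic
features fixed, the log relative hazard y(z'_1, z'_2) is minimized over
the two settings (0, 0) and (1, 1).  Since 0 on the augmented scale
corresponds to adjuvant therapy and 1 to no therapy, y(0, 0) < y(1, 1)
recommends therapy; at a tie the recommendation abstains from treatment
(therapy has toxicity, so indifference favors no therapy).

Benefit is assessed on patients who received no adjuvant therapy and had
no recurrence — therapy was demonstrably unnecessary for them, so a
decision is beneficial when it recommends no therapy.  Two paired decision
sets (model vs reference) are compared by McNemar's test with continuity
correction, chi2 = (|b - c| - 1)^2 / (b + c) on the discordant counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cox import CoxModel
from .io import CohortTable

__all__ = [
    "Recommendation",
    "BenefitComparison",
    "recommend_therapy",
    "define_benefit_group",
    "mcnemar_compare",
]


@dataclass
class Recommendation:
    case_id: str
    y_at_0: float  # risk with z'_1 = z'_2 = 0  (adjuvant therapy)
    y_at_1: float  # risk with z'_1 = z'_2 = 1  (no adjuvant therapy)
    v1: int
    v2: int
    recommend_therapy: int


def recommend_therapy(
    model: CoxModel, features, case_id: str = ""
) -> Recommendation:
    """Evaluate y with both actionable variables at 0 and at 1 and return
    the lower-risk option.

    ``features`` maps radiomic feature names to the case's transformed
    values (a mapping or pandas Series); the augmented factor in every
    interaction (and the augmented main effects) is treated as free.
    """
    if model.terms is None:
        raise ValueError("model carries no term structure; cannot recommend")
    if not any(t.depends_on_augmented for t in model.terms):
        raise ValueError(
            "recommendation undefined: risk is constant in the actionable variables"
        )
    if isinstance(features, pd.Series):
        features = features.to_dict()
    y0 = 0.0
    y1 = 0.0
    for term, b in zip(model.terms, model.coefficients):
        if term.is_augmented_main:
            y1 += b  # augmented variable itself: 0 under therapy, 1 under none
        elif term.kind == "main":
            v = b * _value(features, term.feature_name)
            y0 += v
            y1 += v
        else:
            y1 += b * _value(features, term.feature_name)
    rec = 1 if y0 < y1 else 0  # tie -> no therapy
    v = 0 if rec else 1
    return Recommendation(
        case_id=str(case_id),
        y_at_0=y0,
        y_at_1=y1,
        v1=v,
        v2=v,
        recommend_therapy=rec,
    )


def _value(features, name: str) -> float:
    try:
        v = float(features[name])
    except KeyError as exc:
        raise ValueError(f"missing term value for feature {name!r}") from exc
    if not np.isfinite(v):
        raise ValueError(f"non-finite term value for feature {name!r}")
    return v


def define_benefit_group(cohort: CohortTable) -> tuple[list[str], list[str]]:
    """Cases with no adjuvant therapy and no recurrence (therapy was
    unnecessary).  Returns (benefit_ids, excluded_ids); cases with a
    missing recurrence flag are excluded and reported."""
    f = cohort.frame
    missing = f["recurrence"].isna()
    excluded = [str(i) for i in f.index[missing]]
    keep = f[~missing]
    benefit = keep[(keep["adjuvant_therapy"] == 0) & (keep["recurrence"] == 0)]
    return [str(i) for i in benefit.index], excluded


@dataclass
class BenefitComparison:
    """2x2 model-vs-reference recommendation table with McNemar statistic.

    ``table[i][j]``: i indexes the reference decision (0 = therapy advised,
    1 = no therapy), j the model decision likewise — i.e. rows reference
    yes/no, columns model yes/no.
    """

    table: np.ndarray
    mcnemar_chi2: float
    p: float
    prop_no_model: float
    prop_no_reference: float
    n: int
    correction: bool = True

    def to_dict(self) -> dict:
        return {
            "table": {
                "both_yes": int(self.table[0, 0]),
                "reference_yes_model_no": int(self.table[0, 1]),
                "reference_no_model_yes": int(self.table[1, 0]),
                "both_no": int(self.table[1, 1]),
            },
            "mcnemar_chi2": self.mcnemar_chi2,
            "p": self.p,
            "prop_no_model": self.prop_no_model,
            "prop_no_reference": self.prop_no_reference,
            "n": self.n,
            "continuity_correction": self.correction,
        }


def mcnemar_compare(
    model_rec, reference_rec, correction: bool = True
) -> BenefitComparison:
    """McNemar's paired comparison of two binary decision vectors.

    With continuity correction (default), chi2 = (|b - c| - 1)^2 / (b + c)
    where b = reference-yes/model-no and c = reference-no/model-yes; no
    clamping is applied when |b - c| <= 1.  Also reports each arm's
    "no therapy" proportion.
    """
    m = np.asarray(model_rec, int)
    r = np.asarray(reference_rec, int)
    if m.shape != r.shape:
        raise ValueError("paired decision vectors must have equal length")
    if not (set(m.tolist()) | set(r.tolist())) <= {0, 1}:
        raise ValueError("decisions must be binary 0/1")
    n = m.size
    table = np.zeros((2, 2), dtype=int)
    for ri, mi in zip(r, m):
        table[1 - ri, 1 - mi] += 1  # row 0 = reference yes; col 0 = model yes
    b = int(table[0, 1])
    c = int(table[1, 0])
    if b + c == 0:
        raise ValueError("no discordant pairs; McNemar statistic undefined")
    if correction:
        stat = (abs(b - c) - 1.0) ** 2 / (b + c)
    else:
        stat = (b - c) ** 2 / (b + c)
    p = float(chi2_dist.sf(stat, df=1))
    return BenefitComparison(
        table=table,
        mcnemar_chi2=float(stat),
        p=p,
        prop_no_model=float((m == 0).sum()) / n,
        prop_no_reference=float((r == 0).sum()) / n,
        n=n,
        correction=correction,
    )
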