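"""Augmented adjuvant-therapy features.

Adjuvant therapy perturbs the joint behaviour of radiomic features, so the
association structure of the normalized features differs between the
treated and untreated arms.  For normalized features z_i the association
level between features i and j within a group of n_g cases is the absolute
mean cross-product

    C_g(i, j) = | (1/n_g) sum_h z_i(h) z_j(h) |,

and the two groups' association structures are compared by a two-sample
Kolmogorov-Smirnov test on the off-diagonal entries.  When the structures
differ, two per-case second-order summaries act as proxies for the
likelihood of adjuvant therapy:

    z'_1(h) = ( sum_i z_i(h) )^2        (signed sum squared)
    z'_2(h) = ( sum_i |z_i(h)| )^2      (absolute sum squared)

Both are min-max rescaled to [0, 1] across the cohort, and their geometric
mean G_T = sqrt(z'_1 z'_2) orients the scale: G_T near 0 corresponds to
adjuvant therapy, near 1 to no therapy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationStructure",
    "AugmentedFeatures",
    "association_matrix",
    "compare_association_structures",
    "compute_augmented",
    "gt_therapy_association",
]


@dataclass
class AssociationStructure:
    """Absolute mean cross-product matrix of normalized features for one arm."""

    C: np.ndarray  # p x p, nonnegative, symmetric
    group: str  # "therapy" | "control" (free-text label allowed)
    n_group: int

    def off_diagonal(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries — the sample whose empirical
        CDF represents the arm's association structure."""
        p = self.C.shape[0]
        if p < 2:
            raise ValueError("need p >= 2 features for off-diagonal associations")
        iu = np.triu_indices(p, k=1)
        return self.C[iu]


@dataclass
class AugmentedFeatures:
    """Per-case augmented features, raw and [0, 1]-rescaled."""

    z1_raw: np.ndarray
    z2_raw: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    gt_raw: np.ndarray
    gt: np.ndarray

    def as_frame(self, case_ids=None) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z1_raw": self.z1_raw,
                "z2_raw": self.z2_raw,
                "z1_aug": self.z1,
                "z2_aug": self.z2,
                "gt": self.gt,
            },
            index=case_ids,
        )


def _as_matrix(Z) -> np.ndarray:
    M = Z.to_numpy(dtype=float) if isinstance(Z, pd.DataFrame) else np.asarray(Z, float)
    if M.ndim != 2:
        raise ValueError("expected a 2-d cases x features matrix")
    return M


def association_matrix(Z, mask=None, group: str = "group") -> AssociationStructure:
    """Absolute mean cross-product matrix over the cases selected by ``mask``.

    ``Z`` is the inverse-normal-transformed feature matrix (cases x
    features); ``mask`` a boolean selector (default: all cases).
    """
    M = _as_matrix(Z)
    if mask is None:
        mask = np.ones(M.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sub = M[mask]
    n_g = sub.shape[0]
    if n_g < 2:
        raise ValueError("association matrix needs a group of >= 2 cases")
    C = np.abs(sub.T @ sub / n_g)
    return AssociationStructure(C=C, group=group, n_group=n_g)


def compare_association_structures(
    ct: AssociationStructure, cn: AssociationStructure
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of the two arms' association
    structures (off-diagonal entries as the samples).  Returns (D, p)."""
    if ct.C.shape != cn.C.shape:
        raise ValueError("association matrices have different dimensions")
    a, b = ct.off_diagonal(), cn.off_diagonal()
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def compute_augmented(Z, feature_subset=None) -> AugmentedFeatures:
    """Derive z'_1, z'_2 and G_T from the transformed feature matrix.

    ``feature_subset`` restricts the summed features (an index/column
    selection); by default all m features enter the sums.
    """
    if isinstance(Z, pd.DataFrame) and feature_subset is not None:
        Z = Z[list(feature_subset)]
        M = Z.to_numpy(dtype=float)
    else:
        M = _as_matrix(Z)
        if feature_subset is not None:
            M = M[:, list(feature_subset)]
    if M.shape[0] < 2:
        raise ValueError("augmented features need n >= 2 cases (rescaling degenerate)")
    if M.shape[1] < 1:
        raise ValueError("need m >= 1 features")
    s = M.sum(axis=1)
    a = np.abs(M).sum(axis=1)
    z1_raw = s**2
    z2_raw = a**2
    z1 = _minmax(z1_raw, "z'_1")
    z2 = _minmax(z2_raw, "z'_2")
    return AugmentedFeatures(
        z1_raw=z1_raw,
        z2_raw=z2_raw,
        z1=z1,
        z2=z2,
        gt_raw=np.sqrt(z1_raw * z2_raw),
        gt=np.sqrt(z1 * z2),
    )


def _minmax(x: np.ndarray, label: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError(f"{label} is constant across cases; rescaling degenerate")
    return (x - lo) / (hi - lo)


def gt_therapy_association(
    gt: np.ndarray, therapy: np.ndarray, correction: bool = False
) -> tuple[float, float, float, float]:
    """Association of median-dichotomized G_T with the adjuvant-therapy flag.

    Returns (chi2, chi2_p, rho, rho_p): Pearson chi-square on the 2x2 table
    of high/low G_T x therapy (no Yates correction by default) and Spearman
    correlation between the dichotomized G_T and therapy with two-sided p.
    Values strictly above the median count as high; ties at the median go
    low.
    """
    gt = np.asarray(gt, float)
    therapy = np.asarray(therapy, int)
    if gt.shape != therapy.shape:
        raise ValueError("gt and therapy must have equal length")
    if gt.size < 4:
        raise ValueError("need n >= 4 cases")
    if len(set(therapy.tolist())) < 2:
        raise ValueError("both therapy groups must be present")
    if np.ptp(gt) == 0:
        raise ValueError("all G_T values equal; median split undefined")
    high = (gt > np.median(gt)).astype(int)
    table = np.zeros((2, 2), dtype=int)
    for h, t in zip(high, therapy):
        table[h, t] += 1
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=correction)
    rho, rho_p = stats.spearmanr(high, therapy)
    return float(chi2), float(chi2_p), float(rho), float(rho_p)
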