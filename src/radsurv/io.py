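"""Feature-table and cohort-table containers and CSV I/O.

Interchange dialect: comma-separated UTF-8 with '.' decimal; the first
column is ``case_id``.  The feature table carries one named column per
radiomic feature; the cohort table carries overall-survival days, the
death-event flag, the adjuvant-therapy flag, and optionally a recurrence
flag and a reference recommendation (e.g. a decision-support system's
advice), with empty cells meaning missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_feature_catalog
from .transform import BLOM_OFFSET, inverse_normal_transform

__all__ = [
    "FeatureMatrix",
    "CohortTable",
    "load_feature_table",
    "load_cohort_table",
    "write_feature_table",
    "write_cohort_table",
]

COHORT_REQUIRED = ("os_days", "event", "adjuvant_therapy")
COHORT_OPTIONAL = ("recurrence", "reference_recommendation")


@dataclass
class FeatureMatrix:
    """Cases x features values with an optional catalog and a cached
    inverse-normal-transformed view."""

    frame: pd.DataFrame
    catalog: FeatureCatalog | None = None
    transformed: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.frame.shape[0] < 2 or self.frame.shape[1] < 1:
            raise ValueError("feature matrix needs n >= 2 cases and p >= 1 features")
        if self.frame.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicate case_ids: {dups}")

    @property
    def case_ids(self) -> list[str]:
        return [str(c) for c in self.frame.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self.frame.columns]

    @property
    def n_cases(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def transform(self, offset: float = BLOM_OFFSET) -> pd.DataFrame:
        """Apply the rank-based inverse normal transform column-wise and
        cache the result.  Constant columns are an error: the transform is
        undefined for them and the caller must drop the feature."""
        constant = [c for c in self.frame.columns if self.frame[c].nunique() == 1]
        if constant:
            raise ValueError(f"constant feature columns (drop before transform): {constant}")
        z = self.frame.apply(
            lambda col: inverse_normal_transform(col.to_numpy(float), offset=offset),
            axis=0,
        )
        self.transformed = z
        return z


@dataclass
class CohortTable:
    """Per-case survival outcome and therapy context, indexed by case_id.

    Columns: ``os_days`` (> 0), ``event`` (1 = death observed),
    ``adjuvant_therapy`` (1 = received), ``recurrence`` and
    ``reference_recommendation`` (nullable 0/1).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        for col in COHORT_REQUIRED:
            if col not in f.columns:
                raise ValueError(f"cohort table missing required column {col!r}")
            if f[col].isna().any():
                raise ValueError(f"cohort column {col!r} contains missing values")
        for col in COHORT_OPTIONAL:
            if col not in f.columns:
                f[col] = pd.array([pd.NA] * len(f), dtype="Int64")
        if f.index.duplicated().any():
            raise ValueError("duplicate case_ids in cohort table")
        if (f["os_days"] <= 0).any():
            bad = f.index[f["os_days"] <= 0].tolist()
            raise ValueError(f"os_days must be > 0; offending cases: {bad}")
        for col in ("event", "adjuvant_therapy"):
            vals = set(f[col].unique())
            if not vals <= {0, 1}:
                raise ValueError(f"column {col!r} must be binary, found {sorted(vals)}")
        for col in COHORT_OPTIONAL:
            vals = set(f[col].dropna().unique())
            if not vals <= {0, 1}:
                raise ValueError(f"column {col!r} must be binary, found {sorted(vals)}")

    @property
    def case_ids(self) -> list[str]:
        return [str(c) for c in self.frame.index]

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def os_days(self) -> np.ndarray:
        return self.frame["os_days"].to_numpy(float)

    @property
    def event(self) -> np.ndarray:
        return self.frame["event"].to_numpy(int)

    @property
    def adjuvant_therapy(self) -> np.ndarray:
        return self.frame["adjuvant_therapy"].to_numpy(int)

    @property
    def n_therapy(self) -> int:
        return int(self.frame["adjuvant_therapy"].sum())

    @property
    def n_control(self) -> int:
        return self.n - self.n_therapy

    def aligned_with(self, features: FeatureMatrix) -> None:
        if self.case_ids != features.case_ids:
            raise ValueError("cohort and feature tables list different case_ids")


def load_feature_table(
    path: str | Path,
    catalog_mode: str = "generic",
    catalog: FeatureCatalog | None = None,
) -> FeatureMatrix:
    """Read a feature CSV (first column case_id, numeric body).

    ``catalog_mode='strict_851'`` validates the header against the standard
    851-feature catalog and orders columns canonically; ``'generic'``
    accepts any column set.
    """
    if catalog_mode not in ("strict_851", "generic"):
        raise ValueError(f"unknown catalog_mode {catalog_mode!r}")
    raw = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if raw.shape[1] < 2:
        raise ValueError("feature CSV needs a case_id column plus >= 1 feature")
    raw = raw.set_index(raw.columns[0])
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].tolist()
        raise ValueError(f"duplicate case_ids: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        rows, cols = np.where(numeric.isna().to_numpy())
        cells = [
            f"(case {numeric.index[r]}, column {numeric.columns[c]})"
            for r, c in zip(rows, cols)
        ]
        raise ValueError(f"missing or non-numeric cells: {', '.join(cells)}")
    cat = None
    if catalog_mode == "strict_851":
        cat = catalog or build_feature_catalog()
        unknown = [c for c in numeric.columns if c not in cat]
        if unknown:
            raise ValueError(f"columns not in the 851-feature catalog: {unknown}")
        missing = [n for n in cat.names if n not in numeric.columns]
        if missing:
            raise ValueError(
                f"strict_851 requires all catalog features; missing {len(missing)} "
                f"starting with {missing[:5]}"
            )
        numeric = numeric[cat.names]
    return FeatureMatrix(frame=numeric, catalog=cat)


def write_feature_table(features: FeatureMatrix, path: str | Path) -> None:
    # %.17g guarantees binary round-trip of float64 through the CSV
    features.frame.to_csv(path, index_label="case_id", float_format="%.17g")


def load_cohort_table(path: str | Path) -> CohortTable:
    raw = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    raw = raw.set_index(raw.columns[0])
    frame = pd.DataFrame(index=raw.index)
    frame["os_days"] = pd.to_numeric(raw.get("os_days"), errors="raise")
    for col in ("event", "adjuvant_therapy"):
        frame[col] = pd.to_numeric(raw.get(col), errors="raise").astype(int)
    for col in COHORT_OPTIONAL:
        if col in raw.columns:
            frame[col] = pd.to_numeric(raw[col], errors="raise").astype("Int64")
        else:
            frame[col] = pd.array([pd.NA] * len(raw), dtype="Int64")
    return CohortTable(frame=frame)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(path, index_label="case_id", float_format="%.17g")
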