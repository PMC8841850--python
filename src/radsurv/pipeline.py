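"""End-to-end pipeline: transform -> augmented features -> screening ->
stepwise Cox -> permutation null -> stratification -> calibration ->
recommendations -> benefit comparison, with a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augmented import association_matrix, compare_association_structures, compute_augmented, gt_therapy_association
from .cox import fit_cox, stratify_by_median, term_design_matrix
from .io import (
    CohortTable,
    FeatureMatrix,
    load_cohort_table,
    load_feature_table,
    write_cohort_table,
    write_feature_table,
)
from .permutation import simulate_null
from .recommend import define_benefit_group, mcnemar_compare, recommend_therapy
from .selection import build_candidate_set, stepwise_select, univariate_screen
from .simulate import SimConfig, generate_cohort
from .survival import calibration_at, concordance_index, kaplan_meier, logrank_test
from .transform import BLOM_OFFSET

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs stay on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run settings; defaults mirror the published analysis (screen 203,
    entry/removal 0.05/0.10, 1000 permutations, 2- and 5-year horizons)."""

    features_path: str | None = None
    cohort_path: str | None = None
    test_features_path: str | None = None
    test_cohort_path: str | None = None
    sim: SimConfig | None = None
    catalog_mode: str = "generic"
    k_screen: int = 203
    p_entry: float = 0.05
    p_removal: float = 0.10
    n_permutations: int = 1000
    horizons: tuple = (730.0, 1825.0)
    tau: float | None = None
    ties: str = "breslow"
    rank_offset: float = BLOM_OFFSET
    seed: int = 0
    output_dir: str = "radsurv_run"

    def __post_init__(self):
        has_paths = self.features_path is not None and self.cohort_path is not None
        if not has_paths and self.sim is None:
            raise ValueError(
                "config must provide feature/cohort CSV paths or a sim block"
            )
        if has_paths and self.sim is not None:
            raise ValueError("provide either input paths or a sim block, not both")
        if not 0 < self.p_entry < self.p_removal:
            raise ValueError("require 0 < p_entry < p_removal")
        if self.k_screen < 1 or self.n_permutations < 1:
            raise ValueError("k_screen and n_permutations must be >= 1")
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "horizons" in raw:
            raw["horizons"] = tuple(float(h) for h in raw["horizons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "features_path": self.features_path,
            "cohort_path": self.cohort_path,
            "test_features_path": self.test_features_path,
            "test_cohort_path": self.test_cohort_path,
            "sim": self.sim.to_dict() if self.sim is not None else None,
            "catalog_mode": self.catalog_mode,
            "k_screen": self.k_screen,
            "p_entry": self.p_entry,
            "p_removal": self.p_removal,
            "n_permutations": self.n_permutations,
            "horizons": list(self.horizons),
            "tau": self.tau,
            "ties": self.ties,
            "rank_offset": self.rank_offset,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return d


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_coerce))


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing per-stage CSV/JSON outputs plus a
    manifest that records parameters, versions, seed and timings."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "library_versions": _versions(),
        "config": config.to_dict(),
        "decisions": {
            "rank_offset": config.rank_offset,
            "tie_handling": config.ties,
            "tau": config.tau,
            "median_split": "strictly above median = high; ties go low",
            "mcnemar_continuity_correction": True,
            "empirical_p": "add-one smoothing",
        },
        "stages": {},
        "notes": [],
    }
    state: dict = {}
    stages = [
        ("input", _stage_input),
        ("transform", _stage_transform),
        ("augmented", _stage_augmented),
        ("screening", _stage_screening),
        ("model", _stage_model),
        ("concordance", _stage_concordance),
        ("permutation", _stage_permutation),
        ("stratification", _stage_stratification),
        ("calibration", _stage_calibration),
        ("recommendation", _stage_recommendation),
        ("benefit", _stage_benefit),
    ]
    try:
        for name, fn in stages:
            t0 = _time.perf_counter()
            log.info("stage %s: start", name)
            try:
                fn(config, state, out, manifest)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(_time.perf_counter() - t0, 3),
            }
    finally:
        _json_dump(manifest, out / "manifest.json")
    return out


def _versions() -> dict:
    import lifelines
    import scipy

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "lifelines": lifelines.__version__,
    }


def _stage_input(config, state, out, manifest):
    if config.sim is not None:
        features, cohort, aug = generate_cohort(config.sim)
        state["aug"] = aug
        write_feature_table(features, out / "features.csv")
        write_cohort_table(cohort, out / "cohort.csv")
    else:
        features = load_feature_table(config.features_path, catalog_mode=config.catalog_mode)
        cohort = load_cohort_table(config.cohort_path)
        cohort.aligned_with(features)
    state["features"], state["cohort"] = features, cohort


def _stage_transform(config, state, out, manifest):
    features: FeatureMatrix = state["features"]
    if features.transformed is None:
        features.transform(offset=config.rank_offset)
    state["Z"] = features.transformed


def _stage_augmented(config, state, out, manifest):
    Z = state["Z"]
    cohort: CohortTable = state["cohort"]
    aug = state.get("aug") or compute_augmented(Z)
    state["aug"] = aug
    aug.as_frame(cohort.case_ids).to_csv(out / "augmented.csv", index_label="case_id")
    therapy = cohort.adjuvant_therapy
    report: dict = {}
    if therapy.sum() >= 2 and (len(therapy) - therapy.sum()) >= 2:
        ct = association_matrix(Z, therapy == 1, group="therapy")
        cn = association_matrix(Z, therapy == 0, group="control")
        D, p = compare_association_structures(ct, cn)
        report["ks"] = {"D": D, "p": p, "n_therapy": ct.n_group, "n_control": cn.n_group}
    else:
        manifest["notes"].append("association comparison skipped: an arm has < 2 cases")
    try:
        chi2, chi2_p, rho, rho_p = gt_therapy_association(aug.gt, therapy)
        report["gt_therapy"] = {
            "chi2": chi2,
            "chi2_p": chi2_p,
            "spearman_rho": rho,
            "spearman_p": rho_p,
        }
    except ValueError as exc:
        manifest["notes"].append(f"G_T association test skipped: {exc}")
    _json_dump(report, out / "association.json")


def _stage_screening(config, state, out, manifest):
    cohort: CohortTable = state["cohort"]
    screening = univariate_screen(state["Z"], cohort.os_days, cohort.event, k=config.k_screen)
    state["screening"] = screening
    selected = set(screening.selected)
    pd.DataFrame(
        [
            {"feature": name, "c_index": c, "selected": int(name in selected)}
            for name, c in screening.ranked
        ]
    ).to_csv(out / "screening.csv", index=False)
    manifest["stages"].setdefault("screening_detail", {})
    manifest["stages"]["screening_detail"] = {
        "k_requested": screening.k_requested,
        "k_effective": screening.k_effective,
        "n_fallback": len(screening.fallback_features),
    }


def _stage_model(config, state, out, manifest):
    cohort: CohortTable = state["cohort"]
    candidates = build_candidate_set(state["screening"].selected)
    state["candidates"] = candidates
    model = stepwise_select(
        candidates,
        state["Z"],
        state["aug"],
        cohort.os_days,
        cohort.event,
        p_entry=config.p_entry,
        p_removal=config.p_removal,
        ties=config.ties,
    )
    state["model"] = model
    model.to_json(out / "model.json")
    if model.k == 0:
        manifest["notes"].append(
            "stepwise selection returned the empty model; risk-dependent stages degrade"
        )


def _stage_concordance(config, state, out, manifest):
    cohort: CohortTable = state["cohort"]
    model = state["model"]
    M = term_design_matrix(model.terms, state["Z"], state["aug"])
    risks = model.linear_predictor(M)
    state["risks"] = risks
    report = {"n_terms": model.k, "converged": model.converged}
    if model.k > 0:
        report["train_c_index"] = concordance_index(
            risks, cohort.os_days, cohort.event, tau=config.tau
        ).c_index
    if config.test_features_path and config.test_cohort_path and model.k > 0:
        tf = load_feature_table(config.test_features_path, catalog_mode=config.catalog_mode)
        tc = load_cohort_table(config.test_cohort_path)
        tc.aligned_with(tf)
        Zt = tf.transform(offset=config.rank_offset)
        aug_t = compute_augmented(Zt)
        Mt = term_design_matrix(model.terms, Zt, aug_t)
        report["test_c_index"] = concordance_index(
            model.linear_predictor(Mt), tc.os_days, tc.event, tau=config.tau
        ).c_index
    _json_dump(report, out / "cindex.json")


def _stage_permutation(config, state, out, manifest):
    model = state["model"]
    if model.k == 0:
        manifest["notes"].append("permutation null skipped: empty model")
        return
    cohort: CohortTable = state["cohort"]
    null = simulate_null(
        model.terms,
        state["Z"],
        state["aug"],
        cohort.os_days,
        cohort.event,
        R=config.n_permutations,
        seed=config.seed,
        ties=config.ties,
    )
    pd.DataFrame({"c_index": null.c_indices}).to_csv(
        out / "null_distribution.csv", index=False
    )
    _json_dump(null.summary(), out / "null_summary.json")


def _stage_stratification(config, state, out, manifest):
    model = state["model"]
    if model.k == 0:
        manifest["notes"].append("risk stratification skipped: empty model")
        return
    cohort: CohortTable = state["cohort"]
    groups = stratify_by_median(state["risks"])
    chi2, p = logrank_test(cohort.os_days, cohort.event, groups)
    _json_dump(
        {
            "logrank_chi2": chi2,
            "logrank_p": p,
            "n_high": int(groups.sum()),
            "n_low": int((1 - groups).sum()),
        },
        out / "stratification.json",
    )
    curves = []
    for label, mask in (("high", groups == 1), ("low", groups == 0)):
        km = kaplan_meier(cohort.os_days[mask], cohort.event[mask])
        curves.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": km.times,
                    "survival": km.survival,
                    "at_risk": km.at_risk,
                    "events": km.events,
                }
            )
        )
    pd.concat(curves).to_csv(out / "km_curves.csv", index=False)


def _stage_calibration(config, state, out, manifest):
    model = state["model"]
    if model.k == 0:
        manifest["notes"].append("calibration skipped: empty model")
        return
    cohort: CohortTable = state["cohort"]
    M = term_design_matrix(model.terms, state["Z"], state["aug"])
    points = calibration_at(model, M, cohort.os_days, cohort.event, horizons=config.horizons)
    pd.DataFrame(
        [
            {
                "horizon_days": pt.horizon,
                "predicted_mean_survival": pt.predicted,
                "km_observed": pt.observed,
                "gap": pt.gap,
                "extrapolated": pt.extrapolated,
            }
            for pt in points
        ]
    ).to_csv(out / "calibration.csv", index=False)


def _stage_recommendation(config, state, out, manifest):
    model = state["model"]
    cohort: CohortTable = state["cohort"]
    if model.k == 0 or not any(t.depends_on_augmented for t in model.terms):
        manifest["notes"].append(
            "recommendation skipped: risk is constant in the actionable variables"
        )
        state["recommendations"] = None
        return
    Z = state["Z"]
    rows = []
    for case_id in cohort.case_ids:
        rec = recommend_therapy(model, Z.loc[case_id], case_id=case_id)
        rows.append(
            {
                "case_id": rec.case_id,
                "y_at_0": rec.y_at_0,
                "y_at_1": rec.y_at_1,
                "recommend_therapy": rec.recommend_therapy,
            }
        )
    recs = pd.DataFrame(rows).set_index("case_id")
    recs.to_csv(out / "recommendations.csv", index_label="case_id")
    state["recommendations"] = recs


def _stage_benefit(config, state, out, manifest):
    recs = state.get("recommendations")
    cohort: CohortTable = state["cohort"]
    if recs is None:
        manifest["notes"].append("benefit comparison skipped: no recommendations")
        return
    ref = cohort.frame["reference_recommendation"]
    if ref.isna().all():
        manifest["notes"].append("benefit comparison skipped: no reference decisions")
        return
    benefit_ids, excluded = define_benefit_group(cohort)
    usable = [i for i in benefit_ids if not pd.isna(ref.loc[i])]
    report: dict = {
        "benefit_group_size": len(benefit_ids),
        "excluded_missing_recurrence": excluded,
        "n_compared": len(usable),
        "beneficial_decision": "recommend no therapy for a benefit-group case",
    }
    if len(usable) >= 2:
        try:
            cmp_res = mcnemar_compare(
                recs.loc[usable, "recommend_therapy"].to_numpy(int),
                ref.loc[usable].to_numpy(int),
            )
            report["comparison"] = cmp_res.to_dict()
        except ValueError as exc:
            report["comparison_error"] = str(exc)
    _json_dump(report, out / "benefit_comparison.json")
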