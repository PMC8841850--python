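"""Cox proportional-hazards core.

Predictor terms are either plain radiomic main effects, augmented-feature
main effects (z'_1 or z'_2 themselves), or interactions of an augmented
feature with a radiomic feature.  The model's risk score is the log
relative hazard y = sum_k B_k x_k = log h(t)/h_0(t).

The partial likelihood is maximized by Newton-Raphson with step-halving,
Breslow handling of tied event times by default (Efron available), and the
Breslow estimator for the baseline cumulative hazard.  Convergence is
declared when the largest score component falls below 1e-8; a coefficient
escaping beyond |B| > 20 marks a monotone-likelihood fit as non-converged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PredictorTerm",
    "CoxModel",
    "fit_cox",
    "risk_score",
    "term_design_matrix",
    "stratify_by_median",
    "load_published_model",
]

AUGMENTED_NAMES = ("z1", "z2")


@dataclass(frozen=True)
class PredictorTerm:
    """A model term: main effect or augmented-feature interaction."""

    kind: str  # "main" | "interaction"
    feature_name: str
    augmented_factor: str = "none"  # none | z1 | z2 (interactions only)

    def __post_init__(self):
        if self.kind not in ("main", "interaction"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if (self.kind == "interaction") != (self.augmented_factor != "none"):
            raise ValueError("kind is 'interaction' iff augmented_factor is set")
        if self.augmented_factor not in ("none",) + AUGMENTED_NAMES:
            raise ValueError(f"unknown augmented factor {self.augmented_factor!r}")
        if self.kind == "main" and self.feature_name in AUGMENTED_NAMES:
            # pure augmented main effect: z'_1 or z'_2 entered directly
            pass

    @property
    def is_augmented_main(self) -> bool:
        return self.kind == "main" and self.feature_name in AUGMENTED_NAMES

    @property
    def depends_on_augmented(self) -> bool:
        """True when the term value changes with the actionable variables."""
        return self.kind == "interaction" or self.is_augmented_main

    @property
    def augmented_variable(self) -> str:
        """Which actionable variable the term involves ('none' if neither)."""
        if self.kind == "interaction":
            return self.augmented_factor
        if self.is_augmented_main:
            return self.feature_name
        return "none"

    def label(self) -> str:
        if self.kind == "interaction":
            return f"{self.augmented_factor} x {self.feature_name}"
        return self.feature_name

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_name": self.feature_name,
            "augmented_factor": self.augmented_factor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictorTerm":
        return cls(
            kind=d["kind"],
            feature_name=d["feature_name"],
            augmented_factor=d.get("augmented_factor", "none"),
        )


def term_design_matrix(terms, Z, aug) -> np.ndarray:
    """Evaluate terms on a cohort: columns of the Cox design matrix.

    ``Z`` is the transformed feature DataFrame (columns by feature name),
    ``aug`` the cohort's AugmentedFeatures (rescaled z'_1, z'_2 used).
    """
    n = len(Z)
    cols = []
    for t in terms:
        if t.is_augmented_main:
            cols.append(aug.z1 if t.feature_name == "z1" else aug.z2)
        elif t.kind == "main":
            cols.append(Z[t.feature_name].to_numpy(float))
        else:
            z = aug.z1 if t.augmented_factor == "z1" else aug.z2
            cols.append(z * Z[t.feature_name].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((n, 0))


@dataclass
class CoxModel:
    """Fitted (or published) Cox model with optional baseline hazard."""

    terms: list[PredictorTerm] | None
    coefficients: np.ndarray
    log_partial_likelihood: float = float("nan")
    baseline_times: np.ndarray | None = None
    baseline_cumhaz: np.ndarray | None = None
    n_fit: int = 0
    converged: bool = True
    ties: str = "breslow"
    messages: tuple = ()
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float)
        if self.terms is not None and len(self.terms) != len(self.coefficients):
            raise ValueError("number of terms and coefficients differ")

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def baseline_survival(self, t: float) -> float:
        """Breslow baseline survival S_0(t) = exp(-H_0(t))."""
        if self.baseline_times is None:
            raise ValueError("model has no baseline-hazard estimate")
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        H = 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])
        return float(np.exp(-H))

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        return X @ self.coefficients if self.k else np.zeros(X.shape[0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": [t.to_dict() for t in self.terms] if self.terms is not None else None,
            "coefficients": self.coefficients.tolist(),
            "log_partial_likelihood": self.log_partial_likelihood,
            "baseline": None
            if self.baseline_times is None
            else {
                "times": self.baseline_times.tolist(),
                "cumulative_hazard": self.baseline_cumhaz.tolist(),
            },
            "n_fit": self.n_fit,
            "converged": self.converged,
            "ties": self.ties,
            "messages": list(self.messages),
            "notes": self.notes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CoxModel":
        payload = json.loads(Path(path).read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "CoxModel":
        baseline = payload.get("baseline")
        return cls(
            terms=None
            if payload.get("terms") is None
            else [PredictorTerm.from_dict(d) for d in payload["terms"]],
            coefficients=np.asarray(payload["coefficients"], float),
            log_partial_likelihood=payload.get("log_partial_likelihood", float("nan")),
            baseline_times=None if baseline is None else np.asarray(baseline["times"], float),
            baseline_cumhaz=None
            if baseline is None
            else np.asarray(baseline["cumulative_hazard"], float),
            n_fit=payload.get("n_fit", 0),
            converged=payload.get("converged", True),
            ties=payload.get("ties", "breslow"),
            messages=tuple(payload.get("messages", ())),
            notes=payload.get("notes", {}),
        )


def risk_score(model: CoxModel, values) -> float:
    """Linear predictor y = sum_k B_k x_k for one case (no centering)."""
    x = np.asarray(values, float)
    if x.shape != (model.k,):
        raise ValueError(f"expected {model.k} term values, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing or non-finite term value")
    return float(x @ model.coefficients)


def stratify_by_median(risks) -> np.ndarray:
    """Median split of risk scores: 1 = high risk (> median), ties go low."""
    r = np.asarray(risks, float)
    if r.size < 2:
        raise ValueError("need n >= 2 risk scores")
    if np.ptp(r) == 0:
        raise ValueError("all risk scores equal; median split undefined")
    return (r > np.median(r)).astype(int)


# ---------------------------------------------------------------------------
# Partial-likelihood machinery


class _PartialLikelihood:
    """Sorted-data workspace for Cox partial-likelihood derivatives."""

    def __init__(self, X, time, event, ties="breslow"):
        X = np.asarray(X, float)
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        if X.ndim != 2 or X.shape[0] != time.size or time.size != event.size:
            raise ValueError("shape mismatch between X, time, event")
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        order = np.argsort(-time, kind="stable")  # descending time
        self.X = X[order]
        self.t = time[order]
        self.d = event[order]
        self.ties = ties
        self.n, self.k = X.shape
        # last index of each tie group (descending order => risk set is prefix)
        change = np.flatnonzero(self.t[1:] != self.t[:-1])
        self.last = np.r_[change, self.n - 1]
        starts = np.r_[0, self.last[:-1] + 1]
        self.starts = starts
        self.dg = np.add.reduceat(self.d, starts)  # events per tie group
        self.event_groups = np.flatnonzero(self.dg > 0)
        if self.d.sum() == 0:
            raise ValueError("no observed events; partial likelihood undefined")

    def derivs(self, beta, want_derivs=True):
        X, d = self.X, self.d
        eta = X @ beta if self.k else np.zeros(self.n)
        m = eta.max() if self.n else 0.0
        w = np.exp(eta - m)
        cw = np.cumsum(w)
        ll = float((eta * d).sum())
        U = (X * d[:, None]).sum(axis=0) if want_derivs else None
        I = np.zeros((self.k, self.k)) if want_derivs else None
        if want_derivs and self.k:
            cwx = np.cumsum(X * w[:, None], axis=0)
            cwxx = np.cumsum(w[:, None, None] * (X[:, :, None] * X[:, None, :]), axis=0)
        for g in self.event_groups:
            last, start = self.last[g], self.starts[g]
            dg = int(self.dg[g])
            S0 = cw[last]
            if want_derivs and self.k:
                S1 = cwx[last]
                S2 = cwxx[last]
            if self.ties == "breslow" or dg == 1:
                ll -= dg * (m + np.log(S0))
                if want_derivs and self.k:
                    r1 = S1 / S0
                    U -= dg * r1
                    I += dg * (S2 / S0 - np.outer(r1, r1))
            else:
                # Efron: progressively down-weight the tied events
                idx = slice(start, last + 1)
                ev = self.d[idx] == 1
                w_t = w[idx][ev].sum()
                if want_derivs and self.k:
                    x_t = (self.X[idx][ev] * w[idx][ev, None]).sum(axis=0)
                    xx_t = (
                        w[idx][ev, None, None]
                        * (self.X[idx][ev][:, :, None] * self.X[idx][ev][:, None, :])
                    ).sum(axis=0)
                for j in range(dg):
                    f = j / dg
                    S0j = S0 - f * w_t
                    ll -= m + np.log(S0j)
                    if want_derivs and self.k:
                        S1j = S1 - f * x_t
                        S2j = S2 - f * xx_t
                        r1 = S1j / S0j
                        U -= r1
                        I += S2j / S0j - np.outer(r1, r1)
        return ll, U, I

    def baseline(self, beta):
        """Breslow cumulative baseline hazard at distinct event times
        (ascending)."""
        eta = self.X @ beta if self.k else np.zeros(self.n)
        w = np.exp(eta)
        cw = np.cumsum(w)
        times, haz = [], []
        for g in self.event_groups:
            times.append(self.t[self.last[g]])
            haz.append(self.dg[g] / cw[self.last[g]])
        order = np.argsort(times)
        t_sorted = np.asarray(times)[order]
        h_sorted = np.asarray(haz)[order]
        return t_sorted, np.cumsum(h_sorted)


def fit_cox(
    X,
    time,
    event,
    terms: list[PredictorTerm] | None = None,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-8,
    divergence_bound: float = 20.0,
) -> CoxModel:
    """Maximize the Cox partial likelihood by Newton-Raphson with
    step-halving.

    ``X`` is the n x k term-value matrix (k = 0 gives the baseline-only
    model).  Constant columns are rejected; a singular information matrix
    raises; a coefficient exceeding ``divergence_bound`` in magnitude flags
    the fit as non-converged (monotone likelihood).
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and np.asarray(time).size != 1:
        X = X.T
    n, k = X.shape
    if k:
        spans = np.ptp(X, axis=0)
        if np.any(spans == 0):
            bad = np.flatnonzero(spans == 0).tolist()
            raise ValueError(f"constant term columns at indices {bad}")
    pl = _PartialLikelihood(X, time, event, ties=ties)
    beta = np.zeros(k)
    messages: list[str] = []
    converged = False
    ll, U, I = pl.derivs(beta)
    if k == 0:
        converged = True
    for _ in range(max_iter):
        if k == 0:
            break
        if np.max(np.abs(U)) < tol:
            converged = True
            break
        try:
            delta = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular information matrix in Cox fit: {exc}"
            ) from exc
        step = 1.0
        while step > 1.0 / 4096.0:
            cand = beta + step * delta
            ll_new, U_new, I_new = pl.derivs(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                beta, ll, U, I = cand, ll_new, U_new, I_new
                break
            step /= 2.0
        else:
            messages.append("step-halving failed to improve the partial likelihood")
            break
    else:
        messages.append(f"no convergence in {max_iter} iterations")
    if k and np.max(np.abs(beta)) > divergence_bound:
        converged = False
        messages.append(
            "monotone likelihood suspected: |coefficient| exceeds "
            f"{divergence_bound}"
        )
    bt, bh = pl.baseline(beta)
    return CoxModel(
        terms=terms,
        coefficients=beta,
        log_partial_likelihood=ll,
        baseline_times=bt,
        baseline_cumhaz=bh,
        n_fit=n,
        converged=converged,
        ties=ties,
        messages=tuple(messages),
    )


def load_published_model() -> CoxModel:
    """The reference five-predictor NSCLC radiomic Cox model shipped with
    the package (published coefficients; no baseline hazard available)."""
    text = resources.files("radsurv").joinpath("data/published_model.json").read_text()
    return CoxModel.from_dict(json.loads(text))
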