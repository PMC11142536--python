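"""Patient-grouped splitting, nested cross-validation and the linear SVM.

All partitioning is at the patient level: every spot of a patient lives on
one side of the train/held-out split and inside one cross-validation fold,
so spot-level correlation within a patient can never leak across splits.
Hyperparameter selection (the SVM regularization C) happens in inner
grouped folds; generalization is estimated on outer grouped folds; the
held-out patients are untouched until final evaluation.

Feature construction that must be refit per fold (peak detection, scalers)
is injected through a ``feature_builder`` callable, so the same nested-CV
engine serves the IMS, microscopy and multimodal pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .cohort import SpotRecord
from .metrics import ScoreSet, pr_auc, roc_auc, thresholded_metrics

__all__ = [
    "SplitPlan",
    "GridSpec",
    "CVResult",
    "ModelingError",
    "LeakageError",
    "split_patients",
    "assign_outer_folds",
    "train_linear_svm",
    "nested_cv",
    "evaluate_heldout",
    "make_scaler_builder",
]


class ModelingError(ValueError):
    """Raised for invalid modeling inputs."""


class LeakageError(RuntimeError):
    """Raised when held-out data would touch a fitted quantity."""


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level train/held-out partition plus outer-fold assignment."""

    train_patients: tuple[str, ...]
    heldout_patients: tuple[str, ...]
    outer_folds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.train_patients) & set(self.heldout_patients)
        if overlap:
            raise ModelingError(f"patients on both sides of the split: {sorted(overlap)}")
        extra = set(self.outer_folds) - set(self.train_patients)
        if extra:
            raise ModelingError(f"fold assignment for non-training patients: {sorted(extra)}")

    @property
    def k_outer(self) -> int:
        return max(self.outer_folds.values()) if self.outer_folds else 0


@dataclass(frozen=True)
class GridSpec:
    """Search grid for the SVM regularization parameter C."""

    c_values: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
    selection_metric: str = "roc_auc"

    def __post_init__(self) -> None:
        if not self.c_values or any(c <= 0 for c in self.c_values):
            raise ModelingError("grid must be non-empty with positive C values")
        if self.selection_metric != "roc_auc":
            raise ModelingError("only roc_auc selection is supported")

    @property
    def sorted_c(self) -> tuple[float, ...]:
        return tuple(sorted(self.c_values))


@dataclass
class CVResult:
    """Per-outer-fold metrics with their mean and sd, plus selected C."""

    fold_metrics: list[dict[str, float]]
    selected_c: list[float]

    METRICS = ("roc_auc", "pr_auc", "f1", "precision", "recall")

    @property
    def k_outer(self) -> int:
        return len(self.fold_metrics)

    def mean(self, metric: str) -> float:
        return float(np.mean([m[metric] for m in self.fold_metrics]))

    def sd(self, metric: str) -> float:
        vals = [m[metric] for m in self.fold_metrics]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in self.METRICS}


def _patient_labels(records: list[SpotRecord]) -> dict[str, str]:
    labels: dict[str, str] = {}
    for r in records:
        prev = labels.setdefault(r.patient_id, r.label)
        if prev != r.label:
            raise ModelingError(f"patient {r.patient_id} has conflicting spot labels")
    return labels


def _largest_remainder_allocation(class_sizes: dict[str, int], total: int) -> dict[str, int]:
    """Split `total` across classes proportionally (largest-remainder rule)."""
    n = sum(class_sizes.values())
    quotas = {c: total * k / n for c, k in class_sizes.items()}
    alloc = {c: int(np.floor(q)) for c, q in quotas.items()}
    remainder = total - sum(alloc.values())
    order = sorted(class_sizes, key=lambda c: (-(quotas[c] - alloc[c]), c))
    for c in order[:remainder]:
        alloc[c] += 1
    return alloc


def split_patients(
    records: list[SpotRecord], heldout_fraction: float, seed: int
) -> SplitPlan:
    """Label-stratified patient-level train/held-out split.

    The held-out count is round(heldout_fraction * n_patients), allocated
    across classes by largest remainder and clamped so each class keeps at
    least one patient on each side.  Deterministic given the seed.
    """
    if not 0.0 < heldout_fraction < 1.0:
        raise ModelingError("heldout_fraction must lie in (0, 1)")
    labels = _patient_labels(records)
    by_class: dict[str, list[str]] = {}
    for pid, lab in labels.items():
        by_class.setdefault(lab, []).append(pid)
    if any(len(p) < 2 for p in by_class.values()) or len(by_class) < 2:
        raise ModelingError("need at least 2 patients per class to split")
    n = len(labels)
    n_held = int(round(heldout_fraction * n))
    alloc = _largest_remainder_allocation(
        {c: len(p) for c, p in by_class.items()}, n_held)
    rng = np.random.default_rng(seed)
    heldout: list[str] = []
    train: list[str] = []
    for c in sorted(by_class):
        pool = sorted(by_class[c])
        k = int(np.clip(alloc[c], 1, len(pool) - 1))
        chosen = rng.choice(len(pool), size=k, replace=False)
        mask = np.zeros(len(pool), dtype=bool)
        mask[chosen] = True
        heldout.extend(p for p, m in zip(pool, mask) if m)
        train.extend(p for p, m in zip(pool, mask) if not m)
    return SplitPlan(train_patients=tuple(sorted(train)),
                     heldout_patients=tuple(sorted(heldout)))


def _stratified_folds(
    patients: list[str], labels: dict[str, str], k: int, seed: int
) -> dict[str, int]:
    """Deal patients into k folds, round-robin within each shuffled class."""
    rng = np.random.default_rng(seed)
    folds: dict[str, int] = {}
    cursor = 0
    for c in sorted({labels[p] for p in patients}):
        members = sorted(p for p in patients if labels[p] == c)
        members = [members[i] for i in rng.permutation(len(members))]
        for p in members:
            folds[p] = cursor % k + 1
            cursor += 1
    return folds


def assign_outer_folds(
    plan: SplitPlan, records: list[SpotRecord], k_outer: int, seed: int
) -> SplitPlan:
    """Partition training patients into k_outer label-stratified folds."""
    if k_outer < 2:
        raise ModelingError("k_outer must be >= 2")
    if k_outer > len(plan.train_patients):
        raise ModelingError(
            f"k_outer={k_outer} exceeds the {len(plan.train_patients)} training patients"
        )
    labels = _patient_labels(records)
    folds = _stratified_folds(list(plan.train_patients), labels, k_outer, seed)
    return replace(plan, outer_folds=folds)


class LinearSVMModel:
    """Fitted linear SVM exposing the decision score w . x + b."""

    def __init__(self, estimator: LinearSVC):
        self._estimator = estimator

    def decision_score(self, X: np.ndarray) -> np.ndarray:
        """Higher score means more melanoma-like."""
        return self._estimator.decision_function(np.asarray(X, dtype=float))

    @property
    def coef_(self) -> np.ndarray:
        return self._estimator.coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self._estimator.intercept_[0])


def train_linear_svm(X, y, C: float = 1.0, seed: int = 0) -> LinearSVMModel:
    """Fit a linear SVM; raises if y contains a single class.

    Solved in the primal (squared hinge, L2 penalty) with liblinear's
    Newton-type solver, which is deterministic and stays fast across the
    whole regularization grid; ``seed`` is accepted for interface
    uniformity with the stochastic stages.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelingError("training labels contain a single class")
    est = LinearSVC(C=C, dual=False, tol=1e-4, max_iter=1000)
    with warnings.catch_warnings():
        # near-separable fits at the largest grid C can hit the iteration
        # cap; the truncated Newton solution is fully usable for selection
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return LinearSVMModel(est)


# A feature builder maps training row indices to a transform over any row
# indices; all fitted state (peaks, scalers) must derive from the training
# rows alone.
FeatureBuilder = Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]]


def make_scaler_builder(X) -> FeatureBuilder:
    """Default feature builder: per-feature z-scoring on the fit rows."""
    from .fusion import fit_scaler

    values = X.to_numpy() if hasattr(X, "to_numpy") else np.asarray(X, dtype=float)

    def build(train_idx: np.ndarray):
        scaler = fit_scaler(values, train_idx)

        def transform(idx: np.ndarray) -> np.ndarray:
            return scaler.transform(values[np.asarray(idx)])

        return transform

    return build


def _metric_set(scores: np.ndarray, y: np.ndarray, threshold: float) -> dict[str, float]:
    s = ScoreSet(scores=scores, labels=y)
    _, auc = roc_auc(s)
    _, pr = pr_auc(s)
    out = {"roc_auc": auc, "pr_auc": pr}
    out.update(thresholded_metrics(s, threshold))
    return out


def nested_cv(
    y,
    patient_ids,
    plan: SplitPlan,
    grid: GridSpec,
    feature_builder: FeatureBuilder,
    k_inner: int = 5,
    seed: int = 0,
    threshold: float = 0.0,
) -> CVResult:
    """Grouped nested cross-validation with grid search over C.

    ``y`` and ``patient_ids`` are aligned with the rows the feature builder
    indexes (the full cohort); only rows of training patients are visited.
    For each outer fold, an inner grouped k_inner-fold grid search over the
    remaining training patients picks the C with the best mean inner
    ROC-AUC (ties to the smallest C); the model is refit with that C on all
    non-fold data and scored on the fold.
    """
    if k_inner < 2:
        raise ModelingError("k_inner must be >= 2")
    if not plan.outer_folds:
        raise ModelingError("plan has no outer folds; call assign_outer_folds first")
    y = np.asarray(y, dtype=int)
    patient_ids = np.asarray(patient_ids)
    patient_label = {p: int(y[patient_ids == p][0]) for p in plan.train_patients}

    fold_metrics: list[dict[str, float]] = []
    selected: list[float] = []
    for fold in range(1, plan.k_outer + 1):
        val_patients = [p for p, f in plan.outer_folds.items() if f == fold]
        fit_patients = [p for p, f in plan.outer_folds.items() if f != fold]
        val_idx = np.flatnonzero(np.isin(patient_ids, val_patients))
        fit_idx = np.flatnonzero(np.isin(patient_ids, fit_patients))

        # deal inner folds; if any fold misses a class, redeal once, then fail
        fit_labels = {p: str(patient_label[p]) for p in fit_patients}
        inner = _stratified_folds(fit_patients, fit_labels, k_inner,
                                  seed * 1000 + fold)
        for attempt in range(2):
            bad = any(
                len({fit_labels[p] for p, f in inner.items() if f == j}) < 2
                or len({fit_labels[p] for p, f in inner.items() if f != j}) < 2
                for j in range(1, k_inner + 1)
            )
            if not bad:
                break
            if attempt == 1:
                raise ModelingError(
                    f"outer fold {fold}: an inner fold has a single class even "
                    "after resampling; use fewer folds or more patients per class"
                )
            inner = _stratified_folds(fit_patients, fit_labels, k_inner,
                                      seed * 1000 + fold + 500000)
        mean_auc = {c: [] for c in grid.sorted_c}
        for j in range(1, k_inner + 1):
            iv_pat = [p for p, f in inner.items() if f == j]
            it_pat = [p for p, f in inner.items() if f != j]
            iv_idx = np.flatnonzero(np.isin(patient_ids, iv_pat))
            it_idx = np.flatnonzero(np.isin(patient_ids, it_pat))
            if len(np.unique(y[it_idx])) < 2 or len(np.unique(y[iv_idx])) < 2:
                raise ModelingError(
                    f"inner fold {j} of outer fold {fold} has a single class; "
                    "use fewer folds or more patients per class"
                )
            transform = feature_builder(it_idx)
            X_it, X_iv = transform(it_idx), transform(iv_idx)
            for c in grid.sorted_c:
                model = train_linear_svm(X_it, y[it_idx], C=c, seed=seed)
                _, auc = roc_auc(ScoreSet(model.decision_score(X_iv), y[iv_idx]))
                mean_auc[c].append(auc)
        # ties break toward the smallest C (strongest regularization)
        best_c, best = grid.sorted_c[0], -np.inf
        for c in grid.sorted_c:
            m = float(np.mean(mean_auc[c]))
            if m > best:
                best, best_c = m, c

        transform = feature_builder(fit_idx)
        model = train_linear_svm(transform(fit_idx), y[fit_idx], C=best_c, seed=seed)
        scores = model.decision_score(transform(val_idx))
        fold_metrics.append(_metric_set(scores, y[val_idx], threshold))
        selected.append(best_c)
    return CVResult(fold_metrics=fold_metrics, selected_c=selected)


def evaluate_heldout(
    model: LinearSVMModel,
    X_heldout: np.ndarray,
    y_heldout: np.ndarray,
    spot_ids: np.ndarray,
    train_spot_ids,
    threshold: float = 0.0,
) -> tuple[dict[str, float], ScoreSet]:
    """Score held-out spots and compute their metric set.

    Any overlap between the held-out spot ids and the ids the chain was
    fitted on is a fatal leakage error.
    """
    spot_ids = np.asarray(spot_ids)
    seen = set(train_spot_ids) & set(spot_ids.tolist())
    if seen:
        raise LeakageError(
            f"held-out evaluation received {len(seen)} spots seen during fitting, "
            f"e.g. {sorted(seen)[:5]}"
        )
    scores = model.decision_score(np.asarray(X_heldout))
    y_heldout = np.asarray(y_heldout, dtype=int)
    score_set = ScoreSet(scores=scores, labels=y_heldout, spot_ids=spot_ids)
    return _metric_set(scores, y_heldout, threshold), score_set
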