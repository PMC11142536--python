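"""End-to-end orchestration of the three classification pipelines.

The three pipelines — unimodal IMS, unimodal microscopy, multimodal — share
one patient-level split, one fold assignment and one downstream modeling
path; only the feature construction differs:

* ``ims``: preprocessing chain -> peak matrix -> z-scored block;
* ``microscopy``: patch embeddings -> z-scored block;
* ``multimodal``: both blocks z-scored then concatenated with weights.

Everything that is *fitted* (realignment reference, peak list, scalers,
selected C) derives from training patients only, and is refit inside every
cross-validation fold.  The report compares pipelines on the identical
held-out spots with the paired DeLong test.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort import (MELANOMA, CohortConfig, Patch, SpotRecord, SyntheticCohort,
                     generate_cohort)
from .fusion import BlockScaler, fit_scaler
from .metrics import DeLongResult, ScoreSet, delong_paired
from .modeling import (CVResult, GridSpec, ModelingError, SplitPlan,
                       assign_outer_folds, evaluate_heldout, nested_cv,
                       split_patients, train_linear_svm, _stratified_folds)
from .morphology import EmbedderSpec, embed_patches
from .spectra import (AxisSpec, Spectrum, detect_peaks, resample_to_axis,
                      subtract_baseline, tic_normalize)
from .metrics import roc_auc

logger = logging.getLogger(__name__)

MODES = ("ims", "microscopy", "multimodal")

__all__ = [
    "MODES",
    "ExperimentConfig",
    "FittedInfo",
    "PipelineResult",
    "PipelineReport",
    "run_pipeline",
    "run_experiment",
    "compare_pipelines",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of a full experiment, serializable to/from YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    baseline_window: int = 51
    max_shift: int = 5
    snr_min: float = 3.0
    window_halfwidth: int = 2
    embedder: EmbedderSpec = field(default_factory=EmbedderSpec)
    fusion_weights: tuple[float, float] = (1.0, 1.0)
    grid: GridSpec = field(default_factory=GridSpec)
    k_outer: int = 5
    k_inner: int = 5
    heldout_fraction: float = 0.2
    threshold: float = 0.0
    seed: int = 0

    @property
    def axis(self) -> AxisSpec:
        return AxisSpec(self.cohort.mz_min, self.cohort.mz_max,
                        self.cohort.n_axis_bins)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["fusion_weights"] = list(self.fusion_weights)
        doc["grid"]["c_values"] = list(self.grid.c_values)
        doc["embedder"]["channel_means"] = list(self.embedder.channel_means)
        doc["embedder"]["channel_sds"] = list(self.embedder.channel_sds)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**doc.pop("cohort", {}))
        emb = doc.pop("embedder", {})
        for key in ("channel_means", "channel_sds"):
            if key in emb:
                emb[key] = tuple(emb[key])
        embedder = EmbedderSpec(**emb)
        grid_doc = doc.pop("grid", {})
        if "c_values" in grid_doc:
            grid_doc["c_values"] = tuple(grid_doc["c_values"])
        grid = GridSpec(**grid_doc)
        if "fusion_weights" in doc:
            doc["fusion_weights"] = tuple(doc["fusion_weights"])
        return cls(cohort=cohort, embedder=embedder, grid=grid, **doc)


@dataclass
class FittedInfo:
    """Fitted quantities of a final pipeline chain, exposed for auditing."""

    mode: str
    selected_c: float
    train_spot_ids: tuple[str, ...]
    peak_centers: np.ndarray | None = None
    ims_scaler: BlockScaler | None = None
    morph_scaler: BlockScaler | None = None


@dataclass
class PipelineResult:
    mode: str
    cv: CVResult
    heldout_metrics: dict[str, float]
    heldout_scores: ScoreSet
    fitted: FittedInfo


@dataclass
class PipelineReport:
    """Comparison of the pipelines on one shared split."""

    results: dict[str, PipelineResult]
    delong: dict[str, DeLongResult]
    config: ExperimentConfig
    seed: int

    def summary_table(self) -> dict:
        table = {}
        for mode, res in self.results.items():
            table[mode] = {
                "cv": res.cv.summary(),
                "heldout": res.heldout_metrics,
                "selected_c_per_fold": res.cv.selected_c,
            }
        return table

    def to_json(self, path=None) -> str:
        doc = {
            "seed": self.seed,
            "pipelines": self.summary_table(),
            "delong": {
                pair: {
                    "auc_a": r.auc_a, "auc_b": r.auc_b,
                    "var_diff": r.var_diff, "z": r.z, "p_value": r.p_value,
                }
                for pair, r in self.delong.items()
            },
        }
        text = json.dumps(doc, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


class _IMSFeatures:
    """Per-fold refittable IMS feature construction.

    The per-spot deterministic steps (resample, baseline, TIC) run once at
    construction; realignment reference and the peak list are refit from the
    requested training rows on every ``build`` call.
    """

    def __init__(self, spectra: list[Spectrum], config: ExperimentConfig):
        self.config = config
        axis = config.axis
        rows = []
        for s in spectra:
            r = subtract_baseline(resample_to_axis(s, axis), config.baseline_window)
            # zero-TIC spots must be dropped upstream (see _drop_zero_tic)
            rows.append(tic_normalize(r).intensity)
        self.prepped = np.asarray(rows)  # n_spots x n_bins
        self.mz = axis.centers

    def _aligned(self, idx: np.ndarray, reference: np.ndarray) -> np.ndarray:
        """Vectorized integer-lag realignment of the selected rows against
        the reference (same lag search and tie rule as realign_spectrum)."""
        m = self.config.max_shift
        Q = self.prepped[np.asarray(idx)]
        n = Q.shape[1]
        lags = sorted(range(-m, m + 1), key=lambda l: (abs(l), l))
        corr = np.empty((Q.shape[0], len(lags)))
        for k, lag in enumerate(lags):
            if lag >= 0:
                corr[:, k] = Q[:, lag:] @ reference[: n - lag]
            else:
                corr[:, k] = Q[:, : n + lag] @ reference[-lag:]
        best = np.array(lags)[np.argmax(corr, axis=1)]  # first max = tie to 0
        out = np.zeros_like(Q)
        for lag in np.unique(best):
            rows = best == lag
            if lag >= 0:
                out[rows, : n - lag] = Q[rows, lag:]
            else:
                out[rows, -lag:] = Q[rows, : n + lag]
        return out

    def build(self, train_idx: np.ndarray):
        cfg = self.config
        train_idx = np.asarray(train_idx)
        reference = self.prepped[train_idx].mean(axis=0)
        aligned_train = self._aligned(train_idx, reference)
        peaks = detect_peaks(
            Spectrum(mz=self.mz, intensity=aligned_train.mean(axis=0)),
            cfg.snr_min, cfg.window_halfwidth)
        centers_idx = np.searchsorted(self.mz, peaks.centers)
        w = cfg.window_halfwidth
        n = len(self.mz)

        def peak_rows(aligned: np.ndarray) -> np.ndarray:
            cols = np.empty((aligned.shape[0], len(peaks)))
            for j, i in enumerate(centers_idx):
                cols[:, j] = aligned[:, max(0, i - w): min(n, i + w + 1)].sum(axis=1)
            return cols

        scaler = fit_scaler(peak_rows(aligned_train),
                            np.arange(len(train_idx)))

        def transform(idx: np.ndarray) -> np.ndarray:
            return scaler.transform(peak_rows(self._aligned(idx, reference)))

        transform.peaks = peaks
        transform.scaler = scaler
        return transform


class _MorphFeatures:
    """Per-fold refittable morphology features (embeddings are fit-free)."""

    def __init__(self, patches: list[Patch], config: ExperimentConfig):
        self.embeddings = embed_patches(patches, config.embedder).to_numpy()

    def build(self, train_idx: np.ndarray):
        scaler = fit_scaler(self.embeddings, np.asarray(train_idx))

        def transform(idx: np.ndarray) -> np.ndarray:
            return scaler.transform(self.embeddings[np.asarray(idx)])

        transform.scaler = scaler
        return transform


class _FusedFeatures:
    """Weighted concatenation of the refittable IMS and morphology blocks."""

    def __init__(self, ims: _IMSFeatures, morph: _MorphFeatures,
                 weights: tuple[float, float]):
        self.ims = ims
        self.morph = morph
        self.weights = weights

    def build(self, train_idx: np.ndarray):
        t_ims = self.ims.build(train_idx)
        t_morph = self.morph.build(train_idx)
        w_ims, w_morph = self.weights

        def transform(idx: np.ndarray) -> np.ndarray:
            return np.hstack([w_ims * t_ims(idx), w_morph * t_morph(idx)])

        transform.peaks = t_ims.peaks
        transform.ims_scaler = t_ims.scaler
        transform.morph_scaler = t_morph.scaler
        return transform


def _select_c_grouped(y, patient_ids, patients, grid: GridSpec, builder,
                      k: int, seed: int) -> float:
    """Grouped k-fold grid search over C on the given patients (used for the
    final refit on the full training set); ties go to the smallest C."""
    labels = {p: str(int(y[patient_ids == p][0])) for p in patients}
    folds = _stratified_folds(list(patients), labels, k, seed)
    mean_auc = {c: [] for c in grid.sorted_c}
    for j in range(1, k + 1):
        iv = [p for p, f in folds.items() if f == j]
        it = [p for p, f in folds.items() if f != j]
        iv_idx = np.flatnonzero(np.isin(patient_ids, iv))
        it_idx = np.flatnonzero(np.isin(patient_ids, it))
        transform = builder(it_idx)
        X_it, X_iv = transform(it_idx), transform(iv_idx)
        for c in grid.sorted_c:
            model = train_linear_svm(X_it, y[it_idx], C=c, seed=seed)
            _, auc = roc_auc(ScoreSet(model.decision_score(X_iv), y[iv_idx]))
            mean_auc[c].append(auc)
    best_c, best = grid.sorted_c[0], -np.inf
    for c in grid.sorted_c:
        m = float(np.mean(mean_auc[c]))
        if m > best:
            best, best_c = m, c
    return best_c


@dataclass
class _ExperimentData:
    records: list[SpotRecord]
    spectra: list[Spectrum]
    patches: list[Patch]

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort) -> "_ExperimentData":
        return cls(records=cohort.records, spectra=cohort.spectra,
                   patches=cohort.patches)


def _drop_zero_tic(data: "_ExperimentData", config: ExperimentConfig) -> "_ExperimentData":
    """Exclude spots whose preprocessed spectrum has zero total ion current
    (below minimal spectral quality), with a logged warning."""
    if not data.spectra:
        return data
    keep = []
    for i, s in enumerate(data.spectra):
        r = subtract_baseline(resample_to_axis(s, config.axis),
                              config.baseline_window)
        if r.intensity.sum() > 0:
            keep.append(i)
        else:
            logger.warning("dropping zero-TIC spot %r", s.spot_id)
    if len(keep) == len(data.spectra):
        return data
    return _ExperimentData(
        records=[data.records[i] for i in keep],
        spectra=[data.spectra[i] for i in keep],
        patches=[data.patches[i] for i in keep] if data.patches else [],
    )


def _shared_plan(records, config: ExperimentConfig) -> SplitPlan:
    plan = split_patients(records, config.heldout_fraction, config.seed)
    return assign_outer_folds(plan, records, config.k_outer, config.seed + 1)


def run_pipeline(
    mode: str,
    config: ExperimentConfig,
    data: _ExperimentData | SyntheticCohort | None = None,
    plan: SplitPlan | None = None,
    _features=None,
) -> PipelineResult:
    """Run one named pipeline end to end.

    Generates the synthetic cohort from ``config.cohort`` unless ``data`` is
    provided.  The same :class:`SplitPlan` may be passed in so several modes
    share identical training and held-out spots.
    """
    if mode not in MODES:
        raise ModelingError(f"unknown mode {mode!r}; choose from {MODES}")
    if data is None:
        data = _ExperimentData.from_cohort(generate_cohort(config.cohort))
    elif isinstance(data, SyntheticCohort):
        data = _ExperimentData.from_cohort(data)
    if mode in ("ims", "multimodal") and not data.spectra:
        raise ModelingError(f"mode {mode!r} requires spectra")
    if mode in ("microscopy", "multimodal") and not data.patches:
        raise ModelingError(f"mode {mode!r} requires patches")
    if _features is None and plan is None:
        data = _drop_zero_tic(data, config)

    records = data.records
    y = np.array([1 if r.label == MELANOMA else 0 for r in records])
    patient_ids = np.array([r.patient_id for r in records])
    spot_ids = np.array([r.spot_id for r in records])

    if plan is None:
        plan = _shared_plan(records, config)

    if _features is None:
        if mode == "ims":
            _features = _IMSFeatures(data.spectra, config)
        elif mode == "microscopy":
            _features = _MorphFeatures(data.patches, config)
        else:
            _features = _FusedFeatures(_IMSFeatures(data.spectra, config),
                                       _MorphFeatures(data.patches, config),
                                       config.fusion_weights)
    builder = _features.build

    train_mask = np.isin(patient_ids, plan.train_patients)
    train_idx = np.flatnonzero(train_mask)
    heldout_idx = np.flatnonzero(~train_mask)

    cv = nested_cv(y, patient_ids, plan, config.grid, builder,
                   k_inner=config.k_inner, seed=config.seed,
                   threshold=config.threshold)

    final_c = _select_c_grouped(y, patient_ids, plan.train_patients, config.grid,
                                builder, config.k_inner, config.seed + 7)
    transform = builder(train_idx)
    model = train_linear_svm(transform(train_idx), y[train_idx], C=final_c,
                             seed=config.seed)
    fitted = FittedInfo(
        mode=mode,
        selected_c=final_c,
        train_spot_ids=tuple(spot_ids[train_idx].tolist()),
        peak_centers=(np.asarray(transform.peaks.centers)
                      if hasattr(transform, "peaks") else None),
        ims_scaler=getattr(transform, "ims_scaler",
                           getattr(transform, "scaler", None)
                           if mode == "ims" else None),
        morph_scaler=getattr(transform, "morph_scaler",
                             getattr(transform, "scaler", None)
                             if mode == "microscopy" else None),
    )
    metrics, scores = evaluate_heldout(
        model, transform(heldout_idx), y[heldout_idx], spot_ids[heldout_idx],
        fitted.train_spot_ids, threshold=config.threshold)
    return PipelineResult(mode=mode, cv=cv, heldout_metrics=metrics,
                          heldout_scores=scores, fitted=fitted)


def compare_pipelines(
    results: dict[str, PipelineResult],
    config: ExperimentConfig,
    pairs: list[tuple[str, str]] | None = None,
) -> PipelineReport:
    """Assemble the report: metric tables plus paired DeLong tests."""
    if len(results) < 2:
        raise ModelingError("need at least 2 pipelines to compare")
    modes = list(results)
    ref_ids = results[modes[0]].heldout_scores.spot_ids
    for m in modes[1:]:
        ids = results[m].heldout_scores.spot_ids
        if not np.array_equal(ref_ids, ids):
            raise ModelingError(
                f"pipelines {modes[0]!r} and {m!r} were evaluated on different "
                "held-out spots; share one SplitPlan"
            )
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(modes) for b in modes[i + 1:]]
    delong = {
        f"{a}_vs_{b}": delong_paired(results[a].heldout_scores,
                                     results[b].heldout_scores)
        for a, b in pairs
    }
    return PipelineReport(results=results, delong=delong, config=config,
                          seed=config.seed)


def run_experiment(
    config: ExperimentConfig,
    modes: tuple[str, ...] = MODES,
    data: _ExperimentData | SyntheticCohort | None = None,
) -> PipelineReport:
    """Run every requested pipeline on one shared cohort and split, then
    compare them.  This is the paper-style experiment in one call."""
    if data is None:
        data = _ExperimentData.from_cohort(generate_cohort(config.cohort))
    elif isinstance(data, SyntheticCohort):
        data = _ExperimentData.from_cohort(data)
    data = _drop_zero_tic(data, config)
    plan = _shared_plan(data.records, config)
    # share the per-spot preprocessing / embeddings across pipelines
    ims = _IMSFeatures(data.spectra, config) \
        if any(m in ("ims", "multimodal") for m in modes) else None
    morph = _MorphFeatures(data.patches, config) \
        if any(m in ("microscopy", "multimodal") for m in modes) else None
    features = {
        "ims": ims,
        "microscopy": morph,
        "multimodal": (_FusedFeatures(ims, morph, config.fusion_weights)
                       if ims is not None and morph is not None else None),
    }
    results = {
        m: run_pipeline(m, config, data=data, plan=plan, _features=features[m])
        for m in modes
    }
    return compare_pipelines(results, config)
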