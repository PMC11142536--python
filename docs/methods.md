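# Methods

This note documents the models, algorithmic choices and defaults of
`melafuse`, and what the synthetic experiments do and do not demonstrate.

## Study design being modelled

A cohort of patients, each diagnosed melanoma or nevus, contributes ~21
annotated 50 µm spots. Every spot yields one profile mass spectrum
(700–3500 Da) and one registered H&E patch (48 µm × 48 µm of tissue:
96×96 px at 20x / 0.5 µm per pixel, 192×192 px at 40x / 0.25 µm per
pixel). Classification is at the spot level; all partitioning is at the
patient level, because spots within a patient are strongly correlated and
patient-level leakage would inflate every metric.

## IMS preprocessing

Named steps and the concrete algorithms chosen for them (each swappable):

1. **Resampling** — linear interpolation onto a uniform common axis
   (default 700–3500 Da; 600 bins for synthetic runs, configurable —
   real profile data would use a denser axis).
2. **Baseline subtraction** — centered rolling minimum then centered
   rolling mean, both over `baseline_window` bins (default 51, odd;
   edges replicate the boundary value); result clipped at 0. This is a
   cheap morphological-opening analogue adequate for slowly varying
   chemical baselines.
3. **TIC normalization** — scale each spectrum to unit total ion current.
   Zero-TIC spots (below minimal spectral quality) are dropped with a
   logged warning rather than failing the run.
4. **Realignment** — integer-bin shift maximizing cross-correlation with
   the *training-set* mean spectrum, searched over ±`max_shift` bins
   (default 5), ties toward zero lag, vacated bins zeroed. Corrects
   global acquisition drift; it cannot fix nonlinear mass error (out of
   scope).
5. **Peak detection** — on the realigned training mean spectrum: strict
   local maxima above `snr_min` (default 3) times a robust noise scale,
   `1.4826 · MAD(Δintensity)/√2`. Detection on an aggregate spectrum
   (rather than per spectrum) is a deliberate choice; the peak count is
   data-dependent, never hard-coded.
6. **Peak matrix** — entry (spot, peak) sums intensities within
   ±`window_halfwidth` bins (default 2) of the peak center.

Because reference and peak list are fitted quantities, the
`IMSPipeline.fit/transform` split (and the per-fold feature builders in
the orchestration layer) refit them inside every cross-validation fold.

## Morphology embedding

Patches are bilinearly resized to 224×224 (half-pixel-center convention,
implemented as two cached interpolation matmuls) and channel-normalized
with means/sds (0.5, 0.5) per channel — the constants are configurable
because published pipelines differ. 40x patches are extracted at native
resolution and go through the same resize.

The encoder is a pluggable callable. The built-in default is a
deterministic hand-crafted texture encoder: per-channel 16-bin intensity
histograms, 16-bin gradient-magnitude histograms, mean local variance at
box windows {3, 7, 15, 31}, and channel mean/variance (114 features),
projected to `embed_dim` (default 512) by a Gaussian random projection
seeded from the embedder spec, then scaled to unit norm; constant input
maps to the fixed fallback e₁. It exists so the package is fully testable
offline; an external pre-trained self-supervised network can be dropped in
through the same interface, and nothing downstream changes.

## Fusion

"Normalized … with equal weight" is ambiguous, so the package interprets
it as: per-feature z-scoring within each block using training-row
statistics (population sd; zero-variance features masked to 0), then
unweighted concatenation (weights configurable, default (1, 1)). Column
provenance is preserved so each block can be recovered exactly.

## Modeling

* Patient-level held-out split: label-stratified, largest-remainder
  allocation, default 20% of patients held out, at least one patient per
  class on each side.
* Outer folds: k_outer = 5 label-stratified patient folds; inner grid
  search: k_inner = 5 (defaults), selection metric inner-mean ROC-AUC,
  ties to the smallest C. Grid default C ∈ {10⁻³ … 10³} (7 values).
* Classifier: linear SVM, solved in the primal as L2-regularized squared
  hinge with liblinear's Newton-type solver (`LinearSVC(dual=False)`).
  This formulation was chosen because it is deterministic and remains
  fast and well-behaved over the entire C grid, where hinge-loss dual
  solvers stall on near-separable blocks. Iteration cap 1000; on the
  rare near-separable fits at the largest C the truncated solution is
  still fine for model selection.
* Final model: C selected by one more grouped k_inner-fold grid search on
  the full training set, then refit on all training spots.
* Thresholded metrics (F1/precision/recall) use decision score ≥ 0;
  threshold configurable, and ROC/PR areas are the headline metrics
  precisely because thresholded ones are threshold-sensitive.
* No class reweighting (cohorts are roughly balanced by default).

## Evaluation

ROC-AUC is the Mann–Whitney statistic via midranks; the reported curve is
the (FPR, TPR) staircase whose trapezoidal area equals it. PR curves are
anchored at (recall 0, precision 1) for trapezoid stability — conventions
differ, so this is stated explicitly. The DeLong test uses per-observation
structural components (midrank formulation, written so it is bitwise equal
to the naive O(n²) kernel-matrix route, which is also shipped and used as
a cross-check); p-values are two-sided normal tails and reported as
computed, never floored.

## Visualization

UMAP (cosine metric by default; n_neighbors 15, min_dist 0.1 — unstated
in the source design, so standard defaults) with a fixed seed recorded in
the spec. Hyperspectral rendering clips each 3-D coordinate to its
(1, 99) percentile range before min–max scaling to RGB, to keep a single
outlier from collapsing the color range.

## Synthetic cohort generator

Spectra: smooth decaying baseline + Gaussian peaks (sd 2 bins) at
cohort-fixed centers + i.i.d. bin noise (sd 0.4) + lognormal per-spot TIC
factor (sd 0.15) + per-spot integer m/z jitter (±1 bin), clipped at 0.
Class signal: mean peak heights differ by `ims_effect_size` with
alternating sign across peaks (so TIC stays class-neutral). Patches:
eosin-pink background with hematoxylin-purple blobs from a thresholded
smoothed noise field; melanoma shifts the background color and raises
blob density in proportion to `morph_effect_size`; per-patch color and
density jitter keep single patches only moderately informative.

Patient-level heterogeneity (the reason patient-grouped validation
matters) has two parts, independent across modalities: each patient gets
a displacement along the class axis of peak space
(`ims_patient_sd`, default 0.15) — the whole patient looks systematically
more melanoma- or nevus-like in IMS — and a color/density offset
(`morph_patient_sd`, default 5 gray levels) in morphology.
Complementary-signal regimes flag whole patients as uninformative in one
modality (class-neutral data there), drawn disjointly when the fractions
allow.

Default effect sizes (0.6 intensity units for IMS, 1.2 texture units for
morphology) were set, by per-spot d′ analysis and small pilot runs, so
that spots of informative patients are reliably classifiable while
patient heterogeneity and the uninformative fractions keep the *pipelines*
imperfect: unimodal performance is then capped by its uninformative
patients (held-out ROC-AUC ≈ 0.85–0.95 across seeds) while the multimodal
pipeline, with usable signal for every patient, reaches ≈ 0.94–0.99 and
shows the smallest fold-to-fold sd. That reproduces the qualitative
finding the package exists to demonstrate — fusion best and most stable —
as a structural consequence of complementarity, not a tuned accident.

**What passing synthetic tests does not show:** the generator makes no
attempt at tryptic mass realism, isotope envelopes, stain physics, or
spatial correlation between neighboring spots; absolute AUC values on
real cohorts will differ, and the encoder stand-in is far weaker than a
pre-trained histopathology network. The synthetic experiments validate
the *machinery* (leakage-free grouped validation, fusion, statistics),
not clinical performance.

## Problem sizes used by the shipped experiments

The comparison battery (tests and the acceptance script) runs 60 patients
× ~21 spots, 600-bin axis, 512-d embeddings, k_outer = 5, k_inner = 3,
C grid {10⁻³ … 10} — a grid-and-fold reduction of the package defaults
chosen to keep a 10-seed battery to a few minutes on one CPU without
changing the character of the search. Null-calibration checks use
16-patient cohorts. All of it is deterministic given the seed.

## Numerical notes and edge cases

* Fixed seed ⇒ bit-identical cohorts, splits, folds, fits and scores.
* TIC normalization: relative tolerance 1e-9 on the target sum; scaler
  transforms map zero-variance features to exactly 0; realignment ties
  break toward lag 0; boundary-lag hits are logged.
* DeLong: identical inputs give z = 0, p = 1; zero variance with unequal
  AUCs is a hard error (degenerate design).
* Precision with no predicted positives is 0 (with a logged warning) in
  thresholded metrics, but 1 at the PR-curve anchor — the two conventions
  serve different purposes and are both documented where used.

## Known limitations

Integer-bin realignment only; aggregate-spectrum peak picking may miss
peaks present in a minority of spectra; the built-in encoder ignores
spatial arrangement beyond local variance scales; patient-level
aggregation of predictions (sample-level diagnosis) is deliberately out
of scope — all metrics are spot-level.
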