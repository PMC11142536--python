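"""Synthetic paired-modality cohort generator.

Emulates a histology-guided IMS study of melanocytic lesions: a cohort of
patients, each contributing ~21 annotated 50-um spots, where every spot
yields one profile mass spectrum and one registered H&E patch, and all of a
patient's spots carry the patient's diagnosis (melanoma or nevus).

Spectra are built from an analytically transparent generative family:
a smooth decaying baseline, Gaussian peaks at cohort-fixed m/z centers whose
mean heights differ between classes by ``ims_effect_size``, i.i.d. Gaussian
bin noise, a per-spot lognormal TIC factor, and an integer per-spot m/z
jitter.  Patches are filtered-noise textures: a stained-background color
field with dark nuclear blobs whose density and color statistics shift with
``morph_effect_size``.  Neither family aims at biochemical or stain realism;
they exist so that every downstream stage has a measurable, tunable signal.

Complementary-signal regimes are implemented at the *patient* level: a
configurable fraction of patients is flagged uninformative in one modality
and receives class-neutral data there, so fusing modalities can genuinely
beat either alone under patient-grouped validation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .spectra import Spectrum

__all__ = [
    "MELANOMA",
    "NEVUS",
    "CohortConfig",
    "SpotRecord",
    "PatientEffects",
    "Patch",
    "SyntheticCohort",
    "CohortConfigError",
    "generate_cohort",
    "generate_spectrum",
    "generate_patch",
    "signal_peak_bins",
    "write_cohort",
    "load_cohort",
]

MELANOMA = "melanoma"
NEVUS = "nevus"


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and nuisance parameters of the synthetic cohort.

    Effect sizes are expressed on the raw intensity scale of the generative
    model: ``ims_effect_size`` is the difference between class mean peak
    heights (the per-bin noise has sd ``noise_sd``, so effect/noise_sd is
    the per-peak standardized separation); ``morph_effect_size`` scales both
    the nuclear blob density difference and the background color shift of
    melanoma patches.
    """

    n_patients: int = 60
    spots_per_patient_mean: float = 21.0
    class_prevalence: float = 0.5
    mz_min: float = 700.0
    mz_max: float = 3500.0
    n_axis_bins: int = 600
    n_signal_peaks: int = 10
    ims_effect_size: float = 0.6
    morph_effect_size: float = 1.2
    frac_ims_uninformative_patients: float = 0.0
    frac_morph_uninformative_patients: float = 0.0
    noise_sd: float = 0.4
    baseline_amplitude: float = 1.0
    mz_jitter_bins: int = 1
    tic_scale_sd: float = 0.15
    ims_patient_sd: float = 0.15
    morph_patient_sd: float = 5.0
    patch_px: int = 96
    pixel_size_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_axis_bins": self.n_axis_bins,
            "n_signal_peaks": self.n_signal_peaks,
            "patch_px": self.patch_px,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise CohortConfigError(f"{name} must be a count >= 1 (got {value!r})")
        if self.n_axis_bins < 2:
            raise CohortConfigError("n_axis_bins must be >= 2")
        if self.patch_px < 8:
            raise CohortConfigError("patch_px must be >= 8")
        if self.spots_per_patient_mean <= 0:
            raise CohortConfigError("spots_per_patient_mean must be positive")
        if not 0.0 < self.class_prevalence < 1.0:
            raise CohortConfigError("class_prevalence must lie in (0, 1)")
        if not 700.0 <= self.mz_min < self.mz_max <= 3500.0:
            raise CohortConfigError(
                "mz range must satisfy 700 <= mz_min < mz_max <= 3500"
            )
        fracs = {
            "frac_ims_uninformative_patients": self.frac_ims_uninformative_patients,
            "frac_morph_uninformative_patients": self.frac_morph_uninformative_patients,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise CohortConfigError(f"{name} must lie in [0, 1] (got {value!r})")
        nonneg = {
            "ims_effect_size": self.ims_effect_size,
            "morph_effect_size": self.morph_effect_size,
            "noise_sd": self.noise_sd,
            "baseline_amplitude": self.baseline_amplitude,
            "tic_scale_sd": self.tic_scale_sd,
            "ims_patient_sd": self.ims_patient_sd,
            "morph_patient_sd": self.morph_patient_sd,
            "pixel_size_um": self.pixel_size_um,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise CohortConfigError(f"{name} must be >= 0 (got {value!r})")
        if self.pixel_size_um <= 0:
            raise CohortConfigError("pixel_size_um must be positive")
        if int(self.mz_jitter_bins) != self.mz_jitter_bins or self.mz_jitter_bins < 0:
            raise CohortConfigError("mz_jitter_bins must be an integer >= 0")


@dataclass(frozen=True)
class SpotRecord:
    """One annotated spot: identity, diagnosis and (optional) slide position."""

    patient_id: str
    spot_id: str
    label: str
    center_xy: tuple[int, int] | None = None
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        if self.label not in (MELANOMA, NEVUS):
            raise CohortConfigError(f"label must be melanoma or nevus, got {self.label!r}")


@dataclass(frozen=True)
class PatientEffects:
    """Ground-truth per-patient annotation of where the class signal lives.

    Besides the informativeness flags, a patient carries class-neutral
    random effects shared by all of their spots — per-peak intensity offsets
    and a patch color offset — modelling biological and pre-analytical
    heterogeneity between biopsies.  ``None`` means no offset.
    """

    patient_id: str
    label: str
    ims_informative: bool = True
    morph_informative: bool = True
    peak_height_offsets: np.ndarray | None = None
    color_offset: np.ndarray | None = None
    density_offset: float = 0.0


@dataclass
class Patch:
    """RGB H&E-like image patch for one spot (square, values in [0, 255])."""

    pixels: np.ndarray
    pixel_size: float = 0.5
    spot_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise CohortConfigError("patch must be H x W x 3")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise CohortConfigError("patch must be square")
        if self.pixels.shape[0] < 8:
            raise CohortConfigError("patch side must be >= 8 pixels")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SyntheticCohort:
    records: list[SpotRecord]
    spectra: list[Spectrum]
    patches: list[Patch]
    effects: list[PatientEffects]
    config: CohortConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])

    @property
    def spot_ids(self) -> np.ndarray:
        return np.array([r.spot_id for r in self.records])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "spot_id": self.spot_ids,
                "label": self.labels,
                "pixel_size_um": [r.pixel_size for r in self.records],
            }
        ).set_index("spot_id")


def signal_peak_bins(config: CohortConfig) -> np.ndarray:
    """Cohort-fixed axis bin indices of the class-informative peaks.

    Centers are placed evenly across the interior 80% of the axis with a
    small deterministic jitter derived from the cohort seed, keeping peaks
    well separated from each other and from the axis edges.
    """
    rng = np.random.default_rng(config.seed + 101)
    n = config.n_signal_peaks
    lo, hi = 0.1 * config.n_axis_bins, 0.9 * config.n_axis_bins
    base = np.linspace(lo, hi, n)
    spacing = (hi - lo) / max(n - 1, 1)
    jitter = rng.uniform(-0.2, 0.2, size=n) * spacing
    bins = np.clip(np.rint(base + jitter).astype(int), 1, config.n_axis_bins - 2)
    return np.unique(bins)


def _peak_signs(config: CohortConfig, n: int) -> np.ndarray:
    # alternate up-in-melanoma / up-in-nevus so TIC differences stay small
    return np.where(np.arange(n) % 2 == 0, 1.0, -1.0)


def _axis_centers(config: CohortConfig) -> np.ndarray:
    return np.linspace(config.mz_min, config.mz_max, config.n_axis_bins)


def generate_spectrum(
    label: str,
    patient_effects: PatientEffects,
    config: CohortConfig,
    rng: np.random.Generator,
    spot_id: str | None = None,
) -> Spectrum:
    """Draw one profile spectrum from the generative model.

    Intensity = TIC factor x max(0, baseline + class peak template + noise),
    with the peak template translated by a per-spot integer m/z jitter.
    IMS-uninformative patients receive the class-neutral template.
    """
    if label not in (MELANOMA, NEVUS):
        raise CohortConfigError(f"invalid label {label!r}")
    n = config.n_axis_bins
    mz = _axis_centers(config)
    peak_bins = signal_peak_bins(config)
    signs = _peak_signs(config, len(peak_bins))

    base_height = 2.0
    if patient_effects.ims_informative:
        delta = 0.5 * config.ims_effect_size * signs
        heights = base_height + (delta if label == MELANOMA else -delta)
    else:
        heights = np.full(len(peak_bins), base_height)
    if patient_effects.peak_height_offsets is not None:
        heights = heights + patient_effects.peak_height_offsets[: len(peak_bins)]

    # fixed draw order: jitter, bin noise, TIC factor
    jitter = int(rng.integers(-config.mz_jitter_bins, config.mz_jitter_bins + 1)) \
        if config.mz_jitter_bins > 0 else 0
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    tic = float(np.exp(rng.normal(0.0, config.tic_scale_sd))) \
        if config.tic_scale_sd > 0 else 1.0

    idx = np.arange(n)
    baseline = config.baseline_amplitude * np.exp(-3.0 * idx / n)
    template = np.zeros(n)
    width = 2.0  # peak sd in bins
    for b, h in zip(peak_bins + jitter, heights):
        template += h * np.exp(-0.5 * ((idx - b) / width) ** 2)
    intensity = tic * np.maximum(baseline + template + noise, 0.0)
    return Spectrum(mz=mz, intensity=intensity, spot_id=spot_id)


# H&E-like palette: eosin-pink background, hematoxylin-purple nuclei
_BACKGROUND_RGB = np.array([205.0, 170.0, 205.0])
_NUCLEUS_RGB = np.array([90.0, 60.0, 130.0])
_MELANOMA_COLOR_SHIFT = np.array([-10.0, -14.0, -6.0])  # per unit effect size
_BASE_BLOB_DENSITY = 0.08
_DENSITY_CLASS_FACTOR = 0.15   # relative density increase per unit effect size
_DENSITY_JITTER_SD = 0.08      # per-patch relative density noise
_DENSITY_PATIENT_SD = 0.08     # per-patient relative density offset
_COLOR_JITTER_SD = 8.0
_PIXEL_NOISE_SD = 4.0


def generate_patch(
    label: str,
    patient_effects: PatientEffects,
    config: CohortConfig,
    rng: np.random.Generator,
    spot_id: str | None = None,
) -> Patch:
    """Draw one RGB patch from the texture model.

    A smoothed Gaussian noise field is thresholded into nuclear blobs; for
    informative melanoma patients the blob density rises and the background
    shifts toward hematoxylin, both in proportion to ``morph_effect_size``.
    """
    if label not in (MELANOMA, NEVUS):
        raise CohortConfigError(f"invalid label {label!r}")
    px = config.patch_px
    effect = config.morph_effect_size if (
        patient_effects.morph_informative and label == MELANOMA) else 0.0

    background = _BACKGROUND_RGB + effect * _MELANOMA_COLOR_SHIFT
    if patient_effects.color_offset is not None:
        background = background + patient_effects.color_offset

    # fixed draw order: color jitter, density jitter, texture field, pixel noise
    color_jitter = rng.normal(0.0, _COLOR_JITTER_SD, size=3)
    density_jitter = rng.normal(0.0, _DENSITY_JITTER_SD)
    density = _BASE_BLOB_DENSITY * max(
        0.05,
        1.0 + _DENSITY_CLASS_FACTOR * effect
        + patient_effects.density_offset + density_jitter,
    )
    fld = gaussian_filter(rng.standard_normal((px, px)), sigma=px / 16.0)
    blob_mask = fld > np.quantile(fld, 1.0 - min(density, 0.5))
    pixel_noise = rng.normal(0.0, _PIXEL_NOISE_SD, size=(px, px, 3))

    img = np.empty((px, px, 3))
    img[:] = background + color_jitter
    img[blob_mask] = _NUCLEUS_RGB
    img = np.clip(img + pixel_noise, 0.0, 255.0)
    return Patch(pixels=np.rint(img).astype(np.uint8),
                 pixel_size=config.pixel_size_um, spot_id=spot_id)


def _assign_patient_effects(
    config: CohortConfig, labels: list[str], rng: np.random.Generator
) -> list[PatientEffects]:
    n = config.n_patients
    k_ims = int(round(config.frac_ims_uninformative_patients * n))
    k_morph = int(round(config.frac_morph_uninformative_patients * n))
    order = rng.permutation(n)
    # disjoint sets whenever the fractions allow it; otherwise wrap around
    ims_off = set(order[:k_ims].tolist())
    morph_off = set(order[k_ims:k_ims + k_morph].tolist())
    if k_ims + k_morph > n:
        morph_off |= set(order[: k_ims + k_morph - n].tolist())
    n_peaks = len(signal_peak_bins(config))
    # patient-level displacement along the class axis of peak space: a
    # patient's whole spectrum looks systematically more melanoma- or more
    # nevus-like, which is what limits patient-level discriminability
    signs = _peak_signs(config, n_peaks)
    if config.ims_patient_sd > 0:
        z = rng.normal(0.0, config.ims_patient_sd, size=n)
        peak_offsets = 0.5 * z[:, None] * signs[None, :]
    else:
        peak_offsets = np.zeros((n, n_peaks))
    color_offsets = rng.normal(0.0, config.morph_patient_sd, size=(n, 3)) \
        if config.morph_patient_sd > 0 else np.zeros((n, 3))
    density_offsets = rng.normal(0.0, _DENSITY_PATIENT_SD, size=n) \
        if config.morph_patient_sd > 0 else np.zeros(n)
    return [
        PatientEffects(
            patient_id=f"P{i:04d}",
            label=labels[i],
            ims_informative=i not in ims_off,
            morph_informative=i not in morph_off,
            peak_height_offsets=peak_offsets[i],
            color_offset=color_offsets[i],
            density_offset=float(density_offsets[i]),
        )
        for i in range(n)
    ]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full paired-modality cohort.

    Returns one spectrum and one patch per spot, all of a patient's spots
    sharing that patient's label.  Spot counts per patient are Poisson
    (``spots_per_patient_mean``) truncated at 1.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_mel = int(np.clip(round(config.class_prevalence * n), 1, n - 1)) if n > 1 else 1
    labels = [MELANOMA] * n_mel + [NEVUS] * (n - n_mel)
    labels = [labels[i] for i in rng.permutation(n)]
    effects = _assign_patient_effects(config, labels, rng)

    records: list[SpotRecord] = []
    spectra: list[Spectrum] = []
    patches: list[Patch] = []
    grid_cols = int(np.ceil(np.sqrt(n * config.spots_per_patient_mean)))
    spacing = config.patch_px + 8
    k = 0
    for i, eff in enumerate(effects):
        n_spots = max(1, int(rng.poisson(config.spots_per_patient_mean)))
        for s in range(n_spots):
            spot_id = f"P{i:04d}_S{s:03d}"
            center = ((k % grid_cols) * spacing + spacing // 2,
                      (k // grid_cols) * spacing + spacing // 2)
            records.append(SpotRecord(
                patient_id=eff.patient_id, spot_id=spot_id, label=eff.label,
                center_xy=center, pixel_size=config.pixel_size_um,
            ))
            spectra.append(generate_spectrum(eff.label, eff, config, rng, spot_id))
            patches.append(generate_patch(eff.label, eff, config, rng, spot_id))
            k += 1
    return SyntheticCohort(records=records, spectra=spectra, patches=patches,
                           effects=effects, config=config)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write manifest CSV, per-spot spectrum CSVs and PNG patches."""
    out = Path(outdir)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    (out / "patches").mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "spot_id", "label", "pixel_size_um"])
        for r in cohort.records:
            writer.writerow([r.patient_id, r.spot_id, r.label, r.pixel_size])
    for spec in cohort.spectra:
        pd.DataFrame({"mz": spec.mz, "intensity": spec.intensity}).to_csv(
            out / "spectra" / f"{spec.spot_id}.csv", index=False)
    for patch in cohort.patches:
        Image.fromarray(patch.pixels).save(out / "patches" / f"{patch.spot_id}.png")
    return out


def load_cohort(indir: str | Path) -> tuple[list[SpotRecord], list[Spectrum], list[Patch]]:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    records, spectra, patches = [], [], []
    for row in manifest.itertuples(index=False):
        records.append(SpotRecord(
            patient_id=str(row.patient_id), spot_id=str(row.spot_id),
            label=str(row.label), pixel_size=float(row.pixel_size_um),
        ))
        df = pd.read_csv(indir / "spectra" / f"{row.spot_id}.csv")
        spectra.append(Spectrum(mz=df["mz"].to_numpy(),
                                intensity=df["intensity"].to_numpy(),
                                spot_id=str(row.spot_id)))
        img = np.asarray(Image.open(indir / "patches" / f"{row.spot_id}.png"))
        patches.append(Patch(pixels=img, pixel_size=float(row.pixel_size_um),
                             spot_id=str(row.spot_id)))
    return records, spectra, patches
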