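"""Profile-spectrum preprocessing for spot-based MALDI imaging mass spectrometry.

Each annotated tissue spot yields one profile spectrum over an m/z range
(700-3500 Da for tryptic peptides in the intended application).  The chain
implemented here mirrors standard IMS practice:

    resample to a common m/z axis -> baseline subtraction -> TIC
    normalization -> spectral realignment -> peak detection -> peak matrix

Peak detection operates on the *mean* spectrum of a training cohort; the
resulting peak list is then applied to every spectrum, so held-out data
never influences the feature definition.  :class:`IMSPipeline` packages the
fit (reference + peak list) / transform (per-spot feature rows) split so the
chain can be refit inside cross-validation folds without leakage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "AxisSpec",
    "PeakList",
    "SpectrumError",
    "ZeroTICError",
    "resample_to_axis",
    "subtract_baseline",
    "tic_normalize",
    "realign_spectrum",
    "detect_peaks",
    "build_peak_matrix",
    "mean_spectrum",
    "IMSPipeline",
]


class SpectrumError(ValueError):
    """Raised for invalid spectra or spectrum operations."""


class ZeroTICError(SpectrumError):
    """Raised when a spectrum with zero total ion current is normalized."""


@dataclass
class Spectrum:
    """A single profile mass spectrum for one spot.

    Parameters
    ----------
    mz : array of m/z values in Da, strictly increasing.
    intensity : array of intensities (arbitrary units), same length as mz.
    spot_id : optional identifier of the originating spot.
    """

    mz: np.ndarray
    intensity: np.ndarray
    spot_id: str | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("mz and intensity must be 1-D arrays")
        if len(self.mz) != len(self.intensity):
            raise SpectrumError(
                f"mz and intensity lengths differ ({len(self.mz)} vs "
                f"{len(self.intensity)}) for spot {self.spot_id!r}"
            )
        if len(self.mz) < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise SpectrumError(f"mz must be strictly increasing (spot {self.spot_id!r})")

    def __len__(self) -> int:
        return len(self.mz)

    def copy_with(self, intensity: np.ndarray) -> "Spectrum":
        return Spectrum(mz=self.mz, intensity=np.asarray(intensity, dtype=float),
                        spot_id=self.spot_id)


@dataclass(frozen=True)
class AxisSpec:
    """Uniform common m/z axis: ``n_bins`` centers spanning [mz_min, mz_max]."""

    mz_min: float = 700.0
    mz_max: float = 3500.0
    n_bins: int = 600

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise SpectrumError("AxisSpec requires mz_min < mz_max")
        if self.n_bins < 2:
            raise SpectrumError("AxisSpec requires n_bins >= 2")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.mz_min, self.mz_max, self.n_bins)

    @property
    def bin_width(self) -> float:
        return (self.mz_max - self.mz_min) / (self.n_bins - 1)


@dataclass(frozen=True)
class PeakList:
    """Detected peak centers (Da) plus the half-width, in bins, of the
    integration window used when assembling the peak matrix."""

    centers: np.ndarray
    window_halfwidth: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        if self.centers.ndim != 1:
            raise SpectrumError("peak centers must be 1-D")
        if len(self.centers) > 1 and not np.all(np.diff(self.centers) > 0):
            raise SpectrumError("peak centers must be strictly increasing")
        if self.window_halfwidth < 0:
            raise SpectrumError("window_halfwidth must be >= 0")

    def __len__(self) -> int:
        return len(self.centers)


def resample_to_axis(spectrum: Spectrum, axis: AxisSpec) -> Spectrum:
    """Linearly interpolate a spectrum onto the common axis.

    Bins outside the input's m/z support are set to 0.  Raises if the input
    does not overlap the axis at all.
    """
    if spectrum.mz[-1] < axis.mz_min or spectrum.mz[0] > axis.mz_max:
        raise SpectrumError(
            f"spectrum for spot {spectrum.spot_id!r} (m/z "
            f"{spectrum.mz[0]:.1f}-{spectrum.mz[-1]:.1f}) does not overlap axis "
            f"[{axis.mz_min}, {axis.mz_max}]"
        )
    out = np.interp(axis.centers, spectrum.mz, spectrum.intensity, left=0.0, right=0.0)
    return Spectrum(mz=axis.centers, intensity=out, spot_id=spectrum.spot_id)


def subtract_baseline(spectrum: Spectrum, window: int = 51) -> Spectrum:
    """Remove a slowly varying baseline.

    The baseline estimate is a centered rolling minimum over ``window`` bins
    followed by a centered rolling mean over the same window (edges handled
    by replicating the boundary value).  The estimate is subtracted and the
    result clipped at zero.
    """
    if window < 1 or window % 2 == 0:
        raise SpectrumError("baseline window must be odd and >= 1")
    if window > len(spectrum):
        raise SpectrumError(
            f"baseline window {window} exceeds spectrum length {len(spectrum)}"
        )
    rolled_min = minimum_filter1d(spectrum.intensity, size=window, mode="nearest")
    baseline = uniform_filter1d(rolled_min, size=window, mode="nearest")
    return spectrum.copy_with(np.maximum(spectrum.intensity - baseline, 0.0))


def tic_normalize(spectrum: Spectrum, target_sum: float = 1.0) -> Spectrum:
    """Scale intensities so the total ion current equals ``target_sum``."""
    if target_sum <= 0:
        raise SpectrumError("target_sum must be positive")
    total = float(spectrum.intensity.sum())
    if total <= 0:
        raise ZeroTICError(
            f"spot {spectrum.spot_id!r} has zero total ion current; cannot normalize"
        )
    return spectrum.copy_with(spectrum.intensity * (target_sum / total))


def realign_spectrum(
    spectrum: Spectrum, reference: Spectrum, max_shift: int = 5
) -> tuple[Spectrum, int]:
    """Correct an integer-bin mass shift against a reference spectrum.

    The detected shift maximizes the cross-correlation
    ``sum_i x[i + lag] * ref[i]`` over lags in [-max_shift, max_shift]
    (ties broken toward lag 0).  The output is the input translated by
    ``-shift`` with vacated bins set to 0, so a spectrum displaced by +s
    bins relative to the reference is restored.
    """
    if max_shift < 0:
        raise SpectrumError("max_shift must be >= 0")
    if len(spectrum) != len(reference):
        raise SpectrumError("spectrum and reference must share one axis")
    x = spectrum.intensity
    ref = reference.intensity
    n = len(x)
    best_lag, best_corr = 0, -np.inf
    # visit lags by increasing |lag| so ties resolve toward 0
    for lag in sorted(range(-max_shift, max_shift + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            corr = float(np.dot(x[lag:], ref[: n - lag]))
        else:
            corr = float(np.dot(x[: n + lag], ref[-lag:]))
        if corr > best_corr:
            best_corr, best_lag = corr, lag
    if max_shift > 0 and abs(best_lag) == max_shift:
        logger.warning(
            "realignment hit the search boundary (lag %d) for spot %r",
            best_lag, spectrum.spot_id,
        )
    out = np.zeros_like(x)
    s = best_lag
    if s >= 0:
        out[: n - s] = x[s:]
    else:
        out[-s:] = x[: n + s]
    return spectrum.copy_with(out), best_lag


def _mad_noise(intensity: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * MAD of the first difference / sqrt(2)."""
    d = np.diff(intensity)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0))


def detect_peaks(
    mean_spectrum: Spectrum, snr_min: float = 3.0, window_halfwidth: int = 2
) -> PeakList:
    """Pick peaks on a (preprocessed) mean spectrum.

    A peak is a strict local maximum (greater than both neighbors; endpoints
    excluded) whose height is at least ``snr_min`` times the robust noise
    estimate derived from the first difference of the intensities.
    """
    if snr_min <= 0:
        raise SpectrumError("snr_min must be positive")
    y = mean_spectrum.intensity
    noise = _mad_noise(y)
    interior = np.arange(1, len(y) - 1)
    is_max = (y[interior] > y[interior - 1]) & (y[interior] > y[interior + 1])
    idx = interior[is_max]
    idx = idx[y[idx] >= snr_min * noise]
    return PeakList(centers=mean_spectrum.mz[idx], window_halfwidth=window_halfwidth)


def mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise mean of spectra sharing a common axis."""
    if not spectra:
        raise SpectrumError("cannot average an empty spectrum list")
    mz = spectra[0].mz
    for s in spectra[1:]:
        if len(s) != len(mz) or not np.array_equal(s.mz, mz):
            raise SpectrumError("all spectra must share the common axis")
    stack = np.stack([s.intensity for s in spectra])
    return Spectrum(mz=mz, intensity=stack.mean(axis=0), spot_id=None)


def build_peak_matrix(spectra: list[Spectrum], peaks: PeakList) -> pd.DataFrame:
    """Assemble the spots x peaks feature block.

    Entry (i, j) is the sum of intensities of spectrum i within
    ``window_halfwidth`` bins of peak center j.  Returns a DataFrame with
    spot ids as the index and peak m/z centers as columns.
    """
    if not spectra:
        raise SpectrumError("no spectra given")
    mz = spectra[0].mz
    for s in spectra[1:]:
        if len(s) != len(mz) or not np.array_equal(s.mz, mz):
            raise SpectrumError("all spectra must share the common axis")
    if peaks.centers.size and (
        peaks.centers[0] < mz[0] or peaks.centers[-1] > mz[-1]
    ):
        raise SpectrumError("peak center outside the spectrum axis")
    # snap each center to its nearest axis bin
    right = np.clip(np.searchsorted(mz, peaks.centers), 1, len(mz) - 1)
    left = right - 1
    centers_idx = np.where(
        np.abs(mz[left] - peaks.centers) <= np.abs(mz[right] - peaks.centers),
        left, right,
    )
    w = peaks.window_halfwidth
    stack = np.stack([s.intensity for s in spectra])
    cols = np.empty((stack.shape[0], len(peaks)))
    for j, i in enumerate(centers_idx):
        lo, hi = max(0, i - w), min(len(mz), i + w + 1)
        cols[:, j] = stack[:, lo:hi].sum(axis=1)
    spot_ids = [s.spot_id if s.spot_id is not None else str(i)
                for i, s in enumerate(spectra)]
    return pd.DataFrame(cols, index=pd.Index(spot_ids, name="spot_id"),
                        columns=peaks.centers)


@dataclass
class IMSPipeline:
    """Fit/transform wrapper around the preprocessing chain.

    ``fit`` consumes *training* spectra only: it resamples, baseline-corrects
    and TIC-normalizes them, builds the realignment reference (their mean),
    realigns them against it, and detects peaks on the realigned mean.
    ``transform`` applies the per-spot steps plus realignment against the
    fitted reference and returns peak-matrix rows; it never changes the
    fitted state, so held-out spots cannot leak into the feature definition.
    """

    axis: AxisSpec = field(default_factory=AxisSpec)
    baseline_window: int = 51
    max_shift: int = 5
    snr_min: float = 3.0
    window_halfwidth: int = 2
    drop_zero_tic: bool = True

    reference_: Spectrum | None = field(default=None, repr=False)
    peaks_: PeakList | None = field(default=None, repr=False)

    def _per_spot(self, spectrum: Spectrum) -> Spectrum | None:
        s = resample_to_axis(spectrum, self.axis)
        s = subtract_baseline(s, self.baseline_window)
        try:
            return tic_normalize(s)
        except ZeroTICError:
            if self.drop_zero_tic:
                logger.warning("dropping zero-TIC spot %r", spectrum.spot_id)
                return None
            raise

    def fit(self, spectra: list[Spectrum]) -> "IMSPipeline":
        prepped = [p for p in (self._per_spot(s) for s in spectra) if p is not None]
        if not prepped:
            raise SpectrumError("no usable training spectra (all zero-TIC?)")
        self.reference_ = mean_spectrum(prepped)
        aligned = [realign_spectrum(p, self.reference_, self.max_shift)[0]
                   for p in prepped]
        self.peaks_ = detect_peaks(mean_spectrum(aligned), self.snr_min,
                                   self.window_halfwidth)
        return self

    def transform(self, spectra: list[Spectrum]) -> pd.DataFrame:
        if self.reference_ is None or self.peaks_ is None:
            raise SpectrumError("IMSPipeline.transform called before fit")
        out = []
        for s in spectra:
            p = self._per_spot(s)
            if p is None:
                continue
            out.append(realign_spectrum(p, self.reference_, self.max_shift)[0])
        return build_peak_matrix(out, self.peaks_)

    def fit_transform(self, spectra: list[Spectrum]) -> pd.DataFrame:
        return self.fit(spectra).transform(spectra)
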