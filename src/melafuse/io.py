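"""File interchange: imzML spectra, feature-matrix CSVs with JSON sidecars.

Real profile-mode IMS data usually arrives as imzML; synthetic cohorts are
written as per-spot CSVs plus PNG patches (see :mod:`melafuse.cohort`).
Feature matrices (peaks or embeddings) are stored as CSV with spot ids as
the index and a JSON sidecar recording how they were produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import AxisSpec, PeakList, Spectrum, SpectrumError

__all__ = [
    "write_imzml",
    "read_imzml",
    "save_feature_matrix",
    "load_feature_matrix",
]


def write_imzml(spectra: list[Spectrum], path: str | Path) -> Path:
    """Write spectra sharing one m/z axis as continuous-mode imzML.

    Spots are laid out on a 1 x n grid; spot ids are preserved in the
    companion ``<path>.spots.json`` since imzML itself only stores
    coordinates.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not spectra:
        raise SpectrumError("no spectra to write")
    mz = spectra[0].mz
    for s in spectra[1:]:
        if len(s) != len(mz) or not np.array_equal(s.mz, mz):
            raise SpectrumError("continuous-mode imzML needs one shared m/z axis")
    path = Path(path)
    with ImzMLWriter(str(path), mode="continuous") as writer:
        for i, s in enumerate(spectra):
            writer.addSpectrum(s.mz, s.intensity, (i + 1, 1, 1))
    ids = [s.spot_id if s.spot_id is not None else str(i)
           for i, s in enumerate(spectra)]
    Path(str(path) + ".spots.json").write_text(json.dumps(ids))
    return path


def read_imzml(path: str | Path) -> list[Spectrum]:
    """Read an imzML file (continuous or processed mode) into spectra.

    Spot ids come from the ``.spots.json`` sidecar when present, otherwise
    from the pixel coordinates.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    parser = ImzMLParser(str(path))
    sidecar = Path(str(path) + ".spots.json")
    ids = json.loads(sidecar.read_text()) if sidecar.exists() else None
    out = []
    for i, (x, y, z) in enumerate(parser.coordinates):
        mz, intensity = parser.getspectrum(i)
        spot_id = ids[i] if ids is not None else f"x{x}_y{y}_z{z}"
        out.append(Spectrum(mz=np.asarray(mz, dtype=float),
                            intensity=np.asarray(intensity, dtype=float),
                            spot_id=spot_id))
    return out


def save_feature_matrix(matrix: pd.DataFrame, path: str | Path,
                        metadata: dict | None = None,
                        axis: AxisSpec | None = None,
                        peaks: PeakList | None = None) -> Path:
    """Write a spots x features matrix as CSV plus a JSON sidecar."""
    path = Path(path)
    matrix.to_csv(path)
    sidecar = dict(metadata or {})
    if axis is not None:
        sidecar["axis"] = asdict(axis)
    if peaks is not None:
        sidecar["peaks"] = {"centers": peaks.centers.tolist(),
                            "window_halfwidth": peaks.window_halfwidth}
    sidecar["shape"] = list(matrix.shape)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_feature_matrix(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a matrix written by :func:`save_feature_matrix`."""
    path = Path(path)
    matrix = pd.read_csv(path, index_col=0)
    sidecar = Path(str(path) + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return matrix, meta
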