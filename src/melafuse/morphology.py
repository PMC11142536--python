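"""Patch extraction and morphology embedding ("vector embedding morphology").

Every annotated spot has a physical footprint of 48 um x 48 um on the H&E
slide; at 20x scanning resolution (0.5 um/px) that is a 96x96 patch, at 40x
(0.25 um/px) a 192x192 patch.  Patches are resized to a common encoder input
side (224 px), channel-normalized, and mapped to a fixed-length embedding
(512-d by default).

The encoder is a pluggable callable ``(preprocessed tensor, spec) -> vector``.
The built-in default is a deterministic hand-crafted texture encoder:
per-channel intensity histograms, gradient-magnitude histograms and
multi-scale local-variance summaries, projected to the embedding dimension
by a fixed seeded random projection and scaled to unit norm.  Any external
pre-trained network can be dropped in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .cohort import Patch

__all__ = [
    "EmbedderSpec",
    "EncoderError",
    "extract_patch",
    "preprocess_patch",
    "builtin_texture_encoder",
    "embed_patch",
    "embed_patches",
]


class EncoderError(ValueError):
    """Raised for encoder interface violations or invalid patches."""


@dataclass(frozen=True)
class EmbedderSpec:
    """Configuration of the embedding stage.

    channel_means / channel_sds are applied after scaling pixels to [0, 1];
    the defaults (0.5, 0.5) map pixel values to roughly [-1, 1].
    """

    name: str = "builtin-texture"
    embed_dim: int = 512
    input_side: int = 224
    channel_means: tuple[float, float, float] = (0.5, 0.5, 0.5)
    channel_sds: tuple[float, float, float] = (0.5, 0.5, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise EncoderError("embed_dim must be >= 1")
        if self.input_side < 8:
            raise EncoderError("input_side must be >= 8")
        if any(sd <= 0 for sd in self.channel_sds):
            raise EncoderError("channel_sds must be positive")


def extract_patch(
    image: np.ndarray,
    center_xy: tuple[int, int],
    physical_side: float = 48.0,
    pixel_size: float = 0.5,
    spot_id: str | None = None,
) -> Patch:
    """Cut the square spot patch out of a larger RGB image.

    The patch side in pixels is ``round(physical_side / pixel_size)``; the
    patch is the half-open square of that side centered (by flooring) at
    ``center_xy`` = (x, y) in 0-based pixel coordinates.  Patches that would
    cross the image boundary are rejected — no padding.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise EncoderError("source image must be H x W x 3")
    side = int(round(physical_side / pixel_size))
    cx, cy = int(np.floor(center_xy[0])), int(np.floor(center_xy[1]))
    half = side // 2
    x0, y0 = cx - half, cy - half
    x1, y1 = x0 + side, y0 + side
    h, w = image.shape[:2]
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise EncoderError(
            f"patch for spot {spot_id!r} crosses the image boundary "
            f"(requested x [{x0}, {x1}), y [{y0}, {y1}) on a {w}x{h} image)"
        )
    return Patch(pixels=image[y0:y1, x0:x1], pixel_size=pixel_size, spot_id=spot_id)


@lru_cache(maxsize=16)
def _bilinear_matrix(src: int, dst: int) -> np.ndarray:
    """dst x src interpolation matrix for separable bilinear resizing.

    Uses the half-pixel-center convention: destination pixel i samples the
    source at (i + 0.5) * src/dst - 0.5, clamped to the grid.  ``dst == src``
    yields the identity.
    """
    pos = (np.arange(dst) + 0.5) * (src / dst) - 0.5
    pos = np.clip(pos, 0.0, src - 1.0)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, src - 1)
    frac = pos - lo
    mat = np.zeros((dst, src))
    mat[np.arange(dst), lo] += 1.0 - frac
    mat[np.arange(dst), hi] += frac
    return mat


def preprocess_patch(patch: Patch, spec: EmbedderSpec) -> np.ndarray:
    """Bilinear-resize to the encoder input side and channel-normalize.

    Output is a float array of shape (input_side, input_side, 3) holding
    ``(pixel/255 - channel_mean) / channel_sd``.
    """
    px = patch.pixels.astype(float)
    if px.shape[0] != px.shape[1]:
        raise EncoderError("patch must be square")
    if px.shape[0] != spec.input_side:
        # separable bilinear resize: rows then columns, all channels at once
        s, d = px.shape[0], spec.input_side
        mat = _bilinear_matrix(s, d)
        rows = (mat @ px.reshape(s, s * 3)).reshape(d, s, 3)
        cols = (rows.transpose(0, 2, 1).reshape(d * 3, s) @ mat.T)
        px = cols.reshape(d, 3, d).transpose(0, 2, 1)
    means = np.asarray(spec.channel_means)
    sds = np.asarray(spec.channel_sds)
    out = (px / 255.0 - means) / sds
    if not np.all(np.isfinite(out)):
        raise EncoderError("non-finite values after patch preprocessing")
    return out


_HIST_BINS = 16
_VARIANCE_WINDOWS = (3, 7, 15, 31)  # box-filter sides (pixels)


def _fast_hist(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fixed-range density histogram via bincount (clipping outliers into
    the edge bins)."""
    scaled = (values.ravel() - lo) * (_HIST_BINS / (hi - lo))
    idx = np.clip(scaled.astype(np.intp), 0, _HIST_BINS - 1)
    return np.bincount(idx, minlength=_HIST_BINS) / values.size


def _texture_features(tensor: np.ndarray) -> np.ndarray:
    gy, gx = np.gradient(tensor, axis=(0, 1))
    grad = np.hypot(gx, gy)
    local = np.array([
        ((tensor - uniform_filter(tensor, size=(w, w, 1))) ** 2).mean(axis=(0, 1))
        for w in _VARIANCE_WINDOWS
    ])  # (n_windows, 3)
    feats: list[np.ndarray] = []
    for c in range(3):
        ch = tensor[:, :, c]
        feats.append(_fast_hist(ch, -2.0, 2.0))
        feats.append(_fast_hist(grad[:, :, c], 0.0, 2.0))
        feats.append(local[:, c])
        feats.append(np.array([ch.mean(), ch.var()]))
    return np.concatenate(feats)


@lru_cache(maxsize=8)
def _projection_matrix(seed: int, embed_dim: int, n_features: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((embed_dim, n_features)) / np.sqrt(n_features)


def builtin_texture_encoder(tensor: np.ndarray, spec: EmbedderSpec) -> np.ndarray:
    """Deterministic hand-crafted texture encoder.

    Histogram/variance summaries per channel, projected to ``embed_dim`` by
    a Gaussian random projection seeded from ``spec.seed``, then unit-norm
    scaled.  A constant (texture-free) input maps to the fixed fallback
    vector e1 = (1, 0, ..., 0).
    """
    tensor = np.asarray(tensor, dtype=float)
    fallback = np.zeros(spec.embed_dim)
    fallback[0] = 1.0
    if np.ptp(tensor) == 0:
        return fallback
    f = _texture_features(tensor)
    v = _projection_matrix(spec.seed, spec.embed_dim, f.size) @ f
    norm = np.linalg.norm(v)
    if norm == 0:
        return fallback
    return v / norm


Encoder = Callable[[np.ndarray, EmbedderSpec], np.ndarray]


def embed_patch(
    patch: Patch, spec: EmbedderSpec, encoder: Encoder | None = None
) -> np.ndarray:
    """Embed one patch: preprocess then apply the encoder; validate output."""
    encoder = builtin_texture_encoder if encoder is None else encoder
    tensor = preprocess_patch(patch, spec)
    vec = np.asarray(encoder(tensor, spec), dtype=float)
    if vec.shape != (spec.embed_dim,):
        raise EncoderError(
            f"encoder returned shape {vec.shape}, expected ({spec.embed_dim},)"
        )
    if not np.all(np.isfinite(vec)):
        raise EncoderError("encoder returned non-finite values")
    return vec


def embed_patches(
    patches: list[Patch], spec: EmbedderSpec, encoder: Encoder | None = None
) -> pd.DataFrame:
    """Embed a list of patches into a spots x embed_dim DataFrame.

    Rows are indexed by spot id in input order; the embedding of each patch
    depends only on that patch, so processing order cannot change values.
    """
    rows = [embed_patch(p, spec, encoder) for p in patches]
    ids = [p.spot_id if p.spot_id is not None else str(i)
           for i, p in enumerate(patches)]
    return pd.DataFrame(np.vstack(rows) if rows else np.empty((0, spec.embed_dim)),
                        index=pd.Index(ids, name="spot_id"))
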