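"""UMAP projection and hyperspectral RGB rendering of feature blocks.

Three input types are projected with one shared spec: the IMS peak block,
the morphology embedding block and the fused block.  A 2-D projection is
shown as a scatter colored by diagnosis; a 3-D projection is translated to
an RGB color per spot ("hyperspectral visualization") and painted back at
the spot positions on the slide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from PIL import Image

from .cohort import MELANOMA, SpotRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ProjectionSpec",
    "VisualizationError",
    "project",
    "hyperspectral_rgb",
    "render_spot_map",
    "scatter_by_label",
]


class VisualizationError(ValueError):
    """Raised for invalid projection or rendering inputs."""


@dataclass(frozen=True)
class ProjectionSpec:
    """UMAP settings; cosine distance is the default metric."""

    n_components: int = 2
    metric: str = "cosine"
    n_neighbors: int = 15
    min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components not in (2, 3):
            raise VisualizationError("n_components must be 2 or 3")
        if self.n_neighbors < 2:
            raise VisualizationError("n_neighbors must be >= 2")


def project(features, spec: ProjectionSpec) -> np.ndarray:
    """UMAP-project a spots x features matrix to 2-D or 3-D coordinates."""
    import umap  # deferred: numba compilation is slow at import time

    values = features.to_numpy() if hasattr(features, "to_numpy") \
        else np.asarray(features, dtype=float)
    if values.shape[0] < 10:
        raise VisualizationError("need at least 10 rows to project")
    if values.shape[0] <= spec.n_neighbors:
        raise VisualizationError(
            f"{values.shape[0]} rows but n_neighbors={spec.n_neighbors}; "
            "reduce n_neighbors below the row count"
        )
    if not np.all(np.isfinite(values)):
        raise VisualizationError("features must be finite")
    reducer = umap.UMAP(
        n_components=spec.n_components,
        metric=spec.metric,
        n_neighbors=spec.n_neighbors,
        min_dist=spec.min_dist,
        random_state=spec.seed,
    )
    with warnings.catch_warnings():
        # umap warns that a fixed random_state disables parallelism; intended
        warnings.simplefilter("ignore", UserWarning)
        coords = reducer.fit_transform(values)
    return np.asarray(coords, dtype=float)


def hyperspectral_rgb(
    coords3: np.ndarray, clip_percentiles: tuple[float, float] = (1.0, 99.0)
) -> np.ndarray:
    """Map n x 3 coordinates to RGB triples in [0, 255].

    Each column is clipped to its [low, high] percentile range, min-max
    scaled to [0, 255] and rounded; columns map to (R, G, B) in order.
    Constant columns become 128 with a warning.
    """
    coords3 = np.asarray(coords3, dtype=float)
    if coords3.ndim != 2 or coords3.shape[1] != 3:
        raise VisualizationError("hyperspectral mapping needs exactly 3 columns")
    lo_p, hi_p = clip_percentiles
    out = np.empty_like(coords3)
    for c in range(3):
        col = coords3[:, c]
        lo, hi = np.percentile(col, [lo_p, hi_p])
        if hi == lo:
            logger.warning("constant coordinate column %d; channel set to 128", c)
            out[:, c] = 128.0
            continue
        clipped = np.clip(col, lo, hi)
        out[:, c] = np.rint((clipped - lo) / (hi - lo) * 255.0)
    return out.astype(int)


def render_spot_map(
    records: list[SpotRecord],
    colors: np.ndarray,
    spot_radius_px: int = 3,
    path=None,
) -> np.ndarray:
    """Paint spot colors at their slide positions as an RGB image.

    Spots without coordinates are skipped (their count is logged).  Colors
    are written into the canvas unmodified.  Returns the image array; if
    ``path`` is given, also writes a PNG.
    """
    colors = np.asarray(colors, dtype=int)
    if len(colors) != len(records):
        raise VisualizationError("one color per spot record is required")
    placed = [(r, c) for r, c in zip(records, colors) if r.center_xy is not None]
    skipped = len(records) - len(placed)
    if skipped:
        logger.warning("render_spot_map: %d spots without coordinates skipped", skipped)
    if not placed:
        logger.warning("render_spot_map: no spots with coordinates; empty image")
        img = np.full((1, 1, 3), 255, dtype=np.uint8)
    else:
        xs = np.array([r.center_xy[0] for r, _ in placed])
        ys = np.array([r.center_xy[1] for r, _ in placed])
        r0 = spot_radius_px
        x_off, y_off = xs.min() - r0, ys.min() - r0
        w = xs.max() - x_off + r0 + 1
        h = ys.max() - y_off + r0 + 1
        img = np.full((h, w, 3), 255, dtype=np.uint8)
        for rec, color in placed:
            x, y = rec.center_xy[0] - x_off, rec.center_xy[1] - y_off
            img[y - r0:y + r0 + 1, x - r0:x + r0 + 1] = np.clip(color, 0, 255)
    if path is not None:
        Image.fromarray(img).save(path)
    return img


def scatter_by_label(
    coords2: np.ndarray, labels, path=None, title: str = ""
):
    """2-D scatter of projected spots colored by diagnosis (red melanoma,
    blue nevus).  Returns the matplotlib figure; writes PNG if path given."""
    coords2 = np.asarray(coords2, dtype=float)
    if coords2.ndim != 2 or coords2.shape[1] != 2:
        raise VisualizationError("scatter needs n x 2 coordinates")
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lab, color in ((MELANOMA, "tab:red"), ("nevus", "tab:blue")):
        mask = labels == lab
        ax.scatter(coords2[mask, 0], coords2[mask, 1], s=8, c=color, label=lab)
    ax.set_xlabel("UMAP 1")
    ax.set_ylabel("UMAP 2")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
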