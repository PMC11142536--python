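"""Feature-block standardization and multimodal fusion.

Each modality's spots x features block is z-scored per feature using
statistics computed on *training rows only* (the scaler is the leakage
boundary), then the blocks are concatenated with configurable weights —
equal weights by default.  Column provenance (which modality each fused
column came from) is preserved for reporting and for exact block recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["BlockScaler", "FusedMatrix", "FusionError", "fit_scaler", "fuse"]


class FusionError(ValueError):
    """Raised for invalid scaling or fusion inputs."""


@dataclass(frozen=True)
class BlockScaler:
    """Per-feature training mean/sd with a zero-variance feature mask.

    Standard deviations are population (ddof=0).  Zero-variance features are
    masked: their transformed values are exactly 0 whatever the input.
    """

    means: np.ndarray
    sds: np.ndarray
    zero_variance_mask: np.ndarray

    def transform(self, block: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
        values = block.to_numpy() if isinstance(block, pd.DataFrame) else np.asarray(block)
        if values.shape[1] != self.means.size:
            raise FusionError(
                f"block has {values.shape[1]} features, scaler expects {self.means.size}"
            )
        safe_sds = np.where(self.zero_variance_mask, 1.0, self.sds)
        out = (values - self.means) / safe_sds
        out[:, self.zero_variance_mask] = 0.0
        if isinstance(block, pd.DataFrame):
            return pd.DataFrame(out, index=block.index, columns=block.columns)
        return out


def fit_scaler(block: pd.DataFrame | np.ndarray, train_rows) -> BlockScaler:
    """Fit a :class:`BlockScaler` on the given training rows of a block."""
    values = block.to_numpy() if isinstance(block, pd.DataFrame) else np.asarray(block)
    train = values[np.asarray(train_rows)]
    if train.shape[0] < 2:
        raise FusionError("need at least 2 training rows to fit a scaler")
    means = train.mean(axis=0)
    sds = train.std(axis=0)  # population sd
    return BlockScaler(means=means, sds=sds, zero_variance_mask=(sds == 0))


@dataclass
class FusedMatrix:
    """Weighted concatenation of two standardized modality blocks."""

    values: pd.DataFrame
    provenance: np.ndarray  # per-column, "ims" or "morph"

    def __post_init__(self) -> None:
        if self.values.shape[1] != self.provenance.size:
            raise FusionError("provenance length must match column count")

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def block(self, name: str) -> pd.DataFrame:
        """Columns of the fused matrix that came from one modality."""
        if name not in ("ims", "morph"):
            raise FusionError(f"unknown block {name!r}")
        return self.values.loc[:, self.provenance == name]


def fuse(
    ims_block: pd.DataFrame,
    morph_block: pd.DataFrame,
    weights: tuple[float, float] = (1.0, 1.0),
) -> FusedMatrix:
    """Concatenate standardized blocks: [w_ims * IMS | w_morph * morphology].

    Blocks must be row-aligned by spot id; misalignment is an error naming
    the offending ids.
    """
    if not ims_block.index.equals(morph_block.index):
        bad = sorted(set(ims_block.index).symmetric_difference(morph_block.index))
        raise FusionError(f"blocks are not row-aligned; mismatched spot ids: {bad[:10]}")
    w_ims, w_morph = weights
    left = ims_block * w_ims
    right = morph_block * w_morph
    left.columns = [f"ims:{c}" for c in ims_block.columns]
    right.columns = [f"morph:{c}" for c in morph_block.columns]
    values = pd.concat([left, right], axis=1)
    provenance = np.array(["ims"] * ims_block.shape[1] + ["morph"] * morph_block.shape[1])
    return FusedMatrix(values=values, provenance=provenance)
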