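"""Standardize the two modality blocks on training rows and fuse them.

Each block is z-scored per feature with statistics from training rows only
(the leakage boundary), then concatenated with equal weights.  At the
published scale (5558 peaks + 512 embedding dims) the fused width is 6070.
"""

import numpy as np
import pandas as pd

from melafuse import fit_scaler, fuse

rng = np.random.default_rng(4)
ids = pd.Index([f"s{i}" for i in range(8)], name="spot_id")
ims = pd.DataFrame(rng.normal(2.0, 3.0, size=(8, 5558)), index=ids)
morph = pd.DataFrame(rng.normal(0.0, 1.0, size=(8, 512)), index=ids)

train_rows = np.arange(6)  # rows 0-5 are training spots
ims_z = fit_scaler(ims, train_rows).transform(ims)
morph_z = fit_scaler(morph, train_rows).transform(morph)

fused = fuse(ims_z, morph_z, weights=(1.0, 1.0))
print(f"IMS block: {ims.shape[1]} peaks; morphology block: {morph.shape[1]} dims")
print(f"fused width: {fused.width} columns")
print(f"provenance counts: ims={(fused.provenance == 'ims').sum()}, "
      f"morph={(fused.provenance == 'morph').sum()}")
print("training-row column means after scaling:",
      np.round(np.abs(fused.values.to_numpy()[:6].mean(axis=0)).max(), 12))
# 5558 + 512 = 6070; the near-zero training mean confirms the scaler used
# training rows only, so held-out rows keep whatever offset they have.
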