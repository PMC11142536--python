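"""UMAP views of the three feature blocks.

2-D projections (cosine metric) colored by diagnosis for the IMS block, the
morphology block and the fused block, plus the hyperspectral trick: project
to 3-D, map the coordinates to RGB, and paint each spot at its slide
position so morphologically similar regions share a color.
"""

from pathlib import Path

import numpy as np

from melafuse import (CohortConfig, EmbedderSpec, ProjectionSpec, embed_patches,
                      fit_scaler, fuse, generate_cohort, hyperspectral_rgb,
                      project, render_spot_map, scatter_by_label)
from melafuse.spectra import AxisSpec, IMSPipeline

out = Path("scratch/umap_figures")
out.mkdir(parents=True, exist_ok=True)

cohort = generate_cohort(CohortConfig(n_patients=10, spots_per_patient_mean=12.0,
                                      seed=6))
axis = AxisSpec(700, 3500, cohort.config.n_axis_bins)
ims = IMSPipeline(axis=axis).fit_transform(cohort.spectra)
morph = embed_patches(cohort.patches, EmbedderSpec())

rows = np.arange(len(cohort.records))
ims_z = fit_scaler(ims, rows).transform(ims)
morph_z = fit_scaler(morph, rows).transform(morph)
fused = fuse(ims_z, morph_z).values

spec = ProjectionSpec(n_components=2, metric="cosine", seed=0)
for name, block in [("ims", ims_z), ("morphology", morph_z), ("fused", fused)]:
    coords = project(block, spec)
    scatter_by_label(coords, cohort.labels, path=out / f"umap_{name}.png",
                     title=f"{name} block")
    print(f"{name}: projected {block.shape[1]} dims -> 2-D, "
          f"figure at {out}/umap_{name}.png")

coords3 = project(morph_z, ProjectionSpec(n_components=3, metric="cosine", seed=0))
colors = hyperspectral_rgb(coords3)
render_spot_map(cohort.records, colors, path=out / "hyperspectral_map.png")
print(f"hyperspectral spot map at {out}/hyperspectral_map.png")
# Spots with similar morphology embeddings receive similar RGB colors, so
# coherent tissue regions appear as coherent color fields on the map.
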