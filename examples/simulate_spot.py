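"""Generate a synthetic multiplexed-imaging spot and inspect its ground truth.

The spot is a Voronoi tessellation of jittered-grid cells; each marker
raster follows y = beta0(u,v) + beta1(u,v) * MorphScore + noise, so the
true morphology-intensity coupling is known exactly.
"""

import numpy as np

import morphgwr as mg

fields = {
    "markerA": (
        mg.FieldSpec("gaussian-bump", 1.0, 128.0, offset=4.0),  # intercept surface
        mg.FieldSpec("zero-mean-sinusoid", 1.0, 256.0),         # slope surface
    )
}
sample = mg.simulate_sample(
    n_cells=300, shape=(512, 512), beta_fields=fields, noise_sd=0.3, seed=1
)

n = sample.label_image.max()
b0, b1 = sample.truth.beta_at_centroids("markerA")
print(f"cells: {n}, raster: {sample.label_image.shape}")
print(f"true intercept range over cells: [{b0.min():.2f}, {b0.max():.2f}]")
print(f"true slope range over cells:     [{b1.min():.2f}, {b1.max():.2f}]")
print(f"channel intensity range:         [{sample.channels['markerA'].min():.2f}, "
      f"{sample.channels['markerA'].max():.2f}]")
# The slope field has zero spatial mean: a global regression sees almost no
# average morphology effect even though the local effect reaches +/-1.
print(f"spatial mean of true slope:      {b1.mean():+.3f}")
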