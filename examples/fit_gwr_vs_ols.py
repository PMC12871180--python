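"""Fit GWR with AICc bandwidth selection and compare with global baselines.

On data whose morphology-intensity slope varies over space with zero
spatial mean, a global model explains almost nothing while the local
model recovers most of the variance.
"""

import numpy as np

import morphgwr as mg

fields = {
    "m": (
        mg.FieldSpec("gaussian-bump", 1.0, 128.0, offset=4.0),
        mg.FieldSpec("zero-mean-sinusoid", 1.0, 256.0),
    )
}
coords, scores, responses, truth = mg.simulate_cell_table(
    n_cells=300, shape=(512, 512), beta_fields=fields, noise_sd=0.3, seed=4
)
table = mg.ObservationTable.from_arrays(responses["m"], scores, coords)

ols = mg.fit_ols(table)
ridge = mg.fit_ridge(table, lam=1.0)
sel = mg.select_bandwidth(table)
fit = mg.fit_gwr(table, mg.KernelSpec("gaussian", sel.bandwidth))

print(f"selected bandwidth: {sel.bandwidth:.1f} px "
      f"(bounds {sel.bounds[0]:.1f}-{sel.bounds[1]:.1f}, "
      f"at boundary: {sel.at_boundary})")
for name, f in [("OLS", ols), ("ridge", ridge), ("GWR", fit)]:
    m = mg.model_metrics(table.y, f.fitted)
    print(f"{name:>6}:  R2 = {m['r2']:.3f}  MAE = {m['mae']:.3f}  "
          f"AICc = {f.aicc:.1f}")
print(f"delta AICc (OLS - GWR): {ols.aicc - fit.aicc:+.1f}")

# how well the local slope surface is recovered
_, b1_true = truth.beta_at_centroids("m")
rmse = np.sqrt(np.mean((fit.betas[:, 1] - b1_true) ** 2))
print(f"RMSE of recovered slope surface: {rmse:.3f} (amplitude 1.0)")
# Positive delta AICc and the R2 gap show the local model captures the
# spatially varying coupling a global fit cannot represent.
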