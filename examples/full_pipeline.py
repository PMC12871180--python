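"""Run the whole pipeline: simulate -> features -> screen -> fit -> report.

Two spatially heterogeneous markers and two flat ones are generated; the
report contains one row per screened marker with the model comparison.
"""

import tempfile

import morphgwr as mg

HET = (
    mg.FieldSpec("gaussian-bump", 3.0, 96.0, offset=4.0),
    mg.FieldSpec("zero-mean-sinusoid", 1.0, 192.0),
)
FLAT = (mg.FieldSpec("constant", 4.0), mg.FieldSpec("constant", 0.0))

config = mg.RunConfig(
    mode="synthetic",
    out_dir=tempfile.mkdtemp(prefix="morphgwr_"),
    n_cells=150,
    shape=(384, 384),
    beta_fields={"het_a": HET, "het_b": HET, "noise_a": FLAT, "noise_b": FLAT},
    noise_sd=0.2,
    n_perm=199,
    response="mean_intensity",
    seed=3,
)
report = mg.run_pipeline(config)
cols = ["marker", "r2_ols", "r2_gwr", "delta_aicc",
        "morans_resid_ols", "morans_resid_gwr", "bandwidth", "boundary_flag"]
print(report[cols].round(3).to_string(index=False))
print(f"artifacts in {config.out_dir}")
# Only the heterogeneous markers survive the screen; for each, the local
# model improves R2 and AICc and flattens residual spatial structure.
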