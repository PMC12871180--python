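# morphgwr

Spatially local regression of morphology–protein coupling in multiplexed
tissue imaging.

Multiplexed ion beam imaging (MIBI) and related spatial-proteomics
platforms produce one intensity raster per protein marker over a segmented
tissue spot. Most analyses of such data assume the relationship between
cell morphology and marker intensity is the same everywhere in the tissue.
`morphgwr` drops that assumption: it models per-cell marker intensity with
**geographically weighted regression (GWR)**, whose coefficients vary
continuously over the tissue,

```
y_i = β0(u_i, v_i) + Σ_k βk(u_i, v_i) · x_ik + ε_i,
β̂(u, v) = (XᵀW(u, v)X)⁻¹ XᵀW(u, v) y,
```

where `(u_i, v_i)` are cell-centroid coordinates in pixels, `x_ik` are
morphometric predictors (by default a single PCA-derived **MorphScore**),
and `W(u, v)` is a diagonal kernel-weight matrix — Gaussian
`exp(−d²/2b²)` or compact bisquare `(1−(d/b)²)²` — with bandwidth `b`
chosen by minimizing the corrected Akaike criterion
`AICc = 2n·ln σ̂ + n·ln 2π + n(n+tr S)/(n−2−tr S)`, with `tr S` the
hat-matrix trace (effective number of parameters).

The package is aimed at computational pathology / spatial-omics analysts
who want to quantify *where* and *how strongly* tissue morphology couples
to protein dispersion, and to test whether a local model is warranted at
all. It provides:

- a **synthetic-data generator**: Voronoi-tessellated spots with known
  spatially varying coefficient surfaces, so every stage is verifiable
  against ground truth;
- **preprocessing**: robust 1st/99th-percentile rescaling of channel
  rasters, centroid extraction, TIFF/CSV I/O;
- **per-cell features**: positive fraction, integrated density, top-5%
  mean, max, Gini coefficient, blob count (Li threshold with Otsu
  fallback), six morphometrics reduced by PCA to a MorphScore;
- **spatial screening**: Delaunay adjacency with kNN fallback,
  permutation-tested Moran's I / Geary's C marker selection;
- **regression**: GWR with AICc bandwidth selection, OLS and ridge
  baselines, R²/MAE/MSE, ΔAICc and residual-autocorrelation diagnostics;
- an end-to-end **pipeline** with a comparison report, plus a thin CLI
  (`morphgwr simulate|preprocess|features|diagnose|fit|run-all|report`).

## Worked example

`examples/fit_gwr_vs_ols.py` simulates 300 cells on a 512×512 px spot
whose morphology→intensity slope is a zero-mean sinusoid (amplitude 1)
and whose intercept is a Gaussian bump, with noise SD 0.3, then fits the
three models:

```
selected bandwidth: 30.1 px (bounds 30.1-711.3, at boundary: True)
   OLS:  R2 = 0.000  MAE = 0.705  AICc = 838.9
 ridge:  R2 = 0.000  MAE = 0.705  AICc = 838.9
   GWR:  R2 = 0.811  MAE = 0.335  AICc = 580.9
delta AICc (OLS - GWR): +258.0
RMSE of recovered slope surface: 0.252 (amplitude 1.0)
```

Because the local slope averages to zero over the spot, the global models
see no morphology effect at all (R² ≈ 0), while GWR recovers 81% of the
response variance and the sign and shape of the true coefficient surface;
the positive ΔAICc says the extra local parameters are worth their cost.
The selector lands on the minimum feasible bandwidth (boundary flag),
which is the expected behavior when coordinates are in raw pixel units.
The other examples (`simulate_spot.py`, `screen_markers.py`,
`full_pipeline.py`) walk through the generator, the autocorrelation
screen, and the end-to-end report.

## Layout

`src/morphgwr/` — `synthetic`, `preprocess`, `features`, `spatial`,
`gwr`, `pipeline`, `cli`. `docs/methods.md` describes the model,
generator and numerical choices in detail.
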