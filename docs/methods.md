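# Methods

## Model

For cell `i` at centroid `(u_i, v_i)` (pixel units; `(u, v)` = (column,
row), 0-based pixel centers), the response — a per-cell intensity feature
of one marker — is modeled as

    y_i = β0(u_i, v_i) + Σ_k βk(u_i, v_i) x_ik + ε_i,   ε_i ~ N(0, σ²),

with coefficient surfaces that vary continuously over the tissue. The
estimator at a location is kernel-weighted least squares,

    β̂(u, v) = (XᵀW(u, v)X)⁻¹ XᵀW(u, v) y,

with `W = diag(w_1 … w_n)`, `w_j = exp(−d_j²/2b²)` (Gaussian, default) or
`(1−(d_j/b)²)²·1[d_j<b]` (bisquare), `d_j` the Euclidean distance from
observation `j` to the fitting location and `b` the bandwidth in pixels.
Distances are raw pixel distances — no coordinate rescaling — so
bandwidths read directly in image units.

The default design is an intercept plus a single morphometric predictor,
the MorphScore (below); all six morphometrics can be used instead via
configuration. The assumptions are those of any GWR: the coefficient
surfaces are smooth at the scale of the bandwidth, errors are independent
given location, and the model is linear in the predictors at every
location.

## Effective parameters, AICc, bandwidth

Each local fit contributes a leverage `S_ii = w_ii·x_iᵀ(XᵀWX)⁻¹x_i`
(with `w_ii = 1`, the self-weight); their sum `tr S` is the effective
number of parameters. The trace is accumulated row by row — no n×n hat
matrix is materialized, so memory stays linear in n. Model quality is

    AICc = 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S),  σ̂² = RSS/n,

the standard small-sample GWR form. Global OLS is scored with the same
formula at `tr S = p`, and ridge at `tr S = tr[Z(ZᵀZ+λI)⁻¹Zᵀ] + 1`
(centred z-scored predictors, unpenalized intercept), so ΔAICc is on a
common scale across models.

Bandwidth is selected by golden-section search of AICc over
`[b_min, b_max]` with `b_min = 1.5 ×` median nearest-neighbour distance
(the smallest bandwidth at which local designs are reliably well
conditioned), `b_max =` the spot diameter, and a 0.01 px interval
tolerance. Bandwidths where any local design is singular score +∞. The
bounds themselves are scored explicitly (golden section never samples
them), and a result within 2× tolerance of either bound carries an
`at_boundary` flag. On pixel-unit coordinates with AICc selection the
minimizer frequently lands on the `b_min` floor: the criterion's fit gain
from heavier localization outweighs its complexity penalty. The flag
makes this boundary behavior visible rather than hiding it.

Local solves use an SVD of `XᵀWX` with relative rank tolerance 1e-10;
near-singular local designs raise a localized error naming the offending
location index rather than being silently regularized.

Local R² at each location uses the locally weighted residual and total
sums of squares about the locally weighted mean.

## Screening by spatial autocorrelation

The cell graph is the Delaunay triangulation of the centroids (the
natural dual of the Voronoi-like geometry of segmented tissue). Edges
longer than the 99th-percentile edge length (an actual order statistic,
so small graphs are untouched) are pruned to remove convex-hull slivers;
if the triangulation fails or the pruned graph is disconnected, symmetric
k-nearest-neighbour edges (k starting at 6, growing until connected) are
added. Weights are binary adjacency, row-standardized.

Moran's I `(n/S0)·zᵀWz/zᵀz` and Geary's C
`((n−1)/2S0)·Σw_ij(v_i−v_j)²/zᵀz` are tested by permuting values over
nodes; the two-sided p-value compares departures from the null
expectation (−1/(n−1) for I, 1 for C) with a +1 correction, 999
permutations by default. Markers with `p ≤ α = 0.05` are kept, ranked by
|I|, truncated to the top 8. Only screened markers proceed to regression.

## Per-cell features

Channels are first clipped to their 1st/99th intensity percentiles
(computed over all pixels, background included) and rescaled to [0, 1];
a constant channel maps to zeros with a degeneracy flag. Positivity
within a cell uses Li's minimum-cross-entropy threshold with an Otsu
fallback for degenerate inputs (≤ 2 distinct values or non-convergence);
a constant cell has threshold +∞, hence no positive pixels. Features per
cell and marker: positive fraction, integrated density (sum), mean, mean
of the ⌈0.05·n⌉ brightest pixels, maximum, Gini coefficient
(`Σ|v_i−v_j|/2n²v̄`, 0 for an all-zero cell), number of 8-connected
positive blobs, and log1p / sqrt transforms of integrated density and
top-5% mean. Thresholding is per cell by default (per image via config).

Morphometrics are the standard region properties (area, perimeter,
eccentricity, solidity, extent, equivalent diameter). They are z-scored
(near-constant columns dropped) and projected onto the first principal
component to give the MorphScore; the sign is fixed so the loading on
area is nonnegative. The regression response defaults to
`log1p(integrated_density)` and is configurable; the synthetic
benchmarks use the per-cell mean intensity, which is the scale on which
the generator's truth model is defined.

## Synthetic data

The generator emulates what the analysis assumes, so every stage can be
validated against known truth. Cells are Voronoi regions of jittered-grid
centroids: grid pitch set by the cell count, jitter 40% of the pitch
(capped so the minimum pairwise distance stays ≥ 2 px), which varies
area/eccentricity naturally. Default spot: 512×512 px, 300 cells. The
MorphScore used to render channels is computed from the realized cell
shapes, so morphology and intensity are coupled exactly as downstream
analysis assumes.

Coefficient surfaces are chosen from: constant, diagonal linear gradient
spanning ±amplitude, Gaussian bump `a·exp(−r²/2ℓ²)` centred on the spot,
or a zero-mean sinusoid `a·sin(2πu/ℓ)·sin(2πv/ℓ)` with period ℓ. Each
surface may carry an additive offset so intercepts sit above zero —
channel rasters are clipped at 0, and a positive baseline keeps the
clipping from truncating the generative model. Per-cell noise is i.i.d.
Gaussian; pixels within a cell share the cell value plus pixel noise at
10% of the cell-level SD, so per-cell aggregates dominate.

Benchmark conditions (used by the acceptance script and the heavier
tests): 8 markers, 300 cells on 512×512 px, slope = zero-mean sinusoid of
amplitude 1 and period 256 px (half the spot, so the field varies
smoothly at a scale a moderate bandwidth can resolve), intercept =
Gaussian bump of amplitude 1 and scale 128 px over a baseline of 4,
noise SD 0.3. Each marker of a cohort derives its seed from an
independent child of the base seed.

What the generator does **not** emulate: mass-spectrometry counting
noise, antibody-binding chemistry, segmentation errors, cell-type
mixtures, or multi-spot patient hierarchies. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to real MIBI artifacts.

## Diagnostics and known limitations

Residual Moran's I / Geary's C (permutation-tested on the same cell
graph) quantify how much spatial structure each model leaves behind.
Under strong intercept heterogeneity the global models leave strongly
autocorrelated residuals and GWR flattens them (see
`examples/full_pipeline.py`: OLS residual I ≈ 0.37 → GWR ≈ −0.02).

Two caveats. First, at the AICc-selected floor bandwidth GWR residuals
acquire a *negative* Moran's I of roughly −0.1 (any local smoother
high-passes its residuals; the magnitude grows with tr S/n). When the
true smooth structure is weak relative to noise, this artifact can exceed
the modest positive autocorrelation of the global model's residuals, so
the "GWR residuals are whiter" comparison is reliable only for markers
whose global-model residuals show clear spatial autocorrelation — which
is exactly the inclusion rule the screening stage applies. Second,
in-sample R² at small bandwidths partly reflects flexibility rather than
recoverable structure; the parameter-recovery tests (RMSE of the
recovered slope surface against truth) are the stronger evidence that the
local estimates track the real coefficient fields.

Problem sizes in the test suite and acceptance script (desk scale: spots
of 120–300 cells, cohorts of 8, 50-replicate diagnostics) were chosen to
make every property measurable with comfortable Monte-Carlo margins while
keeping a full run in the low minutes on one core.
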