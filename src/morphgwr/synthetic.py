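"""Synthetic MIBI-like spots with known morphology-intensity coupling.

A simulated spot is a Voronoi tessellation of jittered-grid cell centroids
(mimicking the Voronoi-like geometry of segmented tissue) plus one float
raster per marker. Per-cell marker intensity follows the spatially varying
linear model that geographically weighted regression assumes,

    y_i = beta0(u_i, v_i) + beta1(u_i, v_i) * MorphScore_i + eps_i,

with smooth coefficient surfaces and i.i.d. Gaussian noise, so every
downstream stage (feature extraction, autocorrelation screening, local
regression) can be validated against known ground truth.

Coordinate convention: (u, v) = (column, row) of pixel centers, 0-based.
All downstream modules inherit this.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .errors import CapacityError, ValidationError

FIELD_KINDS = ("constant", "linear-gradient", "gaussian-bump", "zero-mean-sinusoid")

# Within-cell pixel noise SD as a fraction of the cell-level noise SD.
# Kept small so per-cell aggregates remain the dominant signal.
PIXEL_NOISE_FRACTION = 0.1

# Jitter amplitude as a fraction of the grid pitch; varies cell area and
# eccentricity naturally without destroying the minimum-spacing guarantee.
JITTER_FRACTION = 0.4


@dataclass(frozen=True)
class FieldSpec:
    """A smooth scalar coefficient surface over the spot.

    Parameters
    ----------
    kind:
        One of ``constant``, ``linear-gradient``, ``gaussian-bump``,
        ``zero-mean-sinusoid``.
    amplitude:
        Field amplitude, in intensity units per unit of the predictor
        (for a slope field) or plain intensity units (for an intercept).
    length_scale:
        Spatial scale in pixels: the Gaussian bump's SD, or the sinusoid's
        period. Ignored by ``constant`` and ``linear-gradient``.
    offset:
        Additive baseline. Lets intercept surfaces sit above zero so that
        nonnegativity clipping of rendered channels does not truncate the
        generative model.
    """

    kind: str
    amplitude: float
    length_scale: float = 128.0
    offset: float = 0.0

    def __post_init__(self):
        if self.kind not in FIELD_KINDS:
            raise ValidationError(f"unknown field kind {self.kind!r}")
        if not np.isfinite(self.amplitude):
            raise ValidationError("amplitude must be finite")
        if not self.length_scale > 0:
            raise ValidationError("length_scale must be > 0")

    def evaluate(self, u, v, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the field at coordinates (u, v) on a spot of ``shape`` (H, W)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        H, W = shape
        if self.kind == "constant":
            base = np.full_like(u, self.amplitude, dtype=float)
        elif self.kind == "linear-gradient":
            # Diagonal ramp spanning [-amplitude, +amplitude]; zero mean
            # over the domain.
            t = u / max(W - 1, 1) + v / max(H - 1, 1) - 1.0
            base = self.amplitude * t
        elif self.kind == "gaussian-bump":
            cu, cv = (W - 1) / 2.0, (H - 1) / 2.0
            r2 = (u - cu) ** 2 + (v - cv) ** 2
            base = self.amplitude * np.exp(-r2 / (2.0 * self.length_scale**2))
        else:  # zero-mean-sinusoid
            base = (
                self.amplitude
                * np.sin(2 * np.pi * u / self.length_scale)
                * np.sin(2 * np.pi * v / self.length_scale)
            )
        return base + self.offset


@dataclass
class SyntheticTruth:
    """Ground truth underlying a synthetic sample, for recovery tests."""

    beta_fields: dict[str, tuple[FieldSpec, FieldSpec]]  # marker -> (beta0, beta1)
    noise_sd: float
    centroids: np.ndarray  # (n, 2) of (u, v)
    shape: tuple[int, int]
    morph_scores: np.ndarray | None = None

    def beta_at_centroids(self, marker: str) -> tuple[np.ndarray, np.ndarray]:
        b0, b1 = self.beta_fields[marker]
        u, v = self.centroids[:, 0], self.centroids[:, 1]
        return b0.evaluate(u, v, self.shape), b1.evaluate(u, v, self.shape)


@dataclass
class SyntheticSample:
    """A simulated spot: labelled cells plus per-marker intensity rasters."""

    label_image: np.ndarray  # uint16/int, 0 = background (absent here: full tiling)
    channels: dict[str, np.ndarray]  # marker -> float32 raster
    truth: SyntheticTruth
    seed: int


def generate_centroids(
    n_cells: int, shape: tuple[int, int], seed: int
) -> np.ndarray:
    """Sample ``n_cells`` jittered-grid centroids on an (H, W) raster.

    Points are drawn from a regular grid whose pitch is set by ``n_cells``,
    each jittered uniformly; the jitter amplitude is capped so the minimum
    pairwise distance stays >= 2 px. Deterministic given ``seed``.
    """
    H, W = shape
    if n_cells < 3:
        raise ValidationError("n_cells must be >= 3")
    if H < 32 or W < 32:
        raise ValidationError("shape must be at least 32x32")
    capacity = (H // 2) * (W // 2)
    if n_cells > capacity:
        raise CapacityError(
            f"n_cells={n_cells} exceeds capacity {capacity} of a {H}x{W} grid "
            "(min spacing 2 px)"
        )
    rng = np.random.default_rng(seed)
    g = int(np.ceil(np.sqrt(n_cells)))
    pitch_u, pitch_v = W / g, H / g
    pitch = min(pitch_u, pitch_v)
    if pitch <= 2.0:
        raise CapacityError(
            f"n_cells={n_cells} too dense for {H}x{W}: grid pitch {pitch:.2f} <= 2 px"
        )
    # Largest jitter that keeps neighbouring slots >= 2 px apart.
    jitter = min(JITTER_FRACTION * pitch, (pitch - 2.0) / 2.0)
    slots = rng.choice(g * g, size=n_cells, replace=False)
    gu, gv = slots % g, slots // g
    u = (gu + 0.5) * pitch_u + rng.uniform(-jitter, jitter, n_cells)
    v = (gv + 0.5) * pitch_v + rng.uniform(-jitter, jitter, n_cells)
    u = np.clip(u, 0.0, W - 1.0)
    v = np.clip(v, 0.0, H - 1.0)
    return np.column_stack([u, v])


def tessellate(centroids: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Voronoi-label every pixel by its nearest centroid.

    Returns an integer raster where region k (1-based) is the set of pixels
    nearest to centroid k. Background label 0 is unused: the tessellation
    tiles the whole raster.
    """
    centroids = np.asarray(centroids, dtype=float)
    if len(centroids) < 3:
        raise ValidationError("need at least 3 centroids")
    if len(np.unique(centroids, axis=0)) != len(centroids):
        raise ValidationError("duplicate centroids")
    H, W = shape
    vv, uu = np.mgrid[0:H, 0:W]
    pix = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
    _, idx = cKDTree(centroids).query(pix, k=1)
    label = (idx + 1).astype(np.uint16 if len(centroids) < 65535 else np.int32)
    return label.reshape(H, W)


def render_channels(
    label_image: np.ndarray,
    centroids: np.ndarray,
    morph_scores: np.ndarray,
    truth: SyntheticTruth,
    seed: int,
) -> dict[str, np.ndarray]:
    """Render one float32 raster per marker from the truth model.

    Each cell's mean intensity is beta0(u,v) + beta1(u,v)*morph_score + eps
    with eps ~ N(0, noise_sd^2); pixels within a cell share that value plus
    small pixel-level noise (SD = 10% of noise_sd). Values are clipped at 0.
    """
    centroids = np.asarray(centroids, dtype=float)
    morph_scores = np.asarray(morph_scores, dtype=float)
    n = len(centroids)
    if len(morph_scores) != n:
        raise ValidationError("one morph_score per cell required")
    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    for marker in truth.beta_fields:
        b0, b1 = truth.beta_at_centroids(marker)
        cell_values = b0 + b1 * morph_scores + rng.normal(0.0, truth.noise_sd, n)
        raster = cell_values[label_image - 1]
        if truth.noise_sd > 0:
            raster = raster + rng.normal(
                0.0, PIXEL_NOISE_FRACTION * truth.noise_sd, raster.shape
            )
        channels[marker] = np.clip(raster, 0.0, None).astype(np.float32)
    return channels


def _morph_scores_for_labels(label_image: np.ndarray) -> np.ndarray:
    # Local import: features depends on nothing here, but keep the module
    # graph acyclic at import time.
    from .features import morph_score, morphometrics_table

    table = morphometrics_table(label_image)
    return morph_score(table).scores


def simulate_sample(
    n_cells: int = 300,
    shape: tuple[int, int] = (512, 512),
    beta_fields: Mapping[str, tuple[FieldSpec, FieldSpec]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> SyntheticSample:
    """Generate a full synthetic spot.

    Centroids are jittered-grid, cells are their Voronoi regions, the
    MorphScore is computed from the realised cell shapes (so morphology and
    intensity are coupled exactly as downstream analysis assumes), and each
    marker raster is rendered from its (beta0, beta1) coefficient surfaces.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if beta_fields is None:
        beta_fields = {
            "marker_1": (
                FieldSpec("gaussian-bump", 1.0, 128.0, offset=4.0),
                FieldSpec("zero-mean-sinusoid", 1.0, 256.0),
            )
        }
    centroids = generate_centroids(n_cells, shape, seed)
    label_image = tessellate(centroids, shape)
    scores = _morph_scores_for_labels(label_image)
    truth = SyntheticTruth(
        beta_fields=dict(beta_fields),
        noise_sd=float(noise_sd),
        centroids=centroids,
        shape=shape,
        morph_scores=scores,
    )
    channels = render_channels(label_image, centroids, scores, truth, seed)
    return SyntheticSample(
        label_image=label_image, channels=channels, truth=truth, seed=seed
    )


def simulate_cell_table(
    n_cells: int = 300,
    shape: tuple[int, int] = (512, 512),
    beta_fields: Mapping[str, tuple[FieldSpec, FieldSpec]] | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Cell-level view of the same generative model, skipping raster rendering.

    Returns ``(coords, morph_scores, responses, truth)`` where ``responses``
    maps marker name to the per-cell response vector. The geometry and
    MorphScore are identical to :func:`simulate_sample`; only the
    pixel-level rendering (and hence clipping and pixel noise) is skipped.
    Intended for regression-level simulations where rasters are not needed.
    """
    if beta_fields is None:
        beta_fields = {
            "marker_1": (
                FieldSpec("constant", 0.0),
                FieldSpec("zero-mean-sinusoid", 1.0, 256.0),
            )
        }
    centroids = generate_centroids(n_cells, shape, seed)
    label_image = tessellate(centroids, shape)
    scores = _morph_scores_for_labels(label_image)
    truth = SyntheticTruth(
        beta_fields=dict(beta_fields),
        noise_sd=float(noise_sd),
        centroids=centroids,
        shape=shape,
        morph_scores=scores,
    )
    rng = np.random.default_rng(seed)
    responses = {}
    for marker in truth.beta_fields:
        b0, b1 = truth.beta_at_centroids(marker)
        responses[marker] = b0 + b1 * scores + rng.normal(0.0, noise_sd, n_cells)
    return centroids, scores, responses, truth


def write_sample(sample: SyntheticSample, out_dir: str | Path) -> Path:
    """Write a sample as TIFF rasters plus a JSON truth sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "labels.tif", sample.label_image.astype(np.uint16))
    for marker, raster in sample.channels.items():
        tifffile.imwrite(out / f"channel_{marker}.tif", raster.astype(np.float32))
    truth = sample.truth
    sidecar = {
        "seed": sample.seed,
        "noise_sd": truth.noise_sd,
        "shape": list(truth.shape),
        "centroids": truth.centroids.tolist(),
        "beta_fields": {
            m: [
                {
                    "kind": f.kind,
                    "amplitude": f.amplitude,
                    "length_scale": f.length_scale,
                    "offset": f.offset,
                }
                for f in pair
            ]
            for m, pair in truth.beta_fields.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(sidecar, indent=1))
    return out
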