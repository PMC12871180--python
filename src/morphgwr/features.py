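"""Per-cell marker-intensity features and morphometrics.

Intensity features summarise how a marker's signal is distributed inside a
single segmented cell: how much of the cell is positive, how much total
signal it carries, how concentrated the signal is (Gini), and how many
separate positive blobs it forms. Morphometrics are the standard region
properties (area, perimeter, eccentricity, solidity, extent, equivalent
diameter), reduced by PCA to a single MorphScore used as the morphometric
predictor in the regression stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_li, threshold_otsu
from sklearn.decomposition import PCA

from .errors import DegenerateInputError, ValidationError

MORPHOMETRIC_COLUMNS = [
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "extent",
    "equivalent_diameter",
]

INTENSITY_FEATURE_NAMES = [
    "positive_fraction",
    "integrated_density",
    "top5_mean",
    "max_intensity",
    "gini",
    "blob_count",
    "mean_intensity",
    "log1p_integrated_density",
    "sqrt_integrated_density",
    "log1p_top5_mean",
    "sqrt_top5_mean",
]


@dataclass
class MorphScoreResult:
    scores: np.ndarray  # mean 0 across cells; sign: area loading >= 0
    explained_variance_ratio: float
    loadings: pd.Series


def cell_threshold(pixels: np.ndarray) -> float:
    """Positivity threshold for one cell's pixel intensities.

    Li's minimum cross-entropy threshold, falling back to Otsu when the
    input is too degenerate for Li (<= 2 distinct values) or Li fails to
    converge. A constant cell has no positives: threshold = +inf.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    if pixels.size == 0:
        raise ValidationError("empty pixel vector")
    distinct = np.unique(pixels)
    if distinct.size == 1:
        return math.inf
    if distinct.size <= 2:
        return float(threshold_otsu(pixels))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = float(threshold_li(pixels))
        if not np.isfinite(t):
            raise ValueError
        return t
    except Exception:
        return float(threshold_otsu(pixels))


def gini(values: np.ndarray) -> float:
    """Gini coefficient of a nonnegative intensity distribution.

    G = sum_ij |v_i - v_j| / (2 n^2 vbar), with G = 0 for an all-zero
    vector. 0 = perfectly even signal, ->1 = signal concentrated in few
    pixels. Computed via the sorted-values identity, O(n log n).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("empty value vector")
    if np.any(v < 0):
        raise ValidationError("gini requires nonnegative values")
    total = v.sum()
    if total == 0:
        return 0.0
    n = v.size
    s = np.sort(v)
    # sum_ij |v_i - v_j| = 2 * sum_i (2i - n + 1) * s_i  (0-based i)
    weighted = np.sum((2 * np.arange(n) - n + 1) * s)
    return float(weighted / (n * total))


def count_blobs(mask: np.ndarray) -> int:
    """Number of 8-connected components of positive pixels in a cell mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return 0
    return int(measure.label(mask, connectivity=2).max())


def intensity_features(
    image: np.ndarray,
    mask: np.ndarray | None,
    threshold: float,
) -> dict[str, float]:
    """Intensity-feature block for one cell.

    ``image`` is a 2-D crop containing the cell, ``mask`` the boolean cell
    mask within it (all-true if None). Positivity is ``pixel > threshold``.
    top5_mean averages the ceil(0.05 n) brightest pixels (at least one).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 1:
        image = image[None, :]
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    pixels = image[mask]
    n = pixels.size
    if n == 0:
        raise ValidationError("empty cell region")
    positive = pixels > threshold
    k = max(1, math.ceil(0.05 * n))
    top5 = float(np.sort(pixels)[-k:].mean())
    integrated = float(pixels.sum())
    pos_mask = np.zeros(image.shape, dtype=bool)
    pos_mask[mask] = positive
    return {
        "positive_fraction": float(positive.mean()),
        "integrated_density": integrated,
        "top5_mean": top5,
        "max_intensity": float(pixels.max()),
        "gini": gini(np.clip(pixels, 0, None)),
        "blob_count": count_blobs(pos_mask),
        "mean_intensity": float(pixels.mean()),
        "log1p_integrated_density": float(np.log1p(max(integrated, 0.0))),
        "sqrt_integrated_density": float(np.sqrt(max(integrated, 0.0))),
        "log1p_top5_mean": float(np.log1p(max(top5, 0.0))),
        "sqrt_top5_mean": float(np.sqrt(max(top5, 0.0))),
    }


def morphometrics(region_mask: np.ndarray) -> dict[str, float]:
    """Standard region properties of one cell mask.

    area = pixel count; equivalent_diameter = sqrt(4*area/pi); extent =
    area / bounding box area; solidity = area / convex hull area;
    eccentricity from second central moments; perimeter by the usual
    boundary-walk approximation.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValidationError("empty region")
    props = measure.regionprops(region_mask.astype(np.uint8))[0]
    return {
        "area": float(props.area),
        "perimeter": float(props.perimeter),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "extent": float(props.extent),
        "equivalent_diameter": float(props.equivalent_diameter_area),
    }


def morphometrics_table(label_image: np.ndarray) -> pd.DataFrame:
    """Morphometrics for every labelled cell, with centroids.

    Returns one row per nonzero label: cell_id, u, v and the six
    morphometric columns.
    """
    label_image = np.asarray(label_image)
    props = measure.regionprops(label_image)
    if not props:
        raise ValidationError("label image contains no cells")
    rows = []
    for p in props:
        cv, cu = p.centroid  # (row, col) -> (v, u)
        rows.append(
            {
                "cell_id": int(p.label),
                "u": float(cu),
                "v": float(cv),
                "area": float(p.area),
                "perimeter": float(p.perimeter),
                "eccentricity": float(p.eccentricity),
                "solidity": float(p.solidity),
                "extent": float(p.extent),
                "equivalent_diameter": float(p.equivalent_diameter_area),
            }
        )
    return pd.DataFrame(rows)


def morph_score(morph_table: pd.DataFrame) -> MorphScoreResult:
    """First principal component of the z-scored morphometrics.

    Near-constant columns are dropped before z-scoring; the PC1 sign is
    fixed so the loading on area (or the first surviving column) is
    nonnegative. Raises if fewer than 3 cells or no column varies.
    """
    cols = [c for c in MORPHOMETRIC_COLUMNS if c in morph_table.columns]
    X = morph_table[cols].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 cells for MorphScore")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if not keep.any():
        raise DegenerateInputError("all morphometric columns are constant")
    kept_cols = [c for c, k in zip(cols, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pd.Series(pca.components_[0], index=kept_cols)
    anchor = "area" if "area" in kept_cols else kept_cols[0]
    if loadings[anchor] < 0:
        scores = -scores
        loadings = -loadings
    return MorphScoreResult(
        scores=scores,
        explained_variance_ratio=float(pca.explained_variance_ratio_[0]),
        loadings=loadings,
    )


def build_cell_table(
    label_image: np.ndarray,
    channels: dict[str, np.ndarray],
    threshold_scope: str = "cell",
) -> pd.DataFrame:
    """Assemble the tidy per-cell table the regression stage consumes.

    One row per cell: cell_id, u, v, the six morphometrics, morph_score,
    then a ``<marker>__<feature>`` block per channel. ``threshold_scope``
    selects per-cell thresholds (default) or one threshold per image.
    """
    if threshold_scope not in ("cell", "image"):
        raise ValidationError("threshold_scope must be 'cell' or 'image'")
    table = morphometrics_table(label_image)
    table["morph_score"] = morph_score(table).scores
    props = measure.regionprops(np.asarray(label_image))
    for marker, raster in channels.items():
        raster = np.asarray(raster, dtype=float)
        if raster.shape != label_image.shape:
            raise ValidationError(
                f"channel {marker!r} shape {raster.shape} != mask shape "
                f"{label_image.shape}"
            )
        image_thr = cell_threshold(raster.ravel()) if threshold_scope == "image" else None
        blocks = []
        for p in props:
            sl = p.slice
            crop = raster[sl]
            mask = p.image
            thr = image_thr if image_thr is not None else cell_threshold(crop[mask])
            blocks.append(intensity_features(crop, mask, thr))
        block = pd.DataFrame(blocks)
        for feat in block.columns:
            table[f"{marker}__{feat}"] = block[feat].to_numpy()
    return table
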