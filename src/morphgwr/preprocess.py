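"""Raster I/O and robust percentile normalization.

Marker rasters are normalized by clipping to the 1st/99th intensity
percentiles and rescaling that range to [0, 1] — the standard robust
rescale used on mass-imaging channels, which defuses hot pixels without a
hand-tuned ceiling. Percentiles are computed over all pixels, background
included.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class NormalizedChannel:
    raster: np.ndarray  # float in [0, 1]
    p_lo_value: float
    p_hi_value: float
    degenerate: bool = False  # constant input: mapped to all zeros


def robust_rescale(
    raster: np.ndarray, p_lo: float = 1.0, p_hi: float = 99.0
) -> NormalizedChannel:
    """Clip to the [p_lo, p_hi] percentiles and rescale affinely to [0, 1].

    A constant image (equal percentiles) maps to all zeros with the
    ``degenerate`` flag set, so downstream per-cell features stay defined.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.size == 0:
        raise ValidationError("empty raster")
    if not np.all(np.isfinite(raster)):
        raise ValidationError("raster contains NaN or infinite values")
    q_lo, q_hi = np.percentile(raster, [p_lo, p_hi])
    if q_lo == q_hi:
        return NormalizedChannel(
            np.zeros_like(raster), float(q_lo), float(q_hi), degenerate=True
        )
    out = (np.clip(raster, q_lo, q_hi) - q_lo) / (q_hi - q_lo)
    return NormalizedChannel(out, float(q_lo), float(q_hi))


def extract_centroids(label_image: np.ndarray) -> pd.DataFrame:
    """Per-cell centroids as the unweighted mean of member pixel centers.

    Returns a table with columns ``cell_id, u, v`` where (u, v) is
    (column, row), matching the package-wide coordinate convention.
    """
    label_image = np.asarray(label_image)
    if label_image.min() < 0:
        raise ValidationError("labels must be nonnegative integers")
    labels = np.unique(label_image)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValidationError("label image contains no cells")
    rows = []
    for lab in labels:
        vv, uu = np.nonzero(label_image == lab)
        rows.append((int(lab), uu.mean(), vv.mean()))
    return pd.DataFrame(rows, columns=["cell_id", "u", "v"])


def load_sample(sample_dir: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Load a labelled mask plus marker channels from a sample directory.

    Expects ``labels.tif`` and one ``channel_<marker>.tif`` per marker, the
    layout :func:`morphgwr.synthetic.write_sample` produces.
    """
    import tifffile

    sample_dir = Path(sample_dir)
    label_path = sample_dir / "labels.tif"
    if not label_path.exists():
        raise IOError(f"missing label image: {label_path}")
    label_image = tifffile.imread(label_path)
    channels: dict[str, np.ndarray] = {}
    for path in sorted(sample_dir.glob("channel_*.tif")):
        marker = path.stem.removeprefix("channel_")
        raster = tifffile.imread(path)
        if raster.shape != label_image.shape:
            raise IOError(
                f"channel raster {path.name} shape {raster.shape} does not match "
                f"mask shape {label_image.shape}"
            )
        channels[marker] = np.asarray(raster, dtype=float)
    if not channels:
        raise IOError(f"no channel_*.tif files found in {sample_dir}")
    return label_image, channels


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cell table as CSV with header."""
    pd.DataFrame(table).to_csv(path, index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
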