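"""Image loading and feature-table serialization.

Conventions: pixel coordinates are (row, col), 0-based, row 0 at the top;
intensities are floats in [0, 1]. RGB inputs are reduced with the green
channel only, where retinal vessels carry maximal contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

KEY_COLUMNS = ["subject_id", "group_label", "timepoint_label"]


@dataclass
class GrayscaleImage:
    """A single-channel image with intensities scaled to [0, 1]."""

    pixels: np.ndarray
    provenance: str = field(default="")

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("image must be a non-empty 2D raster")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite intensities")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _dtype_scale(arr: np.ndarray) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        return float(max(np.iinfo(arr.dtype).max, 1))
    return 1.0


def read_image(path: str | Path) -> GrayscaleImage:
    """Load a PNG/TIFF image as a GrayscaleImage.

    RGB(A) inputs keep the green channel only; integer intensities are
    rescaled by their dtype range so 8- and 16-bit files land in [0, 1].
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding failures vary by backend
        raise OSError(f"could not read image file {path}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    note = f"loaded from {path.name}"
    if arr.ndim == 3:
        if arr.shape[2] < 3:
            arr = arr[:, :, 0]
            note += "; first channel"
        else:
            arr = arr[:, :, 1]
            note += "; green channel"
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    scale = _dtype_scale(arr)
    pixels = np.clip(arr.astype(float) / scale, 0.0, 1.0)
    return GrayscaleImage(pixels=pixels, provenance=note)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as UTF-8 CSV with canonical column order.

    Values survive a write/read round-trip to 12 significant digits.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in KEY_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    keys = list(zip(*(table[c] for c in KEY_COLUMNS)))
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (subject_id, group_label, timepoint_label) keys")
    out = table[KEY_COLUMNS + FEATURE_NAMES]
    out.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating its column set."""
    table = pd.read_csv(path, encoding="utf-8")
    unknown = [
        c for c in table.columns if c not in KEY_COLUMNS and c not in FEATURE_NAMES
    ]
    if unknown:
        raise ValueError(f"unknown feature column(s): {unknown}")
    missing = [c for c in KEY_COLUMNS + FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return table[KEY_COLUMNS + FEATURE_NAMES]
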