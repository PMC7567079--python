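"""Analysis configuration shared by every pipeline stage."""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters controlling the mask/skeleton/feature pipeline.

    Attributes
    ----------
    canny_sigma : float
        Gaussian smoothing scale (px) for edge detection.
    canny_low_quantile, canny_high_quantile : float
        Gradient-magnitude quantiles in (0, 1) used for hysteresis
        thresholding; low must be strictly below high.
    circular_mask_fraction : float or None
        Diameter of the retained circular field as a fraction of
        min(height, width); ``None`` disables field masking.
    min_object_px : int
        Foreground components smaller than this many pixels are removed
        after morphological closing.
    closing_iterations : int
        Number of 3x3 binary closing passes used to fuse the double edge
        contours that Canny produces across a vessel into one solid band.
    diagonal_step : float
        Length assigned to a diagonal pixel move when measuring traced
        paths; 1.0 emulates pure pixel counting.
    mesh_scope : str
        ``"master"`` counts only regions bounded by the master subgraph;
        ``"all"`` counts every bounded face of the full skeleton.
    alpha : float
        Significance level for group comparisons.
    """

    canny_sigma: float = 2.0
    canny_low_quantile: float = 0.80
    canny_high_quantile: float = 0.95
    circular_mask_fraction: float | None = None
    min_object_px: int = 10
    fill_hole_px: int = 0
    prune_spur_px: float = 0.0
    closing_iterations: int = 2
    diagonal_step: float = math.sqrt(2.0)
    mesh_scope: str = "master"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.canny_sigma > 0:
            raise ValueError("canny_sigma must be > 0")
        if not (0 < self.canny_low_quantile < self.canny_high_quantile < 1):
            raise ValueError(
                "quantiles must satisfy 0 < low < high < 1, got "
                f"low={self.canny_low_quantile} high={self.canny_high_quantile}"
            )
        if self.circular_mask_fraction is not None and not (
            0 < self.circular_mask_fraction <= 1
        ):
            raise ValueError("circular_mask_fraction must be in (0, 1] or None")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")
        if self.fill_hole_px < 0:
            raise ValueError("fill_hole_px must be >= 0")
        if self.prune_spur_px < 0:
            raise ValueError("prune_spur_px must be >= 0")
        if self.closing_iterations < 0:
            raise ValueError("closing_iterations must be >= 0")
        if not self.diagonal_step > 0:
            raise ValueError("diagonal_step must be > 0")
        if self.mesh_scope not in ("master", "all"):
            raise ValueError("mesh_scope must be 'master' or 'all'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


_FIELD_TYPES = {f.name: f for f in fields(AnalysisConfig)}


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "circular_mask_fraction" and raw.lower() == "none":
        return None
    if key == "mesh_scope":
        return raw
    if key in ("min_object_px", "closing_iterations", "fill_hole_px"):
        return int(raw)
    return float(raw)


def load_config(path: str | Path) -> AnalysisConfig:
    """Read a flat ``key=value`` config file.

    Blank lines and ``#`` comments are ignored; unknown keys raise
    ``ValueError`` naming the offending key.
    """
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, raw = line.split("=", 1)
        key = key.strip()
        if key not in _FIELD_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(key, raw)
    return AnalysisConfig(**values)
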