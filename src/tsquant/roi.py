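"""ROI-based quantification of average-intensity projections.

Models the germline OPP measurement: average-project each z-stack, measure
the mean fluorescence inside a hand-drawn polygonal ROI, normalize every
sample to the mean of the control group (so the control averages to exactly
1), and compare groups with an unpaired t-test (see
:func:`tsquant.stats.two_sample_ttest`).

ROI membership uses pixel-center containment under the even-odd rule; the
center of pixel (row j, col i) is at (x, y) = (i + 0.5, j + 0.5), so a
polygon drawn along pixel edges splits pixels unambiguously.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImageStack


@dataclass(frozen=True)
class ROIQuant:
    sample_id: str
    group: str
    roi_mean: float
    normalized: float = float("nan")


def average_projection(stack: ImageStack) -> np.ndarray:
    """Per-pixel mean across z."""
    data = np.asarray(stack.data, dtype=float)
    if data.shape[0] < 1:
        raise ValueError("stack has no z-planes")
    return data.mean(axis=0)


def points_in_polygon(px: np.ndarray, py: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorized over points.

    ``polygon`` is an (n, 2) array of (x, y) vertices, implicitly closed.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    inside = np.zeros(px.shape, dtype=bool)
    x1, y1 = poly[-1]
    for x2, y2 in poly:
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_int)
        x1, y1 = x2, y2
    return inside


def roi_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon."""
    n_y, n_x = shape
    yy, xx = np.mgrid[0:n_y, 0:n_x]
    return points_in_polygon(xx + 0.5, yy + 0.5, polygon)


def roi_mean(image: np.ndarray, polygon: np.ndarray) -> float:
    """Mean intensity over pixels whose centers lie inside the polygon."""
    image = np.asarray(image, dtype=float)
    mask = roi_mask(image.shape, polygon)
    if not mask.any():
        raise ValueError("ROI polygon covers zero pixel centers")
    return float(image[mask].mean())


def normalize_to_control(values: list[ROIQuant], control_group: str) -> list[ROIQuant]:
    """Divide every ROI mean by the control group's mean ROI intensity."""
    control = [v.roi_mean for v in values if v.group == control_group]
    if not control:
        raise ValueError(f"control group {control_group!r} is empty")
    ref = float(np.mean(control))
    if ref == 0:
        raise ValueError("control group mean intensity is zero")
    return [replace(v, normalized=v.roi_mean / ref) for v in values]


def load_rois(path: str | Path) -> dict[str, np.ndarray]:
    """Read ROI polygons from JSON: {sample_id: [[x, y], ...], ...}."""
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def quants_to_frame(values: list[ROIQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": v.sample_id, "group": v.group, "roi_mean": v.roi_mean,
             "normalized": v.normalized}
            for v in values
        ],
        columns=["sample_id", "group", "roi_mean", "normalized"],
    )
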