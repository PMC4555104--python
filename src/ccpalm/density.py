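"""Neighbor-count density filter separating clustered molecules from noise.

A point is a core point when at least ``min_neighbors`` *other* points lie
within ``radius`` (boundary inclusive). The retained set is the core points
plus, when ``keep_neighbors`` is set, every point within the radius of any
core point — keeping the edges of small clusters. Defaults: at least 4
neighbors within a 50 nm radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["FilterParams", "filter_outliers"]


@dataclass(frozen=True)
class FilterParams:
    radius_nm: float = 50.0
    min_neighbors: int = 4
    keep_neighbors: bool = True

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("radius_nm must be > 0")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")

    @classmethod
    def from_pixels(cls, radius_px: float, pixel_size_nm: float, **kw) -> "FilterParams":
        """Pixel-relative radius (e.g. 0.5 px) converted to nm."""
        return cls(radius_nm=radius_px * pixel_size_nm, **kw)


def filter_outliers(points: pd.DataFrame, params: FilterParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a point table into (retained, removed) by the neighbor-count rule.

    Input order is preserved in both outputs and the input is not modified.
    A point is never its own neighbor. Empty input yields two empty tables.
    """
    if len(points) == 0:
        return points.iloc[:0].copy(), points.iloc[:0].copy()
    xy = np.column_stack([
        np.asarray(points["x_nm"], dtype=float),
        np.asarray(points["y_nm"], dtype=float),
    ])
    if not np.all(np.isfinite(xy)):
        raise ValueError("points must have finite coordinates")
    tree = cKDTree(xy)
    # query_ball includes the boundary (distance <= r) and the point itself
    counts = tree.query_ball_point(xy, params.radius_nm, return_length=True) - 1
    core = counts >= params.min_neighbors
    keep = core.copy()
    if params.keep_neighbors and np.any(core):
        core_tree = cKDTree(xy[core])
        near_core = core_tree.query_ball_point(xy, params.radius_nm, return_length=True) > 0
        keep |= near_core
    return points[keep].copy(), points[~keep].copy()
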