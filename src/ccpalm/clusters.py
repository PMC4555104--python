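"""Cluster morphometry: rotated anisotropic 2D Gaussian fits of molecule groups.

Every contoured group of molecules (>= 5, smaller groups are rejected) is
fitted with a freely rotating bivariate Gaussian whose x and y standard
deviations are uncoupled: the maximum-likelihood Gaussian of the coordinate
sample, i.e. the mean plus the eigendecomposition of the sample covariance.
Sigmas convert to FWHM via 2*sqrt(2 ln 2); the smaller FWHM is the cluster
thickness, the larger the length. Clusters thinner than the resolution
threshold (default 25 nm) are flagged as not retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.prepared import prep

__all__ = [
    "FWHM_FACTOR",
    "RoiPolygon",
    "ClusterFit",
    "ClusterSummary",
    "select_in_roi",
    "propose_rois",
    "fit_cluster",
    "summarize_clusters",
    "analyze_rois",
    "fits_to_table",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass
class RoiPolygon:
    """Closed simple polygon (nm) contouring one candidate cluster."""

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if poly.area <= 0 or not poly.is_valid:
            raise ValueError("degenerate or self-intersecting polygon")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class ClusterFit:
    """Rotated 2D Gaussian fitted to one molecule group."""

    label: str
    n_molecules: int
    center: tuple
    sigma_minor_nm: float
    sigma_major_nm: float
    theta: float  # major-axis angle, radians in [0, pi)
    thickness_nm: float
    length_nm: float
    retained: bool


@dataclass
class ClusterSummary:
    n_clusters: int
    n_discarded_small: int
    mean_molecules: float
    sd_molecules: float
    max_molecules: int
    fraction_below_50: float
    thickness_fit: tuple  # (a, b) of thickness = a ln(content) + b
    length_fit: tuple


def select_in_roi(points: pd.DataFrame, roi: RoiPolygon) -> pd.DataFrame:
    """Points inside the polygon (even-odd rule); boundary points included."""
    poly = roi.as_shapely()
    prepared = prep(poly)
    xs = np.asarray(points["x_nm"], dtype=float)
    ys = np.asarray(points["y_nm"], dtype=float)
    # prepared.intersects == covers for points: interior or boundary
    mask = np.fromiter(
        (prepared.intersects(Point(x, y)) for x, y in zip(xs, ys)),
        dtype=bool, count=len(xs),
    )
    return points[mask].copy()


def propose_rois(points: pd.DataFrame, grid_nm: float = 100.0, min_count: int = 5) -> list[RoiPolygon]:
    """Automatic contouring: occupied density-grid components -> hull polygons.

    Bins the points on a square grid, labels 8-connected occupied bins, keeps
    components holding at least ``min_count`` molecules, and returns the
    convex hull of each component's points dilated by one grid cell. Stands in
    for an operator drawing contours around visible clusters.
    """
    if grid_nm <= 0:
        raise ValueError("grid_nm must be > 0")
    if len(points) == 0:
        return []
    x = np.asarray(points["x_nm"], dtype=float)
    y = np.asarray(points["y_nm"], dtype=float)
    x0, y0 = x.min(), y.min()
    ix = np.floor((x - x0) / grid_nm).astype(int)
    iy = np.floor((y - y0) / grid_nm).astype(int)
    grid = np.zeros((iy.max() + 1, ix.max() + 1), dtype=int)
    np.add.at(grid, (iy, ix), 1)
    labels, n = ndimage.label(grid > 0, structure=np.ones((3, 3), dtype=int))
    rois: list[RoiPolygon] = []
    point_labels = labels[iy, ix]
    for k in range(1, n + 1):
        sel = point_labels == k
        if int(sel.sum()) < min_count:
            continue
        hull = MultiPoint(np.column_stack([x[sel], y[sel]])).convex_hull.buffer(grid_nm)
        rois.append(RoiPolygon(np.asarray(hull.exterior.coords), label=f"roi_{len(rois)}"))
    return rois


def fit_cluster(
    points: pd.DataFrame,
    resolution_nm: float = 25.0,
    label: str = "",
) -> ClusterFit:
    """ML bivariate Gaussian of the molecule coordinates.

    Center = sample mean; sigmas and orientation from the eigendecomposition
    of the ML (1/n) covariance. Requires >= 5 molecules. Collinear input gives
    sigma_minor = 0 and retained=False; clusters with thickness below
    ``resolution_nm`` are flagged retained=False.
    """
    xy = np.column_stack([
        np.asarray(points["x_nm"], dtype=float),
        np.asarray(points["y_nm"], dtype=float),
    ])
    n = xy.shape[0]
    if n < 5:
        raise ValueError(f"cluster fit needs at least 5 molecules, got {n}")
    center = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals = np.clip(evals, 0.0, None)
    s_minor, s_major = float(np.sqrt(evals[0])), float(np.sqrt(evals[1]))
    vmaj = evecs[:, 1]
    theta = float(np.arctan2(vmaj[1], vmaj[0])) % np.pi
    thickness = FWHM_FACTOR * s_minor
    length = FWHM_FACTOR * s_major
    retained = thickness >= resolution_nm
    return ClusterFit(
        label=label, n_molecules=n, center=(float(center[0]), float(center[1])),
        sigma_minor_nm=s_minor, sigma_major_nm=s_major, theta=theta,
        thickness_nm=thickness, length_nm=length, retained=bool(retained),
    )


def _log_fit(content: np.ndarray, y: np.ndarray) -> tuple:
    """Least squares y = a ln(x) + b."""
    lx = np.log(content)
    A = np.column_stack([lx, np.ones_like(lx)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def summarize_clusters(fits: list[ClusterFit]) -> ClusterSummary:
    """Population statistics over retained fits (discarded ones counted only)."""
    retained = [f for f in fits if f.retained]
    if not retained:
        raise ValueError("all cluster fits were discarded")
    content = np.asarray([f.n_molecules for f in retained], dtype=float)
    thickness = np.asarray([f.thickness_nm for f in retained])
    length = np.asarray([f.length_nm for f in retained])
    return ClusterSummary(
        n_clusters=len(fits),
        n_discarded_small=len(fits) - len(retained),
        mean_molecules=float(content.mean()),
        sd_molecules=float(content.std(ddof=1)) if content.size > 1 else 0.0,
        max_molecules=int(content.max()),
        fraction_below_50=float(np.mean(content < 50)),
        thickness_fit=_log_fit(content, thickness),
        length_fit=_log_fit(content, length),
    )


def analyze_rois(
    points: pd.DataFrame,
    rois: list[RoiPolygon],
    resolution_nm: float = 25.0,
) -> list[ClusterFit]:
    """Fit every ROI's molecule group; ROIs with < 5 molecules are skipped with a warning."""
    fits = []
    for roi in rois:
        sel = select_in_roi(points, roi)
        if len(sel) < 5:
            warnings.warn(f"ROI {roi.label!r} holds {len(sel)} molecules (<5); skipped")
            continue
        fits.append(fit_cluster(sel, resolution_nm=resolution_nm, label=roi.label))
    return fits


def fits_to_table(fits: list[ClusterFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": f.label, "n_molecules": f.n_molecules,
                "x_nm": f.center[0], "y_nm": f.center[1],
                "sigma_min_nm": f.sigma_minor_nm, "sigma_max_nm": f.sigma_major_nm,
                "theta_rad": f.theta, "thickness_nm": f.thickness_nm,
                "length_nm": f.length_nm, "retained": f.retained,
            }
            for f in fits
        ],
        columns=["label", "n_molecules", "x_nm", "y_nm", "sigma_min_nm", "sigma_max_nm",
                 "theta_rad", "thickness_nm", "length_nm", "retained"],
    )
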