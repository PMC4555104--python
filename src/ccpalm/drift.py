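"""Fiducial-free drift correction from the localizations themselves.

The localization set is split by time into non-overlapping batches, each batch
is rendered as a 2D histogram on one shared grid, consecutive batch images are
registered by phase correlation with sub-pixel Gaussian refinement of the
correlation peak, the cumulative shifts are interpolated with a per-axis
polynomial over frame index, and the resulting per-frame offset is subtracted
from the positions. All fitted localizations participate, including dim
molecules present in only part of the movie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DriftTrajectory",
    "batch_localizations",
    "histogram_image",
    "phase_correlate",
    "fit_drift",
    "correct_drift",
    "estimate_drift",
]


@dataclass
class DriftTrajectory:
    """Per-frame drift (nm) plus the polynomial model and raw batch shifts."""

    dx_nm: np.ndarray
    dy_nm: np.ndarray
    poly_x: np.ndarray | None = None
    poly_y: np.ndarray | None = None
    batch_shifts: list | None = None  # (mid_frame, cum_dx_nm, cum_dy_nm)

    def __post_init__(self) -> None:
        self.dx_nm = np.asarray(self.dx_nm, dtype=float)
        self.dy_nm = np.asarray(self.dy_nm, dtype=float)
        if self.dx_nm.shape != self.dy_nm.shape:
            raise ValueError("dx and dy must have the same length")
        if not (np.all(np.isfinite(self.dx_nm)) and np.all(np.isfinite(self.dy_nm))):
            raise ValueError("drift trajectory must be finite")

    @property
    def n_frames(self) -> int:
        return self.dx_nm.size

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(self.n_frames), "dx_nm": self.dx_nm, "dy_nm": self.dy_nm}
        )

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(dx_nm=-self.dx_nm, dy_nm=-self.dy_nm)


def batch_localizations(locs: pd.DataFrame, batch_size: int) -> list[pd.DataFrame]:
    """Split a time-ordered localization table into consecutive batches.

    Every localization lands in exactly one batch; all batches have
    ``batch_size`` rows except possibly the last. Refuses to proceed with
    fewer than two full batches (too little signal for registration).
    """
    if batch_size < 100:
        raise ValueError("batch_size must be >= 100")
    locs = locs.sort_values("frame", kind="stable").reset_index(drop=True)
    n = len(locs)
    if n < 2 * batch_size:
        raise ValueError(
            f"drift correction refused: {n} localizations form fewer than two full batches of {batch_size}"
        )
    return [locs.iloc[i:i + batch_size] for i in range(0, n, batch_size)]


def histogram_image(
    subset: pd.DataFrame,
    bin_size_nm: float,
    extent: tuple | None = None,
    shape: tuple | None = None,
) -> np.ndarray:
    """2D localization histogram on a fixed global grid.

    ``extent`` is ``(x0, y0)`` in nm of the lower grid corner and ``shape``
    the ``(ny, nx)`` bin counts; both default to the subset's own bounding
    box, but callers registering several subsets must pass one shared grid.
    Bin intervals are half-open ``[lo, hi)`` so a point exactly on an edge is
    assigned to the higher bin; points beyond the last edge land in the last
    bin so the grid sum always equals the subset size.
    """
    if bin_size_nm <= 0:
        raise ValueError("bin_size_nm must be > 0")
    if len(subset) == 0:
        raise ValueError("empty subset")
    x = np.asarray(subset["x_nm"], dtype=float)
    y = np.asarray(subset["y_nm"], dtype=float)
    if extent is None:
        extent = (float(x.min()), float(y.min()))
    if shape is None:
        nx = int(np.floor((x.max() - extent[0]) / bin_size_nm)) + 1
        ny = int(np.floor((y.max() - extent[1]) / bin_size_nm)) + 1
        shape = (ny, nx)
    ix = np.floor((x - extent[0]) / bin_size_nm).astype(int)
    iy = np.floor((y - extent[1]) / bin_size_nm).astype(int)
    ix = np.clip(ix, 0, shape[1] - 1)
    iy = np.clip(iy, 0, shape[0] - 1)
    img = np.zeros(shape, dtype=float)
    np.add.at(img, (iy, ix), 1.0)
    return img


def _gaussian_peak_offset(v: np.ndarray) -> float:
    """Sub-pixel offset of a Gaussian peak from three samples (-1, 0, +1).

    Exact for a sampled Gaussian; values are clamped to a small positive floor
    so correlation side-lobes cannot produce log of non-positive numbers.
    """
    floor = 1e-6 * v[1]
    lv = np.log(np.maximum(v, floor))
    denom = lv[0] + lv[2] - 2.0 * lv[1]
    if denom >= 0:
        return 0.0
    return float(np.clip((lv[0] - lv[2]) / (2.0 * denom), -1.0, 1.0))


def phase_correlate(
    image_a: np.ndarray,
    image_b: np.ndarray,
    lowpass_sigma_bins: float = 1.0,
) -> tuple[float, float]:
    """Sub-pixel shift of ``image_b`` relative to ``image_a`` in bins.

    The normalised cross-power spectrum is inverted to a correlation surface;
    a Gaussian low-pass (spatial sigma ``lowpass_sigma_bins``) shapes the
    otherwise delta-like peak into a Gaussian, whose integer maximum is then
    refined by a separable Gaussian fit over the 3x3 neighbourhood. Returns
    ``(d0, d1)``: shifts along axis 0 and axis 1, i.e.
    ``image_b ~ roll(image_a, (d0, d1))``.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share one shape")
    if not (np.any(a) and np.any(b)):
        raise ValueError("all-zero image")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = np.conj(fa) * fb
    mag = np.abs(cross)
    cross = np.where(mag > 0, cross / np.maximum(mag, np.finfo(float).tiny), 0.0)
    if lowpass_sigma_bins > 0:
        f0 = np.fft.fftfreq(a.shape[0])
        f1 = np.fft.fftfreq(a.shape[1])
        w = np.exp(-2.0 * np.pi**2 * lowpass_sigma_bins**2 * (f0[:, None] ** 2 + f1[None, :] ** 2))
        cross = cross * w
    corr = np.fft.ifft2(cross).real
    p0, p1 = np.unravel_index(np.argmax(corr), corr.shape)
    # 3x3 neighbourhood with circular wrap-around
    rows = np.take(corr, [p0 - 1, p0, p0 + 1], axis=0, mode="wrap")
    patch = np.take(rows, [p1 - 1, p1, p1 + 1], axis=1, mode="wrap")
    d0 = p0 + _gaussian_peak_offset(patch.sum(axis=1))
    d1 = p1 + _gaussian_peak_offset(patch.sum(axis=0))
    if d0 > a.shape[0] / 2:
        d0 -= a.shape[0]
    if d1 > a.shape[1] / 2:
        d1 -= a.shape[1]
    return float(d0), float(d1)


def fit_drift(
    batch_shifts: list,
    degree: int,
    n_frames: int,
) -> DriftTrajectory:
    """Polynomial drift trajectory through cumulative batch shifts.

    ``batch_shifts`` holds ``(mid_frame, cum_dx_nm, cum_dy_nm)`` per batch,
    already cumulated over consecutive registrations. One polynomial per axis
    is fitted in frame index, evaluated at every frame, and anchored to zero
    at the first batch midpoint.
    """
    if len(batch_shifts) <= degree:
        raise ValueError("polynomial degree must be < number of batch shifts")
    mids = np.asarray([s[0] for s in batch_shifts], dtype=float)
    cx = np.asarray([s[1] for s in batch_shifts], dtype=float)
    cy = np.asarray([s[2] for s in batch_shifts], dtype=float)
    # scale frame index for conditioning
    scale = max(n_frames - 1, 1)
    px = np.polynomial.Polynomial.fit(mids / scale, cx, degree)
    py = np.polynomial.Polynomial.fit(mids / scale, cy, degree)
    f = np.arange(n_frames, dtype=float) / scale
    dx = px(f) - px(mids[0] / scale)
    dy = py(f) - py(mids[0] / scale)
    return DriftTrajectory(
        dx_nm=dx, dy_nm=dy,
        poly_x=px.convert().coef, poly_y=py.convert().coef,
        batch_shifts=[(float(m), float(a), float(b)) for m, a, b in batch_shifts],
    )


def correct_drift(locs: pd.DataFrame, traj: DriftTrajectory) -> pd.DataFrame:
    """Subtract the per-frame drift from x_nm / y_nm.

    Returns a copy with corrected coordinates; the uncorrected values are
    preserved in ``x_raw_nm`` / ``y_raw_nm``.
    """
    frames = np.asarray(locs["frame"], dtype=int)
    if len(frames) and (frames.min() < 0 or frames.max() >= traj.n_frames):
        raise ValueError("localization frame outside the drift trajectory")
    out = locs.copy()
    if "x_raw_nm" not in out.columns:
        out["x_raw_nm"] = out["x_nm"]
        out["y_raw_nm"] = out["y_nm"]
    out["x_nm"] = np.asarray(out["x_nm"], dtype=float) - traj.dx_nm[frames]
    out["y_nm"] = np.asarray(out["y_nm"], dtype=float) - traj.dy_nm[frames]
    return out


def estimate_drift(
    locs: pd.DataFrame,
    n_frames: int,
    batch_size: int = 1000,
    bin_size_nm: float = 107.0,
    degree: int = 3,
) -> DriftTrajectory:
    """End-to-end drift estimation: batch, histogram, register, interpolate.

    Consecutive batch images are registered (not all pairs); relative shifts
    are cumulated before the polynomial fit. The effective degree is capped at
    ``n_batches - 1``.
    """
    batches = batch_localizations(locs, batch_size)
    x = np.asarray(locs["x_nm"], dtype=float)
    y = np.asarray(locs["y_nm"], dtype=float)
    # one shared grid, padded so drifting emitters stay on-grid
    pad = 5 * bin_size_nm
    extent = (float(x.min() - pad), float(y.min() - pad))
    nx = int(np.ceil((x.max() + pad - extent[0]) / bin_size_nm)) + 1
    ny = int(np.ceil((y.max() + pad - extent[1]) / bin_size_nm)) + 1
    images = [histogram_image(b, bin_size_nm, extent=extent, shape=(ny, nx)) for b in batches]

    shifts = []
    cum = np.zeros(2)
    mid0 = float(np.median(batches[0]["frame"]))
    shifts.append((mid0, 0.0, 0.0))
    for k in range(1, len(images)):
        d0, d1 = phase_correlate(images[k - 1], images[k])
        cum = cum + np.array([d1, d0]) * bin_size_nm  # (dx, dy) in nm
        mid = float(np.median(batches[k]["frame"]))
        shifts.append((mid, float(cum[0]), float(cum[1])))
    deg = min(degree, len(shifts) - 1)
    return fit_drift(shifts, deg, n_frames)
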