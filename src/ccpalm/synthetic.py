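"""Synthetic ground-truth emitters, blinking kinetics and camera movie rendering.

The generator produces sparse photoconvertible emitters organised in elongated
clusters along a curved cord plus isolated background molecules, simulates
their on/off blinking schedules, and renders noisy EMCCD-like camera frames.
Ground truth is kept alongside so every downstream analysis stage can be
verified against it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .camera import CameraParams

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthEmitter",
    "PhantomLayout",
    "KineticsParams",
    "CameraFrameStack",
    "build_phantom",
    "simulate_kinetics",
    "render_movie",
    "cord_layout",
    "emitters_to_table",
    "emitters_from_table",
]


@dataclass
class GroundTruthEmitter:
    """One true fluorophore with its position and emission schedule.

    ``on_intervals`` are closed frame intervals ``[start, end]`` during which
    the emitter fluoresces; they are disjoint, ordered and start at or after
    ``conversion_frame``.
    """

    id: int
    x: float  # nm
    y: float  # nm
    cluster_id: Optional[int] = None  # None = background molecule
    conversion_frame: int = -1
    on_intervals: list = field(default_factory=list)
    photons_per_frame: float = 500.0
    dark_times_s: list = field(default_factory=list)  # continuous draws, diagnostics

    def validate(self) -> None:
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be > 0")
        prev_end = None
        for start, end in self.on_intervals:
            if start > end:
                raise ValueError(f"interval [{start}, {end}] reversed")
            if self.conversion_frame >= 0 and start < self.conversion_frame:
                raise ValueError("interval precedes conversion_frame")
            if prev_end is not None and start <= prev_end:
                raise ValueError("on_intervals overlap or are unordered")
            prev_end = end

    def is_on(self, frame: int) -> bool:
        return any(s <= frame <= e for s, e in self.on_intervals)


@dataclass
class PhantomLayout:
    """Spatial layout of the simulated sample.

    ``clusters`` is a list of tuples
    ``(center_xy_nm, sigma_minor_nm, sigma_major_nm, angle_rad, n_molecules)``
    describing rotated bivariate-normal molecule clusters. ``cord_path`` is an
    optional polyline (nm) recording the curve the clusters were placed along.
    """

    field_size: tuple = (10_000.0, 10_000.0)  # (width, height) nm
    clusters: list = field(default_factory=list)
    background_density: float = 0.0  # molecules per um^2
    cord_path: Optional[np.ndarray] = None

    def validate(self) -> None:
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError("field_size must have positive area")
        if self.background_density < 0:
            raise ValueError("background_density must be >= 0")
        for c in self.clusters:
            _, s_min, s_max, _, n = c
            if s_min > s_max:
                raise ValueError("cluster sigma_minor must be <= sigma_major")
            if n < 1:
                raise ValueError("cluster n_molecules must be >= 1")


@dataclass(frozen=True)
class KineticsParams:
    """Photoconversion / blinking / bleaching kinetics.

    Activation frames are drawn uniformly over the movie, which reproduces the
    effect of an activation-laser ramp holding the conversion rate steady.
    An emitter alternates on-intervals (geometric, mean ``mean_on_frames``)
    with short dark gaps (exponential, mean ``blink_dark_mean_s``); after each
    on-interval it re-enters a dark state with probability ``p_blink`` and
    otherwise bleaches permanently.
    """

    mean_on_frames: float = 2.0
    blink_dark_mean_s: float = 0.5
    p_blink: float = 0.3
    photons_per_frame: float = 500.0

    def validate(self) -> None:
        if not 0.0 <= self.p_blink < 1.0:
            raise ValueError("p_blink must be in [0, 1)")
        if self.mean_on_frames < 1.0:
            raise ValueError("mean_on_frames must be >= 1")
        if self.blink_dark_mean_s < 0:
            raise ValueError("blink_dark_mean_s must be >= 0")


@dataclass
class CameraFrameStack:
    """Ordered stack of 2D camera frames plus acquisition parameters."""

    frames: np.ndarray  # (n_frames, ny, nx)
    camera: CameraParams

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) array")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


def cord_layout(
    field_size: tuple = (15_000.0, 15_000.0),
    n_clusters: int = 10,
    mean_molecules: float = 20.2,
    thickness_log_coeff: tuple = (14.0, 8.0),
    aspect: tuple = (1.2, 1.8),
    background_density: float = 0.05,
    amplitude_nm: float = 1500.0,
    margin_nm: float = 1500.0,
    seed: int = 0,
) -> PhantomLayout:
    """Build a phantom layout with clusters strung along a curved cord.

    Cluster molecule counts are lognormal with the requested mean, mimicking a
    strongly right-skewed content distribution (a few large clusters, most
    small; minimum 8). Cluster FWHM thickness follows the logarithmic
    content relation ``a * ln(n) + b`` (coefficients ``thickness_log_coeff``,
    ~15% scatter) and length is ``aspect`` times the thickness, capped at
    440 nm; defaults keep thickness < 200 nm and length < 450 nm and make
    clusters dense enough that their members carry >= 4 neighbors within
    50 nm. Cluster axes follow the local cord direction.
    """
    rng = np.random.default_rng(seed)
    w, h = field_size
    xs = np.linspace(margin_nm, w - margin_nm, max(n_clusters, 2))
    phase = rng.uniform(0, 2 * np.pi)
    ys = h / 2 + amplitude_nm * np.sin(2 * np.pi * xs / w + phase)
    cord = np.column_stack([xs, ys])
    # lognormal with mean = mean_molecules and sd ~ 1.2 * mean (heavy tail)
    cv = 1.2
    s2 = np.log(1 + cv**2)
    mu = np.log(mean_molecules) - s2 / 2
    ta, tb = thickness_log_coeff
    clusters = []
    for i in range(n_clusters):
        n = max(8, int(round(rng.lognormal(mu, np.sqrt(s2)))))
        thickness = (ta * np.log(n) + tb) * rng.uniform(0.85, 1.15)
        thickness = float(np.clip(thickness, 30.0, 195.0))
        length = float(min(thickness * rng.uniform(*aspect), 440.0))
        fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
        s_min, s_max = thickness / fwhm, length / fwhm
        # local cord tangent sets the cluster orientation
        j = min(i, len(cord) - 2)
        t = cord[j + 1] - cord[j]
        angle = float(np.arctan2(t[1], t[0])) % np.pi
        clusters.append(((float(cord[i, 0]), float(cord[i, 1])), s_min, s_max, angle, n))
    return PhantomLayout(
        field_size=field_size,
        clusters=clusters,
        background_density=background_density,
        cord_path=cord,
    )


def build_phantom(layout: PhantomLayout, seed: int) -> list[GroundTruthEmitter]:
    """Draw ground-truth emitter positions from a :class:`PhantomLayout`.

    Cluster members are sampled from the rotated bivariate normal of their
    cluster; background molecules are a homogeneous Poisson process over the
    field at ``background_density`` per um^2. Deterministic for a fixed seed.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    emitters: list[GroundTruthEmitter] = []
    eid = 0
    for cid, (center, s_min, s_max, angle, n) in enumerate(layout.clusters):
        cos, sin = np.cos(angle), np.sin(angle)
        # major axis along `angle`, minor perpendicular
        u = rng.normal(0.0, s_max, n)
        v = rng.normal(0.0, s_min, n)
        x = center[0] + u * cos - v * sin
        y = center[1] + u * sin + v * cos
        for k in range(n):
            emitters.append(GroundTruthEmitter(id=eid, x=float(x[k]), y=float(y[k]), cluster_id=cid))
            eid += 1
    w, h = layout.field_size
    area_um2 = (w / 1000.0) * (h / 1000.0)
    n_bg = rng.poisson(layout.background_density * area_um2)
    bx = rng.uniform(0.0, w, n_bg)
    by = rng.uniform(0.0, h, n_bg)
    for k in range(n_bg):
        emitters.append(GroundTruthEmitter(id=eid, x=float(bx[k]), y=float(by[k]), cluster_id=None))
        eid += 1
    return emitters


def simulate_kinetics(
    emitters: Sequence[GroundTruthEmitter],
    kinetics: KineticsParams,
    n_frames: int,
    frame_interval_s: float,
    seed: int,
) -> list[GroundTruthEmitter]:
    """Fill in conversion frames and blinking schedules for every emitter.

    Conversion frames are uniform over the movie so the per-frame activation
    count has no systematic trend. Each schedule alternates on-intervals with
    short dark gaps until the molecule bleaches. Dark gaps are drawn from a
    continuous exponential (mean ``blink_dark_mean_s``) and quantised to at
    least one whole dark frame; the continuous draws are kept on the emitter
    for diagnostics. Mutates and returns the input list.
    """
    kinetics.validate()
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    rng = np.random.default_rng(seed)
    p_on = 1.0 / kinetics.mean_on_frames  # geometric success prob, support >= 1
    for em in emitters:
        conv = int(rng.integers(0, n_frames))
        em.conversion_frame = conv
        em.photons_per_frame = kinetics.photons_per_frame
        em.on_intervals = []
        em.dark_times_s = []
        t = conv
        while t < n_frames:
            dur = int(rng.geometric(p_on))
            start, end = t, min(t + dur - 1, n_frames - 1)
            em.on_intervals.append([start, end])
            if end >= n_frames - 1:
                break
            if rng.random() >= kinetics.p_blink:
                break  # bleached
            dark_s = float(rng.exponential(kinetics.blink_dark_mean_s))
            em.dark_times_s.append(dark_s)
            dark_frames = max(1, int(np.ceil(dark_s / frame_interval_s)))
            t = end + 1 + dark_frames
        em.validate()
    return list(emitters)


def _integrated_gaussian_1d(centers_px: np.ndarray, pos_px: float, sigma_px: float) -> np.ndarray:
    """Fraction of a unit Gaussian at pos_px falling into each 1-px-wide bin."""
    s = sigma_px * np.sqrt(2.0)
    lo = (centers_px - 0.5 - pos_px) / s
    hi = (centers_px + 0.5 - pos_px) / s
    return 0.5 * (erf(hi) - erf(lo))


def render_movie(
    emitters: Sequence[GroundTruthEmitter],
    camera: CameraParams,
    drift=None,
    n_frames: int = 0,
    shape: tuple = (128, 128),
    seed: int = 0,
    noise: str = "simple",
) -> CameraFrameStack:
    """Render blinking emitters into a noisy camera movie.

    Each on emitter contributes a pixel-integrated symmetric Gaussian
    (sigma = ``camera.psf_sigma_px``) at its drifted position. Photon shot
    noise is Poisson. ``noise='simple'`` applies deterministic EM gain plus
    Gaussian read noise; ``noise='emccd'`` draws gamma-distributed gain to
    approximate EMCCD excess noise; ``noise='none'`` renders the noise-free
    expectation (useful for conservation checks). Emitters outside the field
    are clipped silently (logged).

    Parameters
    ----------
    drift : optional
        Object with per-frame ``dx_nm``/``dy_nm`` arrays (a
        :class:`~ccpalm.drift.DriftTrajectory`) added to emitter positions.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    px = camera.pixel_size_nm
    sig = camera.psf_sigma_px
    half = int(np.ceil(4 * sig)) + 1

    # float32 + per-frame noise keeps long movies within a few hundred MB
    photons = np.zeros((n_frames, ny, nx), dtype=np.float32)
    if camera.background_photons > 0:
        photons += np.float32(camera.background_photons)

    n_clipped = 0
    dx = drift.dx_nm if drift is not None else None
    dy = drift.dy_nm if drift is not None else None
    for em in emitters:
        for start, end in em.on_intervals:
            for f in range(start, min(end, n_frames - 1) + 1):
                x_nm = em.x + (dx[f] if dx is not None else 0.0)
                y_nm = em.y + (dy[f] if dy is not None else 0.0)
                cx, cy = x_nm / px, y_nm / px
                if not (-half <= cx < nx + half and -half <= cy < ny + half):
                    n_clipped += 1
                    continue
                i0 = max(0, int(np.floor(cx)) - half)
                i1 = min(nx - 1, int(np.floor(cx)) + half)
                j0 = max(0, int(np.floor(cy)) - half)
                j1 = min(ny - 1, int(np.floor(cy)) + half)
                if i1 < i0 or j1 < j0:
                    n_clipped += 1
                    continue
                gx = _integrated_gaussian_1d(np.arange(i0, i1 + 1, dtype=float), cx, sig)
                gy = _integrated_gaussian_1d(np.arange(j0, j1 + 1, dtype=float), cy, sig)
                photons[f, j0:j1 + 1, i0:i1 + 1] += em.photons_per_frame * np.outer(gy, gx)
    if n_clipped:
        logger.info("render_movie: clipped %d emitter-frames outside the field", n_clipped)

    if noise not in ("none", "simple", "emccd"):
        raise ValueError(f"unknown noise model {noise!r}")
    counts = photons  # reused in place, frame by frame
    for f in range(n_frames):
        p = photons[f].astype(float)
        if noise == "none":
            frame = camera.baseline + camera.em_gain * p
        elif noise == "simple":
            frame = camera.baseline + camera.em_gain * rng.poisson(p).astype(float)
            if camera.read_noise > 0:
                frame += rng.normal(0.0, camera.read_noise, frame.shape)
        else:  # emccd
            shot = rng.poisson(p)
            frame = np.full(shot.shape, camera.baseline, dtype=float)
            nz = shot > 0
            # gamma(k, theta=gain): EMCCD cascade output for k input electrons
            frame[nz] += rng.gamma(shot[nz], camera.em_gain)
            if camera.read_noise > 0:
                frame += rng.normal(0.0, camera.read_noise, frame.shape)
        counts[f] = np.clip(frame, 0.0, None)
    return CameraFrameStack(frames=counts, camera=camera)


def emitters_to_table(emitters: Sequence[GroundTruthEmitter]) -> pd.DataFrame:
    """Ground truth as a flat table; on_intervals JSON-encoded per row."""
    rows = [
        {
            "id": em.id,
            "x_nm": em.x,
            "y_nm": em.y,
            "cluster_id": -1 if em.cluster_id is None else em.cluster_id,
            "conversion_frame": em.conversion_frame,
            "on_intervals": json.dumps(em.on_intervals),
            "photons_per_frame": em.photons_per_frame,
        }
        for em in emitters
    ]
    return pd.DataFrame(
        rows,
        columns=["id", "x_nm", "y_nm", "cluster_id", "conversion_frame", "on_intervals", "photons_per_frame"],
    )


def emitters_from_table(df: pd.DataFrame) -> list[GroundTruthEmitter]:
    out = []
    for row in df.itertuples(index=False):
        cid = None if row.cluster_id < 0 else int(row.cluster_id)
        out.append(
            GroundTruthEmitter(
                id=int(row.id),
                x=float(row.x_nm),
                y=float(row.y_nm),
                cluster_id=cid,
                conversion_frame=int(row.conversion_frame),
                on_intervals=json.loads(row.on_intervals),
                photons_per_frame=float(row.photons_per_frame),
            )
        )
    return out
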