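"""Consolidation of repeated detections of single fluorophores.

Two stages: (1) localizations that appear at the same location (within a
capture radius, default one camera pixel) in consecutive frames are linked
into one molecule; (2) molecules separated by a dark gap of at most ``t_d``
seconds at the same location are merged transitively, earliest-first, to
absorb blinking. The dark-time diagnostic curve — unique-molecule count as a
function of the allowed dark time, with its biphasic fit — supports the
choice of ``t_d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Molecule",
    "MergeParams",
    "link_consecutive",
    "link_blinking",
    "dark_time_curve",
    "molecules_to_table",
]


@dataclass
class Molecule:
    """A consolidated emitter with its detection history."""

    x: float  # nm, precision-weighted mean of members
    y: float
    first_frame: int
    last_frame: int
    n_detections: int
    member_ids: list = field(default_factory=list)
    max_gap_frames: int = 0
    weight: float = 0.0  # accumulated 1/precision^2


@dataclass(frozen=True)
class MergeParams:
    """Linking parameters.

    ``t_d`` is the allowed dark time in seconds, converted to frames through
    ``frame_interval_s``; ``off_gap_frames`` may be given directly instead
    (the two parameterizations used on the two instruments: t_d = 10 s, or an
    off gap of 200 frames with a capture radius of 1 pixel).
    """

    capture_radius_nm: float = 107.0
    t_d_s: float = 10.0
    frame_interval_s: float = 0.05
    off_gap_frames: int | None = None

    def __post_init__(self) -> None:
        if self.capture_radius_nm <= 0:
            raise ValueError("capture_radius_nm must be > 0")
        if self.t_d_s < 0:
            raise ValueError("t_d_s must be >= 0")

    @property
    def gap_frames(self) -> int:
        """Maximum allowed number of dark frames between appearances."""
        if self.off_gap_frames is not None:
            return int(self.off_gap_frames)
        return int(np.floor(self.t_d_s / self.frame_interval_s + 1e-9))


def _weight(precision_nm: float) -> float:
    if precision_nm is None or not np.isfinite(precision_nm) or precision_nm <= 0:
        return 1.0
    return 1.0 / (precision_nm * precision_nm)


def link_consecutive(locs: pd.DataFrame, params: MergeParams) -> list[Molecule]:
    """Greedy frame-to-frame linking of localizations into molecules.

    A localization in frame f joins a track whose last detection was in frame
    f-1 and whose current (precision-weighted) position lies within the
    capture radius; when several candidates compete, the closest pair wins and
    each localization joins at most one track. Localizations in the same frame
    never merge. Track positions are updated as precision-weighted running
    means.
    """
    locs = locs.sort_values("frame", kind="stable")
    frames = np.asarray(locs["frame"], dtype=int)
    xs = np.asarray(locs["x_nm"], dtype=float)
    ys = np.asarray(locs["y_nm"], dtype=float)
    ids = np.asarray(locs.index)
    prec = (
        np.asarray(locs["precision_nm"], dtype=float)
        if "precision_nm" in locs.columns
        else np.full(len(locs), np.nan)
    )

    molecules: list[Molecule] = []
    active: list[Molecule] = []  # tracks whose last_frame == previous frame
    r = params.capture_radius_nm

    for f in np.unique(frames):
        sel = np.flatnonzero(frames == f)
        active = [m for m in active if m.last_frame == f - 1]
        assigned_locs: set[int] = set()
        taken_tracks: set[int] = set()
        if active and sel.size:
            pairs = []
            for ti, m in enumerate(active):
                dx = xs[sel] - m.x
                dy = ys[sel] - m.y
                d = np.hypot(dx, dy)
                for li in np.flatnonzero(d <= r):
                    pairs.append((d[li], ti, int(sel[li])))
            pairs.sort()
            for d, ti, li in pairs:
                if ti in taken_tracks or li in assigned_locs:
                    continue
                m = active[ti]
                w = _weight(prec[li])
                tot = m.weight + w
                m.x = (m.x * m.weight + xs[li] * w) / tot
                m.y = (m.y * m.weight + ys[li] * w) / tot
                m.weight = tot
                m.last_frame = int(f)
                m.n_detections += 1
                m.member_ids.append(int(ids[li]))
                taken_tracks.add(ti)
                assigned_locs.add(li)
        for li in sel:
            if int(li) in assigned_locs:
                continue
            w = _weight(prec[li])
            m = Molecule(
                x=float(xs[li]), y=float(ys[li]),
                first_frame=int(f), last_frame=int(f),
                n_detections=1, member_ids=[int(ids[li])], weight=w,
            )
            molecules.append(m)
            active.append(m)
    return molecules


def link_blinking(molecules: list[Molecule], params: MergeParams) -> list[Molecule]:
    """Merge molecules across dark gaps of at most ``t_d`` at one location.

    Processing is transitive and earliest-first: each group keeps absorbing
    the earliest later molecule that reappears within the capture radius after
    a gap of 1..gap_frames dark frames; ties are broken by smaller spatial
    distance, then by lower molecule index, so output is deterministic.
    """
    gap_max = params.gap_frames
    order = sorted(range(len(molecules)), key=lambda i: (molecules[i].first_frame, i))
    merged = [False] * len(molecules)
    r = params.capture_radius_nm
    out: list[Molecule] = []
    for oi in order:
        if merged[oi]:
            continue
        m = molecules[oi]
        g = Molecule(
            x=m.x, y=m.y, first_frame=m.first_frame, last_frame=m.last_frame,
            n_detections=m.n_detections, member_ids=list(m.member_ids),
            max_gap_frames=m.max_gap_frames, weight=m.weight,
        )
        merged[oi] = True
        while True:
            best = None  # (first_frame, dist, idx)
            for oj in order:
                if merged[oj]:
                    continue
                c = molecules[oj]
                gap = c.first_frame - g.last_frame - 1
                if gap < 0:
                    continue
                if gap > gap_max:
                    break  # order is by first_frame: no later candidate fits
                d = float(np.hypot(c.x - g.x, c.y - g.y))
                if d <= r:
                    key = (c.first_frame, d, oj)
                    if best is None or key < best:
                        best = key
            if best is None:
                break
            oj = best[2]
            c = molecules[oj]
            merged[oj] = True
            tot = g.weight + c.weight
            g.x = (g.x * g.weight + c.x * c.weight) / tot
            g.y = (g.y * g.weight + c.y * c.weight) / tot
            g.weight = tot
            g.max_gap_frames = max(g.max_gap_frames, c.first_frame - g.last_frame - 1)
            g.first_frame = min(g.first_frame, c.first_frame)
            g.last_frame = max(g.last_frame, c.last_frame)
            g.n_detections += c.n_detections
            g.member_ids.extend(c.member_ids)
        out.append(g)
    return out


def _biphasic(t, A, tau, B, C):
    return A * np.exp(-t / tau) + B - C * t


def dark_time_curve(
    molecules: list[Molecule],
    t_d_grid: np.ndarray,
    params: MergeParams,
) -> dict:
    """Unique-molecule count versus allowed dark time, with a biphasic fit.

    For each t_d in the (ascending, >= 5 point) grid, the blink-merge step is
    rerun and the surviving molecule count recorded. The curve is fitted with
    N(t) = A exp(-t/tau) + B - C t: the fast exponential is the blinking
    component, the slow linear decline the coincidental-overlap component.
    Returns a dict with 't_d_s', 'counts', 'tau_s', 'fit' (A, tau, B, C) and
    'fit_ok'; a degenerate fit is flagged but the raw curve still returned.
    """
    t_d_grid = np.asarray(t_d_grid, dtype=float)
    if t_d_grid.size < 5 or np.any(np.diff(t_d_grid) <= 0):
        raise ValueError("t_d_grid must be ascending with at least 5 points")
    counts = np.empty(t_d_grid.size, dtype=int)
    for k, td in enumerate(t_d_grid):
        p = MergeParams(
            capture_radius_nm=params.capture_radius_nm,
            t_d_s=float(td),
            frame_interval_s=params.frame_interval_s,
        )
        counts[k] = len(link_blinking(molecules, p))
    result = {"t_d_s": t_d_grid, "counts": counts, "tau_s": np.nan, "fit": None, "fit_ok": False}
    try:
        span = counts[0] - counts[-1]
        p0 = [max(span, 1.0), max(t_d_grid[1], 0.1), float(counts[-1]), 0.0]
        popt, _ = curve_fit(
            _biphasic, t_d_grid, counts.astype(float), p0=p0,
            bounds=([0.0, 1e-6, 0.0, 0.0], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        result["fit"] = {"A": popt[0], "tau": popt[1], "B": popt[2], "C": popt[3]}
        result["tau_s"] = float(popt[1])
        result["fit_ok"] = bool(np.isfinite(popt).all())
    except Exception:
        pass
    return result


def molecules_to_table(molecules: list[Molecule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_nm": m.x, "y_nm": m.y,
                "first_frame": m.first_frame, "last_frame": m.last_frame,
                "n_detections": m.n_detections, "max_gap_frames": m.max_gap_frames,
            }
            for m in molecules
        ],
        columns=["x_nm", "y_nm", "first_frame", "last_frame", "n_detections", "max_gap_frames"],
    )
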