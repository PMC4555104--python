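"""The full analysis chain and its configuration.

Stages: simulate (optional) -> detect -> localize -> drift -> merge -> filter
-> clusters -> render. Every stage writes its table and the run log records
parameters, seeds, and record counts in/out, with the stage-level conservation
checks asserted (filters cannot grow the table; mergers conserve the total
detection count).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as ccio
from .camera import CameraParams
from .clusters import analyze_rois, fits_to_table, propose_rois, summarize_clusters
from .density import FilterParams, filter_outliers
from .detection import DetectionParams, detect_movie
from .drift import correct_drift, estimate_drift
from .localization import localize_movie, mean_resolution
from .merging import MergeParams, link_blinking, link_consecutive, molecules_to_table
from .render import RenderParams, render_palm
from .synthetic import (
    KineticsParams,
    build_phantom,
    cord_layout,
    emitters_to_table,
    render_movie,
    simulate_kinetics,
)

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; message carries the stage label."""


def default_config() -> dict:
    return {
        "seed": 0,
        "output_dir": "ccpalm_run",
        "camera": CameraParams().to_dict(),
        "simulate": {
            "enabled": True,
            "n_frames": 4000,
            "shape": [128, 128],
            "n_clusters": 8,
            "mean_molecules": 20.2,
            "background_density": 0.05,
            "kinetics": {
                "mean_on_frames": 2.0,
                "blink_dark_mean_s": 0.5,
                "p_blink": 0.3,
                "photons_per_frame": 800.0,
            },
            "noise": "simple",
        },
        "input_movie": None,
        "input_localizations": None,
        "detection": {"psf_sigma_px": 1.8, "glrt_sensitivity": 25.0, "window_half_size": None},
        "localization": {"free_sigma": False, "snr_definition": "amplitude / robust residual std",
                         "glrt_threshold_on": "raw statistic"},
        "drift": {"enabled": True, "batch_size": 1000, "bin_size_nm": None, "degree": 3},
        "merge": {"capture_radius_nm": None, "t_d_s": 10.0, "off_gap_frames": None},
        "filter": {"radius_nm": 50.0, "min_neighbors": 4, "keep_neighbors": True},
        "clusters": {"grid_nm": 150.0, "min_count": 5, "resolution_nm": 25.0},
        "render": {"mode": "gaussian", "spot_width_nm": 214.0, "output_pixel_nm": 10.0},
    }


def _merge_cfg(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_cfg(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the configured stages; returns the artifact bundle.

    The bundle maps stage names to their in-memory results and file paths.
    A stage failure raises :class:`PipelineError` labelled with the stage;
    artifacts written before the failure are kept.
    """
    cfg = _merge_cfg(default_config(), config)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    camera = CameraParams.from_dict(cfg["camera"])
    log: dict = {"seed": seed, "config": cfg, "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    bundle: dict = {"output_dir": out, "log": log}

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                t0 = time.time()
                log["stages"].setdefault(name, {})
                try:
                    r = fn(*a, **kw)
                except Exception as e:  # noqa: BLE001 - relabelled below
                    log["stages"][name]["error"] = str(e)
                    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
                    raise PipelineError(f"stage '{name}' failed: {e}") from e
                log["stages"][name]["seconds"] = round(time.time() - t0, 3)
                return r
            return wrapped
        return deco

    # --- simulate or load -------------------------------------------------
    ground_truth = None
    stack = None
    scfg = cfg["simulate"]
    if cfg.get("input_movie"):
        stack = ccio.read_movie(cfg["input_movie"])
        camera = stack.camera
    elif scfg.get("enabled"):
        @stage("simulate")
        def _simulate():
            shape = tuple(scfg["shape"])
            field = (shape[1] * camera.pixel_size_nm, shape[0] * camera.pixel_size_nm)
            layout = cord_layout(
                field_size=field,
                n_clusters=int(scfg["n_clusters"]),
                mean_molecules=float(scfg["mean_molecules"]),
                background_density=float(scfg["background_density"]),
                seed=seed,
            )
            emitters = build_phantom(layout, seed=seed + 1)
            kin = KineticsParams(**scfg["kinetics"])
            simulate_kinetics(emitters, kin, int(scfg["n_frames"]), camera.frame_interval_s, seed=seed + 2)
            stk = render_movie(
                emitters, camera, drift=None, n_frames=int(scfg["n_frames"]),
                shape=shape, seed=seed + 3, noise=scfg.get("noise", "simple"),
            )
            gt = emitters_to_table(emitters)
            ccio.write_table(out / "ground_truth.csv", gt)
            ccio.write_movie(out / "movie.tiff", stk, seed=seed)
            log["stages"]["simulate"].update(n_emitters=len(emitters), n_frames=stk.n_frames)
            return gt, stk
        ground_truth, stack = _simulate()
        bundle["ground_truth"] = ground_truth

    # --- detect + localize -------------------------------------------------
    if cfg.get("input_localizations"):
        locs = ccio.read_localizations(cfg["input_localizations"])
        n_frames = int(locs["frame"].max()) + 1
    else:
        if stack is None:
            raise PipelineError("stage 'detect' failed: no input movie, simulation disabled")
        det_params = DetectionParams(**cfg["detection"])

        @stage("detect")
        def _detect():
            dets = detect_movie(stack.frames, det_params)
            ccio.write_table(out / "detections.csv", dets)
            log["stages"]["detect"].update(n_in=int(stack.n_frames), n_out=len(dets))
            return dets
        detections = _detect()
        bundle["detections"] = detections

        @stage("localize")
        def _localize():
            lt = localize_movie(stack.frames, detections, det_params, camera)
            ccio.write_table(out / "localizations.csv", lt)
            log["stages"]["localize"].update(n_in=len(detections), n_out=len(lt))
            assert len(lt) <= len(detections)
            return lt
        locs = _localize()
        n_frames = stack.n_frames
    bundle["localizations"] = locs

    # --- drift -------------------------------------------------------------
    dcfg = cfg["drift"]
    if dcfg.get("enabled") and len(locs) >= 2 * int(dcfg["batch_size"]):
        @stage("drift")
        def _drift():
            bin_nm = dcfg["bin_size_nm"] or camera.pixel_size_nm
            traj = estimate_drift(locs, n_frames, batch_size=int(dcfg["batch_size"]),
                                  bin_size_nm=float(bin_nm), degree=int(dcfg["degree"]))
            corrected = correct_drift(locs, traj)
            ccio.write_table(out / "drift.csv", traj.to_table())
            ccio.write_table(out / "localizations_corrected.csv", corrected)
            log["stages"]["drift"].update(n_batches=len(traj.batch_shifts),
                                          max_shift_nm=float(np.hypot(traj.dx_nm, traj.dy_nm).max()))
            return corrected
        locs = _drift()
    else:
        log["stages"]["drift"] = {"skipped": True}
    bundle["localizations_corrected"] = locs

    # --- merge -------------------------------------------------------------
    mcfg = cfg["merge"]
    merge_params = MergeParams(
        capture_radius_nm=float(mcfg["capture_radius_nm"] or camera.pixel_size_nm),
        t_d_s=float(mcfg["t_d_s"]),
        frame_interval_s=camera.frame_interval_s,
        off_gap_frames=mcfg["off_gap_frames"],
    )

    @stage("merge")
    def _merge():
        tracks = link_consecutive(locs, merge_params)
        assert sum(m.n_detections for m in tracks) == len(locs), "detection count not conserved"
        mols = link_blinking(tracks, merge_params)
        assert sum(m.n_detections for m in mols) == len(locs), "detection count not conserved"
        mt = molecules_to_table(mols)
        ccio.write_table(out / "molecules.csv", mt)
        log["stages"]["merge"].update(n_in=len(locs), n_tracks=len(tracks), n_out=len(mols))
        return mt
    molecules = _merge()
    bundle["molecules"] = molecules

    # --- density filter ----------------------------------------------------
    @stage("filter")
    def _filter():
        fp = FilterParams(radius_nm=float(cfg["filter"]["radius_nm"]),
                          min_neighbors=int(cfg["filter"]["min_neighbors"]),
                          keep_neighbors=bool(cfg["filter"]["keep_neighbors"]))
        kept, removed = filter_outliers(molecules, fp)
        assert len(kept) + len(removed) == len(molecules)
        ccio.write_table(out / "molecules_filtered.csv", kept)
        ccio.write_table(out / "molecules_removed.csv", removed)
        log["stages"]["filter"].update(n_in=len(molecules), n_out=len(kept))
        return kept
    filtered = _filter()
    bundle["molecules_filtered"] = filtered

    # --- clusters ------------------------------------------------------------
    ccfg = cfg["clusters"]

    @stage("clusters")
    def _clusters():
        if len(filtered) == 0:
            ccio.write_table(out / "clusters.csv", fits_to_table([]))
            log["stages"]["clusters"].update(n_rois=0, n_fits=0)
            return []
        rois = propose_rois(filtered, grid_nm=float(ccfg["grid_nm"]), min_count=int(ccfg["min_count"]))
        ccio.write_rois(out / "rois.json", rois)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            fits = analyze_rois(filtered, rois, resolution_nm=float(ccfg["resolution_nm"]))
        ccio.write_table(out / "clusters.csv", fits_to_table(fits))
        log["stages"]["clusters"].update(n_rois=len(rois), n_fits=len(fits))
        if any(f.retained for f in fits):
            s = summarize_clusters(fits)
            log["stages"]["clusters"]["summary"] = {
                "mean_molecules": s.mean_molecules, "sd_molecules": s.sd_molecules,
                "fraction_below_50": s.fraction_below_50, "n_discarded_small": s.n_discarded_small,
            }
        return fits
    fits = _clusters()
    bundle["cluster_fits"] = fits

    # --- render --------------------------------------------------------------
    @stage("render")
    def _render():
        if len(filtered) == 0:
            log["stages"]["render"].update(skipped=True)
            return None
        rp = RenderParams(mode=cfg["render"]["mode"],
                          spot_width_nm=float(cfg["render"]["spot_width_nm"]),
                          output_pixel_nm=float(cfg["render"]["output_pixel_nm"]))
        img, extent = render_palm(filtered, rp)
        import tifffile
        tifffile.imwrite(out / "palm_render.tiff", img.astype(np.float32))
        log["stages"]["render"].update(shape=list(img.shape), extent=list(extent))
        return img
    bundle["render"] = _render()

    if len(locs) and "precision_nm" in locs.columns:
        try:
            mu, sd = mean_resolution(locs)
            log["mean_resolution_nm"] = {"mean": mu, "sd": sd}
        except ValueError:
            pass
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    return bundle
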