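"""File I/O: TIFF stacks, CSV tables, ROI JSON, run configs.

Localization tables use a plain CSV dialect with an import shim for
ThunderSTORM-style column names. CSV round-trips are lossless to full float
precision (repr-based formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .camera import CameraParams
from .clusters import RoiPolygon
from .synthetic import CameraFrameStack

__all__ = [
    "write_movie", "read_movie",
    "write_table", "read_table", "read_localizations",
    "write_rois", "read_rois",
    "load_config", "save_config",
]

# ThunderSTORM-style -> native column names
_THUNDERSTORM_MAP = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "uncertainty [nm]": "precision_nm",
    "uncertainty_xy [nm]": "precision_nm",
    "intensity [photon]": "photons",
    "offset [photon]": "background",
    "bkgstd [photon]": "background",
    "sigma [nm]": "sigma_nm",
    "id": "id",
    "frame": "frame",
}


def write_movie(path, stack: CameraFrameStack, seed: int | None = None, extra: dict | None = None) -> None:
    """16-bit multi-frame grayscale TIFF plus a YAML sidecar with metadata."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {"camera": stack.camera.to_dict(), "n_frames": int(stack.n_frames)}
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def read_movie(path) -> CameraFrameStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        camera = CameraParams.from_dict(meta["camera"])
    else:
        camera = CameraParams()
    return CameraFrameStack(frames=frames, camera=camera)


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    # round_trip parser keeps write-then-read exact to the last ulp
    return pd.read_csv(path, float_precision="round_trip")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table, renaming ThunderSTORM-style columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    df = df.rename(columns={k: v for k, v in _THUNDERSTORM_MAP.items() if k in df.columns})
    missing = {"frame", "x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table lacks columns: {sorted(missing)}")
    return df


def write_rois(path, rois: list[RoiPolygon]) -> None:
    payload = [
        {"label": r.label, "vertices_nm": np.asarray(r.vertices).tolist()} for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois(path) -> list[RoiPolygon]:
    payload = json.loads(Path(path).read_text())
    return [RoiPolygon(np.asarray(p["vertices_nm"], dtype=float), label=p.get("label", "")) for p in payload]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_config(path, cfg: dict) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=1))
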