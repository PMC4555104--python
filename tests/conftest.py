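import numpy as np
import pandas as pd
import pytest

from ccpalm.camera import CameraParams
from ccpalm.detection import DetectionParams
from ccpalm.synthetic import GroundTruthEmitter, render_movie


@pytest.fixture(scope="session")
def camera():
    return CameraParams(background_photons=10.0, read_noise=0.0)


@pytest.fixture(scope="session")
def det_params():
    return DetectionParams()


def make_spot_frames(
    camera: CameraParams,
    positions_nm,
    photons,
    n_frames: int = 1,
    shape=(32, 32),
    seed: int = 0,
    noise: str = "simple",
):
    """Render point emitters that are on for the whole short movie."""
    emitters = [
        GroundTruthEmitter(
            id=i, x=float(x), y=float(y), conversion_frame=0,
            on_intervals=[[0, n_frames - 1]], photons_per_frame=float(p),
        )
        for i, ((x, y), p) in enumerate(zip(positions_nm, np.broadcast_to(photons, (len(positions_nm),))))
    ]
    return render_movie(emitters, camera, n_frames=n_frames, shape=shape, seed=seed, noise=noise)


@pytest.fixture(scope="session")
def snr_suite(camera, det_params):
    """~600 single spots with peak SNR uniform in [6, 8], with ground truth.

    Returns (localization table, true positions nm). Used by the localization
    accuracy and precision-consistency tests.
    """
    from ccpalm.detection import Detection
    from ccpalm.localization import LOC_COLUMNS, fit_spot

    rng = np.random.default_rng(42)
    n = 600
    noise_std_photons = np.sqrt(camera.background_photons)
    shape = (24, 24)
    recs, truth = [], []
    for k in range(n):
        snr = rng.uniform(6.0, 8.0)
        peak_photons = snr * noise_std_photons
        flux = peak_photons * 2 * np.pi * camera.psf_sigma_px**2
        cx = (shape[1] / 2 + rng.uniform(-0.5, 0.5)) * camera.pixel_size_nm
        cy = (shape[0] / 2 + rng.uniform(-0.5, 0.5)) * camera.pixel_size_nm
        stack = make_spot_frames(camera, [(cx, cy)], flux, shape=shape, seed=1000 + k)
        det = Detection(frame=0, px=round(cx / camera.pixel_size_nm),
                        py=round(cy / camera.pixel_size_nm), component_size=5, test_statistic=99.0)
        rec = fit_spot(stack.frames[0], det, DetectionParams(), camera)
        recs.append(rec)
        truth.append((cx, cy))
    return pd.DataFrame(recs, columns=LOC_COLUMNS), np.asarray(truth)
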