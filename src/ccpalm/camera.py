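"""Camera / acquisition parameters shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class CameraParams:
    """Acquisition geometry and EMCCD noise model parameters.

    Coordinates are continuous nanometres with the origin at the centre of
    pixel (0, 0); pixel (i, j) spans ``[i - 0.5, i + 0.5) * pixel_size_nm``
    along each axis.
    """

    pixel_size_nm: float = 107.0
    psf_sigma_px: float = 1.8
    frame_interval_s: float = 0.05
    em_gain: float = 10.0
    read_noise: float = 2.0       # counts, std
    baseline: float = 100.0       # counts
    background_photons: float = 0.0  # expected photons / pixel / frame

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.em_gain <= 0:
            raise ValueError("em_gain must be > 0")

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_sigma_px * self.pixel_size_nm

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraParams":
        return cls(**d)
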