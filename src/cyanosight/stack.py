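"""Time-lapse image stack container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """Time-ordered 2-D intensity grids with physical calibration.

    ``frames`` has shape (T, H, W), axis order [t, y, x] with y increasing
    upward (see :mod:`cyanosight.angles`).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    light_direction_deg: float | None = None
    light_onset_frame: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def metadata(self) -> dict:
        m = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "light_direction_deg": self.light_direction_deg,
            "light_onset_frame": self.light_onset_frame,
        }
        m.update(self.meta)
        return m
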