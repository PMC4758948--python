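"""Reading and writing the package's on-disk formats.

Image stacks travel as multi-page grayscale TIFF (16-bit for rendered
stacks, 32-bit float for field maps) with a JSON sidecar holding the
physical metadata.  Tracks and spectra are plain CSV.

Raster files are y-down; the package works in a y-up mathematical frame
(see :mod:`cyanosight.angles`), so every image is flipped along its first
axis here, on the way in and on the way out.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import TrackSet

__all__ = [
    "write_stack",
    "read_stack",
    "write_tracks_csv",
    "read_tracks_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path, stack: np.ndarray, meta: dict) -> None:
    """Write a (T, H, W) or (H, W) array as multi-page TIFF + JSON sidecar."""
    path = Path(path)
    arr = np.asarray(stack)
    arr = arr[::-1] if arr.ndim == 2 else arr[:, ::-1]  # y-up -> y-down
    tifffile.imwrite(path, arr, photometric="minisblack")
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF (stack or single image) and its JSON sidecar if present."""
    path = Path(path)
    arr = tifffile.imread(path)
    arr = arr[::-1] if arr.ndim == 2 else arr[:, ::-1]  # y-down -> y-up
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return arr, meta


def write_tracks_csv(path, ts: TrackSet) -> None:
    ts.to_frame().to_csv(path, index=False)


def read_tracks_csv(path, pixel_size_um: float = 1.0,
                    frame_interval_s: float = 3.0) -> TrackSet:
    df = pd.read_csv(path)
    return TrackSet.from_frame(df, pixel_size_um, frame_interval_s)


def read_spectrum_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column table (wavelength_nm, value); header optional."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("spectrum CSV needs two columns (wavelength_nm, value)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_spectrum_csv(path, wavelength_nm: np.ndarray, value: np.ndarray,
                       value_name: str = "value") -> None:
    pd.DataFrame({"wavelength_nm": wavelength_nm, value_name: value}).to_csv(
        path, index=False
    )
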