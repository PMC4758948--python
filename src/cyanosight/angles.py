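"""Angle conventions shared by every module.

Angles are measured in **degrees**, anticlockwise from the +x axis, in a
mathematical (y-up) frame.  Images are stored in memory with axis order
``[y, x]`` and y increasing *upward*; the IO layer flips raster files
(which are y-down) on read and write so that all in-package geometry can
use the single convention above.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "ang_diff_deg", "unit_vector", "vector_angle_deg"]


def wrap_deg(angle):
    """Wrap angle(s) to the half-open interval (-180, 180]."""
    a = 180.0 - (180.0 - np.asarray(angle, dtype=float)) % 360.0
    return a if np.ndim(angle) else float(a)


def ang_diff_deg(a, b):
    """Signed circular difference a - b, wrapped to (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def unit_vector(angle_deg):
    """Unit vector (x, y) for an angle in the package convention."""
    t = np.deg2rad(angle_deg)
    return np.array([np.cos(t), np.sin(t)])


def vector_angle_deg(dx, dy):
    """Angle of the vector (dx, dy) in degrees, in (-180, 180]."""
    return float(np.rad2deg(np.arctan2(dy, dx)))
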