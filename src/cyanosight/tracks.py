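"""Trajectory containers: single-cell tracks and sets of tracks.

A :class:`Track` is an ordered sequence of (frame, x_um, y_um) samples with
strictly increasing, gap-free frame indices — a broken link starts a new
track.  A :class:`TrackSet` bundles tracks with the imaging calibration
(pixel size, frame interval) needed to express kinematics in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .angles import vector_angle_deg

__all__ = ["Track", "TrackSet"]


@dataclass
class Track:
    """One cell trajectory in physical coordinates (µm)."""

    id: int
    frames: np.ndarray  # int, strictly increasing, no gaps
    x_um: np.ndarray
    y_um: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("empty track")
        d = np.diff(self.frames)
        if len(d) and not np.all(d == 1):
            raise ValueError("track frames must be consecutive (no gaps)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def steps_um(self) -> np.ndarray:
        """Per-interval displacement magnitudes (µm)."""
        return np.hypot(np.diff(self.x_um), np.diff(self.y_um))

    def path_length_um(self) -> float:
        return float(self.steps_um().sum())

    def mean_speed_um_s(self, frame_interval_s: float) -> float:
        """Total path length divided by elapsed time."""
        if len(self) < 2:
            return 0.0
        elapsed = (self.frames[-1] - self.frames[0]) * frame_interval_s
        return self.path_length_um() / elapsed

    def net_displacement_um(self) -> np.ndarray:
        return np.array([self.x_um[-1] - self.x_um[0], self.y_um[-1] - self.y_um[0]])

    def orientation_deg(self) -> float:
        """Angle of the net displacement vector."""
        dx, dy = self.net_displacement_um()
        return vector_angle_deg(dx, dy)

    def slice_frames(self, start_frame: int, end_frame: int) -> "Track":
        """Sub-track covering the closed frame interval [start, end]."""
        m = (self.frames >= start_frame) & (self.frames <= end_frame)
        if not m.any():
            raise ValueError("track does not cover the requested interval")
        return Track(self.id, self.frames[m], self.x_um[m], self.y_um[m], self.label)

    def covers(self, start_frame: int, end_frame: int) -> bool:
        return self.frames[0] <= start_frame and self.frames[-1] >= end_frame


@dataclass
class TrackSet:
    """Collection of tracks plus imaging calibration."""

    tracks: list[Track] = field(default_factory=list)
    pixel_size_um: float = 1.0
    frame_interval_s: float = 3.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track ids must be unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: track_id, frame, t_s, x_um, y_um, label."""
        rows = []
        for t in self.tracks:
            rows.append(
                pd.DataFrame(
                    {
                        "track_id": t.id,
                        "frame": t.frames,
                        "t_s": t.frames * self.frame_interval_s,
                        "x_um": t.x_um,
                        "y_um": t.y_um,
                        "label": t.label if t.label is not None else "",
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["track_id", "frame", "t_s", "x_um", "y_um", "label"]
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        pixel_size_um: float = 1.0,
        frame_interval_s: float = 3.0,
    ) -> "TrackSet":
        tracks = []
        for tid, g in df.groupby("track_id", sort=True):
            g = g.sort_values("frame")
            label = None
            if "label" in g and len(g):
                lab = g["label"].iloc[0]
                label = None if (pd.isna(lab) or lab == "") else str(lab)
            tracks.append(
                Track(int(tid), g["frame"].to_numpy(), g["x_um"].to_numpy(),
                      g["y_um"].to_numpy(), label)
            )
        return cls(tracks, pixel_size_um, frame_interval_s)
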