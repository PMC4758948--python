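"""Track filtering, circular statistics and directionality analysis.

The track filters reproduce the quality-control rules used for
surface-motility time lapses of *Synechocystis*: only cells tracked for at
least 25 consecutive frames, with mean speed in [0.05, 0.4) µm/s and no
single-interval displacement of 8 µm or more, enter the directional
analysis; slower cells are classed immotile, faster ones (or jumps) are
assumed to be mis-associations.

Directionality is summarized with circular statistics: the mean resultant
length r of the displacement angles (0 = isotropic, 1 = perfectly aligned)
and the Rayleigh test of circular uniformity with the standard finite-n
series correction,

    Z = n r^2,
    p = exp(-Z) [1 + (2Z - Z^2)/(4n) - (24Z - 132Z^2 + 76Z^3 - 9Z^4)/(288 n^2)]

clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import ang_diff_deg, vector_angle_deg
from .tracks import Track, TrackSet

__all__ = [
    "FilterConfig",
    "CircStats",
    "filter_tracks",
    "displacement_orientation",
    "circular_stats",
    "directionality_timecourse",
    "direction_switch",
]


@dataclass
class FilterConfig:
    """Quality-control thresholds for raw tracks."""

    min_frames: int = 25
    min_mean_speed_um_s: float = 0.05  # below this: immotile
    max_mean_speed_um_s: float = 0.4
    max_step_um: float = 8.0  # per frame interval
    analysis_window_frames: int = 60
    window_start_after_onset_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.min_mean_speed_um_s < self.max_mean_speed_um_s:
            raise ValueError("need 0 < min_mean_speed < max_mean_speed")
        if self.min_frames < 1 or self.max_step_um <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CircStats:
    """Circular summary of a set of angles."""

    n: int
    mean_direction_deg: float
    r: float
    rayleigh_p: float
    mean_direction_defined: bool = True


def classify_track(track: Track, cfg: FilterConfig, frame_interval_s: float) -> str:
    """Return 'valid' or the first matching reject reason."""
    if track.n_frames < cfg.min_frames:
        return "too_short"
    if len(track) > 1 and track.steps_um().max() >= cfg.max_step_um:
        return "jump"
    v = track.mean_speed_um_s(frame_interval_s)
    # the boundary itself counts as motile (strict reading of "lower
    # than"); tolerate float rounding at the threshold
    if v < cfg.min_mean_speed_um_s and not np.isclose(
            v, cfg.min_mean_speed_um_s, rtol=1e-9, atol=1e-12):
        return "immotile"
    if v >= cfg.max_mean_speed_um_s:
        return "too_fast"
    return "valid"


def filter_tracks(
    ts: TrackSet, cfg: FilterConfig | None = None
) -> tuple[TrackSet, dict[int, str]]:
    """Apply the quality filters; return kept tracks and per-track reasons.

    A track is kept iff it spans at least ``min_frames`` consecutive
    frames, its mean speed lies in [min, max) µm/s, and every step is
    below ``max_step_um``.  The report maps every input track id to
    'valid' or its reject reason ('too_short' / 'immotile' / 'too_fast' /
    'jump').
    """
    cfg = cfg or FilterConfig()
    report: dict[int, str] = {}
    kept = []
    for t in ts:
        reason = classify_track(t, cfg, ts.frame_interval_s)
        report[t.id] = reason
        if reason == "valid":
            kept.append(t)
    return TrackSet(kept, ts.pixel_size_um, ts.frame_interval_s,
                    provenance=dict(ts.provenance, filtered=True)), report


def displacement_orientation(
    track: Track, window_frames: int, start_frame: int
) -> float:
    """Angle (degrees) of the net displacement over a frame window.

    Measured from the position at ``start_frame`` to the position at
    ``start_frame + window_frames``.  Returns NaN (flagged undefined) for
    zero net displacement.
    """
    end_frame = start_frame + window_frames
    if not track.covers(start_frame, end_frame):
        raise ValueError("track does not span the requested window")
    sub = track.slice_frames(start_frame, end_frame)
    dx, dy = sub.net_displacement_um()
    if dx == 0.0 and dy == 0.0:
        return float("nan")
    return vector_angle_deg(dx, dy)


def circular_stats(angles_deg) -> CircStats:
    """Mean direction, mean resultant length and Rayleigh p of angles."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    n = len(a)
    if n == 0:
        raise ValueError("circular_stats needs at least one finite angle")
    t = np.deg2rad(a)
    C, S = np.cos(t).sum(), np.sin(t).sum()
    R = np.hypot(C, S)
    r = R / n
    Z = n * r**2
    p = np.exp(-Z) * (
        1.0
        + (2 * Z - Z**2) / (4 * n)
        - (24 * Z - 132 * Z**2 + 76 * Z**3 - 9 * Z**4) / (288 * n**2)
    )
    p = float(np.clip(p, 0.0, 1.0))
    defined = r > 1e-12
    mean_dir = float(np.rad2deg(np.arctan2(S, C))) if defined else float("nan")
    return CircStats(n, mean_dir, float(r), p, defined)


def directionality_timecourse(
    ts: TrackSet,
    light_direction_deg: float,
    window_frames: int = 60,
    stride: int = 1,
) -> list[tuple[float, float | None]]:
    """Mean resultant length of light-relative headings vs time.

    For every window position, each track covering the window contributes
    the angle of its net displacement over the window, measured relative
    to the light direction (so movement toward the light clusters at 0°).
    Returns (window start time in s, r) pairs; windows with no eligible
    track yield ``None``.
    """
    if not ts.tracks:
        return []
    first = min(t.frames[0] for t in ts)
    last = max(t.frames[-1] for t in ts)
    out: list[tuple[float, float | None]] = []
    for start in range(first, last - window_frames + 1, stride):
        angles = []
        for t in ts:
            if t.covers(start, start + window_frames):
                a = displacement_orientation(t, window_frames, start)
                if np.isfinite(a):
                    angles.append(ang_diff_deg(a, light_direction_deg))
        t_s = start * ts.frame_interval_s
        out.append((t_s, circular_stats(angles).r if angles else None))
    return out


def direction_switch(
    track: Track,
    event_frame: int,
    frame_interval_s: float,
    window_s: float = 132.0,
) -> tuple[float, float, float]:
    """Net-displacement orientations before/after an event, and the turn.

    Uses windows of ``window_s`` seconds on each side of ``event_frame``
    (e.g. the closest approach to a localized light stimulus).  Returns
    (angle_before, angle_after, turn_angle) in degrees, where turn_angle
    is the circular difference wrapped to (-180, 180].
    """
    w = int(round(window_s / frame_interval_s))
    if w < 1:
        raise ValueError("window shorter than one frame interval")
    if not track.covers(event_frame - w, event_frame + w):
        raise ValueError("track does not cover both windows around the event")
    before = displacement_orientation(track, w, event_frame - w)
    after = displacement_orientation(track, w, event_frame)
    turn = float(ang_diff_deg(after, before))
    return before, after, turn
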