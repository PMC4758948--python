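"""Cell detection and frame-to-frame linking.

Detection uses the scale-normalized Laplacian-of-Gaussian (LoG) blob
filter: bright, roughly circular cells of radius R produce maxima of
``-sigma^2 * LoG`` at scale ``sigma = R / sqrt(2)``.  Local maxima are
collected at most one per patch of an ``n_patches x n_patches`` partition
of the image, thresholded on the filter response, and refined to
sub-pixel precision with a separable quadratic fit.

Linking associates detections in consecutive frames by spatial distance
only: mutually-nearest-neighbour pairs within a displacement gate are
joined (greedy by increasing distance when ties occur); every unlinked
detection starts a new track.  There is no gap closing — a missed
detection terminates the track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import ImageStack
from .tracks import Track, TrackSet

__all__ = ["Detection", "log_response", "detect_cells", "link_tracks", "track_stack"]


@dataclass
class Detection:
    """A single blob detection (sub-pixel, image coordinates)."""

    frame: int
    x: float  # px
    y: float  # px
    response: float


def log_response(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negated LoG response; bright blobs give maxima."""
    return -(sigma_px**2) * ndimage.gaussian_laplace(
        np.asarray(frame, dtype=float), sigma_px
    )


def _quadratic_refine(resp: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Sub-pixel peak offset from a separable 3-point quadratic fit."""

    def offset(m1, c, p1):
        denom = m1 - 2 * c + p1
        if denom >= 0:  # not a maximum along this axis
            return 0.0
        return float(np.clip(0.5 * (m1 - p1) / denom, -0.5, 0.5))

    dy = offset(resp[y - 1, x], resp[y, x], resp[y + 1, x])
    dx = offset(resp[y, x - 1], resp[y, x], resp[y, x + 1])
    return x + dx, y + dy


def detect_cells(
    frame: np.ndarray,
    expected_radius_um: float,
    pixel_size_um: float = 1.0,
    n_patches: int = 16,
    min_response: float = 0.0,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect blob-like cells in one image.

    Parameters
    ----------
    frame
        2-D intensity image.
    expected_radius_um
        Expected cell radius; sets the LoG scale ``sigma = R / sqrt(2)``.
    pixel_size_um
        Physical pixel size used to convert the radius to pixels.
    n_patches
        The image is split into ``n_patches x n_patches`` tiles and at
        most one maximum is kept per tile.
    min_response
        Minimum scale-normalized LoG response for a detection.
    """
    if expected_radius_um <= 0:
        raise ValueError("expected_radius_um must be > 0")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    radius_px = expected_radius_um / pixel_size_um
    if radius_px < 1.0:
        raise ValueError("expected radius is smaller than one pixel")
    sigma_px = radius_px / np.sqrt(2.0)

    resp = log_response(frame, sigma_px)
    H, W = resp.shape

    # The truncated filter kernel has a small non-zero DC gain, so flat
    # regions respond at gain * intensity; keep the detection floor above
    # that leak so only genuine blob maxima survive.
    k = 2 * int(4 * sigma_px + 1) + 1
    dc_gain = abs(float(log_response(np.ones((k, k)), sigma_px)[k // 2, k // 2]))
    floor = max(min_response, 2.0 * dc_gain * float(np.abs(frame).max()), 1e-12)

    # strict 8-neighbour local maxima, excluding the 1-px border
    m = ndimage.maximum_filter(resp, size=3, mode="constant", cval=-np.inf)
    is_max = (resp == m) & (resp > floor)
    # strictness: plateaus (e.g. constant images) are not maxima
    eroded = ndimage.minimum_filter(resp, size=3, mode="constant", cval=np.inf)
    is_max &= resp > eroded
    is_max[0, :] = is_max[-1, :] = False
    is_max[:, 0] = is_max[:, -1] = False

    ys, xs = np.nonzero(is_max)
    if len(ys) == 0:
        return []

    # keep the strongest candidate per patch
    py = np.minimum((ys * n_patches) // H, n_patches - 1)
    px = np.minimum((xs * n_patches) // W, n_patches - 1)
    best: dict[tuple[int, int], int] = {}
    for i in range(len(ys)):
        key = (int(py[i]), int(px[i]))
        if key not in best or resp[ys[i], xs[i]] > resp[ys[best[key]], xs[best[key]]]:
            best[key] = i

    dets = []
    for i in sorted(best.values()):
        xsub, ysub = _quadratic_refine(resp, int(ys[i]), int(xs[i]))
        dets.append(Detection(frame_index, xsub, ysub, float(resp[ys[i], xs[i]])))
    dets.sort(key=lambda d: (d.y, d.x))
    return dets


def _match_frames(
    prev: np.ndarray, curr: np.ndarray, gate: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs within ``gate`` (same units as coords)."""
    if len(prev) == 0 or len(curr) == 0:
        return []
    d = np.linalg.norm(prev[:, None, :] - curr[None, :, :], axis=2)
    cand = []
    row_nn = d.argmin(axis=1)
    col_nn = d.argmin(axis=0)
    for i, j in enumerate(row_nn):
        if col_nn[j] == i and d[i, j] < gate:
            cand.append((d[i, j], i, int(j)))
    cand.sort(key=lambda c: (c[0], c[1], c[2]))  # lowest index wins ties
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return pairs


def link_tracks(
    detections_per_frame: list[list[Detection]],
    max_step_um: float = 8.0,
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 3.0,
) -> TrackSet:
    """Link per-frame detections into tracks by spatial distance.

    ``detections_per_frame`` must be ordered by consecutive frame index;
    empty frames are permitted and terminate all open tracks.
    """
    open_tracks: dict[int, list[tuple[int, float, float]]] = {}
    closed: list[list[tuple[int, float, float]]] = []
    next_points: dict[int, list[tuple[int, float, float]]] = {}

    prev_dets: list[Detection] = []
    for k, dets in enumerate(detections_per_frame):
        # pixel i is centred at (i + 0.5) * pixel_size
        coords = (np.array([[d.x, d.y] for d in dets], dtype=float) + 0.5) \
            * pixel_size_um
        prev_coords = (np.array([[d.x, d.y] for d in prev_dets], dtype=float)
                       + 0.5) * pixel_size_um
        pairs = _match_frames(prev_coords.reshape(-1, 2), coords.reshape(-1, 2),
                              max_step_um)
        matched_prev = {i for i, _ in pairs}
        matched_curr = {j for _, j in pairs}

        next_points = {}
        for i, j in pairs:
            pts = open_tracks.pop(i)
            pts.append((dets[j].frame, coords[j, 0], coords[j, 1]))
            next_points[j] = pts
        # unmatched open tracks terminate
        closed.extend(open_tracks.values())
        # unmatched detections start new tracks
        for j, det in enumerate(dets):
            if j not in matched_curr:
                next_points[j] = [(det.frame, coords[j, 0], coords[j, 1])]
        open_tracks = next_points
        prev_dets = dets
        del matched_prev
    closed.extend(open_tracks.values())

    tracks = []
    for tid, pts in enumerate(sorted(closed, key=lambda p: (p[0][0], p[0][1], p[0][2]))):
        arr = np.array(pts)
        tracks.append(Track(tid, arr[:, 0].astype(int), arr[:, 1], arr[:, 2]))
    return TrackSet(tracks, pixel_size_um, frame_interval_s,
                    provenance={"linker": "mutual_nearest_neighbour",
                                "max_step_um": max_step_um})


def evaluate_tracking(
    found: TrackSet,
    truth: TrackSet,
    min_frames: int = 25,
) -> dict:
    """Score recovered tracks against generator ground truth.

    Each recovered point is assigned to the nearest ground-truth cell in
    its frame.  A recovered track is *pure* if every point maps to the
    same cell; pure tracks of at least ``min_frames`` frames recover that
    cell.  Returns the fraction of truth tracks recovered, the mean
    position error (µm) over pure tracks, and the number of identity
    swaps (long impure tracks).
    """
    gt = {t.id: np.stack([t.x_um, t.y_um], axis=1) for t in truth}
    gt_ids = list(gt.keys())
    recovered: dict[int, float] = {}
    swaps = 0
    for f in found:
        ids = []
        errs = []
        for fr, x, y in zip(f.frames, f.x_um, f.y_um):
            d = np.array([
                np.hypot(gt[i][fr, 0] - x, gt[i][fr, 1] - y) for i in gt_ids
            ])
            ids.append(gt_ids[int(np.argmin(d))])
            errs.append(float(d.min()))
        if f.n_frames < min_frames:
            continue
        if len(set(ids)) > 1:
            swaps += 1
            continue
        err = float(np.mean(errs))
        tid = ids[0]
        if tid not in recovered or err < recovered[tid]:
            recovered[tid] = err
    n_truth = sum(1 for t in truth if t.n_frames >= min_frames)
    frac = len(recovered) / n_truth if n_truth else float("nan")
    mean_err = float(np.mean(list(recovered.values()))) if recovered \
        else float("nan")
    return {"recovered_fraction": frac, "mean_error_um": mean_err,
            "n_swaps": swaps, "n_truth": n_truth}


def track_stack(
    stack: ImageStack,
    expected_radius_um: float = 1.5,
    max_step_um: float = 8.0,
    n_patches: int = 16,
    min_response: float = 0.0,
) -> TrackSet:
    """Detect cells in every frame of a stack and link them into tracks."""
    per_frame = [
        detect_cells(
            stack.frames[k], expected_radius_um, stack.pixel_size_um,
            n_patches, min_response, frame_index=k,
        )
        for k in range(stack.n_frames)
    ]
    ts = link_tracks(per_frame, max_step_um, stack.pixel_size_um,
                     stack.frame_interval_s)
    ts.provenance.update(stack.metadata())
    return ts
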