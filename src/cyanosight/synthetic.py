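"""Synthetic time-lapse stacks, ring images and track fixtures.

Everything downstream of raw video — blob detection, linking, the track
filters, circular statistics, circumference profiling — is exercised on
data from this module, which renders cells with known ground truth.

The default scene mirrors the imaging conditions of surface-motility
time-lapse microscopy of *Synechocystis*: ~3 µm diameter blob-like cells
on a flat background captured at one frame per 3 s, cell speeds in the
0.05–0.4 µm/s range, and direction switching toward an oblique light
source roughly one minute after light onset.

Motility models
---------------
``direct_steering``
    Persistent random walk before light onset (plus a programmable switch
    delay); afterwards the heading relaxes exponentially toward the light
    direction with time constant ``steering_tau_s`` while keeping its
    per-step angular noise.  This reproduces the observed behaviour of a
    cell that perceives the light source position directly.
``biased_random_walk``
    Run-and-tumble null model: straight runs interrupted by Poisson
    tumbles; after light onset a tumble re-draws the heading from a
    mixture of uniform (weight 1 − bias) and a light-centred von Mises
    (weight bias).  With ``bias_strength = 0`` displacement directions
    are isotropic.
``immotile``
    Cells never move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.spatial.distance import pdist, squareform

from .angles import ang_diff_deg, wrap_deg
from .stack import ImageStack
from .tracks import Track, TrackSet

__all__ = [
    "MotilityModel",
    "SceneConfig",
    "RingImageConfig",
    "generate_motility_stack",
    "generate_ring_image",
    "make_track_fixtures",
]

log = logging.getLogger(__name__)

_MODES = ("direct_steering", "biased_random_walk", "immotile")

GAUSS_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = 2.355 sigma


@dataclass
class MotilityModel:
    """Kinematic model of a single cell's heading and speed."""

    mode: str = "direct_steering"
    speed_mean_um_s: float = 0.2
    speed_sd_um_s: float = 0.05
    angular_noise_sd_deg: float = 10.0  # per step
    switch_delay_s: float = 60.0  # direct_steering only
    steering_tau_s: float = 30.0  # heading relaxation time constant
    tumble_rate_per_s: float = 0.05  # biased_random_walk only
    bias_strength: float = 0.0  # in [0, 1]

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown motility mode {self.mode!r}; pick from {_MODES}")
        if self.speed_mean_um_s < 0:
            raise ValueError("speed_mean_um_s must be >= 0")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must lie in [0, 1]")
        if self.switch_delay_s < 0:
            raise ValueError("switch_delay_s must be >= 0")


@dataclass
class SceneConfig:
    """Geometry, timing and photometry of a rendered time-lapse scene."""

    field_size_px: tuple[int, int] = (256, 256)  # (H, W)
    pixel_size_um: float = 0.2
    frame_interval_s: float = 3.0
    n_frames: int = 100
    n_cells: int = 20
    cell_radius_um: float = 1.5
    light_onset_frame: int = 20
    light_direction_deg: float = 0.0
    background_level: float = 100.0
    cell_amplitude: float = 1000.0
    noise_model: str = "poisson"  # "poisson", "gaussian:<sd>", or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class RingImageConfig:
    """A fluorescent periplasmic ring with a focal spot on its circumference.

    The intrinsic (pre-blur) angular profile is a uniform ring plus a von
    Mises-shaped bump positioned at ``spot_angle_deg``, scaled so the
    peak-to-front intensity ratio is exactly ``spot_ratio`` and the arc
    FWHM of the bump is ``spot_fwhm_nm``.  The rendered image is that
    profile swept around a radial Gaussian ring, convolved with a Gaussian
    point-spread function of FWHM ``psf_fwhm_nm``.
    """

    image_size_px: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.05
    cell_center_px: tuple[float, float] | None = None  # (x, y); default centre
    ring_radius_um: float = 1.5
    ring_width_um: float = 0.3  # radial FWHM of the ring
    spot_angle_deg: float = 180.0  # position of the focal spot on the ring
    spot_ratio: float = 4.1  # peak / front intensity, pre-blur
    spot_fwhm_nm: float = 550.0  # arc-length FWHM, pre-blur
    psf_fwhm_nm: float = 270.0
    base_intensity: float = 200.0
    noise_model: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_ratio < 1:
            raise ValueError("spot_ratio must be >= 1")
        if self.spot_fwhm_nm <= 0:
            raise ValueError("spot_fwhm_nm must be > 0")
        if self.psf_fwhm_nm < 0:
            raise ValueError("psf_fwhm_nm must be >= 0")


def _apply_noise(img: np.ndarray, noise_model: str, rng: np.random.Generator):
    if noise_model == "none":
        return img
    if noise_model == "poisson":
        return rng.poisson(np.clip(img, 0, None)).astype(float)
    if noise_model.startswith("gaussian"):
        sd = float(noise_model.split(":")[1]) if ":" in noise_model else 1.0
        return img + rng.normal(0.0, sd, img.shape)
    raise ValueError(f"unknown noise model {noise_model!r}")


# ---------------------------------------------------------------------------
# motility simulation


def _simulate_positions(scene: SceneConfig, model: MotilityModel,
                        rng: np.random.Generator) -> np.ndarray:
    """Ground-truth positions, shape (n_cells, n_frames, 2), in µm (x, y)."""
    H, W = scene.field_size_px
    w_um = W * scene.pixel_size_um
    h_um = H * scene.pixel_size_um
    n, T = scene.n_cells, scene.n_frames
    dt = scene.frame_interval_s

    pos = np.empty((n, T, 2))
    if n == 0:
        return pos

    margin = 2.0 * scene.cell_radius_um
    if 2 * margin >= w_um or 2 * margin >= h_um:
        raise ValueError("field too small for the requested cell radius margin")
    # hard-core placement: cells are solid bodies and should not overlap;
    # if the field is too crowded the last draw is accepted anyway and the
    # density warning below fires
    placed: list[np.ndarray] = []
    min_sep = 2.0 * scene.cell_radius_um
    for _ in range(n):
        for _attempt in range(200):
            p = rng.uniform([margin, margin], [w_um - margin, h_um - margin])
            if all(np.hypot(*(p - q)) >= min_sep for q in placed):
                break
        placed.append(p)
    pos[:, 0, :] = np.array(placed)

    if n > 1:
        nnd = squareform(pdist(pos[:, 0, :]))
        np.fill_diagonal(nnd, np.inf)
        if nnd.min(axis=1).mean() < 2 * scene.cell_radius_um:
            log.warning(
                "cell density high: mean nearest-neighbour distance %.2f um "
                "< cell diameter; expect tracking ambiguity",
                nnd.min(axis=1).mean(),
            )

    heading = rng.uniform(-180.0, 180.0, n)
    speed = np.clip(rng.normal(model.speed_mean_um_s, model.speed_sd_um_s, n), 0, None)
    if model.mode == "immotile":
        speed[:] = 0.0

    onset_t = scene.light_onset_frame * dt
    relax = 1.0 - np.exp(-dt / model.steering_tau_s)
    p_tumble = 1.0 - np.exp(-model.tumble_rate_per_s * dt)

    for k in range(1, T):
        t = k * dt
        noise = rng.normal(0.0, model.angular_noise_sd_deg, n)
        if model.mode == "direct_steering":
            if t >= onset_t + model.switch_delay_s:
                heading = heading + relax * ang_diff_deg(
                    scene.light_direction_deg, heading
                )
            heading = wrap_deg(heading + noise)
        elif model.mode == "biased_random_walk":
            tumbling = rng.random(n) < p_tumble
            new_uniform = rng.uniform(-180.0, 180.0, n)
            new_biased = np.rad2deg(
                rng.vonmises(np.deg2rad(scene.light_direction_deg), 2.0, n)
            )
            biased = rng.random(n) < (model.bias_strength if t >= onset_t else 0.0)
            heading = np.where(
                tumbling, np.where(biased, new_biased, new_uniform), heading
            )
            heading = wrap_deg(heading + noise)
        # immotile: heading irrelevant

        step = speed * dt
        x = pos[:, k - 1, 0] + step * np.cos(np.deg2rad(heading))
        y = pos[:, k - 1, 1] + step * np.sin(np.deg2rad(heading))
        # reflective boundaries at the placement margin (cells stay fully
        # inside the imaged field); both position and heading bounce
        lo, hix, hiy = margin, w_um - margin, h_um - margin
        refl_x = (x < lo) | (x > hix)
        refl_y = (y < lo) | (y > hiy)
        x = np.where(x < lo, 2 * lo - x, x)
        x = np.where(x > hix, 2 * hix - x, x)
        y = np.where(y < lo, 2 * lo - y, y)
        y = np.where(y > hiy, 2 * hiy - y, y)
        heading = wrap_deg(np.where(refl_x, 180.0 - heading, heading))
        heading = wrap_deg(np.where(refl_y, -heading, heading))
        trial = np.stack([x, y], axis=1)
        # volume exclusion: a step that would overlap another cell is
        # rejected (both cells of a touching pair stay put this interval)
        if n > 1:
            while True:
                dmat = squareform(pdist(trial))
                np.fill_diagonal(dmat, np.inf)
                bad = (dmat < min_sep).any(axis=1)
                moved = np.any(trial != pos[:, k - 1, :], axis=1)
                revert = bad & moved
                if not revert.any():
                    break  # clean, or overlap pre-dates this step
                trial[revert] = pos[revert, k - 1, :]
        pos[:, k, :] = trial
    return pos


def _render_frame(shape_px: tuple[int, int], centers_um: np.ndarray,
                  pixel_size_um: float, sigma_um: float, amplitude: float,
                  background: float) -> np.ndarray:
    """Additive 2-D Gaussian blobs on a flat background (y-up frame)."""
    H, W = shape_px
    img = np.full((H, W), float(background))
    sigma_px = sigma_um / pixel_size_um
    half = max(3, int(np.ceil(6 * sigma_px)))  # truncation below 2e-8
    for cx_um, cy_um in centers_um:
        cx = cx_um / pixel_size_um - 0.5  # pixel centre convention
        cy = cy_um / pixel_size_um - 0.5
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0, x1 = max(x0, 0), min(x1, W)
        y0, y1 = max(y0, 0), min(y1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2)
        )
    return img


def generate_motility_stack(
    scene: SceneConfig, model: MotilityModel
) -> tuple[ImageStack, TrackSet]:
    """Render a time-lapse stack of moving cells plus its ground truth.

    Cells are radially symmetric Gaussian blobs (sigma = cell_radius / 2)
    on a flat background, with Poisson noise by default.  The returned
    :class:`TrackSet` holds the exact positions used for rendering.
    """
    rng = np.random.default_rng(scene.seed)
    pos = _simulate_positions(scene, model, rng)

    sigma_um = scene.cell_radius_um / 2.0
    frames = np.empty((scene.n_frames, *scene.field_size_px))
    for k in range(scene.n_frames):
        img = _render_frame(
            scene.field_size_px, pos[:, k, :], scene.pixel_size_um,
            sigma_um, scene.cell_amplitude, scene.background_level,
        )
        frames[k] = _apply_noise(img, scene.noise_model, rng)

    stack = ImageStack(
        frames,
        pixel_size_um=scene.pixel_size_um,
        frame_interval_s=scene.frame_interval_s,
        light_direction_deg=scene.light_direction_deg,
        light_onset_frame=scene.light_onset_frame,
    )
    tracks = [
        Track(i, np.arange(scene.n_frames), pos[i, :, 0], pos[i, :, 1])
        for i in range(scene.n_cells)
    ]
    ts = TrackSet(tracks, scene.pixel_size_um, scene.frame_interval_s,
                  provenance={"generator": "generate_motility_stack",
                              "mode": model.mode, "seed": scene.seed})
    return stack, ts


# ---------------------------------------------------------------------------
# ring images


def vonmises_kappa_for_fwhm(fwhm_deg: float) -> float:
    """Concentration of a baseline-subtracted von Mises bump with a given FWHM.

    The bump shape is f(d) = (exp(k (cos d - 1)) - exp(-2k)) / (1 - exp(-2k)),
    equal to 1 at the peak and exactly 0 at the antipode; kappa is solved so
    that f(fwhm/2) = 1/2.
    """
    if not 0 < fwhm_deg < 360:
        raise ValueError("fwhm_deg must lie in (0, 360)")
    half = np.deg2rad(fwhm_deg / 2.0)

    def g(k):
        return (np.exp(k * (np.cos(half) - 1)) - np.exp(-2 * k)) / (
            1 - np.exp(-2 * k)
        ) - 0.5

    return brentq(g, 1e-6, 1e6)


def _spot_bump(delta_deg: np.ndarray, kappa: float) -> np.ndarray:
    d = np.deg2rad(delta_deg)
    return (np.exp(kappa * (np.cos(d) - 1)) - np.exp(-2 * kappa)) / (
        1 - np.exp(-2 * kappa)
    )


def ring_angular_profile(cfg: RingImageConfig, angles_deg: np.ndarray) -> np.ndarray:
    """Intrinsic angular intensity profile A(phi) of the ring, pre-blur."""
    circumference_nm = 2 * np.pi * cfg.ring_radius_um * 1e3
    if cfg.spot_fwhm_nm > circumference_nm / 2:
        raise ValueError("spot_fwhm_nm exceeds half the ring circumference")
    fwhm_deg = cfg.spot_fwhm_nm / circumference_nm * 360.0
    kappa = vonmises_kappa_for_fwhm(fwhm_deg)
    bump = _spot_bump(ang_diff_deg(angles_deg, cfg.spot_angle_deg), kappa)
    return cfg.base_intensity * (1.0 + (cfg.spot_ratio - 1.0) * bump)


def generate_ring_image(cfg: RingImageConfig) -> tuple[np.ndarray, dict]:
    """Render a PSF-blurred fluorescent ring image plus its ground truth.

    Returns the image (y-up frame) and a dict with the intrinsic profile
    (``arc_nm``, ``intensity`` sampled densely starting at the front of
    the cell, anticlockwise), the generating parameters, and the expected
    post-blur FWHM under the Gaussian quadrature model.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_size_px
    if cfg.cell_center_px is None:
        cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    else:
        cx, cy = cfg.cell_center_px

    r_px = cfg.ring_radius_um / cfg.pixel_size_um
    w_sigma_px = (cfg.ring_width_um / GAUSS_FWHM_SIGMA) / cfg.pixel_size_um
    if (r_px + 3 * w_sigma_px) > min(cx, cy, W - 1 - cx, H - 1 - cy):
        raise ValueError("ring does not fit inside the image")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    rr = np.hypot(xx - cx, yy - cy)
    phi = np.rad2deg(np.arctan2(yy - cy, xx - cx))
    angular = ring_angular_profile(cfg, phi)
    img = angular * np.exp(-((rr - r_px) ** 2) / (2 * w_sigma_px**2))

    if cfg.psf_fwhm_nm > 0:
        psf_sigma_px = (cfg.psf_fwhm_nm * 1e-3 / GAUSS_FWHM_SIGMA) / cfg.pixel_size_um
        img = ndimage.gaussian_filter(img, psf_sigma_px, mode="constant")
    img = _apply_noise(img, cfg.noise_model, rng)

    front_angle = wrap_deg(cfg.spot_angle_deg + 180.0)
    arc_angles = np.linspace(0.0, 360.0, 3600, endpoint=False)
    circumference_nm = 2 * np.pi * cfg.ring_radius_um * 1e3
    truth = {
        "cell_center_px": (cx, cy),
        "front_angle_deg": front_angle,
        "arc_nm": arc_angles / 360.0 * circumference_nm,
        "intensity": ring_angular_profile(cfg, wrap_deg(front_angle + arc_angles)),
        "spot_ratio": cfg.spot_ratio,
        "spot_fwhm_nm": cfg.spot_fwhm_nm,
        "expected_blurred_fwhm_nm": float(
            np.hypot(cfg.spot_fwhm_nm, cfg.psf_fwhm_nm)
        ),
    }
    return img, truth


# ---------------------------------------------------------------------------
# track fixtures


def make_track_fixtures(
    spec: list[tuple],
    seed: int = 0,
    frame_interval_s: float = 3.0,
    pixel_size_um: float = 0.2,
) -> TrackSet:
    """Synthesize labelled tracks with exact frame counts and mean speeds.

    Each spec item is ``(n_frames, mean_speed_um_s, max_step_um, label)``
    (``max_step_um`` and ``label`` optional).  When ``max_step_um`` exceeds
    the uniform step implied by the mean speed, one single step of exactly
    ``max_step_um`` is inserted and the remaining steps are shrunk so the
    mean speed stays exact — useful for building jump-rejection fixtures.
    """
    rng = np.random.default_rng(seed)
    tracks = []
    for tid, item in enumerate(spec):
        n_frames, mean_speed = item[0], float(item[1])
        max_step = float(item[2]) if len(item) > 2 and item[2] is not None else None
        label = item[3] if len(item) > 3 else None
        if mean_speed < 0:
            raise ValueError("mean speed must be >= 0")
        if n_frames < 1:
            raise ValueError("n_frames must be >= 1")

        n_steps = n_frames - 1
        base_step = mean_speed * frame_interval_s
        steps = np.full(n_steps, base_step)
        if max_step is not None and n_steps:
            if max_step < base_step:
                raise ValueError(
                    f"unreachable fixture: max_step {max_step} um < mean step "
                    f"{base_step} um"
                )
            if max_step > base_step:
                total = base_step * n_steps
                rest = total - max_step
                if n_steps < 2 or rest < 0:
                    raise ValueError("cannot place the requested max step")
                steps = np.full(n_steps, rest / (n_steps - 1))
                steps[n_steps // 2] = max_step

        heading = rng.uniform(-180, 180)
        headings = wrap_deg(heading + np.cumsum(rng.normal(0, 15, n_steps))) \
            if n_steps else np.empty(0)
        dx = steps * np.cos(np.deg2rad(headings))
        dy = steps * np.sin(np.deg2rad(headings))
        x = np.concatenate([[0.0], np.cumsum(dx)]) + rng.uniform(10, 40)
        y = np.concatenate([[0.0], np.cumsum(dy)]) + rng.uniform(10, 40)
        tracks.append(Track(tid, np.arange(n_frames), x, y, label))
    return TrackSet(tracks, pixel_size_um, frame_interval_s,
                    provenance={"generator": "make_track_fixtures", "seed": seed})
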