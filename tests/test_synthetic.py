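"""Tests of the synthetic scene, ring-image and fixture generators."""

import numpy as np
import pytest

from cyanosight.motility import circular_stats
from cyanosight.synthetic import (
    GAUSS_FWHM_SIGMA,
    MotilityModel,
    RingImageConfig,
    SceneConfig,
    generate_motility_stack,
    generate_ring_image,
    make_track_fixtures,
    ring_angular_profile,
)
from cyanosight.tracking import detect_cells


def small_scene(**kw):
    base = dict(field_size_px=(96, 96), pixel_size_um=0.2, n_frames=5,
                n_cells=3, cell_amplitude=1000.0, background_level=100.0,
                seed=7)
    base.update(kw)
    return SceneConfig(**base)


class TestMotilityStack:
    def test_empty_scene_is_pure_background(self):
        stack, ts = generate_motility_stack(
            small_scene(n_cells=0, noise_model="none"), MotilityModel()
        )
        assert len(ts) == 0
        assert np.allclose(stack.frames, 100.0)

    def test_immotile_cells_never_move(self):
        _, ts = generate_motility_stack(
            small_scene(n_cells=1, n_frames=8), MotilityModel(mode="immotile")
        )
        t = ts.tracks[0]
        assert np.allclose(t.x_um, t.x_um[0]) and np.allclose(t.y_um, t.y_um[0])

    def test_noise_free_steering_step_length_is_speed_times_interval(self):
        # analytic kinematics: 0.2 um/s * 3 s = 0.6 um per step, exactly
        model = MotilityModel(mode="direct_steering", speed_mean_um_s=0.2,
                              speed_sd_um_s=0.0, angular_noise_sd_deg=0.0)
        _, ts = generate_motility_stack(
            small_scene(n_cells=1, n_frames=10, field_size_px=(1024, 1024)),
            model,
        )
        steps = ts.tracks[0].steps_um()
        assert np.allclose(steps, 0.6, atol=1e-12)

    def test_identical_seed_gives_bit_identical_output(self):
        a, ta = generate_motility_stack(small_scene(), MotilityModel())
        b, tb = generate_motility_stack(small_scene(), MotilityModel())
        assert np.array_equal(a.frames, b.frames)
        assert all(
            np.array_equal(x.x_um, y.x_um) and np.array_equal(x.y_um, y.y_um)
            for x, y in zip(ta, tb)
        )

    def test_rendering_centers_match_ground_truth(self):
        # LoG detection on a noise-free single-cell frame recovers the
        # rendered position to better than half a pixel
        stack, ts = generate_motility_stack(
            small_scene(n_cells=1, n_frames=1, noise_model="none"),
            MotilityModel(mode="immotile"),
        )
        det = detect_cells(stack.frames[0], 1.5, 0.2, n_patches=4)
        assert len(det) == 1
        t = ts.tracks[0]
        x_px = t.x_um[0] / 0.2 - 0.5
        y_px = t.y_um[0] / 0.2 - 0.5
        assert np.hypot(det[0].x - x_px, det[0].y - y_px) < 0.5

    def test_unbiased_random_walk_has_isotropic_displacements(self):
        scene = small_scene(field_size_px=(1500, 1500), n_cells=500,
                            n_frames=25, seed=3)
        model = MotilityModel(mode="biased_random_walk", bias_strength=0.0,
                              speed_mean_um_s=0.2)
        _, ts = generate_motility_stack(scene, model)
        angles = [t.orientation_deg() for t in ts]
        assert circular_stats(angles).r < 0.1

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            MotilityModel(mode="levitate")

    def test_high_density_logs_warning(self, caplog):
        import logging

        # 12 cells of 1.5 um radius on a 12.8 um field cannot keep a
        # cell-diameter separation: the generator warns about crowding
        scene = small_scene(n_cells=12, field_size_px=(64, 64), n_frames=2)
        with caplog.at_level(logging.WARNING, "cyanosight.synthetic"):
            generate_motility_stack(scene, MotilityModel(mode="immotile"))
        assert any("density" in r.message for r in caplog.records)


class TestRingImage:
    def test_uniform_ring_when_ratio_is_one(self):
        # integer centre so the four compass points sit at the same radius
        cfg = RingImageConfig(spot_ratio=1.0, psf_fwhm_nm=0.0,
                              cell_center_px=(64.0, 64.0))
        img, truth = generate_ring_image(cfg)
        prof = truth["intensity"]
        assert prof.max() / prof.min() == pytest.approx(1.0, abs=1e-12)
        # image itself is angularly uniform: compare four compass points
        cx, cy = truth["cell_center_px"]
        r = int(round(cfg.ring_radius_um / cfg.pixel_size_um))
        vals = [img[int(cy), int(cx) + r], img[int(cy), int(cx) - r],
                img[int(cy) + r, int(cx)], img[int(cy) - r, int(cx)]]
        assert max(vals) / min(vals) == pytest.approx(1.0, rel=1e-6)

    def test_unblurred_profile_fwhm_matches_config(self):
        cfg = RingImageConfig(spot_fwhm_nm=550.0, psf_fwhm_nm=0.0)
        circ = 2 * np.pi * cfg.ring_radius_um * 1e3
        ang = np.linspace(0, 360, 7200, endpoint=False)
        prof = ring_angular_profile(cfg, ang)
        base, peak = prof.min(), prof.max()
        width_deg = (prof > base + (peak - base) / 2).sum() * 360 / len(ang)
        assert width_deg / 360 * circ == pytest.approx(550.0, abs=circ / 7200)

    def test_blurred_fwhm_follows_gaussian_quadrature(self):
        # oracle: dense 1-D convolution of the intrinsic profile with the PSF
        cfg = RingImageConfig(spot_fwhm_nm=550.0, psf_fwhm_nm=270.0)
        circ = 2 * np.pi * cfg.ring_radius_um * 1e3
        ang = np.linspace(0, 360, 36000, endpoint=False)
        arc = ang / 360 * circ
        prof = ring_angular_profile(cfg, ang)
        sigma = 270.0 / GAUSS_FWHM_SIGMA
        d = arc[1] - arc[0]
        kx = np.arange(-3000, 3000, d)
        ker = np.exp(-(kx**2) / (2 * sigma**2))
        ker /= ker.sum()
        blur = np.convolve(np.tile(prof, 3), ker, mode="same")[
            len(prof):2 * len(prof)]
        base, peak = blur.min(), blur.max()
        fwhm = (blur > base + (peak - base) / 2).sum() * d
        assert fwhm == pytest.approx(np.hypot(550, 270), rel=0.02)

    def test_oversized_spot_rejected(self):
        circ = 2 * np.pi * 1.5e3
        with pytest.raises(ValueError, match="circumference"):
            generate_ring_image(RingImageConfig(spot_fwhm_nm=0.6 * circ))

    def test_deterministic_given_seed(self):
        cfg = RingImageConfig(noise_model="poisson", seed=5)
        a, _ = generate_ring_image(cfg)
        b, _ = generate_ring_image(cfg)
        assert np.array_equal(a, b)


class TestTrackFixtures:
    def test_empty_spec_gives_empty_set(self):
        assert len(make_track_fixtures([])) == 0

    def test_mean_speed_is_exact(self):
        ts = make_track_fixtures([(30, 0.2, None, "valid")])
        t = ts.tracks[0]
        assert t.n_frames == 30
        assert t.mean_speed_um_s(3.0) == pytest.approx(0.2, abs=1e-9)

    def test_max_step_is_placed_exactly_once(self):
        ts = make_track_fixtures([(30, 0.2, 9.0, "jump")])
        steps = ts.tracks[0].steps_um()
        assert steps.max() == pytest.approx(9.0, abs=1e-9)
        assert ts.tracks[0].mean_speed_um_s(3.0) == pytest.approx(0.2, abs=1e-9)

    def test_unreachable_spec_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            make_track_fixtures([(30, 0.2, 0.1, "x")])
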