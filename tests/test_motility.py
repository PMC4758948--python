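"""Tests of track filtering, circular statistics and direction analysis."""

import numpy as np
import pingouin
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import iv
from scipy.stats import kstest

from cyanosight.motility import (
    FilterConfig,
    circular_stats,
    direction_switch,
    directionality_timecourse,
    displacement_orientation,
    filter_tracks,
)
from cyanosight.synthetic import (
    MotilityModel,
    SceneConfig,
    make_track_fixtures,
)
from cyanosight.synthetic import _simulate_positions
from cyanosight.tracks import Track, TrackSet


def straight_track(n, speed, heading_deg, frame_interval=3.0, tid=0,
                   start_frame=0):
    step = speed * frame_interval
    t = np.arange(n)
    x = step * t * np.cos(np.deg2rad(heading_deg))
    y = step * t * np.sin(np.deg2rad(heading_deg))
    return Track(tid, start_frame + t, x, y)


class TestFilters:
    def test_empty_set_passes_through(self):
        kept, report = filter_tracks(TrackSet([], 0.2, 3.0))
        assert len(kept) == 0 and report == {}

    def test_slow_track_rejected_as_immotile(self):
        ts = make_track_fixtures([(30, 0.04, None, "immotile")])
        kept, report = filter_tracks(ts)
        assert len(kept) == 0
        assert report[0] == "immotile"

    def test_threshold_track_at_005_is_motile(self):
        # strict reading: mean speed exactly 0.05 um/s is kept
        ts = make_track_fixtures([(30, 0.05, None, None)])
        kept, _ = filter_tracks(ts)
        assert len(kept) == 1

    def test_labelled_fixture_set_classified_exactly(self):
        # 3 short, 2 immotile, 1 fast, 4 valid -> exactly 4 kept
        spec = [
            (10, 0.2, None, "too_short"),
            (24, 0.1, None, "too_short"),
            (5, 0.3, None, "too_short"),
            (30, 0.04, None, "immotile"),
            (40, 0.01, None, "immotile"),
            (30, 0.45, None, "too_fast"),
            (25, 0.1, None, "valid"),
            (30, 0.2, None, "valid"),
            (60, 0.39, None, "valid"),
            (25, 0.05, None, "valid"),
        ]
        ts = make_track_fixtures(spec, seed=2)
        kept, report = filter_tracks(ts)
        assert len(kept) == 4
        for t in ts:
            assert report[t.id] == t.label

    def test_jump_rejected_by_step_gate(self):
        ts = make_track_fixtures([(30, 0.3, 9.0, "jump")])
        _, report = filter_tracks(ts)
        assert report[0] == "jump"

    def test_filtering_is_idempotent(self):
        spec = [(30, s, None, None) for s in (0.01, 0.1, 0.2, 0.5, 0.3)]
        ts = make_track_fixtures(spec, seed=4)
        once, _ = filter_tracks(ts)
        twice, report = filter_tracks(once)
        assert len(twice) == len(once)
        assert all(v == "valid" for v in report.values())


class TestDisplacementOrientation:
    def test_pure_x_motion_is_zero_degrees(self):
        t = straight_track(61, 0.2, 0.0)
        assert displacement_orientation(t, 60, 0) == pytest.approx(0.0)

    def test_diagonal_motion_is_45_degrees(self):
        t = Track(0, np.arange(2), np.array([0.0, 3.0]), np.array([0.0, 3.0]))
        assert displacement_orientation(t, 1, 0) == pytest.approx(45.0)

    def test_net_displacement_matches_coordinate_arithmetic(self):
        # 0.2 um/s toward 120 deg for 60 frames x 3 s -> 36 um at 120 deg
        t = straight_track(61, 0.2, 120.0)
        sub = t.slice_frames(0, 60)
        assert np.linalg.norm(sub.net_displacement_um()) == pytest.approx(36.0)
        assert displacement_orientation(t, 60, 0) == pytest.approx(120.0)

    def test_zero_net_displacement_flagged_undefined(self):
        t = Track(0, np.arange(3), np.array([0.0, 1.0, 0.0]),
                  np.zeros(3))
        assert np.isnan(displacement_orientation(t, 2, 0))


class TestCircularStats:
    def test_identical_angles_give_unit_r(self):
        cs = circular_stats([33.0] * 12)
        assert cs.r == pytest.approx(1.0)
        assert cs.mean_direction_deg == pytest.approx(33.0)

    def test_balanced_symmetric_set_gives_zero_r(self):
        cs = circular_stats([0.0, 90.0, 180.0, 270.0])
        assert cs.r == pytest.approx(0.0, abs=1e-12)
        assert not cs.mean_direction_defined

    def test_two_orthogonal_angles(self):
        # oracle: direct vector summation
        cs = circular_stats([0.0, 90.0])
        assert cs.r == pytest.approx(np.sqrt(2) / 2, abs=1e-12)
        assert cs.mean_direction_deg == pytest.approx(45.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            circular_stats([])

    def test_matches_independent_circular_package(self, rng):
        angles = rng.uniform(-180, 180, 77)
        cs = circular_stats(angles)
        rad = np.deg2rad(angles)
        assert cs.r == pytest.approx(float(pingouin.circ_r(rad)), abs=1e-12)
        # pingouin uses a different finite-n approximation of the
        # Rayleigh p; the two agree closely but not to machine precision
        z, p = pingouin.circ_rayleigh(rad)
        assert cs.rayleigh_p == pytest.approx(p, abs=5e-3)

    @given(st.floats(-720, 720))
    def test_r_invariant_under_rotation(self, shift):
        angles = np.array([10.0, 40.0, 95.0, 200.0, 310.0])
        a = circular_stats(angles)
        b = circular_stats(angles + shift)
        assert b.r == pytest.approx(a.r, abs=1e-9)

    def test_von_mises_r_converges_to_bessel_ratio(self, rng):
        # r for von Mises(kappa=2) -> I1(2)/I0(2) = 0.6977
        sample = np.rad2deg(rng.vonmises(0.0, 2.0, 2000))
        expected = iv(1, 2.0) / iv(0, 2.0)
        assert circular_stats(sample).r == pytest.approx(expected, abs=0.03)

    def test_rayleigh_p_uniform_under_null(self, rng):
        pvals = [
            circular_stats(rng.uniform(-180, 180, 2000)).rayleigh_p
            for _ in range(200)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestTimecourseAndSwitch:
    @staticmethod
    def ensemble(mode, bias=0.0, n=200, seed=5):
        scene = SceneConfig(field_size_px=(2000, 2000), pixel_size_um=0.2,
                            n_frames=160, n_cells=n, light_onset_frame=20,
                            light_direction_deg=0.0, seed=seed)
        model = MotilityModel(mode=mode, speed_mean_um_s=0.2,
                              switch_delay_s=60.0, bias_strength=bias)
        rng = np.random.default_rng(scene.seed)
        pos = _simulate_positions(scene, model, rng)
        return TrackSet(
            [Track(i, np.arange(160), pos[i, :, 0], pos[i, :, 1])
             for i in range(n)], 0.2, 3.0)

    def test_aligned_tracks_give_unit_r(self):
        ts = TrackSet([straight_track(61, 0.2, 0.0, tid=i) for i in range(5)],
                      0.2, 3.0)
        tc = directionality_timecourse(ts, 0.0, window_frames=60)
        assert all(r == pytest.approx(1.0) for _, r in tc)

    def test_steering_ensemble_r_rises_after_switch(self):
        tc = dict(directionality_timecourse(
            self.ensemble("direct_steering"), 0.0, 60, stride=10))
        # the earliest window (starting at light onset minus 60 s) is
        # still dominated by isotropic pre-onset motion
        assert tc[0.0] < 0.3
        # windows fully inside the aligned phase: onset (60 s) + switch
        # delay (60 s) + heading relaxation have all elapsed
        assert tc[240.0] > 0.8 and tc[270.0] > 0.8

    def test_unbiased_ensemble_r_stays_low(self):
        tc = directionality_timecourse(
            self.ensemble("biased_random_walk", bias=0.0), 0.0, 60, stride=10)
        assert max(r for _, r in tc) < 0.15

    def test_straight_track_has_zero_turn(self):
        t = straight_track(120, 0.2, 30.0)
        before, after, turn = direction_switch(t, 60, 3.0, window_s=132.0)
        assert turn == pytest.approx(0.0, abs=1e-9)
        assert before == pytest.approx(30.0)

    def test_reversal_at_event_gives_180_turn(self):
        n = 120
        x = np.concatenate([np.arange(61), np.arange(59, 0, -1)]) * 0.6
        t = Track(0, np.arange(n + 1)[: len(x)], x, np.zeros(len(x)))
        _, _, turn = direction_switch(t, 60, 3.0, window_s=132.0)
        assert abs(turn) == pytest.approx(180.0)

    def test_programmed_turn_recovered(self):
        # approach at 0 deg, leave at 120 deg, turning at the event frame
        fi = 3.0
        w = 44  # frames per 132 s window
        xa = np.arange(w + 1) * 0.6
        ya = np.zeros(w + 1)
        dx = 0.6 * np.cos(np.deg2rad(120.0))
        dy = 0.6 * np.sin(np.deg2rad(120.0))
        xb = xa[-1] + np.arange(1, w + 1) * dx
        yb = ya[-1] + np.arange(1, w + 1) * dy
        t = Track(0, np.arange(2 * w + 1), np.concatenate([xa, xb]),
                  np.concatenate([ya, yb]))
        _, _, turn = direction_switch(t, w, fi, window_s=132.0)
        assert turn == pytest.approx(120.0, abs=2.0)

    def test_insufficient_coverage_rejected(self):
        t = straight_track(20, 0.2, 0.0)
        with pytest.raises(ValueError, match="cover"):
            direction_switch(t, 10, 3.0, window_s=132.0)
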