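"""Forward-model tests: geometry, trajectories, conditions, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clptrack import (
    EyePose,
    PoseOutOfRangeError,
    RigConfig,
    condition_profile,
    draw_saturation_flags,
    generate_trajectory,
    render_frame,
    render_sequence,
    static_trajectory,
)
from clptrack.rig import SATURATION_SCALE

from conftest import make_condition


def detected_centers(frame, threshold=100):
    from clptrack import detect_blobs

    return sorted((b.centroid_x, b.centroid_y) for b in detect_blobs(frame, threshold))


class TestChartAndTrajectory:
    def test_default_chart_targets_in_protocol_order(self, chart):
        # center first, then bottom-right proceeding clockwise to top-right
        assert chart.targets == (
            (0.0, 0.0),
            (10.0, -10.0),
            (-10.0, -10.0),
            (-10.0, 10.0),
            (10.0, 10.0),
        )

    def test_dwell_one_second_gives_600_poses(self, chart, rig):
        poses = generate_trajectory(chart, 1.0, rig)
        assert len(poses) == 600
        assert all(
            (p.azimuth, p.elevation) == (0.0, 0.0) for p in poses[:120]
        )
        dts = np.diff([p.timestamp for p in poses])
        assert np.allclose(dts, 1 / 120)

    def test_minimal_dwell_gives_one_pose_per_target(self, chart, rig):
        poses = generate_trajectory(chart, 1 / 120, rig)
        assert [(p.azimuth, p.elevation) for p in poses] == list(chart.targets)

    def test_dwell_must_be_positive(self, chart, rig):
        with pytest.raises(ValueError):
            generate_trajectory(chart, 0.0, rig)

    def test_static_trajectory_duration(self, rig):
        cond = condition_profile("C-Alt")
        poses = static_trajectory(cond, rig)
        assert len(poses) == 2400  # 20 s at 120 Hz
        assert {(p.azimuth, p.elevation) for p in poses} == {(0.0, 0.0)}


class TestConditionProfiles:
    @pytest.mark.parametrize(
        "name, lux", [("C-In", 250.0), ("C-Dark", 1.0), ("C-Out", 50_000.0)]
    )
    def test_illuminance(self, name, lux):
        assert condition_profile(name).illuminance_lx == lux

    def test_alt_toggles_every_three_seconds_for_twenty(self):
        cond = condition_profile("C-Alt")
        assert cond.alternation_period == 3.0
        assert cond.duration == 20.0
        on = cond.background_at(0.5)
        off = cond.background_at(3.5)
        assert on[0] > off[0]  # lights start on
        assert cond.background_at(6.1)[0] == on[0]

    def test_indoor_conditions_keep_spots_unambiguous(self, rig):
        # IR filter contract: spot peak clears background by >5 sd indoors
        for name in ("C-In", "C-Dark", "C-Alt"):
            c = condition_profile(name)
            assert rig.spot_peak > c.background_mean + 5 * c.background_sd
            assert c.saturation_prob == 0.0

    def test_outdoor_has_elevated_background_and_saturation(self):
        c = condition_profile("C-Out")
        assert c.background_mean > condition_profile("C-In").background_mean
        assert c.saturation_prob > 0.0

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="C-Indoors"):
            condition_profile("C-Indoors")


class TestRenderGeometry:
    def test_primary_position_spots_symmetric_about_center(self, rig, noiseless):
        rng = np.random.default_rng(0)
        frame = render_frame(EyePose(0, 0), rig, noiseless, rng, saturate=False)
        (lx, ly), (rx, ry) = detected_centers(frame)
        cx, cy = rig.center
        assert math.isclose(rx - lx, rig.spot_separation, abs_tol=1e-6)
        assert math.isclose((lx + rx) / 2, cx, abs_tol=1e-6)
        assert math.isclose(ly, cy, abs_tol=1e-6) and math.isclose(ry, cy, abs_tol=1e-6)

    def test_pose_displaces_spots_linearly(self, rig, noiseless):
        # +10 deg az, +10 deg el at 8 px/deg -> (+80, -80) px (el up = row down)
        rng = np.random.default_rng(0)
        base = detected_centers(render_frame(EyePose(0, 0), rig, noiseless, rng, saturate=False))
        moved = detected_centers(
            render_frame(EyePose(10, 10), rig, noiseless, rng, saturate=False)
        )
        for (bx, by), (mx, my) in zip(base, moved):
            assert math.isclose(mx - bx, 80.0, abs_tol=0.02)
            assert math.isclose(my - by, -80.0, abs_tol=0.02)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        az=st.floats(-10, 10, allow_nan=False),
        el=st.floats(-10, 10, allow_nan=False),
    )
    def test_shift_equivariance(self, noiseless, az, el):
        """Rendering at pose p equals rendering at rest plus p*px_per_degree,
        to within the stage quantization and sub-pixel sampling.  A uniform
        beam isolates the translation model: divergence attenuation reshapes
        the thresholded support with pose by design."""
        rig = RigConfig(
            image_width=120, image_height=120, px_per_degree=2.0,
            spot_separation=24.0, spot_sigma=2.0, divergence_halfangle=1e6,
        )
        rng = np.random.default_rng(0)
        q = rig.quantize(EyePose(az, el))
        base = detected_centers(render_frame(EyePose(0, 0), rig, noiseless, rng, saturate=False))
        moved = detected_centers(render_frame(EyePose(az, el), rig, noiseless, rng, saturate=False))
        dx = rig.px_per_degree * q.azimuth
        dy = -rig.px_per_degree * q.elevation
        # tolerance covers sub-pixel sampling of the thresholded spot support
        for (bx, by), (mx, my) in zip(base, moved):
            assert math.isclose(mx, bx + dx, abs_tol=0.15)
            assert math.isclose(my, by + dy, abs_tol=0.15)

    def test_pose_quantized_to_stage_steps(self, rig, noiseless):
        rng = np.random.default_rng(0)
        f = render_frame(EyePose(0.26, 0.013), rig, noiseless, rng, saturate=False)
        assert f.true_pose.azimuth == pytest.approx(0.5)
        assert f.true_pose.elevation == pytest.approx(0.02)
        # ground truth is a multiple of the step sizes
        assert f.true_pose.azimuth % rig.stage_step_h == 0
        assert round(f.true_pose.elevation / rig.stage_step_v) * rig.stage_step_v == (
            pytest.approx(f.true_pose.elevation)
        )

    def test_pose_out_of_range_rejected(self):
        with pytest.raises(PoseOutOfRangeError):
            EyePose(20.5, 0)

    def test_off_sensor_spot_flagged(self, noiseless):
        # widely mounted spots leave the sensor at an extreme pose
        wide = RigConfig(
            image_width=120, image_height=120, px_per_degree=2.0,
            spot_separation=100.0, spot_sigma=2.0,
        )
        rng = np.random.default_rng(0)
        f = render_frame(EyePose(20, 0), wide, noiseless, rng, saturate=False)
        assert f.off_sensor
        g = render_frame(EyePose(0, 0), wide, noiseless, rng, saturate=False)
        assert not g.off_sensor


class TestNoiseAndSaturation:
    def test_sequences_bit_identical_for_same_seed(self, small_rig, chart):
        cond = condition_profile("C-Out")
        poses = generate_trajectory(chart, 0.05, small_rig)
        a = render_sequence(poses, small_rig, cond, seed=5)
        b = render_sequence(poses, small_rig, cond, seed=5)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))
        c = render_sequence(poses, small_rig, cond, seed=6)
        assert any(not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c))

    def test_no_pixel_exceeds_eight_bits(self, small_rig, chart):
        cond = make_condition("bright", background_mean=25, background_sd=5, saturation_prob=1.0)
        poses = generate_trajectory(chart, 0.05, small_rig)
        for f in render_sequence(poses, small_rig, cond, seed=7):
            assert f.pixels.dtype == np.uint8
            assert f.pixels.max() == 255  # forced saturation clips a plateau

    def test_saturated_spot_loses_energy_to_clipping(self, small_rig, noiseless):
        """The clipped flat-top holds strictly less energy than the unclipped
        amplified Gaussian would."""
        rng = np.random.default_rng(0)
        f = render_frame(EyePose(0, 0), small_rig, noiseless, rng, saturate=True)
        unclipped_total = (
            2 * math.pi * small_rig.spot_sigma**2 * small_rig.spot_peak * (1 + SATURATION_SCALE)
        )
        assert f.saturated
        assert f.pixels.sum() < unclipped_total

    def test_saturation_flags_match_independent_bernoulli_redraw(self, chart):
        """Flag stream equals a direct re-draw of the seeded Bernoulli
        process -- the saturation channel is independent of the noise
        channel."""
        tiny = RigConfig(image_width=48, image_height=48, px_per_degree=1.0,
                         spot_separation=12.0, spot_sigma=1.5)
        cond = make_condition("out-like", background_mean=5, background_sd=2,
                              saturation_prob=0.001)
        n = 10_000
        poses = [EyePose(0, 0, timestamp=i / tiny.frame_rate) for i in range(n)]
        frames = render_sequence(poses, tiny, cond, seed=42)
        flags = np.array([f.saturated for f in frames])
        redraw = draw_saturation_flags(42, n, cond.saturation_prob)
        assert np.array_equal(flags, redraw)
        assert 0 < flags.sum() < 50
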