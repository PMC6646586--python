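"""World geometry, eye kinematics, texture statistics and rendering."""

import dataclasses
import math

import numpy as np
import pytest

from aecvision.environment import (DEPTH_RANGE_M, EpisodeAbort, EyePose,
                                   RenderConfig, WorldState,
                                   apply_eye_command, check_limits,
                                   make_texture,
                                   orientation_energy_histogram,
                                   place_stimulus, project_point,
                                   render_binocular, reset_gaze, step_world,
                                   vergence_for_distance)
from helpers import measure_disparity, spectral_slope


class TestTextures:
    def test_deterministic_under_fixed_seed(self):
        a = make_texture(1, "pink_noise", 256)
        b = make_texture(1, "pink_noise", 256)
        assert np.array_equal(a.pixels, b.pixels)

    @pytest.mark.parametrize("kind", ["pink_noise", "edges", "blocks"])
    def test_range_and_shape(self, kind):
        t = make_texture(3, kind, 256)
        assert t.pixels.shape == (256, 256)
        assert t.pixels.min() >= 0.0 and t.pixels.max() <= 1.0

    def test_pink_noise_spectral_slope(self, pink_texture):
        # 1/f amplitude spectrum: log-log slope near -1
        slope = spectral_slope(pink_texture.pixels)
        assert -1.4 <= slope <= -0.6

    @pytest.mark.parametrize("kind", ["blocks", "edges"])
    def test_cardinal_orientations_dominate(self, kind):
        t = make_texture(5, kind, 512)
        centers, energy = orientation_energy_histogram(t.pixels, n_bins=18)
        top2 = set(centers[np.argsort(energy)[-2:]])
        assert top2 == {0.0, 90.0}

    def test_unsupported_kind(self):
        with pytest.raises(ValueError):
            make_texture(1, "marble")

    def test_file_texture_luminance_conversion(self, tmp_path):
        from PIL import Image

        rgb = np.zeros((300, 320, 3), dtype=np.uint8)
        rgb[..., 0] = 255  # pure red -> BT.601 luminance 0.299
        path = tmp_path / "stim.png"
        Image.fromarray(rgb).save(path)
        t = make_texture(0, "file", path=str(path))
        assert t.pixels.shape == (300, 300)  # center-cropped square
        assert np.allclose(t.pixels, 0.299, atol=2e-3)


class TestWorldKinematics:
    def test_placement_respects_stated_ranges(self, world):
        rng = np.random.default_rng(0)
        depths, vhs = [], []
        for _ in range(10_000):
            w = place_stimulus(world, rng)
            depths.append(w.stimulus_center[2])
            vhs.append(w.stimulus_velocity[0])
        assert min(depths) >= 1.0 and max(depths) <= 2.5
        assert max(abs(v) for v in vhs) <= 7.5
        # and the draws actually cover the ranges
        assert max(depths) > 2.3 and min(depths) < 1.2

    def test_placement_reproducible(self, world):
        w1 = place_stimulus(world, np.random.default_rng(7))
        w2 = place_stimulus(world, np.random.default_rng(7))
        assert np.array_equal(w1.stimulus_center, w2.stimulus_center)
        assert w1.stimulus_velocity == w2.stimulus_velocity

    def test_zero_velocity_keeps_world_fixed(self, world):
        w = step_world(world, dt=0.1)
        assert np.allclose(w.stimulus_center, world.stimulus_center)

    def test_depth_velocity_integration(self, world):
        w = dataclasses.replace(world, stimulus_velocity=(0, 0, -0.375))
        w = step_world(w, dt=0.1)
        assert w.stimulus_center[2] == pytest.approx(1.5 - 0.0375)

    def test_angular_velocity_accumulates_exactly(self, world):
        w = dataclasses.replace(world, stimulus_velocity=(7.5, 0, 0))
        for _ in range(10):
            w = step_world(w, dt=0.1)
        x, _, z = w.stimulus_center
        assert math.degrees(math.atan2(x, z)) == pytest.approx(7.5, abs=1e-9)

    def test_collision_aborts_episode(self, world):
        w = dataclasses.replace(
            world, stimulus_center=np.array([0.0, 0.0, 0.08]),
            stimulus_velocity=(0, 0, -0.375))
        with pytest.raises(EpisodeAbort):
            step_world(w, dt=0.1)


class TestEyeKinematics:
    def test_zero_actions_leave_pose_unchanged(self, eyes):
        new, flag = apply_eye_command(eyes, 0, 0, 0)
        assert new == eyes and not flag

    def test_vergence_action_is_angle_increment(self):
        eyes = EyePose(vergence=3.0)
        new, _ = apply_eye_command(eyes, 0, 0, 1.0)
        assert new.vergence == pytest.approx(4.0)

    def test_acceleration_integration(self, eyes):
        # 16 deg/s^2 for 5 steps of 100 ms from rest -> 8 deg/s
        for _ in range(5):
            eyes, _ = apply_eye_command(eyes, 16.0, 0, 0)
        assert eyes.pan_vel == pytest.approx(8.0)

    def test_velocity_updates_before_position(self, eyes):
        new, _ = apply_eye_command(eyes, 10.0, 0, 0, dt=0.1)
        assert new.pan == pytest.approx(0.1)  # (0 + 1.0 deg/s) * 0.1 s

    @pytest.mark.parametrize("pose,expected", [
        (dict(vergence=0.19), True),
        (dict(vergence=16.31), True),
        (dict(pan=15.0), False),        # boundary inclusive
        (dict(pan=15.01), True),
        (dict(tilt=-15.01), True),
        (dict(), False),
    ])
    def test_joint_limits(self, pose, expected):
        base = dict(vergence=1.0)
        base.update(pose)
        assert check_limits(EyePose(**base)) is expected

    def test_reset_gaze_vergence_matches_geometry(self, eyes):
        # fixation at 3 m: xi* = 2 atan(0.068 / 6) = 1.299 deg
        assert vergence_for_distance(3.0) == pytest.approx(1.2987, abs=1e-3)
        # infinitely far -> 0, clipped to the joint minimum in reset_gaze
        assert vergence_for_distance(1e9) == pytest.approx(0.0, abs=1e-6)
        new = reset_gaze(eyes, np.random.default_rng(0))
        assert new.pan == new.tilt == new.pan_vel == new.tilt_vel == 0.0
        lo = vergence_for_distance(3.0)
        hi = vergence_for_distance(0.3)
        assert lo - 1e-9 <= new.vergence <= hi + 1e-9

    def test_reset_gaze_reproducible(self, eyes):
        a = reset_gaze(eyes, np.random.default_rng(3))
        b = reset_gaze(eyes, np.random.default_rng(3))
        assert a == b


class TestRendering:
    def test_identical_inputs_identical_images(self, world):
        eyes = EyePose(vergence=vergence_for_distance(1.5))
        p1 = render_binocular(world, eyes)
        p2 = render_binocular(world, eyes)
        assert np.array_equal(p1.left, p2.left)
        assert np.array_equal(p1.right, p2.right)
        assert p1.left.shape == (240, 320)

    def test_zero_disparity_at_fixation(self, world):
        eyes = EyePose(vergence=vergence_for_distance(1.5))
        pair = render_binocular(world, eyes)
        c = pair.left[116:124, 156:164] - pair.right[116:124, 156:164]
        assert np.abs(c).max() < 0.02  # sub-interpolation mismatch only

    def test_disparity_matches_analytic_projection(self, pink_texture):
        """Measured center disparity (cross-correlation, sub-pixel) agrees
        with the closed-form pinhole projection within 0.5 px over 100
        random depth/vergence draws."""
        rng = np.random.default_rng(42)
        cfg = RenderConfig()
        worst = 0.0
        for _ in range(100):
            depth = rng.uniform(*DEPTH_RANGE_M)
            verg_err = rng.uniform(-2.0, 2.0)
            verg = float(np.clip(vergence_for_distance(depth) + verg_err,
                                 0.2, 16.3))
            world = WorldState(stimulus_texture=pink_texture,
                               stimulus_center=np.array([0.0, 0.0, depth]))
            eyes = EyePose(vergence=verg)
            pair = render_binocular(world, eyes, cfg)
            measured = measure_disparity(pair.left, pair.right)
            ul, _ = project_point(world.stimulus_center, eyes, "left", cfg)
            ur, _ = project_point(world.stimulus_center, eyes, "right", cfg)
            worst = max(worst, abs(measured - (ul - ur)))
        assert worst < 0.5

    def test_perfect_tracking_stabilizes_frames(self, pink_texture):
        """With eye angular velocity equal to the stimulus angular velocity
        and vergence tracking depth, consecutive frames differ only by
        interpolation noise."""
        depth = 1.8
        v_h = 3.0
        world = WorldState(stimulus_texture=pink_texture,
                           stimulus_center=np.array([0.0, 0.0, depth]),
                           stimulus_velocity=(v_h, 0.0, 0.0))
        eyes = EyePose(pan_vel=v_h, vergence=vergence_for_distance(depth))
        prev = render_binocular(world, eyes)
        diffs_tracking = []
        diffs_static = []
        static_eyes = EyePose(vergence=vergence_for_distance(depth))
        prev_static = render_binocular(world, static_eyes)
        for _ in range(5):
            world = step_world(world, dt=0.1)
            eyes = dataclasses.replace(eyes, pan=eyes.pan + v_h * 0.1)
            cur = render_binocular(world, eyes)
            diffs_tracking.append(np.abs(cur.left - prev.left).mean())
            cur_static = render_binocular(world, static_eyes)
            diffs_static.append(
                np.abs(cur_static.left - prev_static.left).mean())
            prev, prev_static = cur, cur_static
        assert np.mean(diffs_tracking) < 0.02
        assert np.mean(diffs_tracking) < 0.2 * np.mean(diffs_static)

    def test_stimulus_outside_frustum_flagged(self, pink_texture):
        world = WorldState(stimulus_texture=pink_texture,
                           stimulus_center=np.array([30.0, 0.0, 1.5]))
        pair = render_binocular(world, EyePose(vergence=1.0))
        assert not pair.stimulus_visible
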