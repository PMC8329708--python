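"""Unit tests for the eye model, ray casting and activity-map projection."""

import numpy as np
import pytest

from beeflight import beeview, rateanalysis, session, synthgen
from beeflight.beeview import (
    HIT_FIELD,
    HIT_NONE,
    HIT_OUTSIDE,
    ActivityMap,
    EyeModel,
    build_eye_model,
    project_rates,
    raycast,
    read_ascii_grid,
    write_ascii_grid,
)


def flat_terrain(extent=200.0, cell=2.0):
    return synthgen.gen_terrain(
        extent_m=(extent, extent), cell_m=cell, flat=True,
        origin_xy_m=(-extent / 2, -extent / 2),
    )


def single_ray_eye(direction):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return EyeModel(
        ommatidia_dirs=d[None, :],
        horizontal_fov_rad=np.pi,
        vertical_fov_rad=np.pi / 2,
    )


class TestEyeModel:
    def test_unit_norms_and_count(self):
        eye = build_eye_model(1234)
        assert eye.n_ommatidia == 1234
        np.testing.assert_allclose(np.linalg.norm(eye.ommatidia_dirs, axis=1), 1.0,
                                   atol=1e-12)

    def test_rear_blind_wedge(self):
        eye = build_eye_model(5000, h_fov_rad=np.deg2rad(300.0))
        az = np.arctan2(eye.ommatidia_dirs[:, 1], eye.ommatidia_dirs[:, 0])
        assert np.all(np.abs(az) <= np.deg2rad(150.0) + 1e-9)

    def test_vertical_fov(self):
        eye = build_eye_model(5000, v_fov_rad=np.deg2rad(160.0))
        el = np.arcsin(eye.ommatidia_dirs[:, 2])
        assert np.all(np.abs(el) <= np.deg2rad(80.0) + 1e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            build_eye_model(0)


class TestRaycast:
    def test_straight_down(self):
        terrain = flat_terrain()
        eye = single_ray_eye([0.0, 0.0, -1.0])
        hit = raycast(eye, (10.0, -20.0, 15.0, 0.3), terrain)
        r, c = terrain.xy_to_rowcol(np.array([10.0]), np.array([-20.0]))
        assert hit.classes[0] != HIT_NONE
        assert hit.rows[0] == r[0] and hit.cols[0] == c[0]

    def test_45_degrees_right_triangle(self):
        terrain = flat_terrain()
        eye = single_ray_eye([1.0, 0.0, -1.0])  # forward, 45 deg down
        hit = raycast(eye, (0.0, 0.0, 15.0, 0.0), terrain)
        # right triangle: horizontal distance equals the 15 m altitude
        assert hit.x_m[0] == pytest.approx(15.0, abs=terrain.cell_m)
        assert hit.y_m[0] == pytest.approx(0.0, abs=terrain.cell_m)

    def test_yaw_rotates_ray(self):
        terrain = flat_terrain()
        eye = single_ray_eye([1.0, 0.0, -1.0])
        hit = raycast(eye, (0.0, 0.0, 15.0, np.pi / 2), terrain)
        assert hit.x_m[0] == pytest.approx(0.0, abs=terrain.cell_m)
        assert hit.y_m[0] == pytest.approx(15.0, abs=terrain.cell_m)

    def test_horizontal_and_upward_none(self):
        terrain = flat_terrain()
        for d in ([1.0, 0.0, 0.0], [0.0, 1.0, 0.5]):
            hit = raycast(single_ray_eye(d), (0.0, 0.0, 15.0, 0.0), terrain)
            assert hit.classes[0] == HIT_NONE
            assert np.isnan(hit.x_m[0])

    def test_field_vs_outside_classes(self):
        terrain = flat_terrain(extent=100.0, cell=1.0)
        down = single_ray_eye([0.0, 0.0, -1.0])
        assert raycast(down, (0.0, 0.0, 10.0, 0.0), terrain).classes[0] == HIT_FIELD
        assert raycast(down, (-45.0, -45.0, 10.0, 0.0), terrain).classes[0] == HIT_OUTSIDE

    def test_below_ground_pose_rejected(self):
        terrain = flat_terrain()
        with pytest.raises(ValueError):
            raycast(single_ray_eye([0, 0, -1.0]), (0.0, 0.0, -1.0, 0.0), terrain)

    def test_flat_terrain_matches_trigonometry(self):
        terrain = flat_terrain(extent=500.0, cell=4.0)
        eye = build_eye_model(500)
        pose = (10.0, -20.0, 15.0, 0.7)
        hit = raycast(eye, pose, terrain)
        x0, y0, alt, yaw = pose
        c, s = np.cos(yaw), np.sin(yaw)
        d = eye.ommatidia_dirs
        dx = c * d[:, 0] - s * d[:, 1]
        dy = s * d[:, 0] + c * d[:, 1]
        dz = d[:, 2]
        sel = (dz < 0) & (hit.classes != HIT_NONE)
        t = (alt - 0.0) / -dz[sel]
        err = np.hypot(hit.x_m[sel] - (x0 + t * dx[sel]),
                       hit.y_m[sel] - (y0 + t * dy[sel]))
        assert err.max() < terrain.cell_m

    def test_rotation_consistency(self):
        terrain = flat_terrain(extent=500.0, cell=4.0)
        eye = build_eye_model(500)
        psi = 1.1
        h0 = raycast(eye, (0.0, 0.0, 15.0, 0.0), terrain)
        h1 = raycast(eye, (0.0, 0.0, 15.0, psi), terrain)
        valid = (h0.classes != HIT_NONE) & (h1.classes != HIT_NONE)
        cp, sp = np.cos(psi), np.sin(psi)
        rx = cp * h0.x_m[valid] - sp * h0.y_m[valid]
        ry = sp * h0.x_m[valid] + cp * h0.y_m[valid]
        err = np.hypot(rx - h1.x_m[valid], ry - h1.y_m[valid])
        assert err.max() < terrain.cell_m


class TestAsciiGridIO:
    def test_round_trip(self, tmp_path):
        terrain = synthgen.gen_terrain(extent_m=(40.0, 30.0), cell_m=2.0, seed=3)
        asc = tmp_path / "t.asc"
        mask = tmp_path / "t_mask.json"
        write_ascii_grid(terrain, asc, mask)
        back = read_ascii_grid(asc, mask)
        # the writer stores 6 significant digits
        np.testing.assert_allclose(back.heights, terrain.heights, rtol=1e-5, atol=1e-5)
        np.testing.assert_array_equal(back.field_mask, terrain.field_mask)
        assert back.cell_m == terrain.cell_m
        np.testing.assert_allclose(back.origin_xy_m, terrain.origin_xy_m)


def _hover_session(duration_s=2.0, yaw_rate=0.0):
    t = np.arange(0.0, duration_s, 0.01)
    track = session.TelemetryTrack(
        t_s=t, x_m=np.zeros_like(t), y_m=np.zeros_like(t),
        alt_m=np.full_like(t, 10.0), yaw_rad=np.zeros_like(t),
        yaw_rate_rad_s=np.full_like(t, yaw_rate), speed_m_s=np.zeros_like(t),
    )
    n = int(duration_s * 20_000)
    rec = session.RawRecording(np.zeros(n, np.int16), np.zeros(n, np.int16), 20_000.0)
    return session.align(rec, track, 0.0)


class TestProjectRates:
    def test_single_pose_constant_rate(self):
        terrain = flat_terrain(extent=100.0, cell=1.0)
        eye = build_eye_model(300)
        sess = _hover_session()
        rs = rateanalysis.bin_rates(np.linspace(0.01, 1.99, 14), 0.0, 2.0)
        rate = rs.rates[rs.counts > 0][0]
        amap = project_rates(sess, rs, eye, terrain, turn_exclusion_rad_s=None)
        mean = amap.mean_grid
        seen = ~np.isnan(mean)
        assert seen.any()
        vals = np.unique(np.round(mean[seen], 9))
        # hovering: same view every bin; rates differ per bin, but each pixel's
        # mean equals the mean rate across included bins
        assert np.allclose(mean[seen], rs.rates.mean())

    def test_turn_exclusion_drops_all(self):
        terrain = flat_terrain(extent=100.0, cell=1.0)
        eye = build_eye_model(100)
        sess = _hover_session(yaw_rate=1.0)  # above the 0.3 rad/s cutoff
        rs = rateanalysis.bin_rates(np.linspace(0.01, 1.99, 14), 0.0, 2.0)
        amap = project_rates(sess, rs, eye, terrain, turn_exclusion_rad_s=0.3)
        assert amap.count_grid.sum() == 0

    def test_count_conservation_against_bruteforce(self):
        terrain = flat_terrain(extent=100.0, cell=1.0)
        eye = build_eye_model(50)
        sess = _hover_session()
        rs = rateanalysis.bin_rates(np.array([0.5]), 0.0, 2.0)
        amap = project_rates(sess, rs, eye, terrain, turn_exclusion_rad_s=None)
        # brute force: one raycast per included bin; count unique field pixels
        total = 0
        for tc in rs.bin_centers():
            hit = raycast(eye, (0.0, 0.0, 10.0, 0.0), terrain)
            sel = hit.classes == HIT_FIELD
            total += len(set(zip(hit.rows[sel].tolist(), hit.cols[sel].tolist())))
        assert amap.count_grid.sum() == total
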