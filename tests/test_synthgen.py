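"""Unit tests for the synthetic flight, spike-train and recording generators."""

import numpy as np
import pytest

from beeflight import synthgen
from beeflight.synthgen import (
    NoiseModel,
    default_templates,
    gen_recording,
    gen_spike_trains,
    gen_terrain,
    gen_trefoil_telemetry,
    make_template,
    read_ground_truth,
    sample_inhomogeneous_poisson,
    write_ground_truth,
)


class TestTrefoil:
    def test_constant_speed(self, short_track):
        track, _ = short_track
        d = np.hypot(np.diff(track.x_m), np.diff(track.y_m))
        path_speed = d.sum() / (track.t_s[-1] - track.t_s[0])
        assert path_speed == pytest.approx(5.5, rel=0.01)

    def test_single_repetition_covers_flight(self):
        track, bounds = gen_trefoil_telemetry(
            n_repetitions=1, start_xy=(-60, -60), leg_beyond_m=30, turn_radius_m=10
        )
        assert len(bounds) == 1
        assert bounds[0][0] == 0.0
        assert bounds[0][1] == pytest.approx(track.t_s[-1])

    def test_bounds_contiguous(self):
        _, bounds = gen_trefoil_telemetry(
            n_repetitions=3, start_xy=(-60, -60), leg_beyond_m=30, turn_radius_m=10
        )
        assert len(bounds) == 3
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            assert a1 == pytest.approx(b0)

    def test_repetitions_identical(self):
        track, bounds = gen_trefoil_telemetry(
            n_repetitions=2, start_xy=(-60, -60), leg_beyond_m=30, turn_radius_m=10
        )
        period = bounds[0][1] - bounds[0][0]
        k = int(round(period * 100.0))  # 100 Hz telemetry
        n = min(k, len(track.t_s) - k)
        np.testing.assert_allclose(track.x_m[:n], track.x_m[k : k + n], atol=0.02)
        np.testing.assert_allclose(track.y_m[:n], track.y_m[k : k + n], atol=0.02)

    def test_straight_and_turn_yaw_rates(self, short_track):
        track, _ = short_track
        # first two seconds are on the initial straight leg
        early = track.yaw_rate_rad_s[10:200]
        np.testing.assert_allclose(early, 0.0, atol=1e-6)
        assert np.max(np.abs(track.yaw_rate_rad_s)) > 0.1


class TestPoisson:
    def test_homogeneous_count(self):
        rng = np.random.default_rng(5)
        times = sample_inhomogeneous_poisson(
            lambda t: np.full(np.shape(t), 10.0), 0.0, 100.0, 10.0, rng
        )
        assert abs(len(times) - 1000) < 3 * np.sqrt(1000)

    def test_zero_rate(self):
        rng = np.random.default_rng(0)
        out = sample_inhomogeneous_poisson(
            lambda t: np.zeros(np.shape(t)), 0.0, 10.0, 0.0, rng
        )
        assert len(out) == 0

    def test_refractory_enforced(self):
        rng = np.random.default_rng(1)
        times = sample_inhomogeneous_poisson(
            lambda t: np.full(np.shape(t), 200.0), 0.0, 50.0, 200.0, rng, 0.004
        )
        assert np.all(np.diff(times) > 0.004)

    def test_rate_fn_bound_checked(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            sample_inhomogeneous_poisson(
                lambda t: np.full(np.shape(t), 5.0), 0.0, 10.0, 1.0, rng
            )


class TestSpikeTrains:
    def test_no_isi_below_refractory(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, n_units=3, seed=9)
        for times in gt.unit_spike_times:
            assert np.all(np.diff(times) >= 0.004)

    def test_zero_rates_zero_spikes(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, baseline_rate_hz=0.0, rate_gain=0.0, seed=0)
        assert all(len(t) == 0 for t in gt.unit_spike_times)

    def test_deterministic(self, short_track):
        track, _ = short_track
        a = gen_spike_trains(track, seed=3)
        b = gen_spike_trains(track, seed=3)
        for ta, tb in zip(a.unit_spike_times, b.unit_spike_times):
            np.testing.assert_array_equal(ta, tb)

    def test_lag_longer_than_flight(self, short_track):
        track, _ = short_track
        with pytest.raises(ValueError):
            gen_spike_trains(track, lag_s=1e6)

    def test_gain_recovered_by_regression(self, short_track):
        # rate regressed on lagged |yaw rate| recovers rate_gain within 20%
        track, _ = short_track
        from beeflight import rateanalysis

        gains = []
        for seed in range(5):
            gt = gen_spike_trains(
                track, n_units=1, baseline_rate_hz=5.0, rate_gain=80.0,
                lag_s=0.7, seed=seed, refractory_margin_s=0.0, refractory_s=0.0,
            )
            rs = rateanalysis.bin_rates(gt.unit_spike_times[0], 0.0, track.duration_s)
            yaw = rateanalysis.bin_yaw_speed(track, 0.0, track.duration_s)
            k = 7  # 0.7 s at 100 ms bins
            x, y = yaw[: len(yaw) - k], rs.rates[k:]
            slope = np.polyfit(x, y, 1)[0]
            gains.append(slope)
        assert np.mean(gains) == pytest.approx(80.0, rel=0.2)


class TestTemplates:
    def test_trough_normalized(self):
        for tpl in default_templates(4):
            assert tpl.min() == pytest.approx(-1.0)
            # side lobes can shift the deepest sample by one off center
            assert abs(np.argmin(tpl) - len(tpl) // 2) <= 1

    def test_edges_return_to_baseline(self):
        for tpl in default_templates(4):
            assert abs(tpl[0]) < 1e-6 and abs(tpl[-1]) < 1e-6

    def test_distinct_shapes(self):
        tpls = default_templates(3)
        for i in range(3):
            for j in range(i + 1, 3):
                a, b = tpls[i], tpls[j]
                cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                assert cos < 0.7

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_template("quadphasic")


class TestRecording:
    def test_noise_free_differential_reproduces_template(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, n_units=1, baseline_rate_hz=2.0,
                              rate_gain=0.0, seed=4)
        tpl = default_templates(1)
        quiet = NoiseModel(common_mode_harmonics=(), impulse_rate_hz=0.0,
                           independent_noise_sd=0.0)
        rec = gen_recording(gt, tpl, quiet, duration_s=30.0, counts_per_unit=1000.0)
        d = (rec.channel_a.astype(float) - rec.channel_b.astype(float)) / 1000.0
        ts = gt.unit_spike_times[0]
        ts = ts[(ts > 0.01) & (ts < 29.99)]
        c = int(round(ts[0] * 20_000))
        seg = d[c - 14 : c + 15]
        np.testing.assert_allclose(seg, 12.0 * tpl[0], atol=0.01)

    def test_common_mode_cancels_at_true_gain(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, n_units=1, baseline_rate_hz=0.0,
                              rate_gain=0.0, seed=4)
        noisy = NoiseModel(impulse_rate_hz=0.0, independent_noise_sd=0.1)
        rec = gen_recording(gt, default_templates(1), noisy, duration_s=10.0,
                            counts_per_unit=250.0)
        a = rec.channel_a.astype(float)
        b = rec.channel_b.astype(float)
        resid = a - 2.0 * b
        assert resid.std() < 0.05 * a.std()

    def test_deterministic(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, n_units=1, seed=6)
        nm = synthgen.default_noise_model(track)
        r1 = gen_recording(gt, default_templates(1), nm, duration_s=5.0)
        r2 = gen_recording(gt, default_templates(1), nm, duration_s=5.0)
        np.testing.assert_array_equal(r1.channel_a, r2.channel_a)
        np.testing.assert_array_equal(r1.channel_b, r2.channel_b)

    def test_template_count_mismatch(self, short_track):
        track, _ = short_track
        gt = gen_spike_trains(track, n_units=2, seed=0)
        with pytest.raises(ValueError):
            gen_recording(gt, default_templates(1), duration_s=5.0)


class TestTerrain:
    def test_flat(self):
        t = gen_terrain(extent_m=(50.0, 40.0), cell_m=2.0, flat=True)
        assert t.shape == (20, 25)
        assert np.all(t.heights == 0.0)

    def test_mask_polygon(self):
        t = gen_terrain(extent_m=(100.0, 100.0), cell_m=1.0, flat=True)
        r, c = t.xy_to_rowcol(np.array([50.0]), np.array([50.0]))
        assert t.field_mask[r[0], c[0]]  # center inside default field
        r, c = t.xy_to_rowcol(np.array([1.0]), np.array([1.0]))
        assert not t.field_mask[r[0], c[0]]  # corner outside

    def test_deterministic(self):
        a = gen_terrain(seed=4)
        b = gen_terrain(seed=4)
        np.testing.assert_array_equal(a.heights, b.heights)

    def test_validation(self):
        with pytest.raises(ValueError):
            gen_terrain(extent_m=(0.0, 10.0))


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path, short_track):
        track, bounds = short_track
        gt = gen_spike_trains(track, n_units=2, seed=2, repetition_bounds=bounds)
        path = tmp_path / "gt.json"
        write_ground_truth(gt, path)
        back = read_ground_truth(path)
        assert back.n_units == 2
        assert back.injected_lag_s == gt.injected_lag_s
        for ta, tb in zip(gt.unit_spike_times, back.unit_spike_times):
            np.testing.assert_allclose(ta, tb)


class TestNoiseModel:
    def test_band_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(band_hz=(500.0, 100.0))
        NoiseModel().validate_rate(20_000.0)  # 10 kHz edge at Nyquist is fine
        with pytest.raises(ValueError):
            NoiseModel(band_hz=(300.0, 11_000.0)).validate_rate(20_000.0)
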