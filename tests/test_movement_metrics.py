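import numpy as np
import pytest

from tailflow.movement_metrics import (average_normalized_speed, build_pairs,
                                       msrd_curve, track_velocities,
                                       velocity_spatial_correlation,
                                       velocity_temporal_autocorrelation)
from tailflow import synthetic_data as sd

from conftest import make_trackset, rigid_motion_trackset


class TestTrackVelocities:
    def test_static_track_zero_velocity(self):
        ts = make_trackset(np.zeros((3, 6, 3)) + 5.0)
        v = track_velocities(ts)
        np.testing.assert_allclose(v[["vx", "vy", "vz"]], 0.0)

    def test_central_difference_exact_for_quadratic(self):
        # x(t) = a t^2 -> central difference = 2 a t exactly
        a = 0.3
        t = np.arange(8) * 2.0
        pos = np.zeros((1, 8, 3))
        pos[0, :, 0] = a * t**2
        ts = make_trackset(pos)
        v = track_velocities(ts, "central").set_index("frame")
        interior = v.loc[1:6]
        np.testing.assert_allclose(interior["vx"], 2 * a * interior["t_min"], rtol=1e-12)

    def test_gap_flanking_samples_have_no_velocity(self):
        from tailflow.trajectory_io import tracks_from_arrays
        frames = [0, 1, 2, 4, 5, 6]  # gap at 3
        pos = np.column_stack([np.asarray(frames, float), np.zeros(6), np.zeros(6)])
        ts = tracks_from_arrays([1] * 6, frames, pos, 2.0)
        v = track_velocities(ts, "central")
        # frames 2 and 4 flank the gap: no central velocity there
        assert set(v["frame"]) == {0, 1, 5, 6}

    def test_central_noise_variance_quarter_of_forward(self, rng):
        # Monte-Carlo oracle: noisy linear motion, 1e4 draws.
        # forward var = 2 s^2/dt^2, central var = 2 s^2/(2 dt)^2 -> ratio 1/4
        n = 10_000
        dt, sigma = 2.0, 0.4
        x = np.arange(5) * dt * 1.0 + rng.standard_normal((n, 5)) * sigma
        vf = (x[:, 2] - x[:, 1]) / dt
        vc = (x[:, 3] - x[:, 1]) / (2 * dt)
        ratio = vc.var() / vf.var()
        assert abs(ratio - 0.25) < 0.05
        # and the implementation matches the stencils it claims
        pos = np.zeros((n, 5, 3))
        pos[:, :, 0] = x
        ts = make_trackset(pos, dt)
        v = track_velocities(ts, "central")
        mid = v[v["frame"] == 2]["vx"].to_numpy()
        np.testing.assert_allclose(np.sort(mid), np.sort(vc), rtol=1e-12)


class TestBuildPairs:
    def test_grid_k8_pairs_all(self, grid9_static):
        pe = build_pairs(grid9_static, "knn", k=8, t0_policy="fixed",
                         t0_frame=0, directed=True)
        assert len(pe) == 9 * 8

    def test_cutoff_too_short_empty(self):
        pos = np.repeat(np.array([[[0.0, 0, 0]], [[20.0, 0, 0]]]), 3, axis=1)
        ts = make_trackset(pos)
        pe = build_pairs(ts, "cutoff", d_max=15.0, t0_policy="fixed", t0_frame=0)
        assert len(pe) == 0

    def test_cutoff_matches_brute_force(self, rng):
        X = rng.uniform(0, 40, (50, 3))
        ts = make_trackset(np.repeat(X[:, None, :], 2, axis=1))
        pe = build_pairs(ts, "cutoff", d_max=15.0, t0_policy="fixed", t0_frame=0)
        brute = sum(
            1
            for i in range(50)
            for j in range(i + 1, 50)
            if np.linalg.norm(X[i] - X[j]) <= 15.0
        )
        assert len(pe) == brute


class TestMsrd:
    lags = np.arange(0.0, 21.0, 2.0)

    def test_rigid_translation_is_zero(self):
        ts = rigid_motion_trackset()
        pe = build_pairs(ts, "knn", k=8, t0_policy="fixed", t0_frame=0)
        c = msrd_curve(ts, pe, self.lags)
        np.testing.assert_allclose(c.msrd, 0.0, atol=1e-12)
        assert np.all(c.n_pairs > 0)

    def test_unit_displacement_is_rearrangement_criterion(self):
        # neighbor at d0=10 displaced by exactly 10 um at the lag -> m = 1
        pos = np.zeros((2, 2, 3))
        pos[1, :, 0] = 10.0
        pos[1, 1, 1] = 10.0  # perpendicular displacement of 10 um
        ts = make_trackset(pos)
        pe = build_pairs(ts, "cutoff", d_max=15.0, t0_policy="fixed", t0_frame=0)
        c = msrd_curve(ts, pe, [2.0])
        np.testing.assert_allclose(c.msrd, 1.0, rtol=1e-12)

    def test_brownian_closed_form(self, rng):
        # independent pairs, D=1, d0=10, tau=10 -> E[m] = 12 D tau / d0^2 = 1.2
        n_pairs, D, d0, tau = 1500, 1.0, 10.0, 10.0
        rel = rng.standard_normal((n_pairs, 3)) * np.sqrt(2 * 2 * D * tau)
        oracle = np.mean(np.sum(rel**2, axis=1)) / d0**2  # direct simulation
        assert abs(oracle - 1.2) < 3 * np.std(np.sum(rel**2, 1) / d0**2) / np.sqrt(n_pairs)
        ts = sd.gen_brownian_tracks(n_cells=120, n_frames=6, D=1.0,
                                    box=(400, 400, 200), seed=5)
        pe = build_pairs(ts, "cutoff", d_max=30.0)
        c = msrd_curve(ts, pe, [10.0], normalization="none")
        assert abs(c.msrd[0] - 12 * D * tau) < 3 * c.se[0] + 0.1 * 12 * D * tau

    def test_invariance_translation_and_rescale(self, rng):
        ts = sd.gen_brownian_tracks(n_cells=30, n_frames=8, D=0.5, seed=9)
        pe = build_pairs(ts, "knn", k=4, t0_policy="fixed", t0_frame=0)
        base = msrd_curve(ts, pe, self.lags[:6]).msrd
        shifted = ts.with_positions(ts.data[["x_um", "y_um", "z_um"]].to_numpy() + 123.0)
        scaled = ts.with_positions(ts.data[["x_um", "y_um", "z_um"]].to_numpy() * 3.7)
        pe_s = build_pairs(shifted, "knn", k=4, t0_policy="fixed", t0_frame=0)
        pe_r = build_pairs(scaled, "knn", k=4, t0_policy="fixed", t0_frame=0)
        np.testing.assert_allclose(msrd_curve(shifted, pe_s, self.lags[:6]).msrd, base, rtol=1e-9)
        np.testing.assert_allclose(msrd_curve(scaled, pe_r, self.lags[:6]).msrd, base, rtol=1e-9)


class TestTemporalAutocorrelation:
    def test_constant_velocity_is_one(self):
        t = np.arange(10) * 2.0
        pos = np.zeros((5, 10, 3))
        pos[:, :, 0] = 1.3 * t
        ts = make_trackset(pos)
        c = velocity_temporal_autocorrelation(ts, np.arange(0, 13, 2.0))
        np.testing.assert_allclose(c.value, 1.0, rtol=1e-12)

    def test_alternating_velocity_sign_pattern(self):
        # velocity +v, -v each frame -> C(tau) = (-1)^(tau/dt)
        x = np.array([0.0, 2, 0, 2, 0, 2, 0, 2, 0])
        pos = np.zeros((1, 9, 3))
        pos[0, :, 0] = x
        ts = make_trackset(pos, frame_interval=1.0)
        c = velocity_temporal_autocorrelation(ts, [0.0, 1.0, 2.0, 3.0], scheme="forward")
        np.testing.assert_allclose(c.value, [1, -1, 1, -1], rtol=1e-12)

    def test_white_noise_decorrelates(self, rng):
        # i.i.d. velocities: C(tau>=dt) = 0 within 3 sampling SE
        steps = rng.standard_normal((400, 40, 3))
        pos = np.concatenate([np.zeros((400, 1, 3)), np.cumsum(steps, axis=1)], axis=1)
        ts = make_trackset(pos, frame_interval=1.0)
        c = velocity_temporal_autocorrelation(ts, [2.0, 4.0, 6.0], scheme="forward")
        assert np.all(np.abs(c.value) < 3 * c.se)

    def test_time_reversal_symmetry(self, rng):
        pos = np.cumsum(rng.standard_normal((40, 12, 3)), axis=1)
        ts = make_trackset(pos, 2.0)
        rev = make_trackset(pos[:, ::-1], 2.0)
        lags = [0.0, 2.0, 4.0, 6.0]
        a = velocity_temporal_autocorrelation(ts, lags).value
        b = velocity_temporal_autocorrelation(rev, lags).value
        np.testing.assert_allclose(a, b, rtol=1e-9)


class TestSpatialCorrelation:
    bins = np.arange(0.0, 41.0, 10.0)

    def test_uniform_translation_absolute_one(self, rng):
        start = rng.uniform(0, 30, (20, 1, 3))
        t = np.arange(6) * 2.0
        pos = start + np.array([1.0, 0.5, 0.0]) * t[None, :, None]
        ts = make_trackset(pos)
        c = velocity_spatial_correlation(ts, self.bins, "absolute")
        occupied = c.n > 0
        np.testing.assert_allclose(c.value[occupied], 1.0, rtol=1e-9)

    def test_uniform_translation_relative_nan(self, rng):
        start = rng.uniform(0, 30, (20, 1, 3))
        pos = start + np.array([1.0, 0.5, 0.0]) * (np.arange(6) * 2.0)[None, :, None]
        ts = make_trackset(pos)
        c = velocity_spatial_correlation(ts, self.bins, "relative")
        occupied = c.n > 0
        assert occupied.any()
        assert np.isnan(c.value[occupied]).all()  # u == 0: undefined, counts kept

    def test_two_populations_match_exhaustive_enumeration(self):
        # interleaved +v/-v cells on a line; oracle = brute force over all pairs
        n = 16
        x = np.arange(n) * 5.0
        vdir = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        pos = np.zeros((n, 3, 3))
        pos[:, :, 0] = x[:, None] + vdir[:, None] * (np.arange(3) * 2.0)[None, :]
        ts = make_trackset(pos)
        c = velocity_spatial_correlation(ts, self.bins, "absolute")
        # exhaustive oracle over same-frame pairs (velocity defined at frame 1 only)
        dots, dist = [], []
        for i in range(n):
            for j in range(i + 1, n):
                dist.append(abs(x[i] - x[j]))
                dots.append(vdir[i] * vdir[j])
        dots, dist = np.array(dots), np.array(dist)
        for b in range(len(self.bins) - 1):
            sel = (dist >= self.bins[b]) & (dist < self.bins[b + 1])
            if sel.any():
                np.testing.assert_allclose(c.value[b], dots[sel].mean(), rtol=1e-9)


class TestAverageNormalizedSpeed:
    def test_equal_speeds_give_one(self, rng):
        start = rng.uniform(0, 20, (10, 1, 3))
        pos = start + np.array([2.0, 0, 0]) * (np.arange(5) * 2.0)[None, :, None]
        ts = make_trackset(pos)
        s = average_normalized_speed(ts)
        np.testing.assert_allclose(s.mean_norm_speed, 1.0, rtol=1e-12)

    def test_scope_twice_global_mean(self):
        pos = np.zeros((2, 5, 3))
        pos[0, :, 0] = np.arange(5) * 2.0      # speed 1
        pos[1, :, 0] = np.arange(5) * 6.0      # speed 3; global mean 2
        ts = make_trackset(pos)
        s = average_normalized_speed(ts, scope_ids=[1], normalizer=1.5)
        np.testing.assert_allclose(s.mean_norm_speed, 2.0, rtol=1e-12)

    def test_random_half_scope_matches_full_ensemble(self, rng):
        # resampling check: a random half of a homogeneous ensemble tracks the
        # full-ensemble speed series within sampling error
        ts = sd.gen_brownian_tracks(n_cells=200, n_frames=10, D=1.0, seed=3)
        full = average_normalized_speed(ts)
        half = rng.choice(200, 100, replace=False)
        s = average_normalized_speed(ts, scope_ids=half, normalizer=full.normalizer)
        assert np.all(np.abs(s.mean_norm_speed - full.mean_norm_speed) < 4 * s.se)

    def test_zero_normalizer_rejected(self, grid9_static):
        with pytest.raises(ValueError):
            average_normalized_speed(grid9_static, normalizer=0.0)


def test_se_shrinks_with_ensemble_size():
    # doubling the pair ensemble shrinks the SE roughly by sqrt(2)
    ts_small = sd.gen_brownian_tracks(n_cells=60, n_frames=7, D=1.0,
                                      box=(200, 200, 100), seed=21)
    ts_big = sd.gen_brownian_tracks(n_cells=240, n_frames=7, D=1.0,
                                    box=(400, 400, 200), seed=22)
    out = []
    for ts in (ts_small, ts_big):
        pe = build_pairs(ts, "knn", k=8, t0_policy="fixed", t0_frame=0)
        c = msrd_curve(ts, pe, [10.0])
        out.append((c.se[0], c.n_pairs[0]))
    (se_s, n_s), (se_b, n_b) = out
    expected_ratio = np.sqrt(n_s / n_b)
    assert se_b / se_s == pytest.approx(expected_ratio, rel=0.5)
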