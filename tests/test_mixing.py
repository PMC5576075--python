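import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixsync import (CellTrackSet, FixtureSpec, MsddCurve, compute_velocities,
                     directional_derivative, fit_power_law, generate, msdd,
                     neighbor_graph, population_average_dv, strain_rate)
from conftest import make_track_set


class TestVelocities:
    def test_stationary_track_zero_velocity(self):
        pos = np.zeros((10, 3, 3))
        vf = compute_velocities(make_track_set(pos), lag=5)
        assert np.allclose(vf.data[["vx", "vy", "vz"]], 0.0)

    def test_uniform_motion_recovered_exactly(self):
        v = np.array([1.0, 2.0, 3.0])
        t = np.arange(12)[:, None, None]
        pos = np.zeros((12, 2, 3)) + t * v
        for lag in (1, 5):
            vf = compute_velocities(make_track_set(pos), lag=lag)
            assert np.allclose(vf.data[["vx", "vy", "vz"]], v)

    def test_sinusoid_gives_finite_difference_not_derivative(self):
        # x(t) = sin(ω t): the lag-Δ velocity is (sin ω(t+Δ) − sin ωt)/Δ
        w, lag = 0.3, 5.0
        t = np.arange(30, dtype=float)
        pos = np.zeros((30, 1, 3))
        pos[:, 0, 0] = np.sin(w * t)
        vf = compute_velocities(make_track_set(pos), lag=lag)
        expected = (np.sin(w * (vf.data["frame"] + lag)) - np.sin(w * vf.data["frame"])) / lag
        assert np.allclose(vf.data["vx"], expected)
        # and it differs from the instantaneous derivative
        assert not np.allclose(vf.data["vx"], w * np.cos(w * vf.data["frame"]))

    def test_lag_not_multiple_of_frame_interval_rejected(self):
        ts = make_track_set(np.zeros((5, 1, 3)), dt_frame=2.0)
        with pytest.raises(ValueError, match="multiple"):
            compute_velocities(ts, lag=3.0)

    def test_displacement_across_gap_discarded(self):
        df = pd.DataFrame({"track_id": 0, "frame": [0, 1, 2, 4, 5, 6],
                           "x_um": [0, 1, 2, 4, 5, 6.0], "y_um": 0.0, "z_um": 0.0})
        vf = compute_velocities(CellTrackSet(df), lag=2)
        # frames 1 and 2 would need frame 3; frame 2->4 spans the gap
        assert set(vf.data["frame"]) == {0, 4}


class TestNeighborGraph:
    def test_distance_threshold_definition(self):
        pts = np.array([[0, 0, 0], [10.0, 0, 0]])
        adj = neighbor_graph(pts, method="distance", delta=16.0)
        assert list(adj[0]) == [1] and list(adj[1]) == [0]
        adj = neighbor_graph(np.array([[0, 0, 0], [20.0, 0, 0]]), delta=16.0)
        assert len(adj[0]) == 0

    def test_tetrahedron_voronoi_complete_graph(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        adj = neighbor_graph(pts, method="voronoi", delta=16.0)
        for i in range(4):
            assert set(adj[i]) == set(range(4)) - {i}

    def test_coplanar_points_fall_back_with_warning(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float)
        with pytest.warns(UserWarning, match="degenerate"):
            adj = neighbor_graph(pts, method="voronoi", delta=2.0)
        assert all(len(a) == 3 for a in adj)  # all within distance 2


class TestDirectionalDerivative:
    def test_pure_drift_gives_zero(self, rng):
        base = rng.random((1, 20, 3)) * 30
        drift = np.cumsum(rng.normal(size=(12, 1, 3)), axis=0) * 5
        pos = base + drift  # every cell shares the same time-dependent velocity
        ts = make_track_set(pos)
        prof = directional_derivative(ts, compute_velocities(ts, lag=5), delta=16.0)
        assert np.nanmax(prof.data["Dv"].to_numpy()) < 1e-12

    def test_two_cell_closed_form(self):
        # separation (10,0,0) μm, velocity difference (1,0,0) μm/min
        pos = np.zeros((8, 2, 3))
        pos[:, 1, 0] = 10.0
        pos[:, 1, 0] += np.arange(8) * 1.0  # cell 1 moves at 1 μm/min
        ts = make_track_set(pos)
        prof = directional_derivative(ts, compute_velocities(ts, lag=1), delta=16.0)
        first = prof.data[prof.data["frame"] == 0]
        # lag-1 velocities exact; |δ| at frame 0 is 10 μm
        assert np.allclose(first["Dv"], 0.1)

    def test_rigid_rotation_closed_form(self):
        # offsets ⊥ Ω: per-neighbor contribution is the finite-difference
        # rotation rate 2 sin(Ω·lag/2)/lag, independent of distance
        omega, lag = 0.05, 1.0
        # planar ring (z identical -> neighbor offsets in the xy-plane)
        ang = np.linspace(0, 2 * np.pi, 7, endpoint=False)
        x0 = np.stack([10 * np.cos(ang), 10 * np.sin(ang), np.zeros(7)], axis=1)
        F = 11
        t = np.arange(F) * 1.0
        pos = np.empty((F, 7, 3))
        for k, tk in enumerate(t):
            c, s = np.cos(omega * tk), np.sin(omega * tk)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            pos[k] = x0 @ R.T
        ts = make_track_set(pos)
        prof = directional_derivative(ts, compute_velocities(ts, lag=lag), delta=16.0)
        expected = 2 * np.sin(omega * lag / 2) / lag
        assert np.allclose(prof.data["Dv"].dropna(), expected, rtol=1e-9)

    def test_isolated_cell_undefined_not_zero(self):
        pos = np.zeros((6, 2, 3))
        pos[:, 1, 0] = 100.0
        ts = make_track_set(pos)
        prof = directional_derivative(ts, compute_velocities(ts, lag=1), delta=16.0)
        assert prof.data["Dv"].isna().all()
        assert (prof.data["n_neighbors"] == 0).all()


class TestStrainRate:
    @staticmethod
    def _profile(pos, kernel_scale=25.0):
        ts = make_track_set(pos)
        return strain_rate(ts, compute_velocities(ts, lag=1), kernel_scale=kernel_scale)

    def test_rigid_translation_zero_tensor(self, rng):
        base = rng.random((1, 40, 3)) * 40
        pos = base + np.arange(5)[:, None, None] * np.array([2.0, -1.0, 0.5])
        prof = self._profile(pos)
        assert np.nanmax(np.abs(prof.data["strain_norm"])) < 1e-10

    def test_rigid_rotation_symmetric_part_vanishes(self, rng):
        omega = np.array([0.0, 0.0, 0.02])
        x0 = (rng.random((40, 3)) - 0.5) * 40
        F = 5
        pos = np.empty((F, 40, 3))
        for k in range(F):
            a = np.linalg.norm(omega) * k
            c, s = np.cos(a), np.sin(a)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            pos[k] = x0 @ R.T
        prof = self._profile(pos)
        # finite-difference velocities of a rotation are still an affine map
        # of position, whose symmetric gradient is O((Ω dt)²) small
        assert np.nanmax(np.abs(prof.data["strain_norm"])) < 1e-3

    def test_isotropic_expansion_recovers_rate(self, rng):
        a = 0.02
        x0 = rng.random((50, 3)) * 40
        pos = np.array([x0 * np.exp(a * k) for k in range(4)])
        prof = self._profile(pos)
        # exact expected gradient of the lag-1 finite difference: (e^a −1)·I
        expected = np.exp(a) - 1.0
        for comp in ("Sxx", "Syy", "Szz"):
            assert np.allclose(prof.data[comp].dropna(), expected, atol=1e-8)
        for comp in ("Sxy", "Sxz", "Syz"):
            assert np.nanmax(np.abs(prof.data[comp])) < 1e-8

    def test_insufficient_support_flagged(self):
        pos = np.zeros((3, 2, 3))
        pos[:, 1, 0] = 5.0
        prof = self._profile(pos, kernel_scale=10.0)
        assert prof.data["strain_norm"].isna().all()


class TestMsdd:
    def test_global_translation_cancels_exactly(self, rng):
        ts, _ = generate(FixtureSpec("brownian", {"D": 0.5}, N=20, T=15, seed=3))
        drift = np.cumsum(rng.normal(size=(16, 3)), axis=0) * 8
        c0 = msdd(ts, r=16.0)
        c1 = msdd(ts.translated(drift), r=16.0)
        assert np.array_equal(c0.n_pairs, c1.n_pairs)
        assert np.allclose(c0.m, c1.m, rtol=1e-9)

    def test_constant_separation_rate_exact_quadratic(self):
        ts, exp = generate(FixtureSpec("pair-separation", {"v_rel": 0.5, "d0": 1.0}, T=10))
        c = msdd(ts, r=16.0)
        assert np.allclose(c.m, exp["msdd"]["coefficient"] * c.t**2)
        assert c.m[c.t == 4.0] == pytest.approx(4.0)  # (0.5·4)²

    def test_brownian_pairs_match_12Dt_within_3se(self):
        D = 1.0
        ts, _ = generate(FixtureSpec("brownian", {"D": D, "layout": "pairs"},
                                     N=500, T=15, seed=11))
        c = msdd(ts, r=16.0)
        sel = c.t > 0
        n = c.n_pairs[sel]
        assert n.min() >= 200
        expected = 12 * D * c.t[sel]
        # |Δx_i − Δx_j|² ~ (4Dt)·χ²₃: sd of the pair mean is √(2/3)·12Dt/√n
        se = np.sqrt(2.0 / 3.0) * expected / np.sqrt(n)
        assert np.all(np.abs(c.m[sel] - expected) <= 3 * se)

    def test_duplicate_tracks_give_identically_zero(self):
        pos = np.cumsum(np.random.default_rng(0).normal(size=(10, 1, 3)), axis=0)
        pos = np.repeat(pos, 2, axis=1)  # two identical tracks
        c = msdd(make_track_set(pos), r=16.0)
        assert np.all(c.m == 0.0)

    def test_pair_enters_once_at_first_contact(self, two_track_toy):
        # contact (≤16 μm) first happens at frame 4 (distance 14)
        c = msdd(two_track_toy, r=16.0)
        # only lags up to 7-4=3 can be observed for the single pair
        assert c.t.max() == 3.0
        # displacement difference grows at 4 μm/frame from t0=4
        assert np.allclose(c.m, (4.0 * c.t) ** 2)

    def test_never_close_pairs_contribute_nothing(self):
        pos = np.zeros((5, 2, 3))
        pos[:, 1, 0] = 100.0
        with pytest.warns(UserWarning, match="no cell pair"):
            c = msdd(make_track_set(pos), r=16.0)
        assert np.all(c.m == 0)


class TestPowerLawFit:
    def test_exact_power_laws_recovered(self):
        t = np.arange(0, 21, dtype=float)
        for expo in (1.0, 2.0):
            curve = MsddCurve(t, 3.0 * t**expo, np.full(len(t), 10), 16.0)
            fit = fit_power_law(curve, (1.0, 20.0))
            assert fit.exponent == pytest.approx(expo, abs=1e-12)
            assert fit.prefactor == pytest.approx(3.0, rel=1e-9)

    def test_crossover_curve_exponent_between_regimes(self):
        t = np.arange(0, 31, dtype=float)
        m = 3.0 * t + 1.0 * t**2  # crossover at t = 3 min
        curve = MsddCurve(t, m, np.full(len(t), 10), 16.0)
        fit = fit_power_law(curve, (1.0, 10.0))
        assert 1.0 < fit.exponent < 2.0

    def test_too_few_points_rejected(self):
        curve = MsddCurve(np.array([0.0, 1, 2]), np.array([0.0, 1, 4]),
                          np.array([1, 1, 1]), 16.0)
        with pytest.raises(ValueError, match="4"):
            fit_power_law(curve, (1.0, 2.0))


class TestPopulationAverage:
    def test_constant_and_two_value_means(self):
        df = pd.DataFrame({"track_id": [0, 1, 0, 1], "frame": [0, 0, 1, 1],
                           "Dv": [0.2, 0.2, 0.1, 0.3], "n_neighbors": 1})
        from mixsync import MixingProfile
        out = population_average_dv(MixingProfile(df))
        assert out.loc[out["frame"] == 0, "Dv_mean"].iloc[0] == pytest.approx(0.2)
        assert out.loc[out["frame"] == 0, "Dv_sd"].iloc[0] == pytest.approx(0.0)
        assert out.loc[out["frame"] == 1, "Dv_mean"].iloc[0] == pytest.approx(0.2)

    def test_undefined_cells_excluded(self):
        from mixsync import MixingProfile
        df = pd.DataFrame({"track_id": [0, 1], "frame": [0, 0],
                           "Dv": [0.4, np.nan], "n_neighbors": [2, 0]})
        out = population_average_dv(MixingProfile(df))
        assert out["n_cells"].iloc[0] == 1
        assert out["Dv_mean"].iloc[0] == pytest.approx(0.4)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(vx=st.floats(-50, 50), vy=st.floats(-50, 50), vz=st.floats(-50, 50))
def test_drift_invariance_property(vx, vy, vz):
    """D_v is unchanged by an arbitrary constant-velocity global drift."""
    ts, _ = generate(FixtureSpec("brownian", {"D": 0.5}, N=12, T=8, seed=2))
    drift = np.arange(9)[:, None] * np.array([vx, vy, vz])
    vf0 = compute_velocities(ts, lag=2)
    vf1 = compute_velocities(ts.translated(drift), lag=2)
    p0 = directional_derivative(ts, vf0, delta=16.0)
    p1 = directional_derivative(ts.translated(drift), vf1, delta=16.0)
    np.testing.assert_allclose(p0.data["Dv"], p1.data["Dv"], rtol=1e-7, atol=1e-12)
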