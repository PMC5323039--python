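"""Soft-cylinder density CV: switching function, volume, gradients, occupancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poreflux.constants import kbt
from poreflux.density import (
    AnchoredFrame,
    FixedFrame,
    SoftCylinderRegion,
    count_cylinder_occupancy,
    density_and_gradient,
    effective_volume,
    neighbor_list_update,
    region_weight,
    switch_value,
)
from poreflux.dynamics import TrajectoryStore


class TestSwitchValue:
    def test_boundary_values_and_derivatives(self):
        """χ equals 1 / 0 with zero slope at the inner / outer shell edges."""
        for S, dS in [(4.0, 2.0), (6.0, 1.0), (10.0, 0.5)]:
            v, d = switch_value(S - dS / 2, S, dS)
            assert (v, d) == (1.0, 0.0)
            v, d = switch_value(S + dS / 2, S, dS)
            assert (v, d) == (0.0, 0.0)

    def test_midpoint_against_symbolic_evaluation(self):
        """Value and derivative at σ=S match an independent sympy evaluation."""
        import sympy as sp

        S, dS = 4.0, 2.0
        sig, a, b = sp.symbols("sigma a b", positive=True)
        chi = (b**2 - sig**2) ** 2 * (b**2 + 2 * sig**2 - 3 * a**2) / (b**2 - a**2) ** 3
        subs = {a: sp.Rational(3), b: sp.Rational(5), sig: sp.Rational(4)}
        expected_v = float(chi.subs(subs))
        expected_d = float(sp.diff(chi, sig).subs(subs))
        v, d = switch_value(S, S, dS)
        assert v == pytest.approx(expected_v, rel=1e-12)
        assert d == pytest.approx(expected_d, rel=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        sigma=st.floats(0.0, 12.0),
        S=st.floats(1.0, 8.0),
        dS=st.floats(0.2, 2.0),
    )
    def test_range_monotonicity_and_derivative_sign(self, sigma, S, dS):
        if S - dS / 2 < 0:
            dS = 2 * S
        v, d = switch_value(sigma, S, dS)
        assert 0.0 <= v <= 1.0
        assert d <= 0.0  # monotone non-increasing in sigma

    def test_continuity_across_both_boundaries(self):
        """χ and dχ/dσ are numerically continuous on a dense grid straddling the shell."""
        S, dS = 4.0, 2.0
        grid = np.linspace(S - dS, S + dS, 20_001)
        v, d = switch_value(grid, S, dS)
        assert np.max(np.abs(np.diff(v))) < 1e-3
        assert np.max(np.abs(np.diff(d))) < 1e-3

    def test_preconditions(self):
        with pytest.raises(ValueError):
            switch_value(1.0, 2.0, 0.0)
        with pytest.raises(ValueError):
            switch_value(1.0, 0.5, 2.0)  # S - dS/2 < 0
        with pytest.raises(ValueError):
            switch_value(-1.0, 2.0, 1.0)


class TestRegionWeight:
    def test_interior_point(self, region, frame):
        assert region_weight((0.0, 0.0, 0.0), region, frame) == 1.0

    def test_outside_outer_radius_is_zero(self, region, frame):
        p = (region.R + region.dR / 2 + 0.1, 0.0, 0.0)
        assert region_weight(p, region, frame) == 0.0

    def test_factorises_into_two_switches(self, region, frame, rng):
        for _ in range(50):
            p = rng.uniform(-8, 8, 3)
            xz, _ = switch_value(abs(p[2]), region.Z, region.dZ)
            xr, _ = switch_value(np.hypot(p[0], p[1]), region.R, region.dR)
            assert region_weight(p, region, frame) == pytest.approx(xz * xr, abs=1e-14)


class TestEffectiveVolume:
    def test_hard_cylinder_limit(self):
        region = SoftCylinderRegion(R=4.0, dR=1e-6, Z=6.0, dZ=1e-6)
        assert effective_volume(region) == pytest.approx(np.pi * 16.0 * 12.0, rel=1e-6)

    def test_brackets_inner_and_outer_cylinders(self, region):
        v = effective_volume(region)
        ar, az = region.R - region.dR / 2, region.Z - region.dZ / 2
        br, bz = region.outer_radius, region.outer_half_length
        assert np.pi * ar**2 * 2 * az < v < np.pi * br**2 * 2 * bz

    def test_against_adaptive_quadrature(self, region):
        """Closed-form antiderivative agrees with scipy quadrature of the printed integrand."""
        from scipy.integrate import quad

        axial = 2 * quad(lambda z: switch_value(abs(z), region.Z, region.dZ)[0], 0, region.outer_half_length)[0]
        radial = quad(
            lambda r: 2 * np.pi * r * switch_value(r, region.R, region.dR)[0],
            0, region.outer_radius,
        )[0]
        assert effective_volume(region) == pytest.approx(axial * radial, rel=1e-9)

    def test_monotone_in_R_and_Z(self):
        vols_r = [effective_volume(SoftCylinderRegion(r, 1.0, 6.0, 1.0)) for r in (3.0, 4.0, 5.0)]
        vols_z = [effective_volume(SoftCylinderRegion(4.0, 1.0, z, 1.0)) for z in (5.0, 6.0, 7.0)]
        assert vols_r == sorted(vols_r) and len(set(vols_r)) == 3
        assert vols_z == sorted(vols_z) and len(set(vols_z)) == 3

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            SoftCylinderRegion(R=1.0, dR=3.0, Z=6.0, dZ=1.0)  # R - dR/2 < 0
        with pytest.raises(ValueError):
            SoftCylinderRegion(R=4.0, dR=0.0, Z=6.0, dZ=1.0)


class TestDensityAndGradient:
    def test_plateau_configuration(self, region, frame):
        """All particles strictly inside: ρ = N/V and every gradient vanishes."""
        rng = np.random.default_rng(1)
        n = 20
        pos = np.zeros((n, 3))
        pos[:, 0] = rng.uniform(-2, 2, n)
        pos[:, 1] = rng.uniform(-1, 1, n)
        pos[:, 2] = rng.uniform(-4, 4, n)
        res = density_and_gradient(pos, region, frame)
        assert res.rho == pytest.approx(n / res.volume, rel=1e-14)
        assert np.all(res.gradients == 0.0)
        assert np.all(res.weights == 1.0)

    def test_empty_region(self, region, frame):
        pos = np.full((10, 3), 20.0)
        res = density_and_gradient(pos, region, frame)
        assert res.rho == 0.0

    def test_gradients_match_finite_differences(self, region, frame):
        rng = np.random.default_rng(2)
        pos = rng.uniform(-8, 8, (20, 3))
        res = density_and_gradient(pos, region, frame)
        h = 1e-4
        for i in range(20):
            for ax in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, ax] += h
                pm[i, ax] -= h
                fd = (
                    density_and_gradient(pp, region, frame).rho
                    - density_and_gradient(pm, region, frame).rho
                ) / (2 * h)
                an = res.gradients[i, ax]
                if abs(fd) > 1e-12 or abs(an) > 1e-12:
                    assert abs(fd - an) / max(abs(fd), abs(an)) < 1e-5

    def test_rigid_motion_invariance_with_anchored_frame(self, region):
        """ρ is unchanged when particles and reference particles move rigidly together."""
        rng = np.random.default_rng(3)
        n_ref = 9
        ref = np.concatenate(
            [
                rng.normal((0, 0, 0), 0.5, (3, 3)),
                rng.normal((0, 0, -7), 0.5, (3, 3)),
                rng.normal((0, 0, 7), 0.5, (3, 3)),
            ]
        )
        particles = rng.uniform(-7, 7, (30, 3))
        pos = np.vstack([ref, particles])
        af = AnchoredFrame(middle=[0, 1, 2], distal_a=[3, 4, 5], distal_b=[6, 7, 8])
        rho0 = density_and_gradient(pos, region, af).rho

        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        tilt = np.array([[1, 0, 0], [0, np.cos(0.4), -np.sin(0.4)], [0, np.sin(0.4), np.cos(0.4)]])
        moved = pos @ (rot @ tilt).T + np.array([3.0, -11.0, 5.0])
        rho1 = density_and_gradient(moved, region, af).rho
        assert rho1 == pytest.approx(rho0, rel=1e-12)

    def test_total_gradient_translation_invariant_in_exact_mode(self, region):
        """With frame gradients included, the gradients sum to zero (no net bias force)."""
        rng = np.random.default_rng(4)
        ref = np.concatenate(
            [
                rng.normal((0, 0, 0), 0.5, (3, 3)),
                rng.normal((0, 0, -7), 0.5, (3, 3)),
                rng.normal((0, 0, 7), 0.5, (3, 3)),
            ]
        )
        particles = rng.uniform(-7, 7, (30, 3))
        pos = np.vstack([ref, particles])
        af = AnchoredFrame(middle=[0, 1, 2], distal_a=[3, 4, 5], distal_b=[6, 7, 8])
        res = density_and_gradient(pos, region, af, frame_gradients=True)
        assert np.allclose(res.gradients.sum(axis=0), 0.0, atol=1e-12)
        # and the frame-gradient entries agree with finite differences
        h = 1e-5
        for i in [0, 4, 7]:  # one particle from each reference set
            for ax in range(3):
                pp, pm = pos.copy(), pos.copy()
                pp[i, ax] += h
                pm[i, ax] -= h
                fd = (
                    density_and_gradient(pp, region, af).rho
                    - density_and_gradient(pm, region, af).rho
                ) / (2 * h)
                assert res.gradients[i, ax] == pytest.approx(fd, abs=5e-7)

    def test_anchored_frame_validation(self):
        with pytest.raises(ValueError, match="disjoint"):
            AnchoredFrame(middle=[0, 1], distal_a=[1, 2], distal_b=[3])
        with pytest.raises(ValueError, match="non-empty"):
            AnchoredFrame(middle=[], distal_a=[1], distal_b=[2])


class TestNeighborList:
    def test_boundary_particle_included(self, region, frame):
        pos = np.array([[region.outer_radius, 0.0, 0.0], [30.0, 0.0, 0.0]])
        nl = neighbor_list_update(pos, region, frame, margin=0.0)
        assert 0 in nl.indices and 1 not in nl.indices

    def test_list_evaluation_equals_full_evaluation(self, region, frame):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-15, 15, (400, 3))
        nl = neighbor_list_update(pos, region, frame, margin=4.0)
        full = density_and_gradient(pos, region, frame)
        sub = density_and_gradient(pos, region, frame, neighbor_list=nl)
        assert sub.rho == full.rho  # exact, order-stable summation
        assert np.array_equal(sub.gradients, full.gradients)

    def test_stale_list_rejected(self, region, frame):
        pos = np.zeros((5, 3))
        nl = neighbor_list_update(pos, region, frame, margin=2.0)
        nl.age_steps = 100
        with pytest.raises(RuntimeError, match="stale"):
            density_and_gradient(pos, region, frame, neighbor_list=nl, per_step_bound=0.1)


class TestOccupancy:
    def test_hand_built_counts(self, frame):
        pos = np.array(
            [
                [[0, 0, 0], [1, 1, 2], [2, 0, -3], [10, 0, 0], [0, 0, 30]],
            ],
            dtype=float,
        )
        traj = TrajectoryStore(times=[0.0], positions=pos, species=["W"] * 5)
        df = count_cylinder_occupancy(traj, radius=7.0, height=32.0, frame=frame)
        assert df["count"].iloc[0] == 3

    def test_empty_frame(self, frame):
        traj = TrajectoryStore(
            times=[0.0], positions=np.full((1, 4, 3), 50.0), species=["W"] * 4
        )
        df = count_cylinder_occupancy(traj, radius=7.0, height=32.0, frame=frame)
        assert df["count"].iloc[0] == 0

    def test_running_average_window(self, frame):
        n = 10
        pos = np.zeros((n, 1, 3))
        pos[5:, 0, 0] = 50.0  # particle leaves after frame 4
        traj = TrajectoryStore(
            times=np.arange(n, dtype=float), positions=pos, species=["W"]
        )
        df = count_cylinder_occupancy(traj, 7.0, 32.0, frame, window_ps=3.0)
        counts = df["count"].to_numpy()
        ravg = df["running_avg"].to_numpy()
        assert np.array_equal(counts[:5], np.ones(5))
        assert ravg[0] == 1.0
        assert ravg[6] == pytest.approx(np.mean(counts[3:7]))
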