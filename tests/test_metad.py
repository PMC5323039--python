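"""Metadynamics: bias bookkeeping, schedule, walkers, free-energy recovery."""

import numpy as np
import pytest

from poreflux.constants import kbt
from poreflux.density import FixedFrame, SoftCylinderRegion, density_and_gradient
from poreflux.dynamics import BrownianSystem, DoubleWellZ, integrate
from poreflux.metad import (
    BiasPotential,
    CoordinateCV,
    DensityCV,
    HeightSchedule,
    WalkerEnsemble,
    bias_forces,
    deposit,
    fes_from_bias,
    height_schedule,
    run_multiwalker,
)
from poreflux.scenarios import make_scenario

KT = kbt(298.0)


class TestBiasPotential:
    def test_single_deposit_peak_value(self):
        bias = BiasPotential(width=0.0005)
        deposit(bias, center=0.01, height=0.05)
        assert bias.energy(0.01) == pytest.approx(0.05, rel=1e-4)

    def test_far_tail_is_negligible(self):
        bias = BiasPotential(width=0.0005)
        bias.deposit(0.01, 0.05)
        assert bias.energy(0.01 + 10 * 0.0005, from_history=True) < 0.05 * np.exp(-50) * 1.01

    def test_superposition_is_exact(self):
        b1 = BiasPotential(width=0.001)
        b1.deposit(0.0, 0.03)
        b2 = BiasPotential(width=0.001)
        b2.deposit(0.004, 0.02)
        both = BiasPotential(width=0.001)
        both.deposit(0.0, 0.03)
        both.deposit(0.004, 0.02)
        s = np.linspace(-0.003, 0.007, 101)
        assert np.allclose(
            both.energy(s, from_history=True),
            b1.energy(s, from_history=True) + b2.energy(s, from_history=True),
            rtol=1e-12,
        )

    def test_grid_matches_history_within_resolution(self):
        rng = np.random.default_rng(0)
        bias = BiasPotential(width=0.0005)
        for c in rng.normal(0.01, 0.002, 200):
            bias.deposit(c, 0.01)
        # exact at the grid nodes (node values are accumulated Gaussian sums) ...
        nodes = bias.grid[(bias.grid > 0.004) & (bias.grid < 0.016)]
        assert np.allclose(bias.energy(nodes), bias.energy(nodes, from_history=True), atol=1e-10)
        # ... and within interpolation error between them
        s = np.linspace(0.004, 0.016, 301)
        u_hist = bias.energy(s, from_history=True)
        assert np.allclose(bias.energy(s), u_hist, atol=0.01 * u_hist.max())

    def test_negative_height_rejected(self):
        bias = BiasPotential(width=0.0005)
        with pytest.raises(ValueError):
            bias.deposit(0.0, -0.01)

    def test_deposit_log_round_trip(self, tmp_path):
        bias = BiasPotential(width=0.0005)
        bias.deposit(0.01, 0.05, t=4.0)
        bias.deposit(0.012, 0.04, t=8.0)
        path = tmp_path / "deposits.tsv"
        bias.write_tsv(path)
        back = BiasPotential.read_tsv(path)
        assert back.width == bias.width
        assert back.centers == bias.centers and back.heights == bias.heights


class TestBiasForces:
    def test_flat_bias_gives_zero_forces(self, region, frame):
        bias = BiasPotential(width=0.0005)
        pos = np.random.default_rng(1).uniform(-7, 7, (20, 3))
        res = density_and_gradient(pos, region, frame)
        assert np.all(bias_forces(bias, res) == 0.0)

    def test_outside_switching_shells_feels_nothing(self, region, frame):
        bias = BiasPotential(width=0.0005)
        bias.deposit(0.01, 0.5)
        pos = np.array([[0.0, 0.0, 0.0], [1.0, 0.5, -2.0], [20.0, 0.0, 0.0]])
        res = density_and_gradient(pos, region, frame)
        f = bias_forces(bias, res)
        assert np.all(f == 0.0)  # plateau and exterior particles: zero gradient

    def test_energy_change_matches_force_to_first_order(self, region, frame):
        bias = BiasPotential(width=0.002)
        rng = np.random.default_rng(2)
        for c in rng.normal(0.008, 0.003, 50):
            bias.deposit(abs(c), 0.05)
        pos = rng.uniform(-7, 7, (30, 3))
        res = density_and_gradient(pos, region, frame)
        f = bias_forces(bias, res)
        step = 1e-5
        delta = rng.normal(0, 1, (30, 3))
        delta /= np.linalg.norm(delta)
        res2 = density_and_gradient(pos + step * delta, region, frame)
        du = bias.energy(res2.rho, from_history=True) - bias.energy(res.rho, from_history=True)
        assert du == pytest.approx(-np.sum(f * delta) * step, abs=1e-9)


class TestHeightSchedule:
    def test_printed_endpoints(self):
        sched = HeightSchedule(h0=0.035, floor=0.0035, decay_time_ps=4000.0)
        assert sched(0.0) == 0.035
        assert sched(4000.0) == 0.0035
        assert sched(1e6) == 0.0035

    def test_monotone_non_increasing(self):
        ts = np.linspace(0, 8000, 500)
        hs = [height_schedule(t, {"h0": 0.035, "floor": 0.0035, "decay_time_ps": 4000.0}) for t in ts]
        assert np.all(np.diff(hs) <= 0)

    def test_floor_above_initial_rejected(self):
        with pytest.raises(ValueError):
            HeightSchedule(h0=0.001, floor=0.01)


class TestMultiWalker:
    def test_deposit_count_is_walkers_times_rounds(self):
        systems = [
            make_scenario(
                "ideal_gas_bath",
                {"n_density": 0.005, "box": (16.0, 16.0, 20.0), "dt": 0.05, "seed": s},
            )
            for s in range(3)
        ]
        bias = BiasPotential(width=0.0005)
        ens = WalkerEnsemble(systems=systems, bias=bias, interval_ps=2.0, schedule=HeightSchedule())
        cv = DensityCV(SoftCylinderRegion(3.0, 1.0, 4.0, 1.0), FixedFrame())
        result = run_multiwalker(ens, cv, n_steps=200)  # 5 rounds of 40 steps
        assert bias.n_deposits == 3 * 5
        assert result.cv_series.shape == (5, 3)

    def test_null_bias_reproduces_unbiased_integration(self):
        """Zero Gaussian heights: a walker's trajectory equals plain integration."""
        params = {"n_density": 0.01, "box": (14.0, 14.0, 14.0), "dt": 0.05, "seed": 11}
        system_a = make_scenario("ideal_gas_bath", dict(params))
        system_b = make_scenario("ideal_gas_bath", dict(params))
        bias = BiasPotential(width=0.0005)
        sched = HeightSchedule(h0=1e-300, floor=1e-300, decay_time_ps=1.0)
        ens = WalkerEnsemble(systems=[system_a], bias=bias, interval_ps=2.0, schedule=sched)
        cv = DensityCV(SoftCylinderRegion(3.0, 1.0, 4.0, 1.0), FixedFrame())
        result = run_multiwalker(ens, cv, n_steps=400, record_trajectories=True)
        ref = integrate(system_b, 400, sample_stride=400)
        from poreflux.dynamics import wrap_centered

        final_metad = wrap_centered(result.trajectories[0].positions[-1], system_b.box)
        assert np.allclose(final_metad, ref.positions[-1], atol=1e-10)

    def test_nonfinite_cv_aborts_with_walker_id(self):
        class ExplodingCV:
            def value_and_gradient(self, positions):
                return np.nan, np.zeros_like(positions)

            def reset(self):
                pass

        system = make_scenario("ideal_gas_bath", {"n_density": 0.01, "box": (14.0, 14.0, 14.0), "seed": 0})
        ens = WalkerEnsemble(
            systems=[system], bias=BiasPotential(width=0.0005),
            interval_ps=1.0, schedule=HeightSchedule(),
        )
        with pytest.raises(FloatingPointError, match="walker 0"):
            run_multiwalker(ens, ExplodingCV(), n_steps=100)


class TestFesFromBias:
    def test_time_constant_bias_recovered_exactly(self):
        bias = BiasPotential(width=0.3)
        bias.deposit(1.0, 2.0, t=0.0)
        bias.deposit(-1.0, 1.0, t=0.0)
        grid = np.linspace(-2, 2, 201)
        fes = fes_from_bias(bias, t_total=100.0, t_avg_start=50.0, s_grid=grid)
        u = bias.energy(grid, from_history=True)
        assert np.allclose(fes.values, u.max() - u, atol=1e-12)
        assert np.allclose(fes.err, 0.0, atol=1e-12)
        assert fes.values.min() == 0.0

    def test_empty_averaging_window_rejected(self):
        bias = BiasPotential(width=0.3)
        bias.deposit(0.0, 1.0, t=10.0)
        with pytest.raises(ValueError, match="empty"):
            fes_from_bias(bias, t_total=100.0, t_avg_start=100.0)

    def test_double_well_scalar_cv_recovery(self):
        """Metadynamics on a bare coordinate recovers the double-well free energy.

        Oracle: Boltzmann inversion of a long unbiased ensemble run of the
        same system; agreement within 0.2 kcal/mol RMS.
        """
        h, a = 1.5, 3.0
        dt = 0.02

        def build(seed, n):
            return BrownianSystem(
                positions=np.zeros((n, 3)), species=["ion"] * n, D0={"ion": 0.2},
                dt=dt, seed=seed, potential_terms=[DoubleWellZ(h=h, a=a)],
            )

        systems = [build(100 + w, 1) for w in range(4)]
        bias = BiasPotential(width=0.25)
        sched = HeightSchedule(h0=0.08, floor=0.008, decay_time_ps=1500.0)
        ens = WalkerEnsemble(systems=systems, bias=bias, interval_ps=1.0, schedule=sched)
        result = run_multiwalker(ens, CoordinateCV(particle=0), n_steps=int(4000 / dt))
        grid = np.linspace(-5.5, 5.5, 221)
        fes = fes_from_bias(bias, result.total_time_ps, 1500.0, s_grid=grid)

        unbiased = build(999, 64)
        unbiased.positions[32:, 2] = a
        unbiased.positions[:32, 2] = -a
        traj = integrate(unbiased, 100_000, sample_stride=5)
        zs = traj.positions[traj.times > 100.0, :, 2].ravel()
        hist, edges = np.histogram(zs, bins=np.arange(-5.5, 5.6, 0.25), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = hist > 10.0 / zs.size
        g_ref = -KT * np.log(hist[keep])
        g_met = np.interp(centers[keep], fes.z, fes.values)
        resid = g_met - g_ref
        resid -= resid.mean()
        assert np.sqrt(np.mean(resid**2)) < 0.2

    def test_walker_seed_permutation_leaves_fes_compatible(self):
        """Permuting walker seeds changes nothing but sampling noise (error bands overlap)."""
        h, a = 1.0, 2.5

        def run(seed_order):
            systems = [
                BrownianSystem(
                    positions=np.zeros((1, 3)), species=["ion"], D0={"ion": 0.2},
                    dt=0.02, seed=s, potential_terms=[DoubleWellZ(h=h, a=a)],
                )
                for s in seed_order
            ]
            bias = BiasPotential(width=0.25)
            sched = HeightSchedule(h0=0.08, floor=0.008, decay_time_ps=800.0)
            ens = WalkerEnsemble(systems=systems, bias=bias, interval_ps=1.0, schedule=sched)
            res = run_multiwalker(ens, CoordinateCV(particle=0), n_steps=int(2500 / 0.02))
            grid = np.linspace(-4.0, 4.0, 81)
            return fes_from_bias(bias, res.total_time_ps, 800.0, s_grid=grid)

        f1 = run([7, 8, 9, 10])
        f2 = run([10, 9, 8, 7])
        gap = np.abs(f1.values - f2.values)
        tol = f1.err + f2.err + 0.15  # bands plus residual metadynamics ripple
        assert np.all(gap <= tol)
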