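"""Multiple-walker metadynamics on a scalar collective variable.

Concurrent walkers sample independent configurations while depositing
repulsive Gaussians into one shared bias potential U_b(s) at fixed time
intervals; each walker feels the up-to-date shared bias.  Gaussian
heights follow a schedule that decays geometrically from an initial value
to a small final floor and stays there; after the floor is reached the
bias is quasi-static and the free energy is estimated as the negative
*time average* of the bias over the remaining run,

    F(s) = −⟨U_b(s, t)⟩_{t > t_avg_start} + const   (min F = 0),

with the error band given by the difference between estimates from the
two halves of the averaging window.

The collective variable here is either the soft-cylinder particle density
ρ (see :mod:`poreflux.density`) — bias forces on the particles follow by
the chain rule, F_i = −dU_b/dρ · ∂ρ/∂x_i, and are non-zero only inside
the switching shells — or any other object exposing the same
``value_and_gradient`` interface (e.g. a bare coordinate, used by the
recovery tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .density import SoftCylinderRegion, density_and_gradient, neighbor_list_update
from .dynamics import BrownianSystem, TrajectoryStore, wrap_centered
from .profiles import Profile1D


# ------------------------------------------------------------------ CVs


class DensityCV:
    """Soft-cylinder density ρ as a collective variable.

    Maintains a neighbor list (margin in Å, refreshed every
    ``update_stride`` steps) so that only particles near the region enter
    the density evaluation; with the default margin the refresh contract
    is comfortably satisfied by the step sizes used here.
    """

    def __init__(self, region: SoftCylinderRegion, frame, margin: float = 4.0, update_stride: int = 200):
        self.region = region
        self.frame = frame
        self.margin = margin
        self.update_stride = update_stride
        self._nlist = None
        self._steps_since = 0

    def value_and_gradient(self, positions):
        if self._nlist is None or self._steps_since >= self.update_stride:
            self._nlist = neighbor_list_update(positions, self.region, self.frame, self.margin)
            self._steps_since = 0
        self._steps_since += 1
        res = density_and_gradient(
            positions, self.region, self.frame, neighbor_list=self._nlist, validate=False
        )
        return res.rho, res.gradients

    def reset(self):
        self._nlist = None
        self._steps_since = 0


class CoordinateCV:
    """The z-coordinate of one tagged particle (trivial gradient)."""

    def __init__(self, particle: int = 0, axis: int = 2):
        self.particle = particle
        self.axis = axis

    def value_and_gradient(self, positions):
        grad = np.zeros_like(positions)
        grad[self.particle, self.axis] = 1.0
        return float(positions[self.particle, self.axis]), grad

    def reset(self):
        pass


# ------------------------------------------------------------------ bias


@dataclass
class BiasPotential:
    """Gaussian-deposit history plus a dense-grid accumulation of U_b(s).

    The grid (resolution ``width/5`` by default) gives O(1) evaluation of
    the bias and its derivative regardless of deposit count; bounds expand
    automatically when a deposit lands near an edge.  Heights must be
    non-negative and the Gaussian width is fixed for the run.
    """

    width: float
    grid_resolution: float | None = None
    pad_widths: float = 8.0
    times: list = field(default_factory=list)
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)
    _s0: float = field(default=None, repr=False)
    _u: np.ndarray = field(default=None, repr=False)
    _du: np.ndarray = field(default=None, repr=False)
    _grid: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("Gaussian width must be positive")
        if self.grid_resolution is None:
            self.grid_resolution = self.width / 5.0

    @property
    def n_deposits(self) -> int:
        return len(self.centers)

    def _ensure_grid(self, center: float):
        lo = center - self.pad_widths * self.width
        hi = center + self.pad_widths * self.width
        res = self.grid_resolution
        if self._u is None:
            n = int(np.ceil((hi - lo) / res)) + 1
            self._s0 = lo
            self._u = np.zeros(n)
            self._du = np.zeros(n)
            return
        grid_hi = self._s0 + (self._u.size - 1) * res
        if lo < self._s0:
            extra = int(np.ceil((self._s0 - lo) / res))
            self._s0 -= extra * res
            self._u = np.concatenate((np.zeros(extra), self._u))
            self._du = np.concatenate((np.zeros(extra), self._du))
        if hi > grid_hi:
            extra = int(np.ceil((hi - grid_hi) / res))
            self._u = np.concatenate((self._u, np.zeros(extra)))
            self._du = np.concatenate((self._du, np.zeros(extra)))
        if self._grid is None or self._grid.size != self._u.size:
            self._grid = self._s0 + np.arange(self._u.size) * res

    @property
    def grid(self) -> np.ndarray:
        if self._u is None:
            raise ValueError("no deposits yet")
        if self._grid is None or self._grid.size != self._u.size:
            self._grid = self._s0 + np.arange(self._u.size) * self.grid_resolution
        return self._grid

    def deposit(self, center: float, height: float, t: float = 0.0) -> None:
        """Add one Gaussian of the run's width; superposition is exact."""
        if height < 0:
            raise ValueError("Gaussian height must be >= 0")
        self.times.append(float(t))
        self.centers.append(float(center))
        self.heights.append(float(height))
        self._ensure_grid(center)
        s = self.grid
        d = (s - center) / self.width
        g = height * np.exp(-0.5 * d * d)
        self._u += g
        self._du += g * (-(s - center) / self.width**2)

    def energy(self, s, from_history: bool = False):
        """U_b(s); ``from_history`` sums the Gaussians directly (exact)."""
        if from_history:
            s_arr = np.atleast_1d(np.asarray(s, dtype=float))
            c = np.asarray(self.centers)
            h = np.asarray(self.heights)
            d = (s_arr[:, None] - c[None, :]) / self.width
            out = (h[None, :] * np.exp(-0.5 * d * d)).sum(axis=1)
            return float(out[0]) if np.isscalar(s) else out
        if self._u is None:
            return 0.0 if np.isscalar(s) else np.zeros_like(np.asarray(s, dtype=float))
        return np.interp(s, self.grid, self._u)

    def derivative(self, s):
        """dU_b/ds, linearly interpolated from the accumulated grid."""
        if self._du is None:
            return 0.0 if np.isscalar(s) else np.zeros_like(np.asarray(s, dtype=float))
        return np.interp(s, self.grid, self._du)

    def history_arrays(self):
        return (np.asarray(self.times), np.asarray(self.centers), np.asarray(self.heights))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# metadynamics deposit log: width={self.width}\n")
            fh.write("# time_ps\tcenter\theight_kcal_mol\n")
            for t, c, h in zip(self.times, self.centers, self.heights):
                fh.write(f"{t:.10g}\t{c:.10g}\t{h:.10g}\n")

    @classmethod
    def read_tsv(cls, path) -> "BiasPotential":
        width = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# metadynamics deposit log:"):
                    width = float(line.split("width=")[1])
                elif line and not line.startswith("#"):
                    rows.append([float(x) for x in line.split("\t")])
        bias = cls(width=width)
        for t, c, h in rows:
            bias.deposit(c, h, t)
        return bias


def deposit(bias: BiasPotential, center: float, height: float, t: float = 0.0) -> BiasPotential:
    """Functional wrapper around :meth:`BiasPotential.deposit`."""
    bias.deposit(center, height, t)
    return bias


def bias_forces(bias: BiasPotential, density_result) -> np.ndarray:
    """Chain-rule bias forces F_i = −dU_b/dρ(ρ) · ∂ρ/∂x_i."""
    dudr = bias.derivative(density_result.rho)
    return -dudr * density_result.gradients


# ----------------------------------------------------------------- schedule


@dataclass
class HeightSchedule:
    """Gaussian height vs time: geometric decay from h0 to a floor.

    h(t) = max(floor, h0·(floor/h0)^(t/decay_time_ps)) — monotone
    non-increasing, reaching the floor exactly at ``decay_time_ps`` and
    holding it afterwards.
    """

    h0: float = 0.035
    floor: float = 0.0035
    decay_time_ps: float = 4000.0

    def __post_init__(self):
        if self.floor > self.h0:
            raise ValueError("final height must not exceed the initial height")
        if self.floor <= 0 or self.decay_time_ps <= 0:
            raise ValueError("floor and decay time must be positive")

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValueError("t must be >= 0")
        if t >= self.decay_time_ps:
            return self.floor
        return max(self.floor, self.h0 * (self.floor / self.h0) ** (t / self.decay_time_ps))


def height_schedule(t: float, params: HeightSchedule | dict) -> float:
    """Evaluate the Gaussian-height schedule at time ``t`` (ps)."""
    sched = params if isinstance(params, HeightSchedule) else HeightSchedule(**params)
    return sched(t)


# ------------------------------------------------------------------ walkers


@dataclass
class WalkerEnsemble:
    """Concurrent walkers sharing one bias potential.

    Per-walker seeds are derived as ``seed + walker_index`` from the first
    system's seed unless the systems already carry distinct seeds.
    """

    systems: list
    bias: BiasPotential
    interval_ps: float = 4.0
    schedule: HeightSchedule = field(default_factory=HeightSchedule)

    def __post_init__(self):
        if not self.systems:
            raise ValueError("need at least one walker")
        dts = {s.dt for s in self.systems}
        temps = {s.temperature for s in self.systems}
        if len(dts) != 1 or len(temps) != 1:
            raise ValueError("walkers must share dt and temperature")
        if self.interval_ps <= 0:
            raise ValueError("deposit interval must be positive")
        seeds = [s.seed for s in self.systems]
        if len(set(seeds)) != len(seeds):
            base = self.systems[0].seed
            for i, s in enumerate(self.systems):
                s.seed = base + i

    @property
    def n_walkers(self) -> int:
        return len(self.systems)


@dataclass
class MetadResult:
    """Outcome of a multiple-walker run."""

    bias: BiasPotential
    cv_times: np.ndarray          # deposit boundaries (ps)
    cv_series: np.ndarray         # (n_deposit_rounds, n_walkers)
    trajectories: list            # sparse TrajectoryStore per walker
    total_time_ps: float


class GrandCanonicalBath:
    """Exact grand-canonical moves for a non-interacting (ideal-gas) bath.

    Every ``period_ps`` the particle count outside a cylindrical safe zone
    around the CV region is redrawn from its exact Poisson marginal
    (intensity n_bulk), with uniform insertions/deletions restricted to
    the outside zone.  For an ideal gas this move leaves the
    grand-canonical stationary distribution invariant exactly: at
    equilibrium the outside configuration is an independent uniform
    Poisson process, and the zone boundary is far enough from the
    switching shells that the density CV is untouched at the instant of
    the move.  Combined with diffusion, the bath then exchanges particles
    with an effectively infinite reservoir, so sub-volume occupancy
    statistics are truly Poisson rather than binomial in a fixed count.
    """

    def __init__(self, region: SoftCylinderRegion, box, n_bulk: float, margin: float = 6.0, period_ps: float = 50.0):
        self.box = np.asarray(box, dtype=float)
        self.n_bulk = n_bulk
        self.period_ps = period_ps
        self.safe_r = region.outer_radius + margin
        self.safe_z = region.outer_half_length + margin
        if 2 * self.safe_r > min(self.box[0], self.box[1]) or 2 * self.safe_z > self.box[2]:
            raise ValueError("safe zone does not fit inside the periodic box")
        v_safe = np.pi * self.safe_r**2 * 2 * self.safe_z
        self.v_out = float(np.prod(self.box)) - v_safe
        self._out_fraction = self.v_out / float(np.prod(self.box))

    def _outside(self, positions):
        r = np.hypot(positions[:, 0], positions[:, 1])
        return (r > self.safe_r) | (np.abs(positions[:, 2]) > self.safe_z)

    def resample(self, positions: np.ndarray, rng) -> np.ndarray:
        outside = self._outside(positions)
        n_now = int(outside.sum())
        n_new = int(rng.poisson(self.n_bulk * self.v_out))
        if n_new < n_now:
            drop = rng.choice(np.nonzero(outside)[0], size=n_now - n_new, replace=False)
            return np.delete(positions, drop, axis=0)
        if n_new > n_now:
            need = n_new - n_now
            new_pts = []
            while len(new_pts) < need:
                batch = (rng.random((max(8, int(2 * need / self._out_fraction)), 3)) - 0.5) * self.box
                batch = batch[self._outside(batch)]
                new_pts.extend(batch[: need - len(new_pts)])
            return np.vstack([positions, np.asarray(new_pts)])
        return positions


@dataclass(frozen=True)
class CVWalls:
    """Harmonic walls confining the collective variable to [lo, hi].

    U_wall = (k/2)·(s − lo)² below lo and (k/2)·(s − hi)² above hi; zero in
    between, so the free-energy profile between the walls is unaffected.
    Standard practice for keeping walkers inside the range of interest.
    """

    lo: float
    hi: float
    k: float

    def derivative(self, s: float) -> float:
        if s < self.lo:
            return self.k * (s - self.lo)
        if s > self.hi:
            return self.k * (s - self.hi)
        return 0.0


def run_multiwalker(
    ensemble: WalkerEnsemble,
    cv,
    n_steps: int,
    sample_stride: int | None = None,
    record_trajectories: bool = False,
    cv_walls: CVWalls | None = None,
    gc_bath: GrandCanonicalBath | None = None,
) -> MetadResult:
    """Advance all walkers for ``n_steps`` steps each, depositing at intervals.

    Within each deposit interval the walkers advance sequentially (each
    with its own RNG seeded from its system seed); at the interval
    boundary every walker deposits one Gaussian — serialized in walker
    order — into the shared bias, whose updated state all walkers feel in
    the next interval.  The CV of every walker is recorded at each
    boundary.  A non-finite CV aborts with the walker id.  Optional
    harmonic walls on the CV keep the walkers inside the range of
    interest without affecting the free energy in between.
    """
    dt = ensemble.systems[0].dt
    steps_per_interval = max(1, int(round(ensemble.interval_ps / dt)))
    n_rounds = n_steps // steps_per_interval
    if n_rounds < 1:
        raise ValueError("run too short for a single deposit interval")
    if gc_bath is not None:
        if record_trajectories:
            raise ValueError("trajectory recording is not supported with a grand-canonical bath")
        for s in ensemble.systems:
            if np.unique(s.per_particle_D()).size != 1:
                raise ValueError("grand-canonical bath requires a single diffusion constant")
        gc_stride = max(1, int(round(gc_bath.period_ps / ensemble.interval_ps)))
    rngs = [np.random.default_rng(s.seed) for s in ensemble.systems]
    positions = [s.positions.copy() for s in ensemble.systems]

    def _consts(system, n):
        base = system.per_particle_D()
        D = base if n == base.size else np.full(n, float(base[0]))
        return (D / system.kbt * dt)[:, None], np.sqrt(2.0 * D * dt)[:, None]

    consts = [_consts(s, s.n_particles) for s in ensemble.systems]
    if sample_stride is None:
        sample_stride = steps_per_interval
    frames = [[p.copy()] for p in positions] if record_trajectories else None
    frame_times = [0.0]

    cv_series = np.empty((n_rounds, ensemble.n_walkers))
    cv_times = np.empty(n_rounds)
    cvs = [cv] + [_clone_cv(cv) for _ in range(ensemble.n_walkers - 1)]
    step_count = 0
    for rnd in range(n_rounds):
        if gc_bath is not None and rnd > 0 and rnd % gc_stride == 0:
            for w, system in enumerate(ensemble.systems):
                positions[w] = gc_bath.resample(positions[w], rngs[w])
                consts[w] = _consts(system, positions[w].shape[0])
                cvs[w].reset()
        for w, system in enumerate(ensemble.systems):
            pos = positions[w]
            drift, namp = consts[w]
            noise = rngs[w].standard_normal((steps_per_interval, *pos.shape))
            bare_bath = not system.potential_terms
            for k in range(steps_per_interval):
                rho, grad = cvs[w].value_and_gradient(pos)
                if not np.isfinite(rho):
                    raise FloatingPointError(f"walker {w}: non-finite CV at round {rnd}")
                dudr = ensemble.bias.derivative(rho)
                if cv_walls is not None:
                    dudr += cv_walls.derivative(rho)
                if bare_bath:
                    pos += (-dudr * drift) * grad + namp * noise[k]
                else:
                    forces = -dudr * grad
                    for term in system.potential_terms:
                        _, f = term.energy_and_forces(pos)
                        forces += f
                    pos += drift * forces + namp * noise[k]
                # periodic wrapping is needed only to keep coordinates bounded;
                # the region sits at the box center, so wrapping lazily (in sync
                # with the neighbor-list stride) is exact for the density
                if system.box is not None and (k + 1) % 50 == 0:
                    pos[:] = wrap_centered(pos, system.box)
                if record_trajectories and (step_count + k + 1) % sample_stride == 0:
                    frames[w].append(pos.copy())
                    if w == 0:
                        frame_times.append((step_count + k + 1) * dt)
            if system.box is not None:
                pos[:] = wrap_centered(pos, system.box)
            cv_series[rnd, w], _ = cvs[w].value_and_gradient(pos)
        step_count += steps_per_interval
        t = step_count * dt
        h = ensemble.schedule(t)
        for w in range(ensemble.n_walkers):
            ensemble.bias.deposit(cv_series[rnd, w], h, t)
        cv_times[rnd] = t

    trajs = []
    if record_trajectories:
        for w, system in enumerate(ensemble.systems):
            trajs.append(
                TrajectoryStore(
                    times=np.asarray(frame_times[: len(frames[w])]),
                    positions=np.asarray(frames[w]),
                    species=list(system.species),
                    metadata={"walker": w, "seed": system.seed},
                )
            )
    return MetadResult(
        bias=ensemble.bias, cv_times=cv_times, cv_series=cv_series,
        trajectories=trajs, total_time_ps=step_count * dt,
    )


def _clone_cv(cv):
    if isinstance(cv, DensityCV):
        return DensityCV(cv.region, cv.frame, cv.margin, cv.update_stride)
    if isinstance(cv, CoordinateCV):
        return CoordinateCV(cv.particle, cv.axis)
    import copy

    return copy.deepcopy(cv)


# -------------------------------------------------------------------- FES


def fes_from_bias(
    bias: BiasPotential,
    t_total: float,
    t_avg_start: float,
    s_grid: np.ndarray | None = None,
) -> Profile1D:
    """Free energy from the time-averaged bias, with a half-split error band.

    The time average over [t_avg_start, t_total] is computed exactly from
    the deposit history: a deposit made at t_i contributes to U_b for all
    t ≥ t_i, so its weight in the average is the overlap fraction
    (t_total − max(t_i, t_avg_start)) / (t_total − t_avg_start).
    F = −⟨U_b⟩ shifted so min F = 0; the error band is |F₁ − F₂| from the
    two halves of the averaging window.
    """
    times, centers, heights = bias.history_arrays()
    if times.size == 0:
        raise ValueError("bias has no deposits")
    if not (0 <= t_avg_start < t_total):
        raise ValueError("averaging window is empty: t_avg_start must lie within the run")
    if s_grid is None:
        s_grid = bias.grid
    t_mid = 0.5 * (t_avg_start + t_total)

    def averaged_F(t0, t1):
        w = np.clip((t1 - np.maximum(times, t0)) / (t1 - t0), 0.0, 1.0)
        u = _gaussian_sum(s_grid, centers, heights * w, bias.width)
        return u.max() - u

    f_full = averaged_F(t_avg_start, t_total)
    f1 = averaged_F(t_avg_start, t_mid)
    f2 = averaged_F(t_mid, t_total)
    return Profile1D(
        s_grid, f_full, err=np.abs(f1 - f2), units=("A^-3", "kcal_mol"),
        meta={"t_avg_start": t_avg_start, "t_total": t_total},
    )


def _gaussian_sum(s, centers, heights, width, chunk: int = 2000):
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for i in range(0, centers.size, chunk):
        d = (s[:, None] - centers[None, i : i + chunk]) / width
        out += (heights[None, i : i + chunk] * np.exp(-0.5 * d * d)).sum(axis=1)
    return out
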