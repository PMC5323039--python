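"""Overdamped Langevin (Brownian) dynamics with composable potential terms.

The integrator is first-order Euler–Maruyama,

    x ← x + (D₀/k_BT)·F·dt + √(2·D₀·dt)·η,   η ~ N(0, 1),

whose stationary distribution over long runs is the Boltzmann weight of
the supplied potential.  This is the minimal stochastic process with the
statistics assumed by the free-energy and diffusion estimators in this
package; no inertia, solvent forces or pair interactions are modelled.

Units: Å, ps, kcal/mol, K.  Every potential term returns the exact
negative gradient of its energy, which is verified by the test suite via
central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import kbt
from . import density as _density


# ----------------------------------------------------------- potential terms


class PotentialTerm:
    """Base class: maps positions (N,3) → (energy, forces (N,3))."""

    #: restraint terms are excluded from the systematic-force samples
    #: fed to the ABF estimator
    is_restraint = False

    def energy_and_forces(self, positions: np.ndarray):  # pragma: no cover
        raise NotImplementedError


def _select(indices, n):
    return np.arange(n) if indices is None else np.asarray(indices, dtype=int)


@dataclass
class HarmonicWell(PotentialTerm):
    """U = (k/2)·Σ_axes (x − center)² applied to selected particles/axes."""

    k: float
    center: tuple = (0.0, 0.0, 0.0)
    indices: np.ndarray | None = None
    axes: tuple = (0, 1, 2)

    def energy_and_forces(self, positions):
        n = positions.shape[0]
        idx = _select(self.indices, n)
        axes = list(self.axes)
        d = positions[np.ix_(idx, axes)] - np.asarray(self.center)[axes]
        energy = 0.5 * self.k * float(np.sum(d * d))
        forces = np.zeros_like(positions)
        forces[np.ix_(idx, axes)] = -self.k * d
        return energy, forces


@dataclass
class PerParticleHarmonicZ(PotentialTerm):
    """Independent harmonic wells in z, one center (and spring) per particle."""

    k: np.ndarray
    centers_z: np.ndarray

    def energy_and_forces(self, positions):
        k = np.asarray(self.k, dtype=float)
        dz = positions[:, 2] - np.asarray(self.centers_z, dtype=float)
        energy = 0.5 * float(np.sum(k * dz * dz))
        forces = np.zeros_like(positions)
        forces[:, 2] = -k * dz
        return energy, forces


@dataclass
class DoubleWellZ(PotentialTerm):
    """Symmetric double well U(z) = h·[(z/a)² − 1]² on selected particles."""

    h: float = 3.0
    a: float = 5.0
    indices: np.ndarray | None = None

    def energy_z(self, z):
        return self.h * ((z / self.a) ** 2 - 1.0) ** 2

    def force_z(self, z):
        return -4.0 * self.h * z * ((z / self.a) ** 2 - 1.0) / self.a**2

    def energy_and_forces(self, positions):
        n = positions.shape[0]
        idx = _select(self.indices, n)
        z = positions[idx, 2]
        energy = float(np.sum(self.energy_z(z)))
        forces = np.zeros_like(positions)
        forces[idx, 2] = self.force_z(z)
        return energy, forces


def flat_bottom_cylinder_force(position, axis_frame, radius: float, half_length: float, k: float):
    """Restoring force of a flat-bottom cylindrical restraint at one point.

    Zero strictly inside the cylinder; harmonic on the radial/axial excess
    beyond the boundary, directed back toward the allowed volume.
    """
    if radius <= 0 or half_length <= 0:
        raise ValueError("radius and half_length must be positive")
    if k < 0:
        raise ValueError("force constant k must be >= 0")
    origin, axis = axis_frame.origin_axis(np.atleast_2d(position))
    d = np.asarray(position, dtype=float) - origin
    z = float(d @ axis)
    perp = d - z * axis
    r = float(np.linalg.norm(perp))
    force = np.zeros(3)
    if r > radius:
        force -= k * (r - radius) * perp / r
    if abs(z) > half_length:
        force -= k * (abs(z) - half_length) * np.sign(z) * axis
    return force


@dataclass
class FlatBottomCylinder(PotentialTerm):
    """Flat-bottom cylindrical confinement (harmonic beyond the boundary)."""

    radius: float
    half_length: float
    k: float = 10.0
    frame: object = field(default_factory=_density.FixedFrame)
    indices: np.ndarray | None = None
    is_restraint = True

    def energy_and_forces(self, positions):
        n = positions.shape[0]
        idx = _select(self.indices, n)
        origin, axis = self.frame.origin_axis(positions)
        d = positions[idx] - origin
        z = d @ axis
        perp = d - z[:, None] * axis
        r = np.linalg.norm(perp, axis=1)
        dr = np.maximum(r - self.radius, 0.0)
        dz = np.maximum(np.abs(z) - self.half_length, 0.0)
        energy = 0.5 * self.k * float(np.sum(dr * dr + dz * dz))
        forces = np.zeros_like(positions)
        rhat = perp * ((r > 1e-12) / np.maximum(r, 1e-300))[:, None]
        forces[idx] = -self.k * (dr[:, None] * rhat + (dz * np.sign(z))[:, None] * axis)
        return energy, forces


@dataclass
class FlatBottomZSlab(PotentialTerm):
    """Flat-bottom axial confinement |z − center| ≤ half_length (a 'disk').

    Used for the diffusion-window protocol; per-particle centers allowed.
    """

    half_length: float
    centers_z: np.ndarray
    k: float = 10.0
    is_restraint = True

    def energy_and_forces(self, positions):
        dz = positions[:, 2] - np.asarray(self.centers_z, dtype=float)
        excess = np.sign(dz) * np.maximum(np.abs(dz) - self.half_length, 0.0)
        energy = 0.5 * self.k * float(np.sum(excess * excess))
        forces = np.zeros_like(positions)
        forces[:, 2] = -self.k * excess
        return energy, forces


@dataclass
class RegionWell(PotentialTerm):
    """Smooth square well U_i = −depth_i·ξ(x_i) over a soft cylinder region.

    ``depth`` is per-particle (kcal/mol; positive = attractive).  Because ξ
    is exactly 1 on the inner plateau and 0 outside the outer boundary, the
    equilibrium in-region/bulk density ratio of a non-interacting species is
    exactly exp(depth/k_BT).
    """

    region: _density.SoftCylinderRegion
    depth: np.ndarray
    frame: object = field(default_factory=_density.FixedFrame)

    def energy_and_forces(self, positions):
        res = _density.density_and_gradient(positions, self.region, self.frame)
        depth = np.asarray(self.depth, dtype=float)
        energy = -float(np.sum(depth * res.weights))
        # res.gradients is ∂(ξ_i/V)/∂x_i; multiply back by V for ∂ξ_i/∂x_i
        forces = depth[:, None] * res.gradients * res.volume
        return energy, forces


# ------------------------------------------------------------------- system


@dataclass
class BrownianSystem:
    """State and parameters of an overdamped Langevin simulation.

    ``D0`` maps species label → diffusion constant (Å²/ps); a per-particle
    array is also accepted.  ``box``, if given, applies periodic wrapping to
    the centered box [−L/2, L/2) in each dimension.
    """

    positions: np.ndarray
    species: list
    D0: dict | np.ndarray
    temperature: float = 298.0
    dt: float = 0.01
    seed: int = 0
    potential_terms: list = field(default_factory=list)
    box: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.array(self.positions, dtype=float).reshape(-1, 3)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.species) != self.positions.shape[0]:
            raise ValueError("one species label per particle required")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        d = self.per_particle_D()
        if np.any(d <= 0):
            raise ValueError("D0 must be positive for every species")

    def per_particle_D(self) -> np.ndarray:
        if isinstance(self.D0, dict):
            try:
                return np.array([self.D0[s] for s in self.species], dtype=float)
            except KeyError as exc:
                raise ValueError(f"no D0 given for species {exc}") from None
        arr = np.asarray(self.D0, dtype=float)
        if arr.ndim == 0:
            return np.full(len(self.species), float(arr))
        if arr.shape[0] != len(self.species):
            raise ValueError("per-particle D0 array has wrong length")
        return arr

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)

    def total_energy_and_forces(self, positions=None):
        pos = self.positions if positions is None else positions
        energy = 0.0
        forces = np.zeros_like(pos)
        for term in self.potential_terms:
            e, f = term.energy_and_forces(pos)
            energy += e
            forces += f
        return energy, forces


@dataclass
class TrajectoryStore:
    """Frames of a Brownian run: times (ps), positions (F,N,3), species."""

    times: np.ndarray
    positions: np.ndarray
    species: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (frames, particles, 3)")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("one time per frame required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def z_series(self, particle: int = 0) -> np.ndarray:
        return self.positions[:, particle, 2]

    def write_tsv(self, path, sidecar: bool = True) -> None:
        """Write frames as TSV; metadata goes to a JSON sidecar (<path>.meta.json)."""
        with open(path, "w") as fh:
            fh.write("# time_ps\tparticle_id\tspecies\tx\ty\tz\n")
            for f in range(self.n_frames):
                t = self.times[f]
                for i in range(self.n_particles):
                    x, y, z = self.positions[f, i]
                    fh.write(f"{t:.6g}\t{i}\t{self.species[i]}\t{x:.8g}\t{y:.8g}\t{z:.8g}\n")
        if sidecar and self.metadata:
            import json

            with open(f"{path}.meta.json", "w") as fh:
                json.dump({k: _jsonable(v) for k, v in self.metadata.items()}, fh, indent=2)

    @classmethod
    def read_tsv(cls, path) -> "TrajectoryStore":
        import pandas as pd

        df = pd.read_csv(
            path, sep="\t", comment="#",
            names=["time_ps", "particle_id", "species", "x", "y", "z"],
        )
        times = np.sort(df["time_ps"].unique())
        n = df["particle_id"].nunique()
        pos = np.empty((times.size, n, 3))
        species = [None] * n
        for f, t in enumerate(times):
            sub = df[df["time_ps"] == t].sort_values("particle_id")
            pos[f] = sub[["x", "y", "z"]].to_numpy()
            if f == 0:
                species = sub["species"].tolist()
        return cls(times=times, positions=pos, species=species)

    def write_xyz(self, path) -> None:
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{self.n_particles}\nt={self.times[f]:.6g} ps\n")
                for i in range(self.n_particles):
                    x, y, z = self.positions[f, i]
                    fh.write(f"{self.species[i]} {x:.8g} {y:.8g} {z:.8g}\n")


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


# ---------------------------------------------------------------- integrator


def wrap_centered(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap into the centered periodic box [−L/2, L/2)."""
    return (positions + box / 2) % box - box / 2


def integrate(system: BrownianSystem, n_steps: int, sample_stride: int = 1) -> TrajectoryStore:
    """Run Euler–Maruyama for ``n_steps`` steps and record frames.

    With ``sample_stride=1`` the trajectory holds n_steps+1 frames
    (including the initial configuration).  The system itself is not
    mutated; identical (seed, config) gives a bit-identical trajectory.
    Non-finite energies or forces abort with the step and particle index.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(system.seed)
    pos = system.positions.copy()
    D = system.per_particle_D()
    beta = 1.0 / system.kbt
    drift = (beta * D * system.dt)[:, None]
    noise_amp = np.sqrt(2.0 * D * system.dt)[:, None]

    e0, _ = system.total_energy_and_forces(pos)
    if not np.isfinite(e0):
        raise FloatingPointError("non-finite energy at the initial configuration")

    n_frames = n_steps // sample_stride + 1
    frames = np.empty((n_frames, pos.shape[0], 3))
    times = np.empty(n_frames)
    frames[0] = pos
    times[0] = 0.0
    fi = 1
    for step in range(1, n_steps + 1):
        _, forces = system.total_energy_and_forces(pos)
        if not np.all(np.isfinite(forces)):
            bad = int(np.argwhere(~np.isfinite(forces))[0][0])
            raise FloatingPointError(f"non-finite force at step {step}, particle {bad}")
        pos = pos + drift * forces + noise_amp * rng.standard_normal(pos.shape)
        if system.box is not None:
            pos = wrap_centered(pos, system.box)
        if step % sample_stride == 0:
            frames[fi] = pos
            times[fi] = step * system.dt
            fi += 1
    meta = dict(system.metadata)
    meta.update(seed=system.seed, dt=system.dt, n_steps=n_steps, sample_stride=sample_stride)
    return TrajectoryStore(times=times[:fi], positions=frames[:fi], species=list(system.species), metadata=meta)
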