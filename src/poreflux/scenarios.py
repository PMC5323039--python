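"""Scenario factories: ready-to-integrate systems for each estimator.

Each scenario emulates the statistical structure one estimator assumes:

``ou_window``
    Particles in harmonic z-wells (Ornstein–Uhlenbeck processes) — the
    analytic oracle for the position-dependent diffusion estimator.  One
    particle per window center; per-window D₀ supported.
``double_well_permeation``
    A single tagged ion in a symmetric double well along z under
    flat-bottom cylindrical confinement — the ABF test system.
``ideal_gas_bath``
    Non-interacting particles in a periodic box; the occupancy of any
    sub-volume is (near-)Poisson, giving an analytic hydration free
    energy for the density metadynamics.
``two_species_pore``
    Two non-interacting species, one of which feels a smooth attractive
    well inside a soft-cylinder 'pore' — the lipid/water pore-invasion toy
    with an exactly Boltzmann in-pore enrichment.
"""

from __future__ import annotations

import numpy as np

from .constants import kbt
from .density import SoftCylinderRegion, FixedFrame, effective_volume
from .dynamics import (
    BrownianSystem,
    DoubleWellZ,
    FlatBottomCylinder,
    PerParticleHarmonicZ,
    RegionWell,
)

SCENARIO_NAMES = ("ou_window", "double_well_permeation", "ideal_gas_bath", "two_species_pore")


def make_scenario(name: str, params: dict) -> BrownianSystem:
    """Build one of the named scenarios; parameters are echoed in metadata."""
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    builder = {
        "ou_window": _ou_window,
        "double_well_permeation": _double_well,
        "ideal_gas_bath": _ideal_gas_bath,
        "two_species_pore": _two_species_pore,
    }[name]
    system = builder(dict(params))
    system.metadata.setdefault("scenario", name)
    system.metadata.setdefault("params", dict(params))
    return system


def _ou_window(p: dict) -> BrownianSystem:
    k = float(p.pop("k", 1.0))
    D0 = p.pop("D0", 0.2)
    T = float(p.pop("temperature", 298.0))
    dt = float(p.pop("dt", 0.01))
    seed = int(p.pop("seed", 0))
    centers = np.atleast_1d(np.asarray(p.pop("centers", [0.0]), dtype=float))
    _reject_unknown(p, "ou_window")
    if k <= 0:
        raise ValueError("spring constant k must be positive")
    n = centers.size
    D = np.atleast_1d(np.asarray(D0, dtype=float))
    if D.size == 1:
        D = np.full(n, float(D[0]))
    if D.size != n:
        raise ValueError("D0 must be scalar or one value per window center")
    if np.any(D <= 0):
        raise ValueError("D0 must be positive")
    pos = np.zeros((n, 3))
    pos[:, 2] = centers
    term = PerParticleHarmonicZ(k=np.full(n, k), centers_z=centers)
    # analytic OU parameters for each window: var = k_BT/k, tau = k_BT/(D0 k)
    meta = {
        "ou_var": kbt(T) / k,
        "ou_tau": (kbt(T) / (D * k)).tolist(),
        "centers": centers.tolist(),
    }
    return BrownianSystem(
        positions=pos, species=["ion"] * n, D0=D, temperature=T, dt=dt,
        seed=seed, potential_terms=[term], metadata=meta,
    )


def _double_well(p: dict) -> BrownianSystem:
    h = float(p.pop("h", 3.0))
    a = float(p.pop("a", 5.0))
    D0 = float(p.pop("D0", 0.2))
    T = float(p.pop("temperature", 298.0))
    dt = float(p.pop("dt", 0.02))
    seed = int(p.pop("seed", 0))
    radius = float(p.pop("radius", 8.0))
    half_length = float(p.pop("half_length", 50.0))
    k_restraint = float(p.pop("k_restraint", 10.0))
    start_side = p.pop("start_side", "negative")
    n_replicas = int(p.pop("n_replicas", 1))
    _reject_unknown(p, "double_well_permeation")
    if D0 <= 0 or n_replicas < 1:
        raise ValueError("need positive D0 and at least one replica")
    z0 = -a if start_side == "negative" else a
    pos = np.zeros((n_replicas, 3))
    pos[:, 2] = z0
    terms = [
        DoubleWellZ(h=h, a=a),
        FlatBottomCylinder(radius=radius, half_length=half_length, k=k_restraint),
    ]
    meta = {"h": h, "a": a, "start_side": start_side, "barrier_kcal_mol": h}
    return BrownianSystem(
        positions=pos, species=["ion"] * n_replicas, D0={"ion": D0}, temperature=T,
        dt=dt, seed=seed, potential_terms=terms, metadata=meta,
    )


def _ideal_gas_bath(p: dict) -> BrownianSystem:
    n_density = float(p.pop("n_density", 0.0334))
    box = np.asarray(p.pop("box", (30.0, 30.0, 30.0)), dtype=float)
    D0 = float(p.pop("D0", 0.2))
    T = float(p.pop("temperature", 298.0))
    dt = float(p.pop("dt", 0.02))
    seed = int(p.pop("seed", 0))
    poisson_count = bool(p.pop("poisson_count", False))
    _reject_unknown(p, "ideal_gas_bath")
    if n_density <= 0 or D0 <= 0:
        raise ValueError("number density and D0 must be positive")
    volume = float(np.prod(box))
    rng = np.random.default_rng(seed)
    if poisson_count:
        # grand-canonical emulation: the particle count itself is Poisson,
        # so the occupancy of any sub-volume is exactly Poisson (thinning)
        n = int(rng.poisson(n_density * volume))
    else:
        n = int(round(n_density * volume))
    if n < 1:
        raise ValueError("box too small: zero particles")
    pos = (rng.random((n, 3)) - 0.5) * box
    meta = {"n_density": n_density, "n_particles": n, "box_volume_A3": volume}
    return BrownianSystem(
        positions=pos, species=["W"] * n, D0={"W": D0}, temperature=T, dt=dt,
        seed=seed, potential_terms=[], box=box, metadata=meta,
    )


def _two_species_pore(p: dict) -> BrownianSystem:
    region = p.pop("region", None) or SoftCylinderRegion(
        R=float(p.pop("R", 4.0)), dR=float(p.pop("dR", 2.0)),
        Z=float(p.pop("Z", 6.0)), dZ=float(p.pop("dZ", 2.0)),
    )
    box = np.asarray(p.pop("box", (20.0, 20.0, 24.0)), dtype=float)
    densities = dict(p.pop("densities", {"W": 0.01, "L": 0.01}))
    depths = dict(p.pop("well_depth", {"W": 0.0, "L": 2.0}))
    D0 = dict(p.pop("D0", {"W": 0.2, "L": 0.2}))
    T = float(p.pop("temperature", 298.0))
    dt = float(p.pop("dt", 0.02))
    seed = int(p.pop("seed", 0))
    _reject_unknown(p, "two_species_pore")
    volume = float(np.prod(box))
    if region.outer_radius * 2 >= min(box[0], box[1]) or region.outer_half_length * 2 >= box[2]:
        raise ValueError("pore region must fit inside the periodic box")
    rng = np.random.default_rng(seed)
    positions, species, depth_list = [], [], []
    for label in sorted(densities):
        n_s = int(round(densities[label] * volume))
        if n_s < 1:
            raise ValueError(f"box too small: zero particles of species {label}")
        positions.append((rng.random((n_s, 3)) - 0.5) * box)
        species += [label] * n_s
        depth_list += [float(depths.get(label, 0.0))] * n_s
    pos = np.vstack(positions)
    frame = FixedFrame()
    term = RegionWell(region=region, depth=np.asarray(depth_list), frame=frame)
    meta = {
        "region": (region.R, region.dR, region.Z, region.dZ),
        "well_depth": depths,
        "densities": densities,
        "inner_volume_A3": float(np.pi * (region.R - region.dR / 2) ** 2 * 2 * (region.Z - region.dZ / 2)),
        "effective_volume_A3": effective_volume(region),
    }
    return BrownianSystem(
        positions=pos, species=species, D0=D0, temperature=T, dt=dt, seed=seed,
        potential_terms=[term], box=box, metadata=meta,
    )


def _reject_unknown(p: dict, name: str) -> None:
    if p:
        raise ValueError(f"unknown parameters for scenario {name!r}: {sorted(p)}")
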