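"""End-to-end validation studies with analytic oracles.

Each function runs one complete study — synthetic data generation,
sampling, estimation — and returns a dict of measured quantities next to
their analytic expectations.  The studies dimension every estimator in
the package against a case with a known answer:

* geometry: effective cross-sections of the 8 Å and 14 Å confinement
  cylinders (π r²);
* density CV: analytic gradients vs central finite differences, closed-
  form effective volume vs Monte-Carlo integration, switching-function
  boundary values;
* metadynamics: hydration free energy of an ideal-gas bath vs the Poisson
  counting free energy −k_BT·ln(λᴺe^{−λ}/N!);
* ABF: double-well PMF vs the generating potential and vs Boltzmann
  inversion of unbiased sampling;
* diffusion: var/τ estimates on Ornstein–Uhlenbeck windows vs the exact
  D₀;
* conductance: flat-profile closed form, SI unit round-trip, Boltzmann
  barrier scaling;
* two-species pore: in-pore enrichment vs exp(Δε/k_BT).

The default problem sizes are chosen to resolve each oracle within its
stated tolerance on a single CPU core in minutes; they are deliberately
far smaller than the hundreds-of-nanosecond all-atom calculations the
methods originate from.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import gammaln

from . import abf as _abf
from . import diffusion as _diff
from . import metad as _metad
from .conductance import ConductanceParams, conductance, effective_cross_section
from .constants import kbt
from .density import (
    FixedFrame,
    SoftCylinderRegion,
    density_and_gradient,
    effective_volume,
    switch_value,
)
from .dynamics import integrate
from .profiles import Profile1D
from .scenarios import make_scenario


# --------------------------------------------------------------- geometry


def cross_section_areas() -> dict:
    """Effective cross-sections S = π r² of the two confinement radii."""
    return {
        "area_c10_A2": effective_cross_section(8.0),
        "area_c13_A2": effective_cross_section(14.0),
    }


# --------------------------------------------------------------- density CV


def density_cv_checks(seed: int = 0, n_particles: int = 50, mc_samples: int = 10_000_000) -> dict:
    """Gradient/volume/switching correctness measures for the density CV."""
    region = SoftCylinderRegion(R=4.0, dR=2.0, Z=6.0, dZ=2.0)
    frame = FixedFrame()
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-8.0, 8.0, (n_particles, 3))
    res = density_and_gradient(pos, region, frame)
    h = 1e-4
    max_rel = 0.0
    for i in range(n_particles):
        for ax in range(3):
            pp = pos.copy()
            pp[i, ax] += h
            pm = pos.copy()
            pm[i, ax] -= h
            fd = (
                density_and_gradient(pp, region, frame).rho
                - density_and_gradient(pm, region, frame).rho
            ) / (2 * h)
            an = res.gradients[i, ax]
            if abs(fd) > 1e-12 or abs(an) > 1e-12:
                max_rel = max(max_rel, abs(fd - an) / max(abs(fd), abs(an)))

    # Monte-Carlo integration of xi over the outer bounding box
    br, bz = region.outer_radius, region.outer_half_length
    total = 0.0
    chunk = 1_000_000
    done = 0
    while done < mc_samples:
        m = min(chunk, mc_samples - done)
        pts = rng.uniform([-br, -br, -bz], [br, br, bz], (m, 3))
        xz, _ = switch_value(np.abs(pts[:, 2]), region.Z, region.dZ)
        xr, _ = switch_value(np.hypot(pts[:, 0], pts[:, 1]), region.R, region.dR)
        total += float(np.sum(xz * xr))
        done += m
    v_mc = total / mc_samples * (2 * br) ** 2 * (2 * bz)
    v_exact = effective_volume(region)

    inner_val, inner_der = switch_value(region.R - region.dR / 2, region.R, region.dR)
    outer_val, outer_der = switch_value(region.R + region.dR / 2, region.R, region.dR)
    return {
        "max_gradient_rel_err": max_rel,
        "volume_exact_A3": v_exact,
        "volume_mc_A3": v_mc,
        "volume_mc_rel_err": abs(v_mc - v_exact) / v_exact,
        "switch_inner_value": inner_val,
        "switch_inner_derivative": inner_der,
        "switch_outer_value": outer_val,
        "switch_outer_derivative": outer_der,
    }


# ------------------------------------------------------------ metadynamics


def poisson_free_energy(N, lam: float, temperature: float = 298.0):
    """−k_BT·ln(λᴺ e^{−λ}/N!) with the Γ-function extension, min at 0."""
    N = np.asarray(N, dtype=float)
    f = kbt(temperature) * (lam - N * np.log(lam) + gammaln(N + 1.0))
    return f - f.min()


def hydration_poisson_study(
    seed: int = 1,
    lam: float = 20.0,
    t_total_ps: float = 16000.0,
    t_decay_ps: float = 4000.0,
    t_avg_start_ps: float = 5000.0,
    n_walkers: int = 8,
    dt: float = 0.012,
) -> dict:
    """Multiple-walker metadynamics on an ideal-gas bath vs Poisson statistics.

    The bath emulates an open water reservoir (grand-canonical particle
    count), so the occupancy of the target volume is Poisson with
    λ = n_bulk·V.  The soft-cylinder geometry keeps the switching shells a
    small fraction of the volume (weighted counting is slightly
    sub-Poisson in its tails), and harmonic walls on ρ at λ ± 4√λ keep the
    corrective sampling inside the compared occupancy range.

    The free additive constant of the profiles is fixed by minimising the
    worst band-excess (Chebyshev alignment); the comparison tolerance at
    each occupancy is the pointwise half-split band, floored at its
    length-average (the pointwise |F₁−F₂| has structural zeros wherever
    the two halves cross).
    """
    region = SoftCylinderRegion(R=7.8, dR=0.5, Z=11.7, dZ=0.5)
    volume = effective_volume(region)
    n_bulk = lam / volume
    box = (34.0, 34.0, 42.0)
    systems = [
        make_scenario(
            "ideal_gas_bath",
            {
                "n_density": n_bulk,
                "box": box,
                "D0": 0.2,
                "dt": dt,
                "seed": seed + w,
                "poisson_count": True,
            },
        )
        for w in range(n_walkers)
    ]
    bias = _metad.BiasPotential(width=5e-4)
    schedule = _metad.HeightSchedule(h0=0.035, floor=0.0035, decay_time_ps=t_decay_ps)
    ensemble = _metad.WalkerEnsemble(
        systems=systems, bias=bias, interval_ps=4.0, schedule=schedule
    )
    cv = _metad.DensityCV(region, FixedFrame(), margin=4.0, update_stride=50)
    kt = kbt(298.0)
    # low wall closer in: the Poisson low tail is steep (F(N→0) grows fast),
    # and every k_BT of tail the walkers must fill delays convergence of the
    # compared range; 0.5√λ of buffer keeps wall artifacts off N = λ − 3√λ.
    walls = _metad.CVWalls(
        lo=(lam - 3.5 * np.sqrt(lam)) / volume,
        hi=(lam + 4 * np.sqrt(lam)) / volume,
        k=2 * kt * volume**2,
    )
    gc = _metad.GrandCanonicalBath(region, box, n_bulk, margin=6.0, period_ps=48.0)
    result = _metad.run_multiwalker(
        ensemble, cv, int(t_total_ps / dt), cv_walls=walls, gc_bath=gc
    )
    fes = _metad.fes_from_bias(bias, result.total_time_ps, t_avg_start_ps)

    half = int(np.floor(3 * np.sqrt(lam)))
    occupancies = np.arange(int(round(lam)) - half, int(round(lam)) + half + 1)
    rho_n = occupancies / volume
    f_ref = poisson_free_energy(occupancies, lam)
    f_est = np.interp(rho_n, fes.z, fes.values)
    band = np.interp(rho_n, fes.z, fes.err)
    tol = np.maximum(band, band.mean())
    raw = f_est - f_ref
    # free additive constant: Chebyshev alignment against the band
    offsets = np.linspace(raw.min(), raw.max(), 4001)
    excess = np.array([np.max(np.abs(raw - o) - tol) for o in offsets])
    diff = raw - offsets[np.argmin(excess)]
    return {
        "lambda": lam,
        "volume_A3": volume,
        "occupancies": occupancies,
        "f_poisson_kcal_mol": f_ref,
        "f_metad_kcal_mol": f_est,
        "half_split_band": band,
        "tolerance": tol,
        "abs_diff": np.abs(diff),
        "max_abs_diff_kcal_mol": float(np.max(np.abs(diff))),
        "rms_diff_kcal_mol": float(np.sqrt(np.mean(diff**2))),
        "mean_band_kcal_mol": float(band.mean()),
        "max_excess_over_band": float(np.max(np.abs(diff) - tol)),
        "fes": fes,
    }


# ----------------------------------------------------------------- ABF


def abf_double_well_study(
    seed: int = 2,
    h: float = 3.0,
    a: float = 5.0,
    n_steps: int = 400_000,
    refine_steps: int = 150_000,
    n_unbiased: int = 64,
    unbiased_steps: int = 200_000,
) -> dict:
    """Two-sided ABF on U(z)=h[(z/a)²−1]², merged and refined, vs oracles.

    Returns the RMS misfit of the recovered G(z) against the generating
    potential and against Boltzmann inversion of an unbiased ensemble run
    (both after removing the free additive constant).
    """

    def one_run(run_seed, side, grid, steps):
        system = make_scenario(
            "double_well_permeation",
            {
                "h": h, "a": a, "D0": 0.2, "dt": 0.02, "seed": run_seed,
                "start_side": side, "radius": 8.0, "half_length": 9.0,
                "k_restraint": 10.0,
            },
        )
        _abf.run_abf(system, grid, steps)
        return grid

    grid_a = one_run(seed, "negative", _abf.ABFGrid(-8.0, 8.0, 0.2, 1000), n_steps)
    grid_b = one_run(seed + 1, "positive", _abf.ABFGrid(-8.0, 8.0, 0.2, 1000), n_steps)
    pmf_a = _abf.pmf_from_grid(grid_a, anchor="min")
    pmf_b = _abf.pmf_from_grid(grid_b, anchor="min")
    merged = _abf.merge_grids([grid_a, grid_b])
    if refine_steps:
        one_run(seed + 2, "negative", merged, refine_steps)
    pmf = _abf.pmf_from_grid(merged, anchor="min")

    u_ref = h * ((pmf.z / a) ** 2 - 1.0) ** 2
    resid = pmf.values - u_ref
    resid -= resid.mean()
    rms_vs_potential = float(np.sqrt(np.mean(resid**2)))

    # half-split agreement between the two one-sided profiles
    lo = max(pmf_a.z[0], pmf_b.z[0])
    hi = min(pmf_a.z[-1], pmf_b.z[-1])
    zc = pmf.z[(pmf.z >= lo) & (pmf.z <= hi)]
    da = np.interp(zc, pmf_a.z, pmf_a.values)
    db = np.interp(zc, pmf_b.z, pmf_b.values)
    split = da - db
    split -= split.mean()
    half_split_mean = float(np.mean(np.abs(split)))

    # Boltzmann inversion of an unbiased ensemble started in both wells
    system = make_scenario(
        "double_well_permeation",
        {
            "h": h, "a": a, "D0": 0.2, "dt": 0.02, "seed": seed + 3,
            "radius": 8.0, "half_length": 9.0, "n_replicas": n_unbiased,
        },
    )
    system.positions[n_unbiased // 2:, 2] = a  # symmetric initialisation
    traj = integrate(system, unbiased_steps, sample_stride=5)
    zs = traj.positions[traj.times > 200.0, :, 2].ravel()
    counts, edges = np.histogram(zs, bins=np.arange(-8.0, 8.2, 0.2))
    hist = counts / (counts.sum() * 0.2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= 100  # bins with enough samples for a meaningful -kT ln p
    g_inv = -kbt(system.temperature) * np.log(hist[keep])
    zi = centers[keep]
    g_abf = np.interp(zi, pmf.z, pmf.values)
    resid_b = g_abf - g_inv
    resid_b -= resid_b.mean()
    rms_vs_boltzmann = float(np.sqrt(np.mean(resid_b**2)))
    return {
        "pmf": pmf,
        "rms_vs_potential_kcal_mol": rms_vs_potential,
        "rms_vs_boltzmann_kcal_mol": rms_vs_boltzmann,
        "half_split_mean_kcal_mol": half_split_mean,
        "barrier_kcal_mol": h,
    }


# -------------------------------------------------------------- diffusion


def diffusion_recovery_study(
    seed: int = 3,
    d0_values: tuple = (0.1, 0.2, 0.5),
    n_windows: int = 17,
    window_ns: float = 12.0,
    k_spring: float = 1.0,
) -> dict:
    """OU windows with known D₀: recovery error of the var/τ estimator.

    The integration cutoff is set per window by Sokal-style self-consistent
    windowing (≈7 correlation times; τ = k_BT/(D₀k) ≈ 1–6 ps here): a cutoff
    much beyond that only accumulates autocorrelation-tail noise, one much
    below it truncates the integral.  The reported estimate per D₀ is the
    mean over the windows (one third of the 51-window protocol each).
    """
    out = {"d0_values": d0_values, "estimates": {}, "rel_errors": {}}
    dt = 0.01
    n_steps = int(window_ns * 1000 / dt)
    for j, d0 in enumerate(d0_values):
        centers = np.linspace(-50.0, 50.0, n_windows)
        system = make_scenario(
            "ou_window",
            {"k": k_spring, "D0": d0, "dt": dt, "seed": seed + j, "centers": centers},
        )
        traj = integrate(system, n_steps, sample_stride=2)
        windows = _diff.windows_from_trajectory(traj, centers, equilibration_ps=100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ests = [
                _diff.window_diffusion(w, cutoff=_diff.auto_cutoff(w.samples, w.dt))
                for w in windows
            ]
        est = float(np.mean(ests))
        out["estimates"][d0] = est
        out["rel_errors"][d0] = abs(est - d0) / d0
    out["max_rel_err"] = max(out["rel_errors"].values())
    return out


# ------------------------------------------------------------- conductance


def conductance_checks(n_grid: int = 601) -> dict:
    """Closed-form, SI round-trip and barrier-scaling checks of γ."""
    z = np.linspace(-15.0, 15.0, n_grid)
    d0 = 0.2
    params = ConductanceParams(q=1.0, C_mM=100.0, S_A2=201.0, T=298.0, Z1=-15.0, Z2=15.0)
    g_flat = Profile1D(z, np.zeros_like(z), units=("A", "kcal_mol"))
    d_flat = Profile1D(z, np.full_like(z, d0), units=("A", "A2_per_ps"))
    res = conductance(g_flat, d_flat, params)
    res_si = conductance(g_flat, d_flat, params, units="si")
    kt = kbt(params.T)
    from .constants import PER_A3_PER_MM, PS_PER_E2_PER_KCALMOL_PS

    length = params.Z2 - params.Z1
    closed_form = (
        PS_PER_E2_PER_KCALMOL_PS
        * params.q**2
        * (params.C_mM * PER_A3_PER_MM)
        * params.S_A2
        * d0
        / (kt * length)
    )
    barrier = 2.0
    g_bar = Profile1D(z, np.full_like(z, barrier), units=("A", "kcal_mol"))
    res_bar = conductance(g_bar, d_flat, params, anchor_tolerance=np.inf)
    return {
        "gamma_flat_pS": res.gamma_pS,
        "gamma_closed_form_pS": closed_form,
        "flat_rel_err": abs(res.gamma_pS - closed_form) / closed_form,
        "si_rel_err": abs(res.gamma_pS - res_si.gamma_pS) / res.gamma_pS,
        "barrier_scaling_rel_err": abs(
            res_bar.gamma_pS / res.gamma_pS - np.exp(-barrier / kt)
        ) / np.exp(-barrier / kt),
    }


# ------------------------------------------------------- two-species pore


def pore_enrichment_study(
    seed: int = 4,
    depth: float = 2.0,
    run_ns: float = 10.0,
    equilibration_ps: float = 500.0,
    dt: float = 0.02,
    n_blocks: int = 5,
) -> dict:
    """Two-species pore: in-pore enrichment of the well-binding species.

    Counts are taken on the inner plateau (ξ = 1) and in the true bulk
    (ξ = 0), where the Boltzmann ratio is exact:
    enrichment = exp(Δε/k_BT).  The sampling error is estimated from
    block averages of the log-enrichment.
    """
    region = SoftCylinderRegion(R=4.0, dR=2.0, Z=6.0, dZ=2.0)
    system = make_scenario(
        "two_species_pore",
        {
            "region": region,
            "box": (20.0, 20.0, 24.0),
            "densities": {"W": 0.01, "L": 0.01},
            "well_depth": {"W": 0.0, "L": depth},
            "D0": {"W": 0.2, "L": 0.2},
            "dt": dt,
            "seed": seed,
        },
    )
    n_steps = int(run_ns * 1000 / dt)
    traj = integrate(system, n_steps, sample_stride=50)
    keep = traj.times > equilibration_ps
    species = np.asarray(traj.species)
    is_l = species == "L"
    is_w = ~is_l
    a_r, a_z = region.R - region.dR / 2, region.Z - region.dZ / 2
    b_r, b_z = region.outer_radius, region.outer_half_length
    pos = traj.positions[keep]
    r = np.hypot(pos[:, :, 0], pos[:, :, 1])
    az = np.abs(pos[:, :, 2])
    inner = (r <= a_r) & (az <= a_z)
    outer = (r >= b_r) | (az >= b_z)
    counts = {
        "L_in": (inner & is_l).sum(axis=1),
        "W_in": (inner & is_w).sum(axis=1),
        "L_out": (outer & is_l).sum(axis=1),
        "W_out": (outer & is_w).sum(axis=1),
    }

    def enrich(sl):
        return (counts["L_in"][sl].mean() / counts["W_in"][sl].mean()) / (
            counts["L_out"][sl].mean() / counts["W_out"][sl].mean()
        )

    n_frames = counts["L_in"].size
    measured = enrich(slice(None))
    edges = np.linspace(0, n_frames, n_blocks + 1).astype(int)
    blocks = np.log([enrich(slice(a, b)) for a, b in zip(edges[:-1], edges[1:])])
    log_se = float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))
    expected = float(np.exp(depth / kbt(system.temperature)))
    return {
        "measured_enrichment": float(measured),
        "expected_enrichment": expected,
        "log_enrichment_se": log_se,
        "rel_err": abs(measured - expected) / expected,
        "z_score": abs(np.log(measured) - depth / kbt(system.temperature)) / log_se,
        "n_frames": int(n_frames),
    }
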