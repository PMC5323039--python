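"""Pipeline orchestration: scenarios → sampling engines → estimators → reports.

Each stage writes its outputs into the run directory together with a log
and an echo of the validated configuration, so any output can be
reproduced from the echo alone.  A stage failure preserves the partial
outputs, records the failing stage in the log and re-raises.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import abf as _abf
from . import diffusion as _diff
from . import io as _io
from . import metad as _metad
from .conductance import ConductanceParams
from .conductance import conductance as _compute_conductance
from .conductance import half_split_error as _half_split_error
from .density import FixedFrame, SoftCylinderRegion, count_cylinder_occupancy
from .dynamics import integrate
from .scenarios import make_scenario

logger = logging.getLogger("poreflux")


def run_pipeline(config: "_io.RunConfig", base_dir: str | Path = ".") -> dict:
    """Execute all stages in order; returns {stage_index: output_path}."""
    out_dir = Path(base_dir) / config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    _io.dump_config(config, out_dir / "config_echo.yaml")
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    outputs = {}
    try:
        for i, stage in enumerate(config.stages):
            t0 = time.time()
            logger.info("stage %d (%s) starting", i, stage.kind)
            try:
                outputs[i] = _RUNNERS[stage.kind](stage, config.seed, out_dir)
            except Exception:
                logger.exception("stage %d (%s) failed", i, stage.kind)
                raise
            logger.info("stage %d (%s) done in %.1f s", i, stage.kind, time.time() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outputs


def _seeded(scenario, seed):
    params = dict(scenario.params)
    params.setdefault("seed", seed)
    return make_scenario(scenario.name, params)


def _run_simulate(stage, seed, out_dir: Path):
    system = _seeded(stage.scenario, seed)
    traj = integrate(system, stage.n_steps, sample_stride=stage.sample_stride)
    path = out_dir / stage.output
    traj.write_tsv(path)
    return path


def _run_metad(stage, seed, out_dir: Path):
    region = SoftCylinderRegion(**stage.region.model_dump())
    systems = []
    for w in range(stage.n_walkers):
        params = dict(stage.scenario.params)
        params["seed"] = seed + w
        systems.append(make_scenario(stage.scenario.name, params))
    bias = _metad.BiasPotential(width=stage.width)
    sched = _metad.HeightSchedule(h0=stage.h0, floor=stage.floor, decay_time_ps=stage.decay_time_ps)
    ens = _metad.WalkerEnsemble(systems=systems, bias=bias, interval_ps=stage.interval_ps, schedule=sched)
    cv = _metad.DensityCV(region, FixedFrame())
    result = _metad.run_multiwalker(ens, cv, stage.n_steps)
    t_start = stage.t_avg_start_ps
    if t_start is None:
        t_start = max(stage.decay_time_ps, 0.5 * result.total_time_ps)
    fes = _metad.fes_from_bias(bias, result.total_time_ps, t_start)
    bias.write_tsv(out_dir / stage.deposit_log)
    path = out_dir / stage.output
    fes.write_tsv(path)
    return path


def _run_abf(stage, seed, out_dir: Path):
    grid_a = _abf.ABFGrid(stage.z_min, stage.z_max, stage.bin_width, stage.n_full)
    params = dict(stage.scenario.params)
    params["seed"] = seed
    params["start_side"] = "negative"
    sys_a = make_scenario(stage.scenario.name, params)
    _abf.run_abf(sys_a, grid_a, stage.n_steps)
    grids = [grid_a]
    if stage.two_sided:
        grid_b = _abf.ABFGrid(stage.z_min, stage.z_max, stage.bin_width, stage.n_full)
        params = dict(stage.scenario.params)
        params["seed"] = seed + 1
        params["start_side"] = "positive"
        sys_b = make_scenario(stage.scenario.name, params)
        _abf.run_abf(sys_b, grid_b, stage.n_steps)
        grids.append(grid_b)
    merged = _abf.merge_grids(grids)
    if stage.refine_steps > 0:
        params = dict(stage.scenario.params)
        params["seed"] = seed + 2
        sys_c = make_scenario(stage.scenario.name, params)
        _abf.run_abf(sys_c, merged, stage.refine_steps)
    pmf = _abf.pmf_from_grid(merged, bulk_width=stage.bulk_width)
    if stage.two_sided:
        halves = [
            _abf.pmf_from_grid(g, bulk_width=stage.bulk_width, trim_threshold=stage.n_full)
            for g in grids
        ]
        lo = max(h.z[0] for h in halves + [pmf])
        hi = min(h.z[-1] for h in halves + [pmf])
        grid_z = pmf.z[(pmf.z >= lo) & (pmf.z <= hi)]
        band = _half_split_error(halves[0].interp(grid_z), halves[1].interp(grid_z))
        pmf = pmf.interp(grid_z)
        pmf.err = band.band
        pmf.meta["half_split_mean"] = band.mean
    path = out_dir / stage.output
    pmf.write_tsv(path)
    return path


def _run_diffusion(stage, seed, out_dir: Path):
    system = _seeded(stage.scenario, seed)
    centers = np.asarray(system.metadata.get("centers", [0.0]), dtype=float)
    traj = integrate(system, stage.n_steps, sample_stride=stage.sample_stride)
    windows = _diff.windows_from_trajectory(traj, centers, equilibration_ps=stage.equilibration_ps)
    prof = _diff.diffusion_profile(windows, cutoff=stage.cutoff_ps)
    path = out_dir / stage.output
    prof.profile.write_tsv(path)
    return path


def _run_conductance(stage, seed, out_dir: Path):
    G = _io.read_profile(_resolve(stage.pmf, out_dir))
    D = _io.read_profile(_resolve(stage.diffusion, out_dir))
    params = ConductanceParams(
        q=stage.q, C_mM=stage.conc_mM, S_A2=stage.area_A2, T=stage.temp_K,
        Z1=stage.z1, Z2=stage.z2,
    )
    result = _compute_conductance(G, D, params)
    path = out_dir / stage.output
    with open(path, "w") as fh:
        json.dump(
            {
                "gamma_pS": result.gamma_pS,
                "gamma_lo_pS": result.gamma_lo_pS,
                "gamma_hi_pS": result.gamma_hi_pS,
                "integral_ps_per_A": result.integral_ps_per_A,
            },
            fh,
            indent=2,
        )
    return path


def _run_occupancy(stage, seed, out_dir: Path):
    system = _seeded(stage.scenario, seed)
    traj = integrate(system, stage.n_steps, sample_stride=stage.sample_stride)
    df = count_cylinder_occupancy(traj, stage.radius, stage.height, FixedFrame(), stage.window_ps)
    path = out_dir / stage.output
    df.to_csv(path, sep="\t", index=False)
    return path


def _resolve(path_str: str, out_dir: Path) -> Path:
    p = Path(path_str)
    if p.exists():
        return p
    candidate = out_dir / p
    if candidate.exists():
        return candidate
    raise FileNotFoundError(f"input file {path_str} not found (also tried {candidate})")


_RUNNERS = {
    "simulate": _run_simulate,
    "metad": _run_metad,
    "abf": _run_abf,
    "diffusion": _run_diffusion,
    "conductance": _run_conductance,
    "occupancy": _run_occupancy,
}
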