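"""Run configuration (YAML, schema-validated) and tabular file formats.

The canonical tabular format throughout the package is TSV with a
commented header — diff-able and language-neutral.  Profiles are handled
by :class:`poreflux.profiles.Profile1D`; trajectories by
:class:`poreflux.dynamics.TrajectoryStore`.  This module adds the YAML
run-configuration schema used by the pipeline and CLI: unknown keys are
rejected and missing required keys are reported by name.
"""

from __future__ import annotations

from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .profiles import Profile1D


def read_profile(path) -> Profile1D:
    """Read a TSV profile (z, value, optional err)."""
    return Profile1D.read_tsv(path)


def write_profile(path, profile: Profile1D) -> None:
    """Write a profile as TSV; ``read_profile`` round-trips it exactly."""
    profile.write_tsv(path)


def read_xyz(path):
    """Read an XYZ file (first frame) into (labels, positions in Å).

    Lets the density CV and occupancy counter run on externally produced
    coordinates (e.g. a structure exported from a visualiser).
    """
    import numpy as np

    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise ValueError(f"{path}: truncated XYZ file ({n} atoms declared)")
    labels, coords = [], []
    for ln, line in enumerate(lines[2 : n + 2], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {ln}: expected 'label x y z'")
        labels.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return labels, np.asarray(coords)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScenarioConfig(_Strict):
    name: Literal["ou_window", "double_well_permeation", "ideal_gas_bath", "two_species_pore"]
    params: dict = Field(default_factory=dict)


class RegionConfig(_Strict):
    R: float
    dR: float
    Z: float
    dZ: float


class SimulateStage(_Strict):
    kind: Literal["simulate"]
    scenario: ScenarioConfig
    n_steps: int
    sample_stride: int = 1
    output: str = "trajectory.tsv"


class MetadStage(_Strict):
    kind: Literal["metad"]
    scenario: ScenarioConfig
    region: RegionConfig
    n_walkers: int = 8
    interval_ps: float = 4.0
    width: float = 0.0005
    h0: float = 0.035
    floor: float = 0.0035
    decay_time_ps: float = 4000.0
    n_steps: int = 100000
    t_avg_start_ps: Optional[float] = None
    output: str = "fes.tsv"
    deposit_log: str = "deposits.tsv"


class AbfStage(_Strict):
    kind: Literal["abf"]
    scenario: ScenarioConfig
    z_min: float
    z_max: float
    bin_width: float = 0.2
    n_full: int = 1000
    n_steps: int = 300000
    two_sided: bool = True
    refine_steps: int = 0
    bulk_width: float = 10.0
    output: str = "pmf.tsv"


class DiffusionStage(_Strict):
    kind: Literal["diffusion"]
    scenario: ScenarioConfig
    n_steps: int
    sample_stride: int = 2
    cutoff_ps: float = 100.0
    equilibration_ps: float = 50.0
    output: str = "diffusion.tsv"


class ConductanceStage(_Strict):
    kind: Literal["conductance"]
    pmf: str
    diffusion: str
    q: float = 1.0
    conc_mM: float = 100.0
    area_A2: float = 201.0
    temp_K: float = 298.0
    z1: float = -15.0
    z2: float = 15.0
    output: str = "conductance.json"


class OccupancyStage(_Strict):
    kind: Literal["occupancy"]
    scenario: ScenarioConfig
    n_steps: int
    sample_stride: int = 50
    radius: float = 7.0
    height: float = 32.0
    window_ps: float = 1000.0
    output: str = "occupancy.tsv"


Stage = Union[SimulateStage, MetadStage, AbfStage, DiffusionStage, ConductanceStage, OccupancyStage]


class RunConfig(_Strict):
    """Top-level pipeline configuration (YAML)."""

    seed: int = 0
    out_dir: str = "run"
    stages: list[Stage] = Field(min_length=1)


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    """Echo the validated configuration back to YAML (reproducibility record)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
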