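"""One-dimensional Adaptive Biasing Force estimator of G(z).

The z-range is divided into bins (0.2 Å by default).  Each step, the
instantaneous systematic force on the tagged particle's z-coordinate
(restraint terms excluded) is accumulated into the bin at the current z,
and the applied bias is the negative running mean force scaled by a ramp
min(count/N_full, 1) — no bias is applied at full strength until N_full
samples (1000 by default) have been collected in that bin.  At
convergence the landscape is flat and G(z) is recovered by integrating
the mean force:  G(z) = −∫ ⟨F_z⟩ dz.

Grids from independent runs (e.g. started from opposite ends of the pore)
can be merged by pooling (sum, count) pairs, which is exact, associative
and commutative; a merged grid can seed a further refinement run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import math

from .density import FixedFrame
from .dynamics import (
    BrownianSystem,
    DoubleWellZ,
    FlatBottomCylinder,
    HarmonicWell,
    PerParticleHarmonicZ,
    TrajectoryStore,
)
from .profiles import Profile1D


@dataclass
class ABFGrid:
    """Per-bin force sums and sample counts over z, with a ramp threshold."""

    z_min: float
    z_max: float
    bin_width: float = 0.2
    n_full: int = 1000
    force_sum: np.ndarray = field(default=None)
    count: np.ndarray = field(default=None)
    out_of_range: int = 0

    def __post_init__(self):
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")
        if self.bin_width <= 0 or self.n_full < 1:
            raise ValueError("need positive bin width and ramp threshold >= 1")
        n_bins = int(round((self.z_max - self.z_min) / self.bin_width))
        self.z_max = self.z_min + n_bins * self.bin_width
        if self.force_sum is None:
            self.force_sum = np.zeros(n_bins)
        if self.count is None:
            self.count = np.zeros(n_bins, dtype=np.int64)
        if self.force_sum.shape != self.count.shape or self.force_sum.size != n_bins:
            raise ValueError("force_sum/count inconsistent with binning")

    @property
    def n_bins(self) -> int:
        return self.force_sum.size

    @property
    def edges(self) -> np.ndarray:
        return self.z_min + np.arange(self.n_bins + 1) * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        return self.z_min + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def mean_force(self) -> np.ndarray:
        """Running mean force per bin (NaN where unvisited)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.count > 0, self.force_sum / np.maximum(self.count, 1), np.nan)

    def same_binning(self, other: "ABFGrid") -> bool:
        return (
            self.n_bins == other.n_bins
            and np.isclose(self.z_min, other.z_min)
            and np.isclose(self.bin_width, other.bin_width)
        )

    def copy(self) -> "ABFGrid":
        return ABFGrid(
            z_min=self.z_min, z_max=self.z_max, bin_width=self.bin_width,
            n_full=self.n_full, force_sum=self.force_sum.copy(), count=self.count.copy(),
            out_of_range=self.out_of_range,
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ABF grid checkpoint: z_min={self.z_min} bin_width={self.bin_width} n_full={self.n_full}\n")
            fh.write("# z_center\tforce_sum_kcal_mol_A\tcount\n")
            for c, s, n in zip(self.centers, self.force_sum, self.count):
                fh.write(f"{c:.10g}\t{s:.10g}\t{n}\n")

    @classmethod
    def read_tsv(cls, path) -> "ABFGrid":
        meta = {}
        centers, sums, counts = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# ABF grid checkpoint:"):
                    for tok in line.split(":", 1)[1].split():
                        key, val = tok.split("=")
                        meta[key] = float(val)
                elif line and not line.startswith("#"):
                    c, s, n = line.split("\t")
                    centers.append(float(c))
                    sums.append(float(s))
                    counts.append(int(n))
        bw = meta["bin_width"]
        z_min = meta["z_min"]
        return cls(
            z_min=z_min, z_max=z_min + bw * len(centers), bin_width=bw,
            n_full=int(meta["n_full"]), force_sum=np.array(sums),
            count=np.array(counts, dtype=np.int64),
        )


def update_and_bias(grid: ABFGrid, z: float, f_sample: float) -> float:
    """Accumulate one force sample and return the ramped bias force.

    Out-of-range z accumulates nothing, applies zero bias and increments
    the grid's warning counter.
    """
    i = int((z - grid.z_min) / grid.bin_width)
    if z < grid.z_min or i >= grid.n_bins:
        grid.out_of_range += 1
        return 0.0
    grid.force_sum[i] += f_sample
    grid.count[i] += 1
    ramp = min(grid.count[i] / grid.n_full, 1.0)
    return -grid.force_sum[i] / grid.count[i] * ramp


def merge_grids(grids: list) -> ABFGrid:
    """Pool per-bin force sums and counts across grids with identical binning."""
    if not grids:
        raise ValueError("nothing to merge")
    base = grids[0].copy()
    for g in grids[1:]:
        if not base.same_binning(g):
            raise ValueError("cannot merge grids with mismatched binning")
        base.force_sum += g.force_sum
        base.count += g.count
        base.out_of_range += g.out_of_range
    return base


def _scalar_kernel(term):
    """Scalar force closure (x,y,z) → (fx,fy,fz) for recognized single-particle terms.

    Returns None when the term cannot be reduced to a cheap scalar form,
    in which case the generic array path is used.
    """
    if isinstance(term, DoubleWellZ) and term.indices is None:
        h, a2 = term.h, term.a**2

        def dw(x, y, z):
            fz = -4.0 * h * z * (z * z / a2 - 1.0) / a2
            return 0.0, 0.0, fz

        return dw
    if isinstance(term, FlatBottomCylinder) and term.indices is None:
        if not isinstance(term.frame, FixedFrame):
            return None
        origin, axis = term.frame.origin, term.frame.axis
        if not (abs(origin).max() == 0.0 and axis[0] == 0.0 and axis[1] == 0.0 and axis[2] == 1.0):
            return None
        radius, half_len, k = term.radius, term.half_length, term.k

        def fbc(x, y, z):
            fx = fy = fz = 0.0
            r = math.hypot(x, y)
            if r > radius:
                c = -k * (r - radius) / r
                fx, fy = c * x, c * y
            az = abs(z)
            if az > half_len:
                fz = -k * (az - half_len) * (1.0 if z > 0 else -1.0)
            return fx, fy, fz

        return fbc
    if isinstance(term, HarmonicWell) and term.indices is None and tuple(term.axes) == (0, 1, 2):
        k = term.k
        cx, cy, cz = term.center

        def hw(x, y, z):
            return -k * (x - cx), -k * (y - cy), -k * (z - cz)

        return hw
    if isinstance(term, PerParticleHarmonicZ) and np.size(term.k) == 1:
        k = float(np.ravel(term.k)[0])
        c = float(np.ravel(term.centers_z)[0])

        def ppz(x, y, z):
            return 0.0, 0.0, -k * (z - c)

        return ppz
    return None


def _run_abf_scalar(system, grid, n_steps, sys_kernels, res_kernels, max_r, sample_stride):
    """Tight scalar loop for a single tagged particle (fast path)."""
    rng = np.random.default_rng(system.seed)
    x, y, z = (float(v) for v in system.positions[0])
    D = float(system.per_particle_D()[0])
    dt = system.dt
    drift = D / system.kbt * dt
    namp = math.sqrt(2.0 * D * dt)
    n_frames = n_steps // sample_stride + 1
    frames = np.empty((n_frames, 1, 3))
    times = np.empty(n_frames)
    frames[0, 0] = (x, y, z)
    times[0] = 0.0
    fi = 1
    block = 65536
    noise = rng.standard_normal((block, 3))
    bi = block
    for step in range(1, n_steps + 1):
        fx = fy = fz = 0.0
        f_sys_z = 0.0
        for kern in sys_kernels:
            gx, gy, gz = kern(x, y, z)
            fx += gx
            fy += gy
            fz += gz
            f_sys_z += gz
        for kern in res_kernels:
            gx, gy, gz = kern(x, y, z)
            fx += gx
            fy += gy
            fz += gz
        if not math.isfinite(f_sys_z):
            raise FloatingPointError(f"non-finite force at step {step}, particle 0")
        fz += update_and_bias(grid, z, f_sys_z)
        if bi == block:
            noise = rng.standard_normal((block, 3))
            bi = 0
        nx, ny, nz = noise[bi]
        bi += 1
        x += drift * fx + namp * nx
        y += drift * fy + namp * ny
        z += drift * fz + namp * nz
        if x * x + y * y > max_r * max_r:
            raise RuntimeError(
                f"tagged particle escaped the restraint (r={math.hypot(x, y):.1f} Å) at step {step}"
            )
        if step % sample_stride == 0:
            frames[fi, 0] = (x, y, z)
            times[fi] = step * system.dt
            fi += 1
    traj = TrajectoryStore(
        times=times[:fi], positions=frames[:fi], species=list(system.species),
        metadata={"seed": system.seed, "abf": True},
    )
    return grid, traj


def run_abf(
    system: BrownianSystem,
    grid: ABFGrid,
    n_steps: int,
    tagged: int = 0,
    sample_stride: int = 100,
    escape_tolerance: float = 10.0,
) -> tuple[ABFGrid, TrajectoryStore]:
    """Adaptive-biasing-force run on the tagged particle's z-coordinate.

    Each step the systematic z-force on the tagged particle (all potential
    terms except restraints) is fed to :func:`update_and_bias`, and the
    returned bias is added along z before the Euler–Maruyama update.  The
    grid is mutated in place and also returned, so sequential runs (e.g. a
    refinement after merging) continue to accumulate.
    """
    systematic = [t for t in system.potential_terms if not t.is_restraint]
    restraints = [t for t in system.potential_terms if t.is_restraint]
    restraint_radii = [t.radius for t in restraints if hasattr(t, "radius")]
    max_r = (max(restraint_radii) + escape_tolerance) if restraint_radii else np.inf

    if system.n_particles == 1 and tagged == 0:
        sys_kernels = [_scalar_kernel(t) for t in systematic]
        res_kernels = [_scalar_kernel(t) for t in restraints]
        if all(k is not None for k in sys_kernels + res_kernels):
            return _run_abf_scalar(
                system, grid, n_steps, sys_kernels, res_kernels, max_r, sample_stride
            )

    rng = np.random.default_rng(system.seed)
    pos = system.positions.copy()
    D = system.per_particle_D()
    beta = 1.0 / system.kbt
    drift = (beta * D * system.dt)[:, None]
    noise_amp = np.sqrt(2.0 * D * system.dt)[:, None]

    n_frames = n_steps // sample_stride + 1
    frames = np.empty((n_frames, pos.shape[0], 3))
    times = np.empty(n_frames)
    frames[0] = pos
    times[0] = 0.0
    fi = 1

    block = 8192
    noise = rng.standard_normal((block, *pos.shape))
    bi = 0
    for step in range(1, n_steps + 1):
        forces = np.zeros_like(pos)
        f_sys_z = 0.0
        for term in systematic:
            _, f = term.energy_and_forces(pos)
            forces += f
            f_sys_z += f[tagged, 2]
        for term in restraints:
            _, f = term.energy_and_forces(pos)
            forces += f
        if not np.isfinite(f_sys_z):
            raise FloatingPointError(f"non-finite force at step {step}, particle {tagged}")
        bias = update_and_bias(grid, float(pos[tagged, 2]), float(f_sys_z))
        forces[tagged, 2] += bias
        if bi == block:
            noise = rng.standard_normal((block, *pos.shape))
            bi = 0
        pos = pos + drift * forces + noise_amp * noise[bi]
        bi += 1
        r = np.hypot(pos[tagged, 0], pos[tagged, 1])
        if r > max_r:
            raise RuntimeError(
                f"tagged particle escaped the restraint (r={r:.1f} Å) at step {step}"
            )
        if step % sample_stride == 0:
            frames[fi] = pos
            times[fi] = step * system.dt
            fi += 1
    traj = TrajectoryStore(
        times=times[:fi], positions=frames[:fi], species=list(system.species),
        metadata={"seed": system.seed, "abf": True},
    )
    return grid, traj


def pmf_from_grid(
    grid: ABFGrid,
    anchor: str = "bulk",
    bulk_width: float = 10.0,
    trim_threshold: int | None = None,
) -> Profile1D:
    """Integrate the mean force into G(z) over the well-sampled range.

    The reporting range is trimmed to the contiguous span of bins with at
    least ``trim_threshold`` samples (default: the grid's ramp threshold);
    a zero-count gap inside that span is an error.  G is anchored so that
    its mean over the outermost ``bulk_width`` Å at each end is zero
    (``anchor='bulk'``), or so that min G = 0 (``anchor='min'``).
    """
    if trim_threshold is None:
        trim_threshold = grid.n_full
    good = grid.count >= trim_threshold
    if not np.any(good):
        raise ValueError("no bin reaches the reporting threshold")
    lo, hi = np.argmax(good), grid.n_bins - np.argmax(good[::-1])
    inner = grid.count[lo:hi]
    if np.any(inner == 0):
        gaps = grid.centers[lo:hi][inner == 0]
        raise ValueError(f"unsampled gap bins inside the reporting range at z={gaps}")
    centers = grid.centers[lo:hi]
    mean_f = grid.force_sum[lo:hi] / grid.count[lo:hi]
    g = np.concatenate(([0.0], -np.cumsum((mean_f[1:] + mean_f[:-1]) / 2.0 * grid.bin_width)))
    if anchor == "bulk":
        bulk = (centers <= centers[0] + bulk_width) | (centers >= centers[-1] - bulk_width)
        g -= g[bulk].mean()
    elif anchor == "min":
        g -= g.min()
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return Profile1D(centers, g, units=("A", "kcal_mol"), meta={"anchor": anchor})
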