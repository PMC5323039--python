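"""Soft-boundary cylindrical density collective variable.

The wetting/dewetting order parameter is the particle (water-oxygen)
number density inside a cylindrical volume whose boundaries are smoothed
over shells of width ΔR and ΔZ:

    ρ = Σ_i ξ(X_i) / V,

where the per-particle weight ξ factorises into axial and radial switching
functions, ξ = ξ_Z(z)·ξ_R(r), each equal to 1 well inside the cylinder,
0 well outside, and tapering smoothly (with zero slope at both shell
edges) in between.  V is the effective volume ∫ ξ dX, so that ρ equals
the bulk density when the region is uniformly filled.

The cylinder is anchored to a set of reference particles (in the original
application, Cα atoms of the protein) so the biased volume follows the
molecule's diffusion and tumbling: the origin is the centroid of a middle
reference group and the axis is the unit vector between the centroids of
two distal groups.  A :class:`FixedFrame` covers the degenerate case of an
absolute-Cartesian volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

try:  # optional compiled kernel for the per-step density evaluation
    import numba as _numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


# --------------------------------------------------------------------- types


@dataclass(frozen=True)
class SoftCylinderRegion:
    """Geometry of the soft cylinder: nominal radius/half-length and shell widths.

    The radial switching shell spans [R−ΔR/2, R+ΔR/2] and the axial one
    [Z−ΔZ/2, Z+ΔZ/2] on either side.
    """

    R: float
    dR: float
    Z: float
    dZ: float

    def __post_init__(self) -> None:
        if self.dR <= 0 or self.dZ <= 0:
            raise ValueError("switching widths dR, dZ must be positive")
        if self.R - self.dR / 2 < 0:
            raise ValueError("inner radial boundary R - dR/2 must be >= 0")
        if self.Z - self.dZ / 2 < 0:
            raise ValueError("inner axial boundary Z - dZ/2 must be >= 0")

    @property
    def outer_radius(self) -> float:
        return self.R + self.dR / 2

    @property
    def outer_half_length(self) -> float:
        return self.Z + self.dZ / 2


class FixedFrame:
    """An absolute-Cartesian cylinder frame (fixed origin and axis)."""

    def __init__(self, origin=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0)):
        self.origin = np.asarray(origin, dtype=float)
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n <= 0:
            raise ValueError("frame axis must have positive length")
        self.axis = axis / n

    def origin_axis(self, positions=None):
        return self.origin, self.axis


class AnchoredFrame:
    """Cylinder frame derived from three disjoint sets of reference particles.

    The origin is the centroid of ``middle``; the axis is the unit vector
    from the centroid of ``distal_a`` to the centroid of ``distal_b``.
    Anchoring the volume to reference coordinates (rather than absolute
    space) leaves the tumbling and diffusion of the anchoring molecule
    unrestricted under the bias.
    """

    def __init__(self, middle, distal_a, distal_b):
        self.middle = np.asarray(middle, dtype=int)
        self.distal_a = np.asarray(distal_a, dtype=int)
        self.distal_b = np.asarray(distal_b, dtype=int)
        sets = [self.middle, self.distal_a, self.distal_b]
        if any(s.size == 0 for s in sets):
            raise ValueError("all three reference index sets must be non-empty")
        all_idx = np.concatenate(sets)
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("reference index sets must be disjoint")

    def origin_axis(self, positions):
        positions = np.asarray(positions, dtype=float)
        origin = positions[self.middle].mean(axis=0)
        u = positions[self.distal_b].mean(axis=0) - positions[self.distal_a].mean(axis=0)
        n = np.linalg.norm(u)
        if n <= 1e-12:
            raise ValueError("degenerate frame: distal centroids coincide")
        return origin, u / n

    @property
    def reference_indices(self) -> np.ndarray:
        return np.concatenate([self.middle, self.distal_a, self.distal_b])


@dataclass
class DensityResult:
    """Density ρ, per-particle weights ξ_i, gradients ∂ρ/∂x_i and volume V."""

    rho: float
    weights: np.ndarray
    gradients: np.ndarray
    volume: float
    meta: dict = field(default_factory=dict)


# ------------------------------------------------------------ switching math


def switch_value(sigma, S: float, dS: float):
    """Smooth 1→0 switching function χ_S(σ) over [S−dS/2, S+dS/2] and dχ/dσ.

    With a = S−dS/2 and b = S+dS/2,

        χ(σ) = (b²−σ²)²·(b² + 2σ² − 3a²) / (b²−a²)³,

    which equals 1 at σ=a and 0 at σ=b with zero derivative at both shell
    edges.  The derivative has the closed form
    dχ/dσ = 12σ(b²−σ²)(a²−σ²)/(b²−a²)³.  Vectorised over ``sigma``.
    """
    if dS <= 0:
        raise ValueError("switching width dS must be positive")
    a = S - dS / 2
    b = S + dS / 2
    if a < 0:
        raise ValueError("S - dS/2 must be >= 0")
    scalar = np.isscalar(sigma) or np.ndim(sigma) == 0
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    a2, b2 = a * a, b * b
    denom = (b2 - a2) ** 3
    # evaluate the shell polynomial everywhere (cheap), then select by branch
    sc = np.clip(sigma, a, b)
    s2 = sc * sc
    bs = b2 - s2
    val_shell = bs * bs * (b2 + 2 * s2 - 3 * a2) / denom
    der_shell = 12 * sc * bs * (a2 - s2) / denom
    in_shell = (sigma > a) & (sigma < b)
    val = np.where(sigma <= a, 1.0, np.where(in_shell, val_shell, 0.0))
    der = np.where(in_shell, der_shell, 0.0)
    if scalar:
        return float(val), float(der)
    return val, der


def _cyl_coords(positions, region, frame):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    origin, axis = frame.origin_axis(positions)
    d = positions - origin
    if axis[0] == 0.0 and axis[1] == 0.0 and axis[2] == 1.0:
        z = d[:, 2].copy()
        perp = d.copy()
        perp[:, 2] = 0.0
        r = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    else:
        z = d @ axis
        perp = d - z[:, None] * axis
        r = np.sqrt(np.einsum("ij,ij->i", perp, perp))
    return d, z, r, perp, origin, axis


def region_weight(point, region: SoftCylinderRegion, frame) -> float:
    """Weight ξ ∈ [0,1] of a single point: ξ = χ_Z(|z|)·χ_R(r)."""
    _, z, r, _, _, _ = _cyl_coords(point, region, frame)
    xz, _ = switch_value(abs(float(z[0])), region.Z, region.dZ)
    xr, _ = switch_value(float(r[0]), region.R, region.dR)
    return xz * xr


def _chi_shell_integral(S: float, dS: float) -> float:
    """∫ χ_S(σ) dσ over the shell [S−dS/2, S+dS/2], numerically stable.

    With σ = a + dS·x (x ∈ [0, 1]) the powers of dS cancel against the
    (b²−a²)³ denominator, leaving a degree-5 polynomial in x with O(1)
    coefficients — exact for any shell width, including dS → 0.
    """
    a = S - dS / 2
    b = S + dS / 2
    x = Polynomial([0.0, 1.0])
    sigma = Polynomial([a, dS])
    p = (1 - x) ** 2 * (sigma + b) ** 2 * ((a + b) + 2 * x * (sigma + a)) / (a + b) ** 3
    q = p.integ()
    return dS * float(q(1.0) - q(0.0))


@lru_cache(maxsize=64)
def effective_volume(region: SoftCylinderRegion) -> float:
    """Effective volume V = ∫ ξ dX = [∫ ξ_Z dz]·[∫ 2πr ξ_R dr].

    Both factors are elementary.  The radial one has the exact closed form
    π(R² + ΔR²/4) — substituting t = r² turns the shell integrand into
    (1−s)²(1+2s), whose integral over the shell is (b²−a²)/4.  The axial
    one is a + ∫χ over the shell (per side).  Cached per (frozen) region:
    V is needed on every density evaluation.
    """
    axial = 2.0 * (region.Z - region.dZ / 2 + _chi_shell_integral(region.Z, region.dZ))
    radial = np.pi * (region.R**2 + region.dR**2 / 4)
    return float(axial * radial)


# --------------------------------------------------------- density machinery


if _HAVE_NUMBA:

    @_numba.njit(cache=False)
    def _density_kernel(pos, idx, origin, axis, aR, bR, denR, aZ, bZ, denZ, invV, weights, grads):
        """Sequential ξ/∇ξ evaluation (order-stable sums; see neighbor contract)."""
        aR2, bR2 = aR * aR, bR * bR
        aZ2, bZ2 = aZ * aZ, bZ * bZ
        total = 0.0
        for jj in range(idx.size):
            i = idx[jj]
            dx = pos[i, 0] - origin[0]
            dy = pos[i, 1] - origin[1]
            dz_ = pos[i, 2] - origin[2]
            z = dx * axis[0] + dy * axis[1] + dz_ * axis[2]
            px = dx - z * axis[0]
            py = dy - z * axis[1]
            pz = dz_ - z * axis[2]
            r2 = px * px + py * py + pz * pz
            az = abs(z)
            # axial switch
            if az <= aZ:
                xz, dxz = 1.0, 0.0
            elif az >= bZ:
                xz, dxz = 0.0, 0.0
            else:
                s2 = az * az
                bs = bZ2 - s2
                xz = bs * bs * (bZ2 + 2.0 * s2 - 3.0 * aZ2) * denZ
                dxz = 12.0 * az * bs * (aZ2 - s2) * denZ
            if z < 0.0:
                dxz = -dxz
            # radial switch
            if r2 <= aR2:
                xr, dxr = 1.0, 0.0
                r = 0.0
            elif r2 >= bR2:
                xr, dxr = 0.0, 0.0
                r = 0.0
            else:
                r = np.sqrt(r2)
                bs = bR2 - r2
                xr = bs * bs * (bR2 + 2.0 * r2 - 3.0 * aR2) * denR
                dxr = 12.0 * r * bs * (aR2 - r2) * denR
            w = xz * xr
            weights[i] = w
            total += w
            ca = dxz * xr
            if r > 1e-12:
                cr = xz * dxr / r
            else:
                cr = 0.0
            grads[i, 0] = (ca * axis[0] + cr * px) * invV
            grads[i, 1] = (ca * axis[1] + cr * py) * invV
            grads[i, 2] = (ca * axis[2] + cr * pz) * invV
        return total


@dataclass
class NeighborList:
    """Indices of particles inside the region's outer boundary plus a margin.

    The list is valid as long as accumulated displacement since the build
    cannot exceed the margin; :meth:`check_valid` enforces that contract
    given a caller-supplied per-step displacement bound.
    """

    indices: np.ndarray
    margin: float
    age_steps: int = 0

    def check_valid(self, per_step_bound: float) -> None:
        if self.age_steps * per_step_bound > self.margin:
            raise RuntimeError(
                f"neighbor list stale: {self.age_steps} steps × bound "
                f"{per_step_bound} Å exceeds margin {self.margin} Å"
            )


def neighbor_list_update(positions, region: SoftCylinderRegion, frame, margin: float = 4.0) -> NeighborList:
    """Build the list of particles within the soft boundary plus ``margin``."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    _, z, r, _, _, _ = _cyl_coords(positions, region, frame)
    mask = (r <= region.outer_radius + margin) & (np.abs(z) <= region.outer_half_length + margin)
    return NeighborList(indices=np.nonzero(mask)[0], margin=margin)


def density_and_gradient(
    positions,
    region: SoftCylinderRegion,
    frame,
    neighbor_list: NeighborList | None = None,
    per_step_bound: float | None = None,
    frame_gradients: bool = False,
    validate: bool = True,
) -> DensityResult:
    """Compute ρ = Σ ξ_i / V with analytic per-particle gradients.

    Gradients are non-zero only for particles inside the switching shells.
    By default the gradient is taken at fixed frame (the reference
    particles are held by their own dynamics); with ``frame_gradients=True``
    and an :class:`AnchoredFrame`, the derivative of ρ through the moving
    origin and axis is added to the reference particles' entries, which
    restores exact translation invariance of the total gradient.
    """
    positions = np.asarray(positions, dtype=float)
    if validate and not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    n = positions.shape[0]
    V = effective_volume(region)
    weights = np.zeros(n)
    grads = np.zeros((n, 3))

    if neighbor_list is not None:
        if per_step_bound is not None:
            neighbor_list.check_valid(per_step_bound)
        idx = neighbor_list.indices
    else:
        idx = np.arange(n)

    if _HAVE_NUMBA and not frame_gradients:
        origin, axis = frame.origin_axis(positions)
        aR, bR = region.R - region.dR / 2, region.outer_radius
        aZ, bZ = region.Z - region.dZ / 2, region.outer_half_length
        denR = 1.0 / (bR * bR - aR * aR) ** 3
        denZ = 1.0 / (bZ * bZ - aZ * aZ) ** 3
        total = _density_kernel(
            positions, np.ascontiguousarray(idx, dtype=np.int64),
            np.ascontiguousarray(origin, dtype=np.float64),
            np.ascontiguousarray(axis, dtype=np.float64),
            aR, bR, denR, aZ, bZ, denZ, 1.0 / V, weights, grads,
        )
        return DensityResult(rho=total / V, weights=weights, gradients=grads, volume=V)

    d, z, r, perp, origin, axis = _cyl_coords(positions[idx], region, frame_or_resolved(frame, positions))

    xz, dxz_dabs = switch_value(np.abs(z), region.Z, region.dZ)
    xr, dxr = switch_value(r, region.R, region.dR)
    dxz = dxz_dabs * np.sign(z)

    w = xz * xr
    rho = float(w.sum() / V)

    r_safe = np.maximum(r, 1e-300)
    rhat = perp * ((r > 1e-12) / r_safe)[:, None]
    g = (dxz * xr)[:, None] * axis + (xz * dxr)[:, None] * rhat
    if idx.size == weights.size:
        weights[:] = w
        grads[:] = g / V
    else:
        weights[idx] = w
        grads[idx] = g / V

    if frame_gradients:
        if not isinstance(frame, AnchoredFrame):
            raise ValueError("frame_gradients requires an AnchoredFrame")
        _add_frame_gradients(grads, positions, frame, idx, d, z, r, rhat, xz, dxz, xr, dxr, V)

    return DensityResult(rho=rho, weights=weights, gradients=grads, volume=V)


def frame_or_resolved(frame, positions):
    """Resolve an AnchoredFrame against the full position array."""
    if isinstance(frame, AnchoredFrame):
        origin, axis = frame.origin_axis(positions)
        return FixedFrame(origin, axis)
    return frame


def _add_frame_gradients(grads, positions, frame, idx, d, z, r, rhat, xz, dxz, xr, dxr, V):
    """Chain-rule contributions of ρ through the anchored origin and axis."""
    origin, axis = frame.origin_axis(positions)
    # dρ/d(origin) = −Σ_i g_i  (shifting the origin is minus shifting all points)
    g_particles = ((dxz * xr)[:, None] * axis + (xz * dxr)[:, None] * rhat) / V
    drho_dorigin = -g_particles.sum(axis=0)
    grads[frame.middle] += drho_dorigin / frame.middle.size

    # dρ/d(axis): z_i = d_i·a and dr_i/da = −z_i·p̂_i (p̂ ⊥ a).
    drho_da = (
        ((dxz * xr)[:, None] * d).sum(axis=0) - ((xz * dxr * z * r / np.maximum(r, 1e-300))[:, None] * rhat).sum(axis=0)
    ) / V
    u = positions[frame.distal_b].mean(axis=0) - positions[frame.distal_a].mean(axis=0)
    norm_u = np.linalg.norm(u)
    proj = (np.eye(3) - np.outer(axis, axis)) / norm_u  # da/du
    drho_du = proj @ drho_da
    grads[frame.distal_b] += drho_du / frame.distal_b.size
    grads[frame.distal_a] -= drho_du / frame.distal_a.size


# ------------------------------------------------------------- occupancy


def count_cylinder_occupancy(trajectory, radius: float, height: float, frame, window_ps: float = 1000.0) -> pd.DataFrame:
    """Per-frame particle counts inside a hard cylinder, by species.

    Counts particles with r ≤ radius and |z| ≤ height/2 in the frame's
    cylindrical coordinates, and appends a running average over a trailing
    time window (default 1 ns).  Returns a tidy DataFrame with columns
    ``time_ps, species, count, running_avg``.
    """
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be positive")
    species = np.asarray(trajectory.species)
    labels = sorted(set(species.tolist()))
    rows = {lab: [] for lab in labels}
    for f in range(trajectory.n_frames):
        pos = trajectory.positions[f]
        origin, axis = frame.origin_axis(pos)
        d = pos - origin
        z = d @ axis
        perp = d - z[:, None] * axis
        r = np.linalg.norm(perp, axis=1)
        inside = (r <= radius) & (np.abs(z) <= height / 2)
        for lab in labels:
            rows[lab].append(int(np.sum(inside & (species == lab))))
    times = np.asarray(trajectory.times)
    out = []
    for lab in labels:
        counts = np.asarray(rows[lab], dtype=float)
        ravg = _running_average(times, counts, window_ps)
        out.append(
            pd.DataFrame(
                {"time_ps": times, "species": lab, "count": rows[lab], "running_avg": ravg}
            )
        )
    return pd.concat(out, ignore_index=True)


def _running_average(times, values, window_ps):
    """Trailing-window mean (inclusive of the current frame)."""
    out = np.empty_like(values, dtype=float)
    start = 0
    csum = np.concatenate(([0.0], np.cumsum(values)))
    for i, t in enumerate(times):
        while times[start] < t - window_ps:
            start += 1
        out[i] = (csum[i + 1] - csum[start]) / (i + 1 - start)
    return out
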