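"""Single-channel conductance and selectivity from G(z) and D(z) profiles.

In the 1-D Smoluchowski (diffusive) picture of permeation, the
conductance of a pore of effective cross-section S bathed in a symmetric
electrolyte of concentration C is

    γ = q²·C·S / (k_B T) · [ ∫_{Z1}^{Z2} exp(G(z)/k_B T) / D(z) dz ]⁻¹,

where q is the permeant charge, G(z) its potential of mean force
(anchored to zero in bulk) and D(z) its position-dependent diffusion
coefficient.  For flat profiles this reduces to the closed form
γ = q²·C·S·D/(k_B T·L), which the unit conversion is validated against:
the same expression is evaluated both in the package's Å/ps/kcal-mol
units and entirely in SI, and the two must agree to rounding error.

Selectivity between two ions is the pointwise PMF difference
ΔG(z) = G_a(z) − G_b(z).  Uncertainty follows the difference-of-halves
convention: bands are re-evaluations at G ± err, not Gaussian
propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .constants import (
    E_CHARGE_C,
    KCAL_MOL_J,
    PER_A3_PER_MM,
    PS_PER_E2_PER_KCALMOL_PS,
    kbt,
)
from .profiles import Profile1D, common_grid


@dataclass(frozen=True)
class ConductanceParams:
    """Inputs of the conductance integral.

    q in elementary charges, C in mM, S in Å², T in K, Z1 < Z2 in Å.
    """

    q: float = 1.0
    C_mM: float = 100.0
    S_A2: float = 201.0
    T: float = 298.0
    Z1: float = -15.0
    Z2: float = 15.0

    def __post_init__(self):
        if self.C_mM <= 0 or self.S_A2 <= 0 or self.T <= 0:
            raise ValueError("C, S and T must be positive")
        if self.Z1 >= self.Z2:
            raise ValueError("Z1 must be smaller than Z2")


def effective_cross_section(radius_A: float) -> float:
    """Effective lumen cross-section S = π·r² (Å²) from the confinement radius."""
    if radius_A <= 0:
        raise ValueError("radius must be positive")
    return float(np.pi * radius_A**2)


class ConductanceResult(NamedTuple):
    gamma_pS: float
    gamma_lo_pS: float | None   # from G + err (higher barriers)
    gamma_hi_pS: float | None   # from G − err
    integral_ps_per_A: float


def conductance(
    G: Profile1D,
    D: Profile1D,
    params: ConductanceParams,
    anchor_tolerance: float = 0.5,
    units: str = "internal",
) -> ConductanceResult:
    """Evaluate the Smoluchowski conductance (pS) with an error band.

    Both profiles are linearly interpolated onto their union grid over
    [Z1, Z2] and the integral is done by the trapezoidal rule.  D must be
    positive everywhere in range; a G profile whose mean over the 20% of
    the range nearest each end exceeds ``anchor_tolerance`` kcal/mol
    triggers a warning (the expression assumes bulk-anchored G).  If G
    carries an error band, the result includes γ recomputed at G ± err.
    """
    grid = common_grid(G, D, lo=params.Z1, hi=params.Z2)
    g = G.interp(grid)
    d = D.interp(grid)
    if np.any(d.values <= 0):
        raise ValueError("D(z) must be positive over the integration range")
    edge = max(2, int(0.2 * grid.size))
    bulk_mean = 0.5 * (abs(g.values[:edge].mean()) + abs(g.values[-edge:].mean()))
    if bulk_mean > anchor_tolerance:
        warnings.warn(
            f"G(z) does not look bulk-anchored (edge mean {bulk_mean:.2f} kcal/mol)",
            RuntimeWarning,
            stacklevel=2,
        )
    kT = kbt(params.T)

    def gamma_of(gvals):
        integral = np.trapezoid(np.exp(gvals / kT) / d.values, grid)
        if units == "internal":
            c_a3 = params.C_mM * PER_A3_PER_MM
            return (
                PS_PER_E2_PER_KCALMOL_PS * params.q**2 * c_a3 * params.S_A2 / (kT * integral),
                integral,
            )
        if units == "si":
            q_c = params.q * E_CHARGE_C
            c_m3 = params.C_mM * PER_A3_PER_MM * 1e30
            s_m2 = params.S_A2 * 1e-20
            kt_j = kT * KCAL_MOL_J  # same thermal energy, in joules
            integral_si = integral * 1e-12 / 1e-10  # ps/Å → s/m
            gamma_s = q_c**2 * c_m3 * s_m2 / (kt_j * integral_si)
            return gamma_s * 1e12, integral
        raise ValueError(f"unknown unit system {units!r}")

    gamma, integral = gamma_of(g.values)
    lo = hi = None
    if g.err is not None:
        lo = gamma_of(g.values + g.err)[0]
        hi = gamma_of(g.values - g.err)[0]
    return ConductanceResult(gamma, lo, hi, integral)


def selectivity_profile(G_a: Profile1D, G_b: Profile1D) -> Profile1D:
    """ΔG(z) = G_a − G_b on the overlap grid; errors combined in quadrature."""
    grid = common_grid(G_a, G_b)
    a = G_a.interp(grid)
    b = G_b.interp(grid)
    err = None
    if a.err is not None or b.err is not None:
        ea = a.err if a.err is not None else np.zeros_like(grid)
        eb = b.err if b.err is not None else np.zeros_like(grid)
        err = np.sqrt(ea**2 + eb**2)
    return Profile1D(grid, a.values - b.values, err, units=G_a.units)


class HalfSplitBand(NamedTuple):
    band: np.ndarray      # pointwise |half1 − half2|
    mean: float           # band averaged over the profile length


def half_split_error(profile_half1: Profile1D, profile_half2: Profile1D) -> HalfSplitBand:
    """Difference-of-halves error: pointwise band and its length average."""
    if profile_half1.z.shape != profile_half2.z.shape or not np.allclose(
        profile_half1.z, profile_half2.z
    ):
        raise ValueError("half-split profiles must share a common grid")
    band = np.abs(profile_half1.values - profile_half2.values)
    return HalfSplitBand(band=band, mean=float(band.mean()))
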