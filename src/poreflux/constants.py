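"""Physical constants and unit conversions.

Internal unit system: length in Å, time in ps, energy in kcal/mol,
temperature in K, charge in elementary charges.  These are the natural
units of the quantities the package manipulates (free-energy profiles in
kcal/mol, diffusion coefficients in Å²/ps, conductances in pS).
"""

from __future__ import annotations

import scipy.constants as _si

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_MOL_K: float = 1.987204e-3

#: kcal/mol expressed in joules (per molecule).
KCAL_MOL_J: float = _si.calorie * 1000.0 / _si.N_A

#: Elementary charge in coulombs.
E_CHARGE_C: float = _si.e

#: Avogadro's number (1/mol).
N_AVOGADRO: float = _si.N_A

#: Boltzmann constant in J/K (SI path of the conductance calculation).
KB_SI: float = _si.k

#: Conversion: number concentration in Å⁻³ per 1 mM of bulk concentration.
#: 1 mM = 1e-3 mol/L = 1e-3·N_A molecules per 1e27 Å³.
PER_A3_PER_MM: float = N_AVOGADRO * 1e-3 / 1e27

#: Conductance prefactor: e²/(kcal/mol · ps) expressed in picosiemens.
#: Appears in γ = q²·C·S/(k_B T) · [∫ e^{G/k_BT}/D dz]⁻¹ when q is in e,
#: C in Å⁻³, S in Å², G and k_BT in kcal/mol, D in Å²/ps and z in Å.
PS_PER_E2_PER_KCALMOL_PS: float = E_CHARGE_C**2 / (KCAL_MOL_J * 1e-12) * 1e12


def kbt(temperature: float) -> float:
    """k_B·T in kcal/mol for a temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_MOL_K * temperature
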