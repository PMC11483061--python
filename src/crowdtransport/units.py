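"""Internal unit system and physical constants.

Everything in the package is expressed in a single unit system:
lengths in Å, times in ns, viscosities in cP, temperatures in K,
pressures in bar, concentrations in g/L or mM.  The formulas mixing
SI constants (kB) with these observables are funnelled through the
converters below so there is exactly one place where powers of ten live.
"""

from __future__ import annotations

import math

#: Boltzmann constant, J/K (SI, 2019 exact).
KB_J_PER_K = 1.380649e-23

#: Number density of 1 Å⁻³ expressed in millimolar.
#: 1 Å⁻³ = 1e27 L⁻¹ = 1e27 / NA mol/L = 1.66054e6 mM.
INV_ANGSTROM3_TO_MM = 1.66054e6

#: m²/s  →  Å²/ns   (1 m² = 1e20 Å², 1 s = 1e9 ns)
M2_PER_S_TO_A2_PER_NS = 1.0e11

#: 1/s  →  1/ns
PER_S_TO_PER_NS = 1.0e-9

CP_TO_PA_S = 1.0e-3
ANGSTROM_TO_M = 1.0e-10
BAR_TO_PA = 1.0e5
NS_TO_S = 1.0e-9

#: Default absolute temperature, K.
T_DEFAULT = 298.0


def kBT(temperature: float) -> float:
    """Thermal energy in J at ``temperature`` kelvin."""
    return KB_J_PER_K * temperature


def translational_pbc_term(xi: float, eta_cp: float, box_l: float,
                           temperature: float) -> float:
    """kB·T·ξ / (6π η L) in Å²/ns for η in cP and L in Å."""
    d_si = kBT(temperature) * xi / (
        6.0 * math.pi * eta_cp * CP_TO_PA_S * box_l * ANGSTROM_TO_M)
    return d_si * M2_PER_S_TO_A2_PER_NS


def rotational_pbc_term(eta_cp: float, box_l: float,
                        temperature: float) -> float:
    """kB·T / (6 η L³) in ns⁻¹ for η in cP and L in Å."""
    dr_si = kBT(temperature) / (
        6.0 * eta_cp * CP_TO_PA_S * (box_l * ANGSTROM_TO_M) ** 3)
    return dr_si * PER_S_TO_PER_NS


def green_kubo_prefactor(volume_a3: float, temperature: float) -> float:
    """Convert ∫⟨P P⟩dτ in bar²·ns into a viscosity in cP.

    η[Pa·s] = (V/kBT) · I with V in m³ and I in Pa²·s; the combined
    conversion for V in Å³ and I in bar²·ns is V·1e-26/(kB·T) cP.
    """
    return volume_a3 * 1.0e-26 / kBT(temperature)


def stokes_einstein_radius_t(d_t: float, eta_cp: float,
                             temperature: float) -> float:
    """Translational hydrodynamic radius in Å from Dt [Å²/ns], η [cP]."""
    d_si = d_t / M2_PER_S_TO_A2_PER_NS
    r_m = kBT(temperature) / (6.0 * math.pi * eta_cp * CP_TO_PA_S * d_si)
    return r_m / ANGSTROM_TO_M


def stokes_einstein_radius_r(d_r: float, eta_cp: float,
                             temperature: float) -> float:
    """Rotational hydrodynamic radius in Å from Dr [ns⁻¹], η [cP]."""
    dr_si = d_r / PER_S_TO_PER_NS
    r3_m3 = kBT(temperature) / (8.0 * math.pi * eta_cp * CP_TO_PA_S * dr_si)
    return r3_m3 ** (1.0 / 3.0) / ANGSTROM_TO_M


def d_t_from_radius(rh_a: float, eta_cp: float, temperature: float) -> float:
    """Stokes-Einstein Dt [Å²/ns] of a sphere of radius Rh [Å]."""
    d_si = kBT(temperature) / (
        6.0 * math.pi * eta_cp * CP_TO_PA_S * rh_a * ANGSTROM_TO_M)
    return d_si * M2_PER_S_TO_A2_PER_NS


def d_r_from_radius(rh_a: float, eta_cp: float, temperature: float) -> float:
    """Stokes-Einstein-Debye Dr [ns⁻¹] of a sphere of radius Rh [Å]."""
    dr_si = kBT(temperature) / (
        8.0 * math.pi * eta_cp * CP_TO_PA_S * (rh_a * ANGSTROM_TO_M) ** 3)
    return dr_si * PER_S_TO_PER_NS
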