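"""Unit system and physical constants.

Internal unit system used throughout the package:

==========  =========================
quantity    unit
==========  =========================
length      angstrom (A)
time        femtosecond (fs)
mass        atomic mass unit (amu)
energy      kcal/mol  (user-facing)
charge      elementary charge (e)
==========  =========================

Dynamics is integrated in the *derived* energy unit amu*A^2/fs^2; the
single conversion factor ``KCAL_TO_INTERNAL`` maps kcal/mol onto it.
Spectra are reported in wavenumbers (cm^-1); the conversion
``nu_tilde = omega / (2 pi c)`` is applied only at module boundaries.

All constants are CODATA-2018 derived and centralized here so that no
other module hard-codes a conversion factor.
"""

from __future__ import annotations

import math

AVOGADRO = 6.02214076e23
#: J per kcal/mol (thermochemical calorie)
J_PER_KCALMOL = 4184.0 / AVOGADRO
#: kg per amu
KG_PER_AMU = 1.66053906892e-27
#: J per internal energy unit (amu * A^2 / fs^2)
J_PER_INTERNAL = KG_PER_AMU * 1e-20 / 1e-30

#: multiply an energy in kcal/mol by this to get amu*A^2/fs^2
KCAL_TO_INTERNAL = J_PER_KCALMOL / J_PER_INTERNAL
#: multiply an energy in amu*A^2/fs^2 by this to get kcal/mol
INTERNAL_TO_KCAL = 1.0 / KCAL_TO_INTERNAL

#: Boltzmann constant, kcal/mol/K
KB_KCALMOL = 1.380649e-23 / J_PER_KCALMOL
#: Planck constant (exact SI), J*s
PLANCK_H = 6.62607015e-34
#: reduced Planck constant, (kcal/mol)*fs
HBAR_KCALMOL_FS = PLANCK_H / (2.0 * math.pi) / J_PER_KCALMOL * 1e15
#: reduced Planck constant, internal units * fs
HBAR_INTERNAL = HBAR_KCALMOL_FS * KCAL_TO_INTERNAL

#: speed of light, cm/fs
C_CM_PER_FS = 2.99792458e-5

#: kcal per kJ (thermochemical)
KJ_TO_KCAL = 1.0 / 4.184


def omega_from_wavenumber(nu_tilde_cm1: float) -> float:
    """Angular frequency (rad/fs) from a wavenumber (cm^-1)."""
    return 2.0 * math.pi * C_CM_PER_FS * nu_tilde_cm1


def wavenumber_from_omega(omega_rad_fs: float) -> float:
    """Wavenumber (cm^-1) from an angular frequency (rad/fs)."""
    return omega_rad_fs / (2.0 * math.pi * C_CM_PER_FS)


def beta_kcalmol(temperature_K: float) -> float:
    """Inverse temperature 1/(kB T) in (kcal/mol)^-1."""
    return 1.0 / (KB_KCALMOL * temperature_K)


def beta_internal(temperature_K: float) -> float:
    """Inverse temperature in (amu*A^2/fs^2)^-1."""
    return beta_kcalmol(temperature_K) / KCAL_TO_INTERNAL


def beta_hbar_omega(nu_tilde_cm1: float, temperature_K: float) -> float:
    """The dimensionless quantum parameter beta*hbar*omega."""
    return beta_kcalmol(temperature_K) * HBAR_KCALMOL_FS * omega_from_wavenumber(
        nu_tilde_cm1
    )
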