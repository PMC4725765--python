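"""Physical constants and unit conversions.

Internal unit system: length nm, time ps, charge e, temperature K.
Spectra are reported in wavenumbers (cm^-1); wavevectors in nm^-1
(helpers provide A^-1 for plotting conventions).

All SI prefactors are computed here, once, so that no other module
hard-codes a unit conversion.
"""

from __future__ import annotations

import numpy as np

# SI (CODATA 2018, exact where so defined)
K_BOLTZMANN = 1.380649e-23  # J/K
EPSILON_0 = 8.8541878128e-12  # F/m
E_CHARGE = 1.602176634e-19  # C
C_LIGHT_CM_PS = 2.99792458e-2  # speed of light, cm/ps

# angular frequency (rad/ps) per wavenumber (cm^-1): omega = 2*pi*c*nu_tilde
WAVENUMBER_TO_RADPS = 2.0 * np.pi * C_LIGHT_CM_PS
RADPS_TO_WAVENUMBER = 1.0 / WAVENUMBER_TO_RADPS


def wavenumber_to_radps(nu_cm1):
    """cm^-1 -> rad/ps.  Converting 2*pi*c rad/ps yields exactly 1 cm^-1."""
    return np.asarray(nu_cm1, dtype=float) * WAVENUMBER_TO_RADPS


def radps_to_wavenumber(omega_radps):
    """rad/ps -> cm^-1."""
    return np.asarray(omega_radps, dtype=float) * RADPS_TO_WAVENUMBER


def tau_ps_to_gamma_cm1(tau_ps: float) -> float:
    """Lifetime tau (ps) -> damping gamma = 1/tau expressed in cm^-1."""
    if tau_ps <= 0:
        raise ValueError("tau must be positive")
    return float(RADPS_TO_WAVENUMBER / tau_ps)


def gamma_cm1_to_tau_ps(gamma_cm1: float) -> float:
    """Damping gamma (cm^-1) -> lifetime tau = 1/gamma in ps."""
    if gamma_cm1 <= 0:
        raise ValueError("gamma must be positive")
    return float(RADPS_TO_WAVENUMBER / gamma_cm1)


def nm_inv_to_angstrom_inv(k_nm: float) -> float:
    """Wavevector nm^-1 -> A^-1."""
    return k_nm * 0.1


def susceptibility_prefactor(volume_nm3: float, temperature_K: float) -> float:
    """Prefactor 1/(eps0 V kB T) in units of 1/(e^2 nm^2).

    Multiplying a mean-square polarization amplitude <|P(k)|^2> in e^2 nm^2
    by this factor yields the dimensionless static susceptibility.
    """
    if volume_nm3 <= 0 or temperature_K <= 0:
        raise ValueError("volume and temperature must be positive")
    joule = EPSILON_0 * (volume_nm3 * 1e-27) * K_BOLTZMANN * temperature_K
    return E_CHARGE**2 * 1e-18 / joule


# group velocity: slope d(nu_tilde)/dk in cm^-1 * nm  ->  m/s
# omega[rad/s] = 2*pi*c[cm/s]*nu_tilde,  k[1/m] = k[1/nm]*1e9
SLOPE_CM1_NM_TO_M_S = 2.0 * np.pi * 2.99792458e10 * 1e-9
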