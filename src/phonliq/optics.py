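"""Longitudinal and transverse responses from optical constants.

At k -> 0 the dielectric function follows from the measured refractive
index and extinction coefficient, eps = (n + i k)^2, and the two
susceptibility components are

    chi_T = eps - 1          (what is conventionally called "the"
                              susceptibility; peaks mark TO modes)
    chi_L = 1 - 1/eps        (Im chi_L = eps''/|eps|^2; peaks mark LO modes)

so a single table of n(w), k(w) yields both the transverse and the
longitudinal band positions, hence the LO-TO splitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import OpticalConstantsTable

__all__ = [
    "eps_from_nk",
    "chi_T_from_eps",
    "chi_L_from_eps",
    "band_peak_frequencies",
    "optics_table",
    "PeakReport",
]

LIBRATIONAL_BAND = (300.0, 1000.0)  # cm^-1
OH_STRETCH_BAND = (2800.0, 3800.0)  # cm^-1


def eps_from_nk(table: OpticalConstantsTable) -> np.ndarray:
    """Complex dielectric function eps = (n + ik)^2 on the table's grid."""
    return (table.n + 1j * table.k) ** 2


def chi_T_from_eps(eps) -> np.ndarray:
    """Transverse susceptibility chi_T = eps - 1."""
    return np.asarray(eps, dtype=complex) - 1.0


def chi_L_from_eps(eps) -> np.ndarray:
    """Longitudinal susceptibility chi_L = 1 - 1/eps (requires eps != 0)."""
    eps = np.asarray(eps, dtype=complex)
    if np.any(np.abs(eps) < 1e-12):
        raise ValueError("eps vanishes on the grid; chi_L undefined")
    return 1.0 - 1.0 / eps


def _refine_peak(w: np.ndarray, y: np.ndarray, i: int) -> float:
    """3-point quadratic interpolation of the maximum around grid index i."""
    if i == 0 or i == w.size - 1:
        return float(w[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(w[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(w[i] + delta * (w[i + 1] - w[i]))


def band_peak_frequencies(
    wavenumber: np.ndarray,
    im_chi_T: np.ndarray,
    im_chi_L: np.ndarray,
    band: tuple[float, float] = LIBRATIONAL_BAND,
) -> tuple[float, float]:
    """(w_TO, w_LO): windowed argmax of Im chi_T and Im chi_L with 3-point
    quadratic refinement.  Raises if a spectrum is monotone in the window
    (no interior local maximum)."""
    w = np.asarray(wavenumber, dtype=float)
    sel = (w >= band[0]) & (w <= band[1])
    if sel.sum() < 3:
        raise ValueError("band window contains fewer than 3 grid points")
    out = []
    for y in (np.asarray(im_chi_T, float), np.asarray(im_chi_L, float)):
        yb, wb = y[sel], w[sel]
        i = int(np.argmax(yb))
        if i == 0 or i == yb.size - 1:
            raise ValueError("spectrum is monotone in the band window")
        out.append(_refine_peak(wb, yb, i))
    return out[0], out[1]


@dataclass
class PeakReport:
    """LO/TO band maxima extracted from one optical-constants table."""

    band: tuple[float, float]
    omega_to_cm1: float
    omega_lo_cm1: float

    @property
    def splitting_cm1(self) -> float:
        return self.omega_lo_cm1 - self.omega_to_cm1


def optics_table(table: OpticalConstantsTable) -> pd.DataFrame:
    """Full conversion table: eps, Im chi_T, Im chi_L per grid point."""
    eps = eps_from_nk(table)
    chi_t = chi_T_from_eps(eps)
    chi_l = chi_L_from_eps(eps)
    return pd.DataFrame(
        {
            "wavenumber_cm1": table.wavenumber,
            "eps_re": eps.real,
            "eps_im": eps.imag,
            "chiT_im": chi_t.imag,
            "chiL_im": chi_l.imag,
        }
    )
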