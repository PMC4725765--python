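"""Polarization time-correlation functions and Kubo susceptibility spectra.

The normalized correlation function of a polarization component P(k, t),

    phi(k, t) = <P*(k, 0) P(k, t)> / <|P(k, 0)|^2>,

is estimated with the stationary (all time origins) estimator, computed by
FFT, then averaged over the wavevectors of one |k| shell; the transverse
case additionally averages its two components.  The classical Kubo formula
turns phi into the frequency-dependent susceptibility

    chi(k, w) = chi(k, 0) [1 + i w  int_0^inf phi(k, t) e^{i w t} dt],

with static values chi_L(k,0) = C0 / (eps0 V kB T) and
chi_T(k,0) = C0 / (2 eps0 V kB T) (C0 summed over the two transverse
components; the factor 1/2 expresses isotropy).

The one-sided Fourier transform is evaluated by trapezoidal quadrature with
an optional Hann taper on the final 10% of lags, and an optional
exponential tail extension when phi has not decayed below 0.02 at the last
lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import susceptibility_prefactor, wavenumber_to_radps
from .polarization import PolarizationSeries

__all__ = [
    "CorrelationFunction",
    "SusceptibilitySpectrum",
    "correlation_function",
    "static_susceptibility",
    "susceptibility_spectrum",
    "default_frequency_grid",
    "autocorrelation_fft",
    "kramers_kronig_real",
]

DECAY_THRESHOLD = 0.02


@dataclass
class CorrelationFunction:
    """Normalized, shell-averaged polarization correlation function."""

    component: str  # "L" or "T"
    k_mag: float  # nm^-1
    lags: np.ndarray  # ps, uniform spacing dt_out
    phi: np.ndarray  # dimensionless, phi[0] == 1
    amplitude: float  # C(k, 0) = <|P|^2>, e^2 nm^2 (T: summed over comps)
    metadata: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class SusceptibilitySpectrum:
    """Complex susceptibility chi(k, w) on a wavenumber grid."""

    component: str
    k_mag: float
    wavenumber: np.ndarray  # cm^-1
    chi: np.ndarray  # complex, dimensionless
    chi0: float
    metadata: dict = field(default_factory=dict)

    @property
    def im(self) -> np.ndarray:
        return self.chi.imag


def autocorrelation_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Stationary autocorrelation  ac[t] = mean_t0 x*(t0) x(t0+t), t<=max_lag.

    FFT-based; identical to the direct O(N^2) sum to roundoff.
    """
    x = np.asarray(x)
    n = x.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    X = np.fft.fft(x, n=nfft, axis=-1)
    ac = np.fft.ifft(np.conj(X) * X, axis=-1)[..., : max_lag + 1]
    counts = n - np.arange(max_lag + 1)
    return ac / counts


def correlation_function(
    series: PolarizationSeries,
    shell,
    component: str = "L",
    max_lag: float | None = None,
) -> CorrelationFunction:
    """Shell-averaged normalized correlation function of one component.

    shell: shell index (int) or |k| magnitude in nm^-1 (float).
    max_lag: maximum lag in ps; clamped (with a warning) to 25% of the
    trajectory length, the regime where the stationary estimator is
    reliable.
    """
    if component not in ("L", "T"):
        raise ValueError("component must be 'L' or 'T'")
    kset = series.kset
    ishell = (
        int(shell) if isinstance(shell, (int, np.integer)) else kset.shell_index(shell)
    )
    members = kset.shells[ishell]
    if len(members) == 0:
        raise ValueError("empty wavevector shell")
    n_t = series.n_frames
    if n_t < 2:
        raise ValueError("need at least 2 frames")
    dt = series.dt_out
    hard_cap = 0.25 * n_t * dt
    if max_lag is None:
        max_lag = hard_cap
    if max_lag > hard_cap:
        warnings.warn(
            f"max_lag {max_lag:.3g} ps exceeds 25% of the trajectory; "
            f"clamped to {hard_cap:.3g} ps",
            stacklevel=2,
        )
        max_lag = hard_cap
    n_lag = max(1, int(round(max_lag / dt)))
    n_lag = min(n_lag, n_t - 1)

    if component == "L":
        data = series.PL[members]  # (m, n_t)
    else:
        data = series.PT[members].reshape(-1, n_t)  # (2m, n_t)
    ac = autocorrelation_fft(data, n_lag)  # (rows, n_lag+1)
    c_mean = ac.mean(axis=0)
    c0 = float(c_mean[0].real)
    if component == "T":
        amplitude = 2.0 * c0  # summed over both transverse components
    else:
        amplitude = c0
    phi = c_mean.real / c0
    lags = np.arange(n_lag + 1) * dt
    return CorrelationFunction(
        component=component,
        k_mag=float(kset.shell_magnitudes[ishell]),
        lags=lags,
        phi=phi,
        amplitude=amplitude,
        metadata={"n_vectors": len(members), "n_frames": n_t},
    )


def static_susceptibility(
    amplitude: float, component: str, volume_nm3: float, temperature_K: float
) -> float:
    """Static susceptibility from the mean-square polarization amplitude.

    chi_L(k,0) = C0/(eps0 V kB T); chi_T(k,0) = C0/(2 eps0 V kB T) with C0
    summed over both transverse components (isotropy).
    """
    pref = susceptibility_prefactor(volume_nm3, temperature_K)
    if component == "L":
        return amplitude * pref
    if component == "T":
        return 0.5 * amplitude * pref
    raise ValueError("component must be 'L' or 'T'")


def default_frequency_grid(
    max_cm1: float = 4000.0, spacing_cm1: float = 2.0
) -> np.ndarray:
    """Default reporting grid, 0-4000 cm^-1 at 2 cm^-1 spacing."""
    return np.arange(0.0, max_cm1 + 0.5 * spacing_cm1, spacing_cm1)


def _exponential_tail(phi: np.ndarray, dt: float):
    """Fit A exp(-t/tau) to the final 20% of lags (positive values only)."""
    n = phi.size
    i0 = max(n - max(n // 5, 4), 1)
    seg = phi[i0:]
    t = np.arange(i0, n) * dt
    pos = seg > 0
    if pos.sum() < 3:
        return None
    coef = np.polyfit(t[pos], np.log(seg[pos]), 1)
    rate = -coef[0]
    if rate <= 0:
        return None
    return float(np.exp(coef[1])), float(1.0 / rate)  # A, tau


def susceptibility_spectrum(
    corr: CorrelationFunction,
    chi0: float,
    grid_cm1: np.ndarray | None = None,
    taper: bool = True,
    extend_tail: bool = True,
) -> SusceptibilitySpectrum:
    """Kubo-formula spectrum chi(k, w) = chi0 [1 + i w  F[phi](w)].

    F is the one-sided Fourier transform over the available lags
    (trapezoidal rule, optional Hann half-taper over the final 10% of
    lags).  If phi has not decayed below 0.02 at the last lag, an
    exponential tail fitted to the final lags is integrated analytically;
    with extend_tail=False the undecayed tail is only recorded as a
    metadata warning.
    """
    if grid_cm1 is None:
        grid_cm1 = default_frequency_grid()
    grid_cm1 = np.asarray(grid_cm1, dtype=float)
    omega = wavenumber_to_radps(grid_cm1)  # rad/ps
    phi = corr.phi.astype(float).copy()
    t = corr.lags
    meta = dict(corr.metadata)
    tail = None
    if abs(phi[-1]) > DECAY_THRESHOLD:
        if extend_tail:
            tail = _exponential_tail(phi, corr.dt)
            meta["tail_extension"] = tail
            if tail is None:
                meta["warning"] = "undecayed phi; tail fit failed"
        else:
            meta["warning"] = "phi not decayed below 0.02 at max lag"
            warnings.warn(meta["warning"], stacklevel=2)
    w = np.ones_like(phi)
    if taper:
        n_tap = max(int(0.1 * phi.size), 2)
        ramp = 0.5 * (1.0 + np.cos(np.pi * np.arange(n_tap) / n_tap))
        w[-n_tap:] = ramp
        if tail is not None:
            w = np.ones_like(phi)  # taper would bias the matched tail
    # trapezoidal one-sided transform for all frequencies at once
    kernel = np.exp(1j * np.outer(omega, t))  # (n_w, n_t)
    wt = w * phi
    trap = np.trapezoid(kernel * wt[None, :], t, axis=1)
    ft = trap
    if tail is not None:
        A, tau = tail
        T_end = t[-1]
        ft = ft + A * np.exp(-T_end / tau) * np.exp(1j * omega * T_end) * tau / (
            1.0 - 1j * omega * tau
        )
    chi = chi0 * (1.0 + 1j * omega * ft)
    return SusceptibilitySpectrum(
        component=corr.component,
        k_mag=corr.k_mag,
        wavenumber=grid_cm1,
        chi=chi,
        chi0=float(chi0),
        metadata=meta,
    )


def kramers_kronig_real(wavenumber: np.ndarray, im_chi: np.ndarray) -> np.ndarray:
    """Re chi reconstructed from Im chi by the Kramers-Kronig relation.

    Principal-value integral (2/pi) P int_0^inf w' Im chi(w') / (w'^2 - w^2)
    dw' on the sampled grid, excluding the singular point.  A consistency
    diagnostic for well-resolved spectra, not a production transform.
    """
    w = np.asarray(wavenumber, dtype=float)
    im = np.asarray(im_chi, dtype=float)
    re = np.empty_like(im)
    for i, wi in enumerate(w):
        denom = w**2 - wi**2
        integrand = np.where(np.abs(denom) > 1e-12, w * im / np.where(denom == 0, 1, denom), 0.0)
        re[i] = 2.0 / np.pi * np.trapezoid(integrand, w)
    return re
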