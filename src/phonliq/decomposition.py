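"""Distance-decomposed correlation functions and spectra.

The collective correlation function is a double sum over molecules,
C(k,t) = < sum_i p_i*(k,0) sum_j p_j(k,t) >.  Restricting the second sum to
molecules within a radius R of molecule i at the lag origin,

    C(k,t;R) = < sum_i p_i*(k,0) sum_{j: |r_ij(0)| <= R} p_j(k,t) >,

interpolates between the self-only response (R below the nearest-neighbour
distance) and the full response (R = sqrt(3) L / 2, the largest
minimum-image distance), revealing the spatial range of collective modes.
Sphere membership is frozen at the lag origin; distances are between
molecular reference points under the minimum-image convention.

All family members are normalized by the full C(k,0) so they converge
toward the full normalized correlation function as R grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import wavenumber_to_radps
from .polarization import PolarizationSeries
from .response import CorrelationFunction, autocorrelation_fft

__all__ = [
    "DecomposedSpectrumFamily",
    "decomposed_correlation",
    "self_distinct_split",
    "decomposed_spectra",
    "gaussian_smooth",
]

_COMP_ROWS = {"L": (0,), "T": (1, 2)}


def _molecular_series(series: PolarizationSeries, members, component):
    """Per-molecule scalar series for every (shell member, component row)."""
    rows = _COMP_ROWS[component]
    out = []
    for ik in members:
        if ik not in series.mol_proj:
            raise ValueError(
                f"per-molecule polarization missing for k index {ik}; "
                "recompute with keep_molecular"
            )
        for r in rows:
            out.append(series.mol_proj[ik][r])  # (n_mol, n_t)
    return out


def _origin_positions(series: PolarizationSeries):
    ref = series.ref_positions
    if ref is None:
        raise ValueError("series carries no molecular reference positions")
    return ref


def _pair_distances(pos, box_edge):
    d = pos[:, None, :] - pos[None, :, :]
    d -= box_edge * np.round(d / box_edge)
    return np.linalg.norm(d, axis=-1)


def _masked_correlation_static(A, mask, n_lag):
    """mean_t0 sum_i A_i*(t0) (mask @ A)_i(t0+t) for a static mask."""
    G = mask.astype(float) @ A  # (n_mol, n_t)
    n = A.shape[1]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    FA = np.fft.fft(A, n=nfft, axis=1)
    FG = np.fft.fft(G, n=nfft, axis=1)
    cross = np.fft.ifft(np.conj(FA) * FG, axis=1)[:, : n_lag + 1].sum(axis=0)
    counts = n - np.arange(n_lag + 1)
    return cross / counts


def _masked_correlation_moving(A, positions, box_edge, radius, n_lag, stride):
    """Per-origin sphere membership for trajectories with moving molecules."""
    n_mol, n_t = A.shape
    acc = np.zeros(n_lag + 1, dtype=complex)
    counts = np.zeros(n_lag + 1)
    for t0 in range(0, n_t, stride):
        mask = _pair_distances(positions[t0], box_edge) <= radius
        lag_max = min(n_lag, n_t - 1 - t0)
        G = mask.astype(float) @ A[:, t0 : t0 + lag_max + 1]
        acc[: lag_max + 1] += np.conj(A[:, t0]) @ G
        counts[: lag_max + 1] += 1
    return acc / np.maximum(counts, 1)


def decomposed_correlation(
    series: PolarizationSeries,
    shell,
    radii,
    component: str = "L",
    max_lag: float | None = None,
    origin_stride: int = 1,
) -> list[CorrelationFunction]:
    """Distance-restricted correlation functions, one per radius.

    radii: ascending radii in nm; values above sqrt(3) L / 2 are clamped
    (with a warning) since no minimum-image pair is farther apart.  Each
    member's phi is normalized by the full C(k,0), so the largest-radius
    member converges to the full normalized correlation function.
    """
    if component not in _COMP_ROWS:
        raise ValueError("component must be 'L' or 'T'")
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly ascending")
    r_cap = np.sqrt(3.0) * series.box_edge / 2.0
    if radii and radii[-1] > r_cap * (1 + 1e-12):
        warnings.warn(
            f"radii above sqrt(3)L/2 = {r_cap:.4g} nm clamped", stacklevel=2
        )
        radii = [min(r, r_cap) for r in radii]

    kset = series.kset
    ishell = (
        int(shell) if isinstance(shell, (int, np.integer)) else kset.shell_index(shell)
    )
    members = kset.shells[ishell]
    A_list = _molecular_series(series, members, component)
    n_t = A_list[0].shape[1]
    dt = series.dt_out
    hard_cap = 0.25 * n_t * dt
    if max_lag is None or max_lag > hard_cap:
        if max_lag is not None:
            warnings.warn("max_lag clamped to 25% of trajectory", stacklevel=2)
        max_lag = hard_cap
    n_lag = min(max(1, int(round(max_lag / dt))), n_t - 1)

    pos = _origin_positions(series)
    static = pos.ndim == 2

    # full response: identical estimator path as correlation_function
    full = np.mean(
        [autocorrelation_fft(A.sum(axis=0), n_lag) for A in A_list], axis=0
    )
    c0_full = float(full[0].real)

    out = []
    lags = np.arange(n_lag + 1) * dt
    for radius in radii:
        if static and radius >= r_cap * (1 - 1e-12):
            c_r = full  # every pair included: reuse the full estimator
        elif static:
            mask = _pair_distances(pos, series.box_edge) <= radius
            c_r = np.mean(
                [_masked_correlation_static(A, mask, n_lag) for A in A_list], axis=0
            )
        else:
            c_r = np.mean(
                [
                    _masked_correlation_moving(
                        A, pos, series.box_edge, radius, n_lag, origin_stride
                    )
                    for A in A_list
                ],
                axis=0,
            )
        out.append(
            CorrelationFunction(
                component=component,
                k_mag=float(kset.shell_magnitudes[ishell]),
                lags=lags,
                phi=c_r.real / c0_full,
                amplitude=c0_full * (2.0 if component == "T" else 1.0),
                metadata={"radius_nm": float(radius), "normalization": "full_C0"},
            )
        )
    return out


def self_distinct_split(
    series: PolarizationSeries,
    shell,
    component: str = "L",
    max_lag: float | None = None,
) -> tuple[CorrelationFunction, CorrelationFunction]:
    """(self, distinct) correlation functions; self + distinct = full exactly.

    Both are normalized by the full C(k,0), so the self member's phi(0) is
    the self fraction of the static amplitude.
    """
    if component not in _COMP_ROWS:
        raise ValueError("component must be 'L' or 'T'")
    kset = series.kset
    ishell = (
        int(shell) if isinstance(shell, (int, np.integer)) else kset.shell_index(shell)
    )
    members = kset.shells[ishell]
    A_list = _molecular_series(series, members, component)
    n_t = A_list[0].shape[1]
    dt = series.dt_out
    cap = 0.25 * n_t * dt
    if max_lag is None or max_lag > cap:
        max_lag = cap
    n_lag = min(max(1, int(round(max_lag / dt))), n_t - 1)
    full = np.mean(
        [autocorrelation_fft(A.sum(axis=0), n_lag) for A in A_list], axis=0
    )
    self_part = np.mean(
        [autocorrelation_fft(A, n_lag).sum(axis=0) for A in A_list], axis=0
    )
    c0 = float(full[0].real)
    lags = np.arange(n_lag + 1) * dt
    k_mag = float(kset.shell_magnitudes[ishell])
    mk = {"normalization": "full_C0"}
    mk_self = dict(mk, part="self")
    mk_dist = dict(mk, part="distinct")
    amp = c0 * (2.0 if component == "T" else 1.0)
    return (
        CorrelationFunction(component, k_mag, lags, self_part.real / c0, amp, mk_self),
        CorrelationFunction(
            component, k_mag, lags, (full - self_part).real / c0, amp, mk_dist
        ),
    )


@dataclass
class DecomposedSpectrumFamily:
    """Im chi(k, w; R) for an ascending family of radii plus the self term.

    All members share one frequency grid and the full response's static
    normalization; the largest-radius member equals the undecomposed
    spectrum.
    """

    component: str
    k_mag: float
    wavenumber: np.ndarray
    radii: np.ndarray
    chi: np.ndarray  # (n_R, n_w) complex
    chi_self: np.ndarray
    chi_full: np.ndarray
    metadata: dict = field(default_factory=dict)


def _unnormalized_spectrum(corr: CorrelationFunction, chi0_full, grid_cm1, taper=True):
    """Kubo transform for a family member: chi0_full*(phi(0) + i w F[phi])."""
    omega = wavenumber_to_radps(grid_cm1)
    phi, t = corr.phi, corr.lags
    w = np.ones_like(phi)
    if taper:
        n_tap = max(int(0.1 * phi.size), 2)
        w[-n_tap:] = 0.5 * (1.0 + np.cos(np.pi * np.arange(n_tap) / n_tap))
    kernel = np.exp(1j * np.outer(omega, t))
    ft = np.trapezoid(kernel * (w * phi)[None, :], t, axis=1)
    return chi0_full * (phi[0] + 1j * omega * ft)


def decomposed_spectra(
    series: PolarizationSeries,
    shell,
    radii,
    chi0_full: float,
    component: str = "L",
    grid_cm1: np.ndarray | None = None,
    max_lag: float | None = None,
    origin_stride: int = 1,
) -> DecomposedSpectrumFamily:
    """Distance-decomposed susceptibility spectra on a common grid.

    chi0_full: static susceptibility of the full (undecomposed) response,
    from :func:`phonliq.response.static_susceptibility`.
    """
    from .response import default_frequency_grid

    if grid_cm1 is None:
        grid_cm1 = default_frequency_grid()
    fam = decomposed_correlation(
        series, shell, radii, component, max_lag, origin_stride
    )
    self_c, dist_c = self_distinct_split(series, shell, component, max_lag)
    full_c = CorrelationFunction(
        component=self_c.component,
        k_mag=self_c.k_mag,
        lags=self_c.lags,
        phi=self_c.phi + dist_c.phi,
        amplitude=self_c.amplitude,
        metadata={"normalization": "full_C0", "part": "full"},
    )
    chi = np.stack([_unnormalized_spectrum(c, chi0_full, grid_cm1) for c in fam])
    chi_self = _unnormalized_spectrum(self_c, chi0_full, grid_cm1)
    chi_full = _unnormalized_spectrum(full_c, chi0_full, grid_cm1)
    return DecomposedSpectrumFamily(
        component=component,
        k_mag=fam[0].k_mag,
        wavenumber=np.asarray(grid_cm1, float),
        radii=np.array([c.metadata["radius_nm"] for c in fam]),
        chi=chi,
        chi_self=chi_self,
        chi_full=chi_full,
        metadata={"chi0_full": float(chi0_full)},
    )


def gaussian_smooth(y: np.ndarray, grid_spacing_cm1: float, sigma_cm1: float = 10.0):
    """Gaussian smoothing for plotting only — never for fitted quantities."""
    return gaussian_filter1d(np.asarray(y, float), sigma_cm1 / grid_spacing_cm1)
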