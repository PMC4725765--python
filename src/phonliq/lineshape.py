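"""Debye + damped-resonance fits of Im chi(k, w) and derived mode properties.

The librational band of a polar liquid overlaps a Debye relaxation wing, so
the imaginary susceptibility is fit with

    Im chi(w) = dchi * w tau_D / (1 + w^2 tau_D^2)                (Debye)
             + (A/2) w [ gamma/((w-w0)^2+gamma^2)
                       + gamma/((w+w0)^2+gamma^2) ]               (VVW)

where the resonance term is the Van Vleck-Weisskopf lineshape with
resonance frequency w0 and damping gamma = 1/tau (both cm^-1); in the
underdamped regime it is numerically indistinguishable from the standard
damped harmonic oscillator with full friction 2*gamma.  An optional second
resonance accommodates the hydrogen-bond-stretch band.

From fits across a set of wavevectors the module extracts the dispersion
relation w0(k), its slope (the group velocity), the LO-TO splitting at the
smallest k, the propagation range R = tau * v_g, and a generalized
Lyddane-Sachs-Teller consistency report in which longitudinal frequencies
of damped modes enter through their complex modulus |w_L|^2 = w_L^2 +
gamma_L^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    RADPS_TO_WAVENUMBER,
    SLOPE_CM1_NM_TO_M_S,
    wavenumber_to_radps,
)
from .response import SusceptibilitySpectrum

__all__ = [
    "LineshapeFit",
    "DispersionResult",
    "debye_im",
    "vvw_im",
    "fit_band",
    "dispersion",
    "lo_to_splitting",
    "propagation_range",
    "round_one_sig",
    "lst_check",
    "LSTReport",
]


def debye_im(w_cm1, dchi: float, tau_d_ps: float):
    """Imaginary part of a Debye relaxation, dchi * w tau/(1 + w^2 tau^2).

    Maximum dchi/2 at w = 1/tau_d.  w in cm^-1, tau_d in ps.
    """
    if tau_d_ps <= 0:
        raise ValueError("tau_d must be positive")
    x = wavenumber_to_radps(w_cm1) * tau_d_ps
    return dchi * x / (1.0 + x * x)


def vvw_im(w_cm1, A: float, w0_cm1: float, gamma_cm1: float):
    """Van Vleck-Weisskopf imaginary lineshape (all frequencies in cm^-1).

    A is the zero-frequency real weight up to O(gamma/w0); gamma is the
    half-width (gamma = 1/tau).
    """
    if w0_cm1 <= 0 or gamma_cm1 <= 0:
        raise ValueError("w0 and gamma must be positive")
    w = np.asarray(w_cm1, dtype=float)
    g = gamma_cm1
    return (
        0.5
        * A
        * w
        * (g / ((w - w0_cm1) ** 2 + g * g) + g / ((w + w0_cm1) ** 2 + g * g))
    )


@dataclass
class LineshapeFit:
    """Result of a Debye+resonance fit of one Im chi(k, w)."""

    component: str
    k_mag: float  # nm^-1
    debye_dchi: float
    debye_tau_ps: float
    resonances: list[tuple[float, float, float]]  # (A, w0 cm^-1, gamma cm^-1)
    residual_rms: float
    covariance: np.ndarray | None
    param_names: list[str]
    success: bool
    metadata: dict = field(default_factory=dict)

    @property
    def omega0(self) -> float:
        """Resonance frequency of the primary band (cm^-1)."""
        return self.resonances[0][1]

    @property
    def gamma(self) -> float:
        """Damping of the primary band (cm^-1)."""
        return self.resonances[0][2]

    @property
    def tau_ps(self) -> float:
        """Lifetime 1/gamma in ps."""
        return RADPS_TO_WAVENUMBER / self.gamma

    @property
    def underdamped(self) -> bool:
        return self.gamma < self.omega0

    def gamma_rel_uncertainty(self) -> float:
        """Relative 1-sigma uncertainty of the primary gamma, inf if unknown."""
        if self.covariance is None:
            return np.inf
        i = self.param_names.index("gamma1")
        return float(np.sqrt(self.covariance[i, i]) / max(self.gamma, 1e-30))


def _model(params, w, n_res):
    dchi, tau = params[0], params[1]
    out = debye_im(w, dchi, max(tau, 1e-12))
    for j in range(n_res):
        A, w0, g = params[2 + 3 * j : 5 + 3 * j]
        out = out + vvw_im(w, A, max(w0, 1e-9), max(g, 1e-9))
    return out


def _initial_guess(w, im, n_res, floor_cm1=100.0):
    """Deterministic, seedless initialization: w0 at the band argmax, gamma
    from the half-width, Debye tau from the low-frequency wing."""
    sel = w >= min(floor_cm1, 0.5 * w.max())
    wb, ib = w[sel], im[sel]
    i_pk = int(np.argmax(ib))
    w0 = float(wb[i_pk])
    half = 0.5 * ib[i_pk]
    above = np.nonzero(ib >= half)[0]
    g = max(0.5 * (wb[above[-1]] - wb[above[0]]), w[1] - w[0]) if above.size > 1 else 10.0
    A = float(ib[i_pk] * 2.0 * g / w0)
    # low-frequency wing: Im ~ dchi * w tau  =>  slope gives dchi*tau
    wing = w < 0.5 * w0
    tau0 = 1.0
    dchi0 = 0.0
    if wing.sum() >= 2:
        w_w = w[wing][1:]
        resid = im[wing][1:] - vvw_im(w_w, A, w0, g)
        resid = np.clip(resid, 0.0, None)
        if resid.max() > 0:
            i_dm = int(np.argmax(resid))
            w_dm = max(w_w[i_dm], w[1] - w[0])
            tau0 = RADPS_TO_WAVENUMBER / w_dm
            dchi0 = 2.0 * resid[i_dm]
    return np.array([max(dchi0, 1e-6), tau0, A, w0, g])


def fit_band(
    spectrum: SusceptibilitySpectrum,
    model: str = "debye+1res",
    band: tuple[float, float] | None = None,
    init: np.ndarray | dict | None = None,
) -> LineshapeFit:
    """Nonlinear least-squares fit of Im chi with a Debye + resonance model.

    model: "debye+1res" or "debye+2res".  band: optional (wmin, wmax)
    window in cm^-1 restricting the fit.  init: optional full parameter
    vector [dchi, tau_d, A1, w01, g1, (A2, w02, g2)] or dict overriding
    individual named parameters.  Bounded (all parameters >= 0)
    trust-region least squares; deterministic for identical inputs.
    """
    n_res = {"debye+1res": 1, "debye+2res": 2}.get(model)
    if n_res is None:
        raise ValueError(f"unknown model {model!r}")
    w = spectrum.wavenumber
    im = spectrum.im
    mask = w > 0
    if band is not None:
        mask &= (w >= band[0]) & (w <= band[1])
    w_fit, im_fit = w[mask], im[mask]
    if w_fit.size < 5 + 3 * n_res:
        raise ValueError("too few frequency points in fit window")
    p0 = _initial_guess(w_fit, im_fit, n_res)
    names = ["dchi", "tau_d", "A1", "w01", "gamma1"]
    if n_res == 2:
        # staged initialization: converge the 1-resonance model, then seed
        # the second resonance at the residual's peak away from the first
        one = fit_band(spectrum, model="debye+1res", band=band)
        A1, w01, g1 = one.resonances[0]
        resid = im_fit - _model(
            [one.debye_dchi, one.debye_tau_ps, A1, w01, g1], w_fit, 1
        )
        away = np.abs(w_fit - w01) > 2.0 * g1
        if away.sum() > 3 and resid[away].max() > 0:
            i2 = int(np.argmax(resid[away]))
            w02 = float(w_fit[away][i2])
            A2 = float(resid[away][i2] * 2.0 * g1 / max(w02, 1.0))
        else:
            w02, A2 = 0.3 * w01, 0.2 * A1
        p0 = np.array(
            [one.debye_dchi, one.debye_tau_ps, A1, w01, g1,
             max(A2, 1e-6), max(w02, 10.0), g1]
        )
        names += ["A2", "w02", "gamma2"]
    if isinstance(init, dict):
        for key, val in init.items():
            p0[names.index(key)] = val
    elif init is not None:
        p0 = np.asarray(init, dtype=float)

    lower = np.full(p0.size, 0.0)
    lower[1] = 1e-6  # tau_d
    lower[3::3] = 1.0  # resonance frequencies
    lower[4::3] = 0.1  # dampings
    p0 = np.clip(p0, lower + 1e-12, None)
    scale = np.maximum(np.abs(p0), 1e-3)
    res = least_squares(
        lambda p: _model(p, w_fit, n_res) - im_fit,
        p0,
        bounds=(lower, np.full(p0.size, np.inf)),
        x_scale=scale,
        method="trf",
        max_nfev=20000,
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    if not res.success:
        warnings.warn(
            f"fit did not converge (status {res.status}); initial rms "
            f"{np.sqrt(np.mean((_model(p0, w_fit, n_res) - im_fit) ** 2)):.3g}, "
            f"final rms {rms:.3g}",
            stacklevel=2,
        )
    dof = max(w_fit.size - p0.size, 1)
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        cov = jtj_inv * (res.fun @ res.fun) / dof
    except np.linalg.LinAlgError:
        cov = None
    p = res.x
    resonances = [
        (float(p[2 + 3 * j]), float(p[3 + 3 * j]), float(p[4 + 3 * j]))
        for j in range(n_res)
    ]
    # report the primary (librational) band first: the stronger peak weight
    resonances.sort(key=lambda r: -(r[0] * r[1]))
    return LineshapeFit(
        component=spectrum.component,
        k_mag=spectrum.k_mag,
        debye_dchi=float(p[0]),
        debye_tau_ps=float(p[1]),
        resonances=resonances,
        residual_rms=rms,
        covariance=cov,
        param_names=names,
        success=bool(res.success),
        metadata={"model": model, "n_points": int(w_fit.size), "cost": float(res.cost)},
    )


# --------------------------------------------------------------------------
# dispersion and derived quantities
# --------------------------------------------------------------------------


@dataclass
class DispersionBranch:
    """Dispersion of one component across wavevectors."""

    component: str
    k: np.ndarray  # nm^-1
    omega0: np.ndarray  # cm^-1
    tau_ps: np.ndarray
    v_g: float | None  # m/s, slope over the linear window
    k_window: tuple[float, float] | None
    r_squared: float | None

    @property
    def omega_smallest_k(self) -> float:
        return float(self.omega0[0])

    @property
    def tau_smallest_k(self) -> float:
        return float(self.tau_ps[0])


@dataclass
class DispersionResult:
    """Paired longitudinal/transverse dispersion summary."""

    longitudinal: DispersionBranch
    transverse: DispersionBranch

    @property
    def omega_lo(self) -> float:
        return self.longitudinal.omega_smallest_k

    @property
    def omega_to(self) -> float:
        return self.transverse.omega_smallest_k

    @property
    def splitting(self) -> float:
        return lo_to_splitting(self.omega_lo, self.omega_to)

    def propagation_ranges(self) -> tuple[float | None, float | None]:
        out = []
        for br in (self.longitudinal, self.transverse):
            out.append(
                propagation_range(br.tau_smallest_k, br.v_g)
                if br.v_g is not None
                else None
            )
        return tuple(out)

    def to_dict(self) -> dict:
        r_l, r_t = self.propagation_ranges()
        return {
            "omega_lo_cm1": self.omega_lo,
            "omega_to_cm1": self.omega_to,
            "splitting_cm1": self.splitting,
            "tau_lo_ps": self.longitudinal.tau_smallest_k,
            "tau_to_ps": self.transverse.tau_smallest_k,
            "v_g_longitudinal_m_s": self.longitudinal.v_g,
            "v_g_transverse_m_s": self.transverse.v_g,
            "range_longitudinal_nm": r_l,
            "range_transverse_nm": r_t,
            "k_nm_inv": {
                "L": self.longitudinal.k.tolist(),
                "T": self.transverse.k.tolist(),
            },
            "omega0_cm1": {
                "L": self.longitudinal.omega0.tolist(),
                "T": self.transverse.omega0.tolist(),
            },
        }


def _linear_window(k, w0, r2_min):
    """Longest contiguous window of >=3 points with linear R^2 >= r2_min."""
    n = k.size
    best = None
    for i in range(n - 2):
        for j in range(i + 3, n + 1):
            kk, ww = k[i:j], w0[i:j]
            coef = np.polyfit(kk, ww, 1)
            pred = np.polyval(coef, kk)
            ss_res = np.sum((ww - pred) ** 2)
            ss_tot = np.sum((ww - ww.mean()) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            if r2 >= r2_min:
                cand = (j - i, r2, i, j, coef[0])
                if best is None or cand[:2] > best[:2]:
                    best = cand
    return best


def dispersion(
    fits: list[LineshapeFit],
    component: str,
    k_window: tuple[float, float] | None = None,
    r2_min: float = 0.98,
) -> DispersionBranch:
    """Dispersion relation w0(k) and group velocity for one component.

    fits: LineshapeFit per wavevector shell (any order).  The group
    velocity is the slope of w0 vs k over the declared k_window (nm^-1),
    or over the longest automatic window with linear R^2 >= r2_min;
    absent such a window v_g is None (with a warning).
    """
    fits = [f for f in fits if f.component == component]
    if len(fits) < 3:
        raise ValueError("need fits at >= 3 wavevectors")
    fits = sorted(fits, key=lambda f: f.k_mag)
    k = np.array([f.k_mag for f in fits])
    w0 = np.array([f.omega0 for f in fits])
    tau = np.array([f.tau_ps for f in fits])
    v_g = win = r2 = None
    if k_window is not None:
        sel = (k >= k_window[0]) & (k <= k_window[1])
        if sel.sum() < 2:
            raise ValueError("k_window contains fewer than 2 points")
        coef = np.polyfit(k[sel], w0[sel], 1)
        pred = np.polyval(coef, k[sel])
        ss_tot = np.sum((w0[sel] - w0[sel].mean()) ** 2)
        r2 = 1.0 - np.sum((w0[sel] - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
        v_g = float(coef[0] * SLOPE_CM1_NM_TO_M_S)
        win = (float(k[sel][0]), float(k[sel][-1]))
    else:
        found = _linear_window(k, w0, r2_min)
        if found is None:
            warnings.warn("no linear-dispersion window found; v_g not reported",
                          stacklevel=2)
        else:
            _, r2, i, j, slope = found
            v_g = float(slope * SLOPE_CM1_NM_TO_M_S)
            win = (float(k[i]), float(k[j - 1]))
    return DispersionBranch(
        component=component,
        k=k,
        omega0=w0,
        tau_ps=tau,
        v_g=v_g,
        k_window=win,
        r_squared=None if r2 is None else float(r2),
    )


def lo_to_splitting(omega_lo_cm1: float, omega_to_cm1: float) -> float:
    """LO-TO splitting, the exact difference w_LO - w_TO (cm^-1)."""
    if not (np.isfinite(omega_lo_cm1) and np.isfinite(omega_to_cm1)):
        raise ValueError("frequencies must be finite")
    return float(omega_lo_cm1 - omega_to_cm1)


def propagation_range(tau_ps: float, v_g_m_s: float) -> float:
    """Propagation range R = tau * v_g in nm (1 m/s = 1e-3 nm/ps)."""
    if tau_ps < 0 or v_g_m_s < 0:
        raise ValueError("tau and v_g must be nonnegative")
    return float(tau_ps * v_g_m_s * 1e-3)


def round_one_sig(x: float) -> float:
    """Round to one significant figure (the '~0.3 nm'-style report)."""
    if x == 0:
        return 0.0
    mag = 10.0 ** np.floor(np.log10(abs(x)))
    return float(np.round(x / mag) * mag)


# --------------------------------------------------------------------------
# generalized Lyddane-Sachs-Teller check
# --------------------------------------------------------------------------


@dataclass
class LSTReport:
    """Both sides of the generalized LST relation and their discrepancy."""

    lhs: float  # eps_static / eps_inf
    rhs: float  # product over modes
    n_debye: int
    n_resonances: int

    @property
    def relative_discrepancy(self) -> float:
        return abs(self.rhs - self.lhs) / abs(self.lhs)


def lst_check(
    debye_modes: list[tuple[float, float]],
    resonances: list[tuple[float, float, float] | tuple[float, float, float, float]],
    eps_static: float,
    eps_inf: float,
    cutoff_cm1: float | None = None,
) -> LSTReport:
    """Generalized Lyddane-Sachs-Teller consistency report.

    debye_modes: (w_D_longitudinal, w_D) relaxation-rate pairs.
    resonances: (w_L, w_T, gamma_L[, gamma_T]); longitudinal frequencies of
    damped modes enter as complex moduli |w_L|^2 = w_L^2 + gamma_L^2
    (likewise w_T if gamma_T is given).  Modes with w_T below cutoff_cm1
    are excluded, mirroring the practice of setting aside the poorly
    constrained low-frequency hydrogen-bond region.

    Compares eps_static/eps_inf with
    prod_i (w_DL,i / w_D,i) * prod_j |w_L,j|^2 / |w_T,j|^2.
    """
    if eps_static <= 0 or eps_inf <= 0:
        raise ValueError("dielectric constants must be positive")
    rhs = 1.0
    n_d = n_r = 0
    for w_dl, w_d in debye_modes:
        if w_dl <= 0 or w_d <= 0:
            raise ValueError("Debye rates must be positive")
        if cutoff_cm1 is not None and w_d < cutoff_cm1 and w_dl < cutoff_cm1:
            continue
        rhs *= w_dl / w_d
        n_d += 1
    for mode in resonances:
        w_l, w_t, g_l = mode[0], mode[1], mode[2]
        g_t = mode[3] if len(mode) > 3 else 0.0
        if w_l <= 0 or w_t <= 0:
            raise ValueError("resonance frequencies must be positive")
        if cutoff_cm1 is not None and w_t < cutoff_cm1:
            continue
        rhs *= (w_l**2 + g_l**2) / (w_t**2 + g_t**2)
        n_r += 1
    return LSTReport(
        lhs=eps_static / eps_inf, rhs=rhs, n_debye=n_d, n_resonances=n_r
    )
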