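"""Synthetic trajectories and optical-constant tables with planted truth.

The trajectory generator integrates damped-harmonic Langevin dynamics for
one point dipole per site of a cubic lattice,

    mu_dd = -Omega^2 mu - 2*gamma*mu_d + xi(t),

where Omega^2 contains an on-site restoring term omega0^2, a
nearest-neighbour coupling kappa (acting through the lattice Laplacian,
eigenfrequencies omega_T(k)^2 = omega0^2 + 2 kappa sum_a (1 - cos k_a a)),
and a k-independent mean-field term Delta^2 acting on the longitudinal
projection of the dipole field only, so the planted branches are

    omega_T(k)^2 = omega0^2 + 2 kappa sum_a (1 - cos k_a a)
    omega_L(k)^2 = omega_T(k)^2 + Delta^2.

Delta is the simplest controllable analogue of the long-range dipole-dipole
interaction responsible for LO-TO splitting; the estimator pipeline, not a
force field, is under test.  gamma is the spectroscopic half-width
(gamma = 1/tau of the resulting lineshape), hence the friction coefficient
2*gamma in the equation of motion; white noise xi obeys the
fluctuation-dissipation balance for that friction.

Only the combination kB*T / (dipole inertia) enters the dynamics; it is
fixed by declaring the configured dipole magnitude mu to be the r.m.s.
thermal dipole of an uncoupled site:  <mu_dot_x^2> = mu^2 omega0^2 / 3.
The configured temperature (K) is carried into the emitted trajectory and
used only in the susceptibility prefactor.

Integration uses the BAOAB splitting with the exact Ornstein-Uhlenbeck
velocity update; trajectories are bit-reproducible for a given seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .constants import gamma_cm1_to_tau_ps, wavenumber_to_radps
from .core_io import DipoleTrajectory, OpticalConstantsTable, Topology, Trajectory

__all__ = [
    "LangevinDipoleConfig",
    "PlantedTruth",
    "generate_langevin_trajectory",
    "lorentz_eps",
    "generate_lorentz_table",
]


@dataclass
class LangevinDipoleConfig:
    """Study conditions for the dipole-lattice generator.

    Defaults mirror an ambient-water simulation cell: 8x8x8 = 512
    molecules at 0.31 nm spacing (a 2.48 nm box), a librational on-site
    frequency of 632 cm^-1 with 29.47 cm^-1 damping (0.18 ps lifetime), a
    mean-field longitudinal term Delta = 640.8 cm^-1 (planting a
    900 / 632 cm^-1 LO/TO pair at vanishing coupling), nearest-neighbour
    coupling 4e4 cm^-2, an r.m.s. dipole of 0.048 e nm (2.3 D), and 2^14
    output frames at 4 fs spacing.
    """

    n_cells: int = 8
    spacing_nm: float = 0.31
    omega0_cm1: float = 632.0
    gamma_cm1: float = 29.47
    mu_enm: float = 0.048
    kappa_cm2: float = 4.0e4
    delta_cm1: float = 640.8
    temperature_K: float = 300.0
    dt_ps: float = 4.0e-4
    stride: int = 10
    n_frames: int = 16384
    burn_in_ps: float = 2.0
    seed: int = 0
    emit: str = "point"  # "point" | "3site"
    site_charge_e: float = 1.0  # 3site mode: +-q placed to realize the dipole

    def omega_max_cm1(self) -> float:
        w2 = self.omega0_cm1**2 + 12.0 * self.kappa_cm2 + self.delta_cm1**2
        return float(np.sqrt(w2))

    def validate(self) -> None:
        if self.n_cells < 1 or self.spacing_nm <= 0:
            raise ValueError("lattice dimensions must be positive")
        if self.omega0_cm1 <= 0 or self.gamma_cm1 <= 0 or self.mu_enm <= 0:
            raise ValueError("omega0, gamma and mu must be positive")
        if self.kappa_cm2 < 0 or self.delta_cm1 < 0:
            raise ValueError("kappa and delta must be nonnegative")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.n_frames < 1 or self.stride < 1 or self.dt_ps <= 0:
            raise ValueError("frame/step settings must be positive")
        w2min = self.omega0_cm1**2  # kappa >= 0 keeps all eigenfrequencies real
        if w2min <= 0:
            raise ValueError("lattice eigenfrequencies must be positive")
        dt_bound = 0.1 / wavenumber_to_radps(self.omega_max_cm1())
        if self.dt_ps > dt_bound:
            raise ValueError(
                f"dt = {self.dt_ps:.3g} ps violates the stability bound "
                f"dt < 0.1/max omega = {dt_bound:.3g} ps"
            )
        if self.emit not in ("point", "3site"):
            raise ValueError("emit must be 'point' or '3site'")

    @classmethod
    def from_dict(cls, d: dict) -> "LangevinDipoleConfig":
        return cls(**d)


@dataclass
class PlantedTruth:
    """Closed-form dispersion planted by a :class:`LangevinDipoleConfig`."""

    omega0_cm1: float
    gamma_cm1: float
    kappa_cm2: float
    delta_cm1: float
    spacing_nm: float
    box_edge_nm: float
    n_cells: int
    config: dict = field(default_factory=dict)

    @property
    def tau_ps(self) -> float:
        return gamma_cm1_to_tau_ps(self.gamma_cm1)

    def omega_T(self, k_nm_inv) -> float:
        """Transverse branch at wavevector k (3-vector, nm^-1), in cm^-1."""
        k = np.asarray(k_nm_inv, dtype=float)
        s = np.sum(1.0 - np.cos(k * self.spacing_nm))
        return float(np.sqrt(self.omega0_cm1**2 + 2.0 * self.kappa_cm2 * s))

    def omega_L(self, k_nm_inv) -> float:
        """Longitudinal branch omega_L^2 = omega_T^2 + Delta^2, in cm^-1."""
        return float(np.sqrt(self.omega_T(k_nm_inv) ** 2 + self.delta_cm1**2))

    def splitting(self, k_nm_inv) -> float:
        return self.omega_L(k_nm_inv) - self.omega_T(k_nm_inv)

    def shell_omegas(self, kset, ishell) -> tuple[float, float]:
        """(omega_T, omega_L) averaged over one shell's members."""
        members = kset.shells[ishell]
        wt = np.mean([self.omega_T(kset.vectors[i]) for i in members])
        wl = np.mean([self.omega_L(kset.vectors[i]) for i in members])
        return float(wt), float(wl)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        return cls(**json.loads(Path(path).read_text()))


def _fourier_multipliers(n, spacing, omega0, kappa, delta):
    """Per-lattice-mode squared-frequency field and longitudinal projector."""
    q = 2.0 * np.pi * np.fft.fftfreq(n)  # k_a * a
    qa = q[:, None, None] * np.ones((1, n, n))
    qb = q[None, :, None] * np.ones((n, 1, n))
    qc = q[None, None, :] * np.ones((n, n, 1))
    w2 = omega0**2 + 2.0 * kappa * (
        (1 - np.cos(qa)) + (1 - np.cos(qb)) + (1 - np.cos(qc))
    )
    qvec = np.stack([qa, qb, qc], axis=-1)
    qnorm = np.linalg.norm(qvec, axis=-1)
    qhat = np.zeros_like(qvec)
    nz = qnorm > 0
    qhat[nz] = qvec[nz] / qnorm[nz][..., None]
    return w2, qhat, delta**2


def _make_force(n, spacing, omega0, kappa, delta):
    w2, qhat, d2 = _fourier_multipliers(n, spacing, omega0, kappa, delta)

    def force(mu_field):  # mu_field: (n, n, n, 3) real
        mh = np.fft.fftn(mu_field, axes=(0, 1, 2))
        fh = -w2[..., None] * mh
        if d2 > 0:
            s = np.einsum("abcx,abcx->abc", qhat, mh)
            fh -= d2 * qhat * s[..., None]
        return np.fft.ifftn(fh, axes=(0, 1, 2)).real

    return force


def generate_langevin_trajectory(
    config: LangevinDipoleConfig,
) -> tuple[Trajectory | DipoleTrajectory, PlantedTruth]:
    """Integrate the dipole lattice and emit a trajectory plus its truth.

    Returns a :class:`DipoleTrajectory` (emit="point") or a 3-site
    :class:`Trajectory` whose +-q sites realize each instantaneous dipole
    (emit="3site", exercising the line-charge polarization path).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    a = config.spacing_nm
    box = n * a
    w0 = wavenumber_to_radps(config.omega0_cm1)  # rad/ps
    gam = wavenumber_to_radps(config.gamma_cm1)
    kap = config.kappa_cm2 * wavenumber_to_radps(1.0) ** 2
    dlt = wavenumber_to_radps(config.delta_cm1)
    sigma_v = config.mu_enm * w0 / np.sqrt(3.0)  # <mu_dot_x^2>^1/2

    force = _make_force(n, a, w0, kap, dlt)
    dt = config.dt_ps
    fric = 2.0 * gam
    c1 = np.exp(-fric * dt)
    c2 = sigma_v * np.sqrt(1.0 - c1 * c1)

    shape = (n, n, n, 3)
    mu = rng.normal(0.0, sigma_v / w0, size=shape)
    vel = rng.normal(0.0, sigma_v, size=shape)
    F = force(mu)

    n_burn = int(round(config.burn_in_ps / dt))
    n_steps = n_burn + config.n_frames * config.stride
    frames = np.empty((config.n_frames, n * n * n, 3))
    blow_up = (50.0 * config.mu_enm) ** 2
    out_idx = 0
    next_out = n_burn + config.stride - 1
    v2_acc = 0.0  # running <mu_dot_x^2> over emitted frames (equipartition)
    for step in range(n_steps):
        vel += 0.5 * dt * F
        mu += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal(shape)
        mu += 0.5 * dt * vel
        F = force(mu)
        vel += 0.5 * dt * F
        if step == next_out:
            if np.max(np.sum(mu * mu, axis=-1)) > blow_up:
                dt_bound = 0.1 / wavenumber_to_radps(config.omega_max_cm1())
                raise RuntimeError(
                    f"dipole energy blow-up at step {step}; reduce dt below "
                    f"the stability bound {dt_bound:.3g} ps"
                )
            frames[out_idx] = mu.reshape(-1, 3)
            v2_acc += float(np.mean(vel * vel))
            out_idx += 1
            next_out += config.stride
    dt_out = dt * config.stride

    idx = np.indices((n, n, n)).reshape(3, -1).T
    positions = (idx + 0.5) * a

    truth = PlantedTruth(
        omega0_cm1=config.omega0_cm1,
        gamma_cm1=config.gamma_cm1,
        kappa_cm2=config.kappa_cm2,
        delta_cm1=config.delta_cm1,
        spacing_nm=a,
        box_edge_nm=box,
        n_cells=n,
        config=asdict(config),
    )
    # equipartition diagnostics: target and measured <mu_dot_x^2>
    truth.config["target_v2"] = float(sigma_v**2)
    truth.config["measured_v2"] = v2_acc / config.n_frames

    if config.emit == "point":
        traj = DipoleTrajectory(
            positions=positions,
            dipoles=frames,
            box_edge=box,
            dt_out=dt_out,
            temperature=config.temperature_K,
        )
        return traj, truth

    # 3-site mode: +q at r + d/2, -q at r - d/2 with q d = |mu|, plus a
    # neutral spectator at r (exercises the line-charge construction).
    q = config.site_charge_e
    n_mol = n * n * n
    site_pos = np.empty((config.n_frames, 3 * n_mol, 3))
    mag = np.linalg.norm(frames, axis=-1)
    mag = np.where(mag > 0, mag, 1.0)
    unit = frames / mag[..., None]
    half_d = (np.linalg.norm(frames, axis=-1) / q / 2.0)[..., None] * unit
    site_pos[:, 0::3] = positions[None, :, :] + half_d
    site_pos[:, 1::3] = positions[None, :, :] - half_d
    site_pos[:, 2::3] = positions[None, :, :]
    charges = np.tile([q, -q, 0.0], n_mol)
    mol_of = np.repeat(np.arange(n_mol), 3)
    labels = ["P", "N", "S"] * n_mol
    topo = Topology(site_charges=charges, molecule_of_site=mol_of, site_labels=labels)
    traj = Trajectory(
        positions=site_pos,
        box_edge=box,
        dt_out=dt_out,
        temperature=config.temperature_K,
        topology=topo,
    )
    return traj, truth


# --------------------------------------------------------------------------
# Lorentz-oscillator optical constants
# --------------------------------------------------------------------------


def lorentz_eps(grid_cm1, eps_inf: float, modes) -> np.ndarray:
    """eps(w) = eps_inf + sum_j wp_j^2 / (w0_j^2 - w^2 - i gamma_j w)."""
    w = np.asarray(grid_cm1, dtype=float)
    eps = np.full(w.shape, eps_inf, dtype=complex)
    for wp, w0, g in modes:
        if wp <= 0 or w0 <= 0 or g <= 0:
            raise ValueError("Lorentz mode parameters must be positive")
        eps += wp**2 / (w0**2 - w**2 - 1j * g * w)
    return eps


def generate_lorentz_table(
    eps_inf: float, modes, grid_cm1
) -> OpticalConstantsTable:
    """Optical-constants table of a Lorentz-oscillator dielectric model.

    modes: iterable of (plasma frequency wp, resonance w0, damping gamma),
    all cm^-1.  n + ik is the principal square root (n >= 0); for passive
    eps (Im >= 0) the extinction k is nonnegative.
    """
    if eps_inf <= 0:
        raise ValueError("eps_inf must be positive")
    eps = lorentz_eps(grid_cm1, eps_inf, modes)
    nk = np.sqrt(eps)
    return OpticalConstantsTable(
        wavenumber=np.asarray(grid_cm1, dtype=float),
        n=nk.real,
        k=np.clip(nk.imag, 0.0, None),
    )
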