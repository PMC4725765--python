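"""Wavevector grids and k-resolved polarization components.

In a cubic periodic box of edge L the allowed wavevectors are
k = (2*pi/L)(nx, ny, nz) with integer n.  For each k the longitudinal
polarization follows from the charge density via i k . P(k) = -rho(k),

    P_L(k) = (i/|k|) sum_j q_j exp(-i k . r_j),

while the transverse part requires molecule-resolved polarization vectors,
built with the Raineri-Friedman line-charge construction

    p_i(k) = exp(-i k . r_c,i) sum_alpha q_alpha d_alpha phi(k . d_alpha),
    phi(x) = (1 - exp(-i x)) / (i x),   phi(0) = 1,

whose divergence reproduces the molecular charge density exactly:
i k . sum_i p_i(k) = -rho(k).  The Fourier sign convention exp(-i k . r)
is used throughout.

A point-dipole path (p_i(k) = mu_i exp(-i k . r_i)) serves trajectories
that carry explicit dipoles instead of charged sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DipoleTrajectory, Topology, Trajectory, ValidationError

__all__ = [
    "WaveVectorSet",
    "PolarizationSeries",
    "enumerate_wavevectors",
    "longitudinal_polarization",
    "molecular_polarization",
    "molecular_reference_points",
    "transverse_basis",
    "transverse_projection",
    "compute_polarization",
]


# --------------------------------------------------------------------------
# wavevectors
# --------------------------------------------------------------------------


@dataclass
class WaveVectorSet:
    """Integer wavevector triples grouped into |k| shells.

    Vectors are ordered by (nx^2+ny^2+nz^2, nx, ny, nz); shells collect
    vectors of identical integer squared magnitude, so members agree in |k|
    exactly.
    """

    box_edge: float
    integers: np.ndarray  # (n_k, 3) int
    vectors: np.ndarray  # (n_k, 3) nm^-1
    shells: list[np.ndarray]  # index arrays into vectors
    shell_magnitudes: np.ndarray  # (n_shells,) nm^-1

    @property
    def n_vectors(self) -> int:
        return self.integers.shape[0]

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    def shell_index(self, k_mag: float, rtol: float = 1e-6) -> int:
        """Locate the shell whose |k| matches k_mag."""
        diffs = np.abs(self.shell_magnitudes - k_mag)
        i = int(np.argmin(diffs))
        if diffs[i] > rtol * max(k_mag, self.shell_magnitudes[i]):
            raise ValueError(f"no shell with |k| ~ {k_mag}")
        return i


def enumerate_wavevectors(box_edge: float, n_max: int) -> WaveVectorSet:
    """All k = (2*pi/L) n with integer triples n, 0 < max|n_i| <= n_max."""
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    rng = np.arange(-n_max, n_max + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    n2 = np.sum(grid * grid, axis=1)
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], n2))
    grid = grid[order]
    n2 = n2[order]
    vectors = (2.0 * np.pi / box_edge) * grid.astype(float)
    shells = [np.nonzero(n2 == v)[0] for v in np.unique(n2)]
    mags = (2.0 * np.pi / box_edge) * np.sqrt(np.unique(n2).astype(float))
    return WaveVectorSet(
        box_edge=box_edge,
        integers=grid,
        vectors=vectors,
        shells=shells,
        shell_magnitudes=mags,
    )


# --------------------------------------------------------------------------
# polarization components
# --------------------------------------------------------------------------


def _check_k(k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if k.shape != (3,) or not np.any(k != 0):
        raise ValueError("k must be a nonzero 3-vector")
    return k


def longitudinal_polarization(positions, topology: Topology, k) -> complex:
    """Longitudinal polarization scalar (i/|k|) sum_j q_j exp(-i k . r_j)."""
    k = _check_k(k)
    kmag = float(np.linalg.norm(k))
    phase = np.exp(-1j * positions @ k)
    return 1j / kmag * complex(topology.site_charges @ phase)


def _phi(x: np.ndarray) -> np.ndarray:
    """phi(x) = (1 - exp(-ix))/(ix), phi(0) = 1; stable near x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape, dtype=complex)
    small = np.abs(x) < 1e-7
    xs = x[~small]
    out[~small] = (1.0 - np.exp(-1j * xs)) / (1j * xs)
    out[small] = 1.0 - 0.5j * x[small]
    return out


def molecular_reference_points(positions, topology: Topology, box_edge: float):
    """Per-molecule reference point: |q|-weighted centroid of the unwrapped
    molecule (minimum-image displacements from the molecule's first site)."""
    pos = np.asarray(positions, dtype=float)
    nmol = topology.n_molecules
    anchors = np.zeros((nmol, 3))
    ref = np.zeros((nmol, 3))
    w = np.abs(topology.site_charges)
    for i in range(nmol):
        sites = topology.sites_of_molecule(i)
        r0 = pos[sites[0]]
        d = pos[sites] - r0
        d -= box_edge * np.round(d / box_edge)
        wi = w[sites]
        tot = wi.sum()
        if tot <= 0:
            raise ValidationError(f"molecule {i} carries no charged sites")
        anchors[i] = r0
        ref[i] = r0 + (wi[:, None] * d).sum(axis=0) / tot
    return ref, anchors


def molecular_polarization(positions, topology: Topology, k, box_edge: float):
    """Raineri-Friedman molecular polarization vectors, (n_molecules, 3).

    Each molecule must be neutral; intramolecular displacements are taken
    minimum-image so wrapped trajectories are handled.
    """
    k = _check_k(k)
    pos = np.asarray(positions, dtype=float)
    ref, _ = molecular_reference_points(pos, topology, box_edge)
    nmol = topology.n_molecules
    p = np.zeros((nmol, 3), dtype=complex)
    for i in range(nmol):
        sites = topology.sites_of_molecule(i)
        d = pos[sites] - ref[i]
        d -= box_edge * np.round(d / box_edge)
        q = topology.site_charges[sites]
        kd = d @ k
        contrib = (q * _phi(kd))[:, None] * d
        p[i] = contrib.sum(axis=0) * np.exp(-1j * (ref[i] @ k))
    return p


def transverse_basis(k) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair {e1, e2} perpendicular to k.

    e1 = normalize(k x a) with a the coordinate axis least aligned with k
    (ties broken in x < y < z order), e2 = k_hat x e1.
    """
    k = _check_k(k)
    khat = k / np.linalg.norm(k)
    axis = int(np.argmin(np.abs(khat)))  # argmin returns first on ties: x<y<z
    a = np.zeros(3)
    a[axis] = 1.0
    e1 = np.cross(k, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(khat, e1)
    return e1, e2


def transverse_projection(p, k) -> tuple[complex, complex]:
    """Components of a (complex) polarization vector along the transverse
    basis of k.  |p|^2 = |p_L|^2 + |p_T1|^2 + |p_T2|^2 holds to 1e-12."""
    e1, e2 = transverse_basis(k)
    p = np.asarray(p, dtype=complex)
    return complex(p @ e1), complex(p @ e2)


# --------------------------------------------------------------------------
# series over a trajectory
# --------------------------------------------------------------------------


@dataclass
class PolarizationSeries:
    """Per-wavevector polarization time series for one trajectory.

    PL: (n_k, n_t) complex longitudinal scalars (e nm).
    PT: (n_k, 2, n_t) complex transverse components (e nm).
    mol_proj: per requested k index, (3, n_molecules, n_t) complex scalar
        projections (L, T1, T2) of each molecular polarization vector.
    ref_positions: (n_molecules, 3) if molecules are static, else
        (n_t, n_molecules, 3) origin-frame reference points.
    """

    kset: WaveVectorSet
    PL: np.ndarray
    PT: np.ndarray
    dt_out: float
    box_edge: float
    temperature: float
    n_molecules: int
    mol_proj: dict[int, np.ndarray] = field(default_factory=dict)
    ref_positions: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.PL.shape[1]

    @property
    def volume(self) -> float:
        return self.box_edge**3


def _resolve_molecular_indices(kset: WaveVectorSet, keep_molecular):
    if keep_molecular is None:
        return []
    if keep_molecular == "all":
        return list(range(kset.n_vectors))
    if isinstance(keep_molecular, str) and keep_molecular.startswith("shell:"):
        return list(kset.shells[int(keep_molecular.split(":")[1])])
    return [int(i) for i in keep_molecular]


def compute_polarization(
    traj, kset: WaveVectorSet, keep_molecular=None
) -> PolarizationSeries:
    """Longitudinal/transverse polarization series for every wavevector.

    traj: Trajectory (charged sites; P_L from the charge density, P_T from
    Raineri-Friedman molecular vectors) or DipoleTrajectory (point dipoles).
    keep_molecular: None, "all", "shell:<i>", or explicit k indices for which
    per-molecule projections are retained (needed by distance decomposition).
    """
    keep = set(_resolve_molecular_indices(kset, keep_molecular))
    n_k = kset.n_vectors
    if isinstance(traj, DipoleTrajectory):
        n_t = traj.n_frames
        PL = np.empty((n_k, n_t), dtype=complex)
        PT = np.empty((n_k, 2, n_t), dtype=complex)
        mol_proj = {}
        mu = traj.dipoles  # (n_t, n_mol, 3)
        for ik in range(n_k):
            k = kset.vectors[ik]
            khat = k / np.linalg.norm(k)
            e1, e2 = transverse_basis(k)
            phase = np.exp(-1j * traj.positions @ k)  # (n_mol,)
            aL = (mu @ khat) * phase  # (n_t, n_mol)
            a1 = (mu @ e1) * phase
            a2 = (mu @ e2) * phase
            PL[ik] = aL.sum(axis=1)
            PT[ik, 0] = a1.sum(axis=1)
            PT[ik, 1] = a2.sum(axis=1)
            if ik in keep:
                mol_proj[ik] = np.stack([aL.T, a1.T, a2.T])
        return PolarizationSeries(
            kset=kset,
            PL=PL,
            PT=PT,
            dt_out=traj.dt_out,
            box_edge=traj.box_edge,
            temperature=traj.temperature,
            n_molecules=traj.n_molecules,
            mol_proj=mol_proj,
            ref_positions=traj.positions.copy(),
        )

    if not isinstance(traj, Trajectory):
        raise TypeError("traj must be a Trajectory or DipoleTrajectory")

    topo = traj.topology
    n_t = traj.n_frames
    nmol = topo.n_molecules
    PL = np.empty((n_k, n_t), dtype=complex)
    PT = np.empty((n_k, 2, n_t), dtype=complex)
    mol_proj = {ik: np.empty((3, nmol, n_t), dtype=complex) for ik in keep}
    refs = np.empty((n_t, nmol, 3))
    for t in range(n_t):
        pos = traj.positions[t]
        refs[t], _ = molecular_reference_points(pos, topo, traj.box_edge)
        for ik in range(n_k):
            k = kset.vectors[ik]
            khat = k / np.linalg.norm(k)
            e1, e2 = transverse_basis(k)
            PL[ik, t] = longitudinal_polarization(pos, topo, k)
            p = molecular_polarization(pos, topo, k, traj.box_edge)
            PT[ik, 0, t] = (p @ e1).sum()
            PT[ik, 1, t] = (p @ e2).sum()
            if ik in keep:
                mol_proj[ik][0, :, t] = p @ khat
                mol_proj[ik][1, :, t] = p @ e1
                mol_proj[ik][2, :, t] = p @ e2
    return PolarizationSeries(
        kset=kset,
        PL=PL,
        PT=PT,
        dt_out=traj.dt_out,
        box_edge=traj.box_edge,
        temperature=traj.temperature,
        n_molecules=nmol,
        mol_proj=mol_proj,
        ref_positions=refs,
    )
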