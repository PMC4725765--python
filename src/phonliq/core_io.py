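"""Shared data model and file I/O.

Trajectories are exchanged as extended-XYZ (a ``Lattice=...`` comment line
plus whitespace columns) with a JSON topology sidecar supplying per-site
charges and the site->molecule map.  Only cubic boxes are supported.
Optical-constant tables are plain CSV with columns ``wavenumber_cm1,n,k``.

Two trajectory flavours exist:

* :class:`Trajectory` — explicit charged sites (the molecular-dynamics view);
* :class:`DipoleTrajectory` — one point dipole per molecule at a fixed
  reference position (the reduced view emitted by the synthetic generator
  and consumed directly by the polarization module).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CHARGE_NEUTRALITY_TOL = 1e-9  # e, per molecule


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally valid input violating a data-model invariant."""


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------


@dataclass
class Topology:
    """Static per-site metadata: charges (e) and molecule membership."""

    site_charges: np.ndarray
    molecule_of_site: np.ndarray
    site_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.site_charges = np.asarray(self.site_charges, dtype=float)
        self.molecule_of_site = np.asarray(self.molecule_of_site, dtype=int)
        if self.site_charges.shape != self.molecule_of_site.shape:
            raise ValidationError("site_charges and molecule_of_site lengths differ")
        if self.n_sites == 0:
            raise ValidationError("topology has no sites")
        mols = np.unique(self.molecule_of_site)
        if not np.array_equal(mols, np.arange(len(mols))):
            raise ValidationError("molecule indices must be contiguous from 0")
        if not self.site_labels:
            self.site_labels = ["X"] * self.n_sites
        if len(self.site_labels) != self.n_sites:
            raise ValidationError("site_labels length mismatch")
        net = np.zeros(len(mols))
        np.add.at(net, self.molecule_of_site, self.site_charges)
        worst = np.abs(net).max()
        if worst > CHARGE_NEUTRALITY_TOL:
            raise ValidationError(
                f"molecule net charge {worst:.3g} e exceeds neutrality "
                f"tolerance {CHARGE_NEUTRALITY_TOL} e"
            )

    @property
    def n_sites(self) -> int:
        return self.site_charges.size

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_of_site.max()) + 1

    def sites_of_molecule(self, i: int) -> np.ndarray:
        return np.nonzero(self.molecule_of_site == i)[0]

    def to_json(self, path) -> None:
        payload = {
            "charges": self.site_charges.tolist(),
            "molecules": self.molecule_of_site.tolist(),
            "labels": self.site_labels,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "Topology":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"topology sidecar is not valid JSON: {exc}") from exc
        for key in ("charges", "molecules"):
            if key not in payload:
                raise ValidationError(f"topology sidecar missing field '{key}'")
        return cls(
            site_charges=np.array(payload["charges"], dtype=float),
            molecule_of_site=np.array(payload["molecules"], dtype=int),
            site_labels=list(payload.get("labels", [])),
        )


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------


def _validate_box_dt(box_edge, dt_out, temperature):
    if box_edge <= 0:
        raise ValidationError("box_edge must be positive")
    if dt_out <= 0:
        raise ValidationError("dt_out must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")


@dataclass
class Trajectory:
    """Site-resolved trajectory in a cubic periodic box.

    positions: (n_frames, n_sites, 3) nm; may lie outside [0, L) —
    wrapping is the consumer's responsibility.
    """

    positions: np.ndarray
    box_edge: float
    dt_out: float
    temperature: float
    topology: Topology

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must have shape (n_frames, n_sites, 3)")
        if self.positions.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        if self.positions.shape[1] != self.topology.n_sites:
            raise ValidationError("frame site count does not match topology")
        _validate_box_dt(self.box_edge, self.dt_out, self.temperature)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return self.box_edge**3


@dataclass
class DipoleTrajectory:
    """Point-dipole trajectory: fixed molecule positions, evolving dipoles.

    positions: (n_molecules, 3) nm; dipoles: (n_frames, n_molecules, 3) e nm.
    """

    positions: np.ndarray
    dipoles: np.ndarray
    box_edge: float
    dt_out: float
    temperature: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must have shape (n_molecules, 3)")
        if (
            self.dipoles.ndim != 3
            or self.dipoles.shape[2] != 3
            or self.dipoles.shape[1] != self.positions.shape[0]
        ):
            raise ValidationError("dipoles must have shape (n_frames, n_molecules, 3)")
        if self.dipoles.shape[0] < 1:
            raise ValidationError("trajectory must contain at least one frame")
        _validate_box_dt(self.box_edge, self.dt_out, self.temperature)

    @property
    def n_frames(self) -> int:
        return self.dipoles.shape[0]

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return self.box_edge**3


# --------------------------------------------------------------------------
# extended-XYZ
# --------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_KV_RE = re.compile(r'(\w+)=("[^"]*"|\S+)')


def _parse_comment(line: str) -> dict:
    out = {}
    for key, val in _KV_RE.findall(line):
        out[key] = val.strip('"')
    return out


def _cubic_edge_from_lattice(lattice_str: str) -> float:
    vals = np.array(lattice_str.split(), dtype=float)
    if vals.size != 9:
        raise FormatError("Lattice field must contain 9 numbers")
    m = vals.reshape(3, 3)
    diag = np.diag(m)
    if np.any(np.abs(m - np.diag(diag)) > 1e-12) or np.ptp(diag) > 1e-9 * diag[0]:
        raise ValidationError("only cubic boxes are supported")
    if diag[0] <= 0:
        raise ValidationError("box edge must be positive")
    return float(diag[0])


def _comment_line(box_edge, dt_out, temperature, columns, frame):
    lat = f"{box_edge:.12g} 0 0 0 {box_edge:.12g} 0 0 0 {box_edge:.12g}"
    return (
        f'Lattice="{lat}" Properties={columns} '
        f"dt_out={dt_out:.12g} temperature={temperature:.12g} frame={frame}"
    )


def write_trajectory(traj, path) -> None:
    """Write a :class:`Trajectory` or :class:`DipoleTrajectory` as extended-XYZ.

    Round-trips through :func:`read_trajectory` / :func:`read_dipole_trajectory`
    to better than 1e-6 nm.
    """
    if traj.n_frames == 0:
        raise ValidationError("refusing to write an empty trajectory")
    dipole_mode = isinstance(traj, DipoleTrajectory)
    columns = (
        "species:S:1:pos:R:3:dipole:R:3" if dipole_mode else "species:S:1:pos:R:3"
    )
    lines = []
    if dipole_mode:
        labels = ["M"] * traj.n_molecules
        for f in range(traj.n_frames):
            lines.append(str(traj.n_molecules))
            lines.append(
                _comment_line(traj.box_edge, traj.dt_out, traj.temperature, columns, f)
            )
            for lab, r, mu in zip(labels, traj.positions, traj.dipoles[f]):
                lines.append(
                    f"{lab} {r[0]:.9f} {r[1]:.9f} {r[2]:.9f} "
                    f"{mu[0]:.12e} {mu[1]:.12e} {mu[2]:.12e}"
                )
    else:
        labels = traj.topology.site_labels
        for f in range(traj.n_frames):
            lines.append(str(traj.topology.n_sites))
            lines.append(
                _comment_line(traj.box_edge, traj.dt_out, traj.temperature, columns, f)
            )
            for lab, r in zip(labels, traj.positions[f]):
                lines.append(f"{lab} {r[0]:.9f} {r[1]:.9f} {r[2]:.9f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_frames(path, n_extra_cols):
    """Yield (labels, data array, meta dict) per frame."""
    text = Path(path).read_text().splitlines()
    i, n_lines = 0, len(text)
    frames = []
    while i < n_lines:
        if not text[i].strip():
            i += 1
            continue
        try:
            n_sites = int(text[i].strip())
        except ValueError as exc:
            raise FormatError(f"expected site count at line {i + 1}") from exc
        if i + 1 + n_sites >= n_lines + 1:
            raise FormatError("truncated frame")
        comment = text[i + 1]
        mlat = _LATTICE_RE.search(comment)
        if mlat is None:
            raise ValidationError("missing Lattice field in frame comment")
        meta = _parse_comment(comment)
        edge = _cubic_edge_from_lattice(mlat.group(1))
        labels, rows = [], []
        for line in text[i + 2 : i + 2 + n_sites]:
            parts = line.split()
            if len(parts) < 4 + n_extra_cols:
                raise FormatError(f"too few columns in atom line: {line!r}")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : 4 + n_extra_cols]])
        frames.append((labels, np.array(rows), edge, meta))
        i += 2 + n_sites
    if not frames:
        raise FormatError("no frames found")
    counts = {len(f[0]) for f in frames}
    if len(counts) > 1:
        raise FormatError(f"frames disagree on site count: {sorted(counts)}")
    return frames


def _frame_meta(frames):
    edge = frames[0][2]
    meta = frames[0][3]
    dt_out = float(meta.get("dt_out", 0.0))
    temperature = float(meta.get("temperature", 0.0))
    if dt_out <= 0:
        raise ValidationError("missing or nonpositive dt_out in frame comment")
    if temperature <= 0:
        raise ValidationError("missing or nonpositive temperature in frame comment")
    return edge, dt_out, temperature


def read_trajectory(path, topology_path) -> Trajectory:
    """Read an extended-XYZ trajectory plus its JSON topology sidecar."""
    topo = Topology.from_json(topology_path)
    frames = _read_frames(path, n_extra_cols=0)
    if len(frames[0][0]) != topo.n_sites:
        raise FormatError(
            f"file has {len(frames[0][0])} sites per frame, topology has "
            f"{topo.n_sites}"
        )
    edge, dt_out, temperature = _frame_meta(frames)
    positions = np.stack([f[1][:, :3] for f in frames])
    return Trajectory(
        positions=positions,
        box_edge=edge,
        dt_out=dt_out,
        temperature=temperature,
        topology=topo,
    )


def read_dipole_trajectory(path) -> DipoleTrajectory:
    """Read a point-dipole extended-XYZ file (pos + dipole columns)."""
    frames = _read_frames(path, n_extra_cols=3)
    edge, dt_out, temperature = _frame_meta(frames)
    positions = frames[0][1][:, :3]
    dipoles = np.stack([f[1][:, 3:6] for f in frames])
    return DipoleTrajectory(
        positions=positions,
        dipoles=dipoles,
        box_edge=edge,
        dt_out=dt_out,
        temperature=temperature,
    )


# --------------------------------------------------------------------------
# optical constants
# --------------------------------------------------------------------------


@dataclass
class OpticalConstantsTable:
    """Tabulated refractive index n and extinction coefficient k on a
    strictly increasing wavenumber grid (cm^-1)."""

    wavenumber: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if not (self.wavenumber.shape == self.n.shape == self.k.shape):
            raise ValidationError("wavenumber, n, k must share one grid")
        if self.wavenumber.size < 1:
            raise ValidationError("empty table")
        order = np.argsort(self.wavenumber, kind="stable")
        self.wavenumber = self.wavenumber[order]
        self.n = self.n[order]
        self.k = self.k[order]
        if np.any(np.diff(self.wavenumber) <= 0):
            raise ValidationError("duplicate wavenumber entries")
        if np.any(self.n < 0) or np.any(self.k < 0):
            raise ValidationError("negative n or k")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavenumber_cm1": self.wavenumber, "n": self.n, "k": self.k}
        ).to_csv(path, index=False)


def read_optical_constants(path) -> OpticalConstantsTable:
    """Read a CSV/TSV table with columns wavenumber_cm1, n, k ('#' comments)."""
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        nu = df[cols["wavenumber_cm1"]].to_numpy(dtype=float)
        n = df[cols["n"]].to_numpy(dtype=float)
        k = df[cols["k"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise FormatError(f"missing column {exc} in optical-constants table") from exc
    return OpticalConstantsTable(wavenumber=nu, n=n, k=k)
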