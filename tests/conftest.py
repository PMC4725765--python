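"""Shared fixtures: synthetic lattice runs reused across the suite.

The heavy fixtures are session-scoped so each Langevin integration runs
once; seeds are fixed for reproducibility.
"""

from __future__ import annotations

import numpy as np
import pytest

import phonliq as pq


def run_pipeline(traj, truth, n_shells=3, max_lag_ps=3.0, grid_max=2000.0):
    """Polarization -> correlation -> spectrum -> fit for the smallest shells."""
    kset = pq.enumerate_wavevectors(traj.box_edge, 1)
    series = pq.compute_polarization(traj, kset)
    grid = np.arange(0.0, grid_max + 1.0, 2.0)
    out = {"kset": kset, "series": series, "truth": truth, "fits": {}, "spectra": {},
           "corrs": {}}
    for ishell in range(n_shells):
        for comp in ("L", "T"):
            corr = pq.correlation_function(series, ishell, comp, max_lag=max_lag_ps)
            chi0 = pq.static_susceptibility(
                corr.amplitude, comp, series.volume, series.temperature
            )
            spec = pq.susceptibility_spectrum(corr, chi0, grid)
            out["corrs"][comp, ishell] = corr
            out["spectra"][comp, ishell] = spec
            out["fits"][comp, ishell] = pq.fit_band(spec)
    return out


@pytest.fixture(scope="session")
def default_lattice_run():
    """Full-size default fixture (512 molecules, 2^14 frames) with planted
    dispersion and LO-TO splitting; the end-to-end validation workhorse."""
    cfg = pq.LangevinDipoleConfig(seed=7)
    traj, truth = pq.generate_langevin_trajectory(cfg)
    return run_pipeline(traj, truth)


@pytest.fixture(scope="session")
def uncoupled_small_run():
    """Isotropic uncoupled dipoles (kappa = 0, Delta = 0): 64 molecules."""
    cfg = pq.LangevinDipoleConfig(
        n_cells=4,
        kappa_cm2=0.0,
        delta_cm1=0.0,
        omega0_cm1=600.0,
        gamma_cm1=50.0,
        dt_ps=8.0e-4,
        stride=5,
        n_frames=8192,
        seed=21,
    )
    traj, truth = pq.generate_langevin_trajectory(cfg)
    kset = pq.enumerate_wavevectors(traj.box_edge, 1)
    series = pq.compute_polarization(traj, kset, keep_molecular="shell:0")
    return {"traj": traj, "truth": truth, "kset": kset, "series": series}


@pytest.fixture(scope="session")
def coupled_small_run():
    """Coupled lattice with planted splitting, per-molecule projections kept
    for the distance-decomposition contracts; 64 molecules."""
    cfg = pq.LangevinDipoleConfig(
        n_cells=4,
        n_frames=6144,
        seed=13,
    )
    traj, truth = pq.generate_langevin_trajectory(cfg)
    kset = pq.enumerate_wavevectors(traj.box_edge, 1)
    series = pq.compute_polarization(traj, kset, keep_molecular="shell:0")
    return {"traj": traj, "truth": truth, "kset": kset, "series": series}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def water_like_topology():
    """Two 3-site neutral molecules with water-like charges (-2q, +q, +q)."""
    q = 0.42
    charges = np.array([-2 * q, q, q, -2 * q, q, q])
    molecules = np.array([0, 0, 0, 1, 1, 1])
    return pq.Topology(charges, molecules, ["O", "H", "H", "O", "H", "H"])
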