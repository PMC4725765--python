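"""HDF5 result store and CSV export for correlation functions and spectra.

Layout:  /corr/{L,T}/k=<mag>  (lags, phi, amplitude attrs)
         /chi/{L,T}/k=<mag>   (wavenumber, chi complex, chi0 attr)
Every file carries the provenance attrs written by :func:`open_store`.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .response import CorrelationFunction, SusceptibilitySpectrum

__all__ = [
    "open_store",
    "save_correlation",
    "save_spectrum",
    "load_spectrum",
    "spectra_to_csv",
]


def open_store(path, mode="a", provenance: dict | None = None) -> h5py.File:
    f = h5py.File(path, mode)
    if provenance:
        for key, val in provenance.items():
            f.attrs[key] = json.dumps(val) if isinstance(val, (dict, list)) else val
    return f


def _group(f, kind, component, k_mag):
    return f.require_group(f"{kind}/{component}").require_group(f"k={k_mag:.6g}")


def save_correlation(f: h5py.File, corr: CorrelationFunction) -> None:
    g = _group(f, "corr", corr.component, corr.k_mag)
    for name, data in (("lags", corr.lags), ("phi", corr.phi)):
        if name in g:
            del g[name]
        g.create_dataset(name, data=data)
    g.attrs["amplitude"] = corr.amplitude
    g.attrs["metadata"] = json.dumps(corr.metadata)


def save_spectrum(f: h5py.File, spec: SusceptibilitySpectrum) -> None:
    g = _group(f, "chi", spec.component, spec.k_mag)
    for name, data in (("wavenumber", spec.wavenumber), ("chi", spec.chi)):
        if name in g:
            del g[name]
        g.create_dataset(name, data=data)
    g.attrs["chi0"] = spec.chi0
    g.attrs["metadata"] = json.dumps({k: v for k, v in spec.metadata.items()
                                      if isinstance(v, (str, int, float, bool))})


def load_spectrum(f: h5py.File, component: str, k_mag: float) -> SusceptibilitySpectrum:
    g = f[f"chi/{component}/k={k_mag:.6g}"]
    return SusceptibilitySpectrum(
        component=component,
        k_mag=k_mag,
        wavenumber=g["wavenumber"][...],
        chi=g["chi"][...],
        chi0=float(g.attrs["chi0"]),
        metadata=json.loads(g.attrs.get("metadata", "{}")),
    )


def spectra_to_csv(spectra: list[SusceptibilitySpectrum], path) -> None:
    """Im chi(k, w) matrix, one column per wavevector shell."""
    if not spectra:
        raise ValueError("no spectra to export")
    grid = spectra[0].wavenumber
    data = {"wavenumber_cm1": grid}
    for s in spectra:
        if not np.array_equal(s.wavenumber, grid):
            raise ValueError("spectra are not on a common grid")
        data[f"im_chi_{s.component}_k{s.k_mag:.4g}"] = s.im
    pd.DataFrame(data).to_csv(path, index=False)
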