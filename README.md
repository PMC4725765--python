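# phonliq

Wavevector- and frequency-resolved dielectric response of polar liquids
from molecular trajectories: collective optical-phonon-like modes,
LO–TO splitting, and their spatial range.

## The problem

Vibrational bands of liquids (for water: the librational band near
400–900 cm⁻¹ and the OH stretch near 3500 cm⁻¹) are usually assigned to
single-molecule motions. But the nonlocal dielectric susceptibility,
resolved in wavevector **k**, can reveal *collective* modes: dispersive
peaks whose longitudinal and transverse branches split at long wavelength
(LO–TO splitting), the fingerprint of coherent long-range dipole–dipole
coupling — optical phonons propagating through the hydrogen-bond network.

`phonliq` implements that analysis end to end:

1. **Polarization components per k.** In a cubic box of edge *L* the
   allowed wavevectors are **k** = (2π/L)(n<sub>x</sub>, n<sub>y</sub>,
   n<sub>z</sub>). The longitudinal polarization follows from the charge
   density, P<sub>L</sub>(**k**) = (i/|k|) Σ<sub>j</sub> q<sub>j</sub>
   e<sup>−i**k**·**r**<sub>j</sub></sup>; the transverse part uses
   molecule-resolved polarization vectors built with the
   Raineri–Friedman line-charge construction, whose divergence reproduces
   the charge density exactly.
2. **Kubo susceptibility.** From the normalized correlation function
   φ(k,t) = ⟨P*(k,0)P(k,t)⟩/⟨|P(k,0)|²⟩ (averaged over all time origins
   and over each |k| shell),
   χ(k,ω) = χ(k,0)·[1 + iω ∫₀^∞ φ(k,t) e<sup>iωt</sup> dt], with
   χ<sub>L</sub>(k,0) = ⟨|P<sub>L</sub>|²⟩/(ε₀Vk<sub>B</sub>T) and
   χ<sub>T</sub>(k,0) = ⟨|P<sub>T</sub>|²⟩/(2ε₀Vk<sub>B</sub>T).
3. **Lineshape fits.** Im χ is fit with Debye + Van Vleck–Weisskopf
   resonance terms, Im χ = Δχ·ωτ<sub>D</sub>/(1+ω²τ<sub>D</sub>²) +
   (A/2)·ω·[γ/((ω−ω₀)²+γ²) + γ/((ω+ω₀)²+γ²)], giving ω₀(k) and the
   lifetime τ = 1/γ per branch; from these the dispersion slope
   v<sub>g</sub> = dω/dk, the splitting ω<sub>LO</sub> − ω<sub>TO</sub>
   at the smallest k, and the propagation range R = τ·v<sub>g</sub>.
4. **Distance decomposition.** Restricting the cross-molecular sum to
   pairs within radius R separates self and distinct contributions and
   reveals how far the collective mode reaches.
5. **Optical constants.** Tabulated n(ω), k(ω) give ε = (n+ik)²,
   χ<sub>T</sub> = ε−1 (TO peaks) and χ<sub>L</sub> = 1−1/ε (LO peaks),
   so experimental tables yield the same LO/TO analysis at k→0.
6. **Generalized Lyddane–Sachs–Teller check.** ε(0)/ε(∞) is compared
   with Π(ω<sub>D,L</sub>/ω<sub>D</sub>)·Π(|ω<sub>L</sub>|²/ω<sub>T</sub>²),
   damped longitudinal modes entering through |ω<sub>L</sub>|² = ω² + γ².

Because the full analysis needs nanosecond trajectories of real water
models, the package ships a **Langevin dipole-lattice generator** with
analytically known (planted) dynamics — on-site frequency, damping,
nearest-neighbour coupling (→ dispersion) and a mean-field longitudinal
term Δ (→ LO–TO splitting, ω<sub>L</sub>² = ω<sub>T</sub>² + Δ²) — so
every pipeline stage is validated against closed-form truth.

## Worked example

A 4×4×4 dipole lattice (64 molecules, 8192 frames at 4 fs) with the
default water-like conditions — on-site frequency 632 cm⁻¹, damping
29.47 cm⁻¹, coupling κ = 4×10⁴ cm⁻², mean-field Δ = 640.8 cm⁻¹:

```python
import numpy as np
import phonliq as pq

cfg = pq.LangevinDipoleConfig(n_cells=4, n_frames=8192, seed=1)
traj, truth = pq.generate_langevin_trajectory(cfg)
kset = pq.enumerate_wavevectors(traj.box_edge, 1)
series = pq.compute_polarization(traj, kset)

fits = {}
for comp in ("L", "T"):
    corr = pq.correlation_function(series, 0, comp, max_lag=3.0)
    chi0 = pq.static_susceptibility(corr.amplitude, comp,
                                    series.volume, series.temperature)
    spec = pq.susceptibility_spectrum(corr, chi0, np.arange(0., 2000., 2.))
    fits[comp] = pq.fit_band(spec)
    print(f"{comp}: chi0 = {chi0:.2f}, omega0 = {fits[comp].omega0:.1f} cm^-1, "
          f"gamma = {fits[comp].gamma:.1f} cm^-1, tau = {fits[comp].tau_ps:.3f} ps")

split = pq.lo_to_splitting(fits["L"].omega0, fits["T"].omega0)
k1 = kset.vectors[kset.shells[0][0]]
print(f"fitted LO-TO splitting = {split:.1f} cm^-1 "
      f"(planted {truth.splitting(k1):.1f} cm^-1)")
```

prints

```
L: chi0 = 8.00, omega0 = 942.2 cm^-1, gamma = 30.6 cm^-1, tau = 0.174 ps
T: chi0 = 14.82, omega0 = 690.3 cm^-1, gamma = 27.5 cm^-1, tau = 0.193 ps
fitted LO-TO splitting = 252.0 cm^-1 (planted 251.0 cm^-1)
```

The fitted resonance of each branch lands on the planted lattice
dispersion at the first wavevector shell (|k| = 2π/1.24 nm⁻¹ here), the
fitted damping reproduces the planted 29.47 cm⁻¹ within sampling error,
and the LO–TO splitting recovers the planted value within 1 cm⁻¹.

The same pipeline is available from the shell:

```sh
phonliq synth --out run --seed 1
phonliq spectra --traj run.extxyz --out run.h5 --csv run.csv
phonliq fit --spectra run.h5 --out fit.json
phonliq report --fit fit.json
```

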