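# Methods

## Model and observables

The package treats a polar liquid as a set of neutral molecules with
partial charges (or, in reduced form, point dipoles) in a cubic periodic
box of edge L. Periodicity restricts wavevectors to
k = (2π/L)(n_x, n_y, n_z) with integer triples; vectors of equal |k| are
grouped into shells and all estimators are averaged over shell members,
which reduces estimator noise (the ±k members are complex-conjugate
duplicates, so a 6-member shell carries 3 independent samples).

Longitudinal polarization comes from the charge density through
ik·P(k) = −ρ(k), i.e. P_L(k) = (i/|k|) Σ_j q_j exp(−ik·r_j). Transverse
polarization needs molecule-resolved vectors; these are built with the
line-charge (Raineri–Friedman) construction

    p_i(k) = exp(−ik·r_c,i) Σ_α q_α d_α φ(k·d_α),
    φ(x) = (1 − e^{−ix})/(ix),  φ(0) = 1,

with d_α the minimum-image displacement of site α from the molecular
reference point r_c,i. This choice makes the divergence identity
ik·Σ_i p_i(k) = −ρ(k) exact, so the charge-density and molecular routes
to P_L agree to rounding — a property the test suite checks on every
fixture. Two conventions here were genuinely open and are our own:

* the line integral runs from the molecular reference point to each
  site (reference-to-site), which is what the φ form above encodes;
* the reference point is the |q|-weighted centroid Σ|q_α|r_α / Σ|q_α| —
  symmetric, charge-based, and independent of masses.

The Fourier sign convention is exp(−ik·r) everywhere. The transverse
basis at each k is deterministic: e₁ = normalize(k × a) with a the
coordinate axis least aligned with k (ties broken x<y<z), e₂ = k̂ × e₁.

## Susceptibility

The normalized correlation function φ(k,t) uses the stationary estimator
(every frame is a time origin, computed by FFT; identical to the direct
O(N²) sum to 1e-10), clamped to lags ≤ 25% of the trajectory. The
classical Kubo relation then gives

    χ(k,ω) = χ(k,0) [1 + iω ∫₀^∞ φ(k,t) e^{iωt} dt],
    χ_L(k,0) = ⟨|P_L|²⟩ / (ε₀ V k_B T),
    χ_T(k,0) = ⟨|P_T1|² + |P_T2|²⟩ / (2 ε₀ V k_B T),

the transverse ½ expressing isotropy. The longitudinal fluctuation
formula is taken to yield χ_L ≡ 1 − 1/ε_L directly, keeping the
simulated observable on the same footing as the optical-constants route
(χ_L = 1 − 1/ε); the prefactors are isolated in one function
(`response.static_susceptibility`) so an amended convention is a
one-line change.

The one-sided Fourier transform uses trapezoidal quadrature with an
optional Hann taper over the final 10% of lags. If φ has not decayed
below 0.02 at the last lag, an exponential fitted to the final 20% of
lags is integrated analytically as a tail (and the taper is dropped so
the matched tail is not biased); with the tail disabled the condition is
only recorded as a metadata warning. The default reporting grid is
0–4000 cm⁻¹ at 2 cm⁻¹ spacing, spanning the librational and OH-stretch
regions. Frequencies convert as ν̃ = ω/(2πc) with c = 2.99792458×10⁻²
cm/ps, owned by one constants module (internal units nm, ps, e, K).

## Lineshape fitting

Im χ(k,ω) is fit with a Debye term plus one or two Van Vleck–Weisskopf
resonances (all frequencies in cm⁻¹):

    Debye:  Δχ · ωτ_D / (1 + ω²τ_D²)
    VVW:    (A/2) · ω · [γ/((ω−ω₀)²+γ²) + γ/((ω+ω₀)²+γ²)]

γ is the half-width and the lifetime is τ = 1/γ. In the underdamped
regime this resonance is numerically the damped harmonic oscillator with
full friction 2γ: at γ/ω₀ ≈ 0.013 the two profiles agree pointwise to
~1% of peak; at γ/ω₀ ≈ 0.1 they differ pointwise by ~9% of peak, yet a
VVW fit of an oscillator spectrum still recovers ω₀ within 2%. The VVW
normalization (the A/2 prefactor, making A the zero-frequency real
weight up to O(γ/ω₀)) is this package's explicit choice.

Fits use bounded (all parameters ≥ 0) trust-region least squares with a
deterministic, seedless initialization: ω₀ at the band argmax, γ from
the half-width, the Debye wing from the low-frequency residual. The
two-resonance model is staged — the one-resonance fit converges first,
then the second resonance is seeded at the residual's peak away from the
first. Parameter covariance comes from the Gauss–Newton approximation at
the solution; transverse lifetimes should not be trusted when the γ
uncertainty exceeds ~50% (`LineshapeFit.gamma_rel_uncertainty`).

Group velocities are the slope of ω₀(k) over a declared k-window or,
absent one, the longest contiguous window of ≥3 points with linear
R² ≥ 0.98; conversion is v_g[m/s] = 2πc × 10⁻⁹ × slope[cm⁻¹·nm]. The
propagation range R = τ·v_g is reported both exactly and rounded to one
significant figure. The generalized Lyddane–Sachs–Teller report compares
ε_static/ε_inf with Π(ω_{D,L}/ω_D)·Π(|ω_L|²/|ω_T|²) where damped
longitudinal modes enter through |ω_L|² = ω_res² + γ²; this is exact for
a single damped Lorentz dielectric (the quadratic's root modulus is
independent of damping), which the tests exploit as an oracle. Modes
below a configurable cutoff (default 300 cm⁻¹) can be excluded, since
the many overlapping hydrogen-bond modes there are poorly constrained by
any small set of Debye terms.

## Distance decomposition

The double molecular sum in C(k,t) is restricted to pairs within radius
R of each molecule i, with three conventions that were open choices:

* sphere membership is frozen at the lag origin (molecules do not enter
  or leave during a lag window);
* distances are between molecular reference points, minimum-image, at
  the origin frame;
* every family member is normalized by the full C(k,0), so members
  converge toward the full normalized response as R grows (rather than
  each being self-normalized).

R = √3·L/2 is the largest minimum-image distance; at that radius the
code reuses the full-response estimator path, so the largest member
reproduces the undecomposed correlation bit for bit. Self and distinct
parts satisfy self + distinct = full exactly by construction. Gaussian
smoothing (σ = 10 cm⁻¹) is available for plotting only and is never
applied to quantities that are fit.

## Synthetic data: what it emulates and what it does not

The generator integrates one 3-component dipole per site of an n×n×n
cubic lattice under damped-harmonic Langevin dynamics:

    μ̈ = −Ω² μ − 2γ μ̇ + ξ(t)

where Ω² contains the on-site ω₀², a nearest-neighbour coupling κ acting
through the lattice Laplacian, and a k-independent mean-field term Δ²
applied (via FFT) to the longitudinal projection of the dipole field
only. The planted branches are therefore known in closed form:

    ω_T(k)² = ω₀² + 2κ Σ_a (1 − cos k_a a),
    ω_L(k)² = ω_T(k)² + Δ².

Δ is the simplest controllable analogue of the long-range dipole–dipole
interaction that splits LO from TO; a full Ewald dipole lattice is out
of scope because the estimator pipeline, not a force field, is under
test. Parameter conventions: the configured γ (cm⁻¹) is the lineshape
half-width (hence friction 2γ in the equation of motion, and the
overdamped limit relaxes with τ_D → 2γ/ω₀²); only k_B T/(dipole inertia)
enters the dynamics, and it is fixed by declaring the configured dipole
magnitude μ to be the r.m.s. thermal dipole of an uncoupled site
(⟨μ̇_x²⟩ = μ²ω₀²/3, verified by the equipartition test). The temperature
in kelvin is carried into the emitted trajectory and used only in the
susceptibility prefactor.

Integration is BAOAB with the exact Ornstein–Uhlenbeck velocity step;
configs must satisfy dt < 0.1/ω_max (rad/ps), which keeps the
velocity-Verlet frequency bias far below the fit tolerances. Runs are
bit-reproducible for a given seed. Two emission modes exist: point
dipoles (consumed directly), and a 3-site mode placing ±q at ±d/2 about
each site with q·d equal to the instantaneous dipole plus a neutral
spectator — exercising the line-charge construction end to end.

Default conditions mirror an ambient-water simulation cell: 8×8×8 = 512
molecules at a = 0.31 nm spacing (2.48 nm box, roughly 512 waters at
ambient density), ω₀ = 632 cm⁻¹ and γ = 29.47 cm⁻¹ (a 0.18 ps
lifetime), Δ = 640.8 cm⁻¹ (so the planted k→0 LO/TO pair is
900/632 cm⁻¹), κ = 4×10⁴ cm⁻², μ = 0.048 e·nm (≈ 2.3 D), 2¹⁴ frames at
4 fs output spacing (65.5 ps), dt = 0.4 fs. This fixture runs in about
a minute on one CPU; the test suite uses 4×4×4 variants (a few seconds
each) where molecule-resolved storage or repeated runs are needed.

What the planted model does **not** emulate: anharmonicity, molecular
translation and exchange, hydrogen-bond network topology, induced
(polarizable) dipoles, and the multi-band structure of real water.
Passing tests therefore demonstrate that the estimator chain — k-vector
enumeration, polarization components, correlation estimation, Kubo
transform, lineshape fitting, splitting and decomposition — is correct
and unbiased at realistic amplitudes and noise levels; they do not
validate any force field.

The Lorentz-oscillator generator provides the optical-constants
counterpart: ε(ω) = ε_inf + Σ ω_p²/(ω₀² − ω² − iγω), emitted as n, k
tables (principal square root, n ≥ 0), for which the LO frequency
√(ω₀² + ω_p²/ε_inf) and the LST ratio are known exactly.

## Numerical choices and degenerate inputs

* Shells are grouped by integer |n|², so membership is exact, with a
  deterministic (|n|², lexicographic) ordering.
* φ(x) in the line-charge construction switches to its series below
  |x| < 1e-7 to avoid cancellation.
* Peak extraction from gridded spectra uses windowed argmax plus 3-point
  quadratic refinement; monotone spectra in the window raise rather
  than return an endpoint.
* Neutrality is enforced per molecule at 1e-9 e; non-cubic boxes,
  empty trajectories, zero wavevectors, non-ascending radii and
  oversized radii are rejected or clamped with explicit messages.
* Fit determinism: identical inputs give identical fits; no randomness
  anywhere in the fitting path.

## Known limitations

* The transverse molecular route is O(n_k · n_frames · n_sites); for
  large site-resolved trajectories the point-dipole reduction is the
  practical path.
* Per-molecule storage for distance decomposition is O(n_k_kept ·
  n_molecules · n_frames) complex and is therefore opt-in
  (`keep_molecular`).
* The Kramers–Kronig helper is a grid-quadrature diagnostic, adequate
  for the 5%-level consistency checks it serves, not a production
  transform.
* The generalized LST report treats modes as independent; strongly
  overlapping Debye + resonance regions (as in real water below
  300 cm⁻¹) make the factorization approximate, which is exactly why
  the low-frequency cutoff option exists.
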