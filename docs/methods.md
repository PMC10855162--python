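# Methods

## Scattering model

Point nuclei at positions R⃗_j(t) scatter neutrons with Q-independent
coherent/incoherent scattering lengths b_j^coh, b_j^inc (fm); X-rays see the
atomic form factor f(Q), represented by the standard four-Gaussian
(Cromer–Mann) sum. The coherent scattering function is the
orientation/time average of the squared amplitude,

    S(Q) = ⟨ |Σ_j b_j e^{iQ⃗·R⃗_j(t)}|² ⟩_{t,Ω},

and the incoherent intermediate scattering function is the self-correlation

    I_inc(Q,τ) = Σ_j (b_j^inc)² ⟨ e^{iQ⃗·[R⃗_j(t+τ)−R⃗_j(t)]} ⟩_{t,Ω}.

Assumptions: classical point scatterers (no inelasticity beyond what the
trajectory contains, no anomalous/magnetic terms), cuboid periodic cells,
and static scattering lengths per species. Amplitudes are computed in fm;
scattering length *densities* use Å⁻² with the fm→Å conversion (1 fm =
10⁻⁵ Å) applied only at that boundary.

## Orientational averaging

The average over Q⃗ directions is a Monte-Carlo mean over n_Ω unit vectors
drawn as normalised 3-component Gaussians (exactly uniform on the sphere)
from a seeded `numpy` generator. One orientation set is drawn per run and
reused for every Q magnitude and frame: two curves computed in the same run
(e.g. naive vs Q-clean) then differ only by the physics, not by sampling
noise, and corrections cancel sample-by-sample. Whether fresh orientations
per Q magnitude would be preferable is a genuinely open choice; the fixed
set was chosen for exactly this variance-cancellation property and is
recorded in the output header via the seed. The MC standard error reported
per Q is the spread of the frame-averaged per-orientation intensities over
orientations, divided by √n_Ω.

Q = 0 is evaluated exactly (every phase factor is 1, S(0) = (Σb)²) rather
than skipped, since the production grids start at 0.

## Wrapped vs unwrapped trajectories

Diffraction needs the correct density inside the cell → wrapped input;
time correlations need continuous paths → unwrapped input. The flag is
user-declared, cross-checked by a containment test for wrapped input
(cell convention `[origin, origin+edges)`, default origin 0), and each
calculation refuses the wrong convention unless forced. The coherent
intermediate scattering function in *time* is deliberately not offered:
it would need both conventions at once, which is contradictory; the CLI
rejects the combination with that explanation.

## Finite-size corrections

**r-clean.** ρ̄_sol = Σ b_n / Σ V_n^vdW over the solvent selection (van der
Waals spheres; a `cell-volume` variant divides by an explicit per-atom cell
volume for synthetic lattices, whose sites have no physical vdW radius —
for the lattice toy the sidecar species' vdW radius is chosen so that
V^vdW = 1 Å³ = the cell volume, making both routes agree). Every atom's
length becomes b_j − ρ̄_sol·V_j^vdW and the naive pipeline runs unchanged.
The method's known global intensity shift is *not* silently rescaled;
`fit_scale_factor` computes the least-squares factor explicitly (for the
toy it is (Δb/b_solute)² ≈ 7.71 against the solute-only reference).

**Q-clean.** The analytic amplitude of a homogeneous cuboid,
F_box = e^{iQ⃗·R⃗_c}·ρ̄·abc·sinc(Q_x a/2)·sinc(Q_y b/2)·sinc(Q_z c/2) with
sinc(x) = sin(x)/x, sinc(0) = 1, is subtracted from the system amplitude
per (frame, Q, orientation) *before* squaring. Fixed-box semantics: one
configured cuboid for all frames, required to match the trajectory cell
within 1% per edge (override with force). Non-cuboid cells are rejected.
SLD input accepts a `sld_scale` (typically 1e-5) so values can be entered
in the 10⁻⁵ Å⁻² table convention.

## Autocorrelation and diffusion fits

The time-origin average uses the unbiased all-origins estimator
C(k) = (M−k)⁻¹ Σ_t s(t+k)s*(t), evaluated by zero-padded FFT (padding to
the next power of two ≥ 2M); it agrees with the direct O(M²) sum to 1e-10
and keeps the large-τ tail quiet. `fit_diffusion` fits
I_norm = exp(−Q²Dτ) by a log-linear least-squares fit through the origin
restricted to the initial decade of decay (I_norm ≥ 0.1), which is exact
for free diffusion and robust to the noisy tail.

## Synthetic systems: what they emulate and what they do not

* **Sphere-in-solvent lattice toy** (defaults: 20 Å cube, 1 Å simple cubic
  cell → 8000 sites, first site at (0.5, 0.5, 0.5), sphere R = 5 Å at the
  box centre (10, 10, 10), b_solute = −3.739 fm, b_solvent = 6.646 fm;
  membership rule r ≤ R, under which 552 sites are solute and none lies
  exactly on the surface). It emulates a nanoscale object in a finite box
  with exactly known geometry; it has no thermal disorder, no realistic
  pair correlations and a perfectly crystalline "solvent", so its
  wide-angle pattern is Bragg-like and only the small-angle region mimics
  real solute scattering.
* **Homogeneous lattice**: the same lattice with one species. Its naive
  small-angle signal is pure box artefact, so Q-clean must suppress it
  (measured factor ~10⁵ at Q = 0.2 Å⁻¹); it is the null test.
* **Brownian box** (defaults 500 particles, 46 Å box, D = 0.5 Å²/ps,
  dt = 0.1 ps, 2000 frames): independent Gaussian steps of per-axis
  variance 2D·dt, unwrapped. Its I_norm is *exactly* exp(−Q²Dτ), which is
  what makes it a parameter-recovery oracle — but it has no interactions,
  no hydrodynamics, no rotational or vibrational components, so passing
  tests demonstrate estimator correctness, not force-field realism.

Tests that pass on these systems validate the computational machinery
(amplitudes, averaging, corrections, correlators) — they say nothing about
whether a given MD force field reproduces experimental scattering.

## The toy's first minimum and the volume-equivalent radius

The Q-clean small-angle curve of the toy has its first minimum at
Q = 0.8833 Å⁻¹ (301-point grid on 0–1 Å⁻¹). This equals, to MC precision,
the exact Debye orientational average of the 552 discrete solute sites —
i.e. the correction is exact — but it is *not* the continuum value for the
nominal radius, 4.4934/5 = 0.899 Å⁻¹. The discrete solute occupies 552
unit cells = 552 Å³, a volume-equivalent radius R_eff = (3·552/4π)^{1/3}
= 5.094 Å, and 0.8833·R_eff = 4.495 reproduces the analytic first-zero
relation QR ≈ 4.4934 within one grid step. The analytic sphere reference
is therefore parameterised by R_eff; with the nominal R = 5 Å the minimum
positions differ by 1.7% in Q — a property of lattice discretisation, not
of the correction.

## Numerical choices

* Q-vector batches are chunked so the (N × n_Q·n_Ω) phase matrix stays
  within memory; results are independent of the chunk size.
* The Debye oracle is O(N²) and guarded (warning above N = 2000); it is
  validation-only.
* Normalisation of S(Q) to D(Q) is a pluggable mode (`per-atom`,
  `per-b2`, `none`, default `per-atom`): absolute-scale conventions are
  instrument- and workflow-specific, so none is hard-coded. I(Q,τ) is
  normalised by its τ = 0 value.
* dt is taken from configuration, never from DCD headers (unreliable).
* PDB element resolution falls back from the element columns to the atom
  name (digits stripped, two-letter symbols like CL recognised, water
  names OW/HW mapped to O/H).
* The shipped species table (H, D, C, N, O, P, S) uses Sears (1992)
  neutron lengths, International Tables Vol. C Cromer–Mann coefficients
  and Bondi (1964) vdW radii; it is replaceable/extendable via
  `--species-db`. Stored b_H is the full-precision −3.7390 fm.
* Water SLDs use the H₂O density at 300 K (0.996556 g/cm³) and assume the
  same molecular number density for all isotopologues; computed mixture
  SLDs agree with standard table values to ≲0.5% (the residual reflects
  rounded density/molar-mass digits in such tables).

## Problem sizes used in validation

Production-resolution toy curves use 301 Q points × 100 orientations
(seconds on one core). Oracle comparisons use ≤500-atom random boxes with
400 orientations; the wide-angle invariance check uses a 1000-atom box at
Q = 5–10 Å⁻¹; diffusion recovery uses the default Brownian fixture
(500 × 2000 frames, 2 Q values × 10 orientations). These sizes give MC
errors small enough for 3σ oracle tests and ≤5% parameter-recovery bias.

## Known limitations

* Cuboid cells only (both for trajectories and the Q-clean shape);
  triclinic cells and other subtraction shapes are rejected.
* Fixed-box Q-clean semantics: for NPT trajectories with a fluctuating
  cell the configured cuboid is an approximation (flagged by the 1% edge
  guard).
* No energy-domain S(Q,ω): comparisons are in the τ domain.
* No analytic orientational average for crystals: Bragg peaks need very
  dense orientation sampling, which the MC scheme makes expensive.
* Incoherent contributions are not added to diffractograms, and coherent
  time correlations are not computed (see wrapped/unwrapped dilemma).
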