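# Methods

## Problem

Photoacoustic tomography (PAT) reconstructs the optically generated initial
acoustic pressure `p0(r)` from boundary ultrasound measurements.  The
reconstruction needs the speed of sound `c(r)`, which is rarely known in
tissue; treating it as a second unknown makes the inverse problem severely
ill-posed.  This package implements a 2D joint inversion in which `I`
photoacoustic datasets — generated by *different* initial pressures inside
the *same* object (different illumination directions, wavelengths, or
exogenous boundary absorbers) — are inverted simultaneously for all `I`
initial pressure fields and the single shared `c` field.  The extra
datasets constrain `c` from multiple acoustic directions and measurably
reduce artefacts relative to the conventional single-dataset joint
inversion, which the twin experiment in `scripts/acceptance.py` and
`tests/test_acceptance.py` quantifies.

## Acoustic model and discretisation

The forward model is the lossless heterogeneous wave equation
`c^-2 p_tt - lap p = 0` with `p(.,0) = p0`, `p_t(.,0) = 0`, solved by a
k-space pseudo-spectral scheme: the first-order velocity/density system with
spectral derivatives on spatially staggered grids, a leapfrog time stagger,
and the k-space correction `sinc(c_ref k dt / 2)` applied in the spectral
propagator.  With `c_ref` equal to the medium speed the scheme is exact for
homogeneous media at any stable step (the test suite verifies machine-level
agreement with the closed-form free-space solution over 500 steps);
`c_ref = max(c)` is the default for simulation, while inversion fixes
`c_ref` at the *upper optimisation bound* so the propagator's spectral
filter does not depend on the unknown.  A hard stability guard rejects
`max(c) dt / dx > 2/pi`.

The domain is a square target region, a sensor margin band holding
point-like sensors snapped to grid nodes, and a split-field PML
(polynomial order 4, per-step peak absorption 2) whose measured boundary
reflection is below 0.01% of the incident peak — comfortably under the 1%
contract asserted in tests.  Initial conditions are injected by splitting
`p0` equally between the two density components and giving the first
velocity update a half step, which realises `p_t(.,0) = 0` to second order
(and exactly in the homogeneous spectral sense).

## Objective, priors, noise

The estimate minimises

```
eps(x) = sum_i 1/2 ||L_e^i (y^i - f_i(p0^i, c))||^2
       + sum_i 1/2 ||L_p0 (p0^i - eta_p0)||^2 + 1/2 ||L_c (c - eta_c)||^2
```

over `x = (p0^1..p0^I, c)` on the target pixels.  Measurement noise is
additive white Gaussian; its standard deviation is set to the noise level
times the peak-to-peak amplitude of the (noisy) dataset, so
`L_e = I/sigma_e`.  Each field carries an Ornstein–Uhlenbeck (exponential
covariance) Gaussian prior `Gamma = sigma^2 exp(-d/tau)`: correlated at
length `tau` yet heavy-tailed enough to admit sharp inclusions.  Prior
means are the midpoint of the expected parameter range and the standard
deviation is a quarter of that range, placing ~95% of prior mass inside
it.  Covariances are dense (Cholesky) up to 10^4 pixels; beyond that a
distance-truncated sparse approximation (drop below `exp(-d/tau) = 1e-4`)
with a sparse LU is used, validated against the dense route on overlapping
sizes.

## Gradients: exact discrete adjoint

Gradients come from one adjoint sweep per dataset.  The adjoint solver is
the *algebraic transpose* of the forward time stepper (same spectral
operators and PML factors, reversed order), driven by the weighted
residual `(f_i - y^i)/sigma_e^2` injected at the sensor nodes.  Its
terminal snapshot is exactly `F^T` applied to the weighted residual — the
initial-pressure gradient term — and the forward/adjoint pressure pairing
accumulated along the sweep, `(2/c) [sum_n p^n q^n - p0 q_T]`, is the
algebraically exact speed-of-sound gradient of the discrete objective
(the continuum equivalent is the classical time integral of
`-2/c^3 p_tt` against the time-reversed adjoint field; the discrete
pairing form is preferred because it is exact for the scheme actually
being differentiated).  Consequences verified by the tests: the adjoint
dot-product identity holds to ~1e-12 relative and finite-difference
gradient checks agree to ~1e-9, far inside the 1e-3/1e-2 contracts.
Margins and PML hold `c` at a fixed background value and `p0` at zero;
gradients exist only on target pixels.

## Optimisation

Bound-constrained L-BFGS (memory 20): two-loop recursion seeded with
`H0 = (kappa.phi)/(phi.phi) I`, curvature pairs rejected below
`1e-10 ||kappa|| ||phi||`, elementwise projection `P(z) = clip(z, L, U)`
inside an Armijo backtracking search (`c1 = 1e-4`, halving, first step
scaled by `1/||g||_inf`) evaluated at projected trial points.  Bounds:
`p0 >= 0`; `c` in `[1300, 1800]` m/s (upper bound 3000 for the bone-like
high-contrast phantom).  A level stops after 5 consecutive relative
objective decreases below 1e-4 or at its iteration cap.  Line-search
objective evaluations store their forward solves so the subsequent
gradient call at the accepted point reuses them (one forward pass per
dataset per iteration is saved).

## Multigrid continuation

The joint objective is non-convex (cycle skipping).  Reconstruction starts
on a coarse grid — supporting only low frequencies, hence a smoother
objective — and the converged estimate is bilinearly prolonged (on
physical pixel-centre coordinates, clamped to the hull so bounds survive)
to the next finer grid as its initial guess; priors, sensors and bounds
are rebuilt per level and the measured data are low-passed at the level's
supported band `min(c)/(2 dx)` (zero-phase Butterworth, order 6) and
linearly interpolated onto its time axis.  The L-BFGS history is grid
specific and restarts at each level.  The driver refuses schedules that
reuse the data-simulation `dx` (inverse crime) unless overridden.  The
initial guess on the coarsest level is zero pressure and the prior-mean
speed.  Published discretisation tables round pixel sizes, so level
extents need not tile the nominal domain exactly; extents are allowed to
differ by up to 8% and the sensor inset is adjusted per level to keep the
sensor ring on the same physical contour as during data simulation.

## Synthetic data

*Simple phantoms* (20 mm domain): nine 1580 m/s disks in a 1430 m/s
background, optional 1482 m/s water-bath layer, optional 2500 m/s
bone-like rectangle; four initial-pressure datasets of 10 Pa disks in
distinct spatial arrangements.  The inclusion layout is a parameterised
default approximating the canonical figure arrangement — the exact
geometry is not published — so full-scale error values are expected to be
geometry-approximate.  Rasterisation is centre-inside-region; disk areas
converge to `pi r^2` under refinement (tested).

*Tissue-mimicking phantom*: a procedural 2D breast-like stand-in
(volume-fraction maps for oxy-/deoxyhaemoglobin, water, fat; vessel-like
curvilinear structures; reference reduced scattering with power-law
wavelength scaling, exponent 1.2; a smoothly heterogeneous speed of sound
in 1430–1580 m/s).  Initial pressures are `Gamma_gruneisen mu_a phi`
(Grueneisen scale 1 — the overall pressure scale is arbitrary by
linearity) with the fluence `phi` from a continuous-wave
diffusion-approximation model: `-div(kappa grad phi) + mu_a phi = 0`,
`kappa = 1/(2(mu_a + mu_s'))` (2D convention), Robin boundary condition
`kappa dphi/dn + phi/2 = I_s` with unit inward flux on illuminated sides,
finite-volume five-point discretisation with harmonic-mean face
diffusivities.  The bundled chromophore table is a representative
synthetic stand-in at literature scale (600–1000 nm), not measured
spectra.  Verified generator properties: multi-illumination pressure sets
are pairwise >10% apart in relative L2 (the mechanism that eases the
ill-posedness), while multi-wavelength sets are shape-similar
(normalised cross-correlation >0.9) — reproducing the known limitation
that wavelength diversity alone changes amplitude more than geometry.
What the generator does *not* emulate: 3D light and sound propagation,
acoustic absorption/dispersion, finite-bandwidth or directional sensors,
and real measured-system noise correlations — so passing tests demonstrate
correctness of the method under the stated model, not hardware-level
fidelity.

## Experiment scales

The desk-scale twin experiment uses a 12.8 mm domain: a 64^2 data grid
(0.2 mm pixels, 320 x 40 ns samples, 64 sensors 0.4 mm outside the target)
with three 1580 m/s inclusions and four initial-pressure datasets; 1%
peak-to-peak Gaussian noise; a two-level schedule (28^2 at 0.457 mm, then
40^2 at 0.32 mm).  Iteration caps (50 coarse, 110 fine) are set so the
fine level terminates through the relative-decrease stopping rule rather
than the cap — the joint mode fits four datasets and genuinely needs
~90 fine-level iterations, and stopping it early understates its
advantage.  These sizes keep a full proposed-plus-reference comparison
around two minutes per noise seed on one CPU while leaving several
acoustic wavelengths across every inclusion.  The full-scale pipeline (335^2 data grid, four-level
schedule down to 156.3 um, 236 sensors) is provided in
`scripts/reproduce_full_scale.py` and takes hours per run.

## Numerical choices and edge cases

- FFTs are real-to-complex (`rfft2`), float64 throughout.
- `second_time_derivative` uses centred differences with second-order
  one-sided stencils at the ends.
- Temporal resampling refuses to extrapolate beyond the recorded horizon;
  identical axes return data bit-for-bit.
- Sensor snapping is nearest-node; duplicate nodes after snapping on very
  coarse grids are merged (layouts are deterministic).
- The sign convention ties the residual `f - y` to a descent-consistent
  gradient; all sign choices are pinned by finite-difference tests rather
  than convention arguments.
- Line-search failure clears the L-BFGS history and retries steepest
  descent once; a second failure ends the level with a warning status.

## Known limitations

2D only; no acoustic absorption or density heterogeneity; white noise
only (no time-correlated noise models); slowness/squared-slowness
parameterisations are not implemented; the multi-wavelength route is
included as a study condition even though it barely helps — as expected
from the shape-similarity of its generated pressures.
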