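# Methods

## Scope and units

The package analyses time-resolved 2D velocity fields `(u, v)` on a
regular node-centered grid, `x` cross-stream and `y` streamwise, CGS
units throughout (cm, s; stresses in cm²/s², strain rates in 1/s, flux
densities in cm²/s³).  Units are recorded in file metadata and never
converted silently.

## Filter-space technique

The low-pass filter at cutoff `L` is applied per frame by FFT on a padded
copy of the field.  Kernels, defined by their transfer function G(k):

| kernel | G(k) | L-mapping |
|---|---|---|
| `gaussian` (default) | exp(−k²σ²/2) | σ² = L²/12 (second moment of a top-hat of width L) |
| `sharp-spectral` | 1 for \|k\| ≤ k_c | k_c = π/L |
| `top-hat` | sinc(k_x L/2)·sinc(k_y L/2) | box width L |

The gaussian default keeps the subgrid Reynolds stress
positive-semidefinite (it is a filtered outer product with a positive
kernel); the sharp filter is an exact spectral projector and is used for
the projector-algebra checks and sensitivity comparisons.

Padding extends the frame by `mirror` (default), `periodic` or `zero`
before the FFT; pad widths are 8σ (gaussian), 0.6L (top-hat) and 3L
(sharp, whose sinc kernel decays slowly — sharp filtering of non-periodic
data is approximate by nature).  Filtering near a boundary is
contaminated by the extension, so all reported spatial averages exclude
an interior margin, L/2 by default.  Closed-form checks (a linear field
is invariant under a symmetric kernel; the laminar-shear flux vanishes)
are asserted at margin 2L ≈ 7σ, where mirror-extension contamination —
which decays only as a Gaussian tail of the distance to the edge — is
below 1e−8; at the default L/2 (≈1.7σ) it is at the percent level, which
is fine for flux averages but not for 1e−8 assertions.

Masked nodes (swimmer bodies, unsupported reconstruction nodes) are
handled by normalized convolution: filter the zero-filled field and the
mask indicator, divide, and mask output nodes whose coverage falls below
0.5.

## Stress tensors and eigenframes

`tau_ij(L) = (u_i u_j)^L − u_i^L u_j^L` and its exact splits (classical
Leonard/cross/subgrid-Reynolds, and the generalized-central-moment form
whose parts are invariant under a uniform velocity offset) are built from
the same filter configuration throughout; the identity
`tau = Leonard + cross + tau_S` holds to roundoff by construction and is
asserted, not assumed.

Strain rates use 2nd-order centered differences (one-sided at edges), so
the same code path serves non-periodic PTV-like fields and periodic
solver output; spectral differentiation is available behind a flag for
periodic fields.  For a 2D deviatoric symmetric tensor `[[a, b], [b, −a]]`
the eigenvalues are ±√(a²+b²) and the extensional eigenvector angle is
`atan2(b, a)/2`, an axial quantity reported in [0, π); angle differences
are folded to [0, π/2].  Nodes whose deviatoric magnitude is below
1e−12 of the field rms are flagged degenerate (orientation undefined) and
excluded from alignment statistics.

The default reported flux is `Qs` (subgrid-Reynolds part): it dominates
the net transfer, and the Leonard/cross parts are the ones most
contaminated by edge padding in a finite interrogation window.  `Q` is
computed alongside for comparison.

## Synthetic data generator

The generator reproduces the laboratory conditions the analysis assumes:

- **Grid / window**: 7 cm × 7 cm at dx = 0.07 cm (101×101 nodes).
- **Shear**: streamwise-uniform `v(x)`, linear ramp −1.2 to +1.2 cm/s
  across 7 cm (γ = 0.343 1/s); a tanh profile with matched central slope
  is available.
- **Jet**: Gaussian-plume planar jet.  The cross-profile half-width grows
  as b(s) = b0 + 0.11·s with b0 = d/√π, and the axial speed decays as
  √(b0/b(s)), which conserves the momentum flux ρU0²d exactly until a
  smooth far-field cutoff (speed < 1% of U0 beyond the stated extent).
  Swimmer-scale default: d = 0.3 cm, U0 = 2 cm/s, matching a
  centimeter-scale swimmer's wake strength; an optional spectral Helmholtz
  projection removes the envelope's residual divergence (Nyquist modes are
  dropped there, where spectral differentiation of a real field is
  ill-defined).
- **Swimmer events**: the jet is anchored at the swimmer position,
  antiparallel to the swimming direction; the folded angle between
  swimming direction and the shear's extensional eigenvector must equal
  the declared `theta_s` to 1e−9 (checked, not fixed up).
- **Schedules**: on/off intervals are exponential with the stated mean
  (14 s default, the laboratory pulsing of the analog jets).
- **PTV emulation**: particles seeded uniformly (9,000/frame, 60 fps
  defaults), advected by classical RK4 with the frame interval subdivided
  ×4, velocity sampled by linear space–time interpolation; exiting
  particles are truncated and reseeded under fresh ids; Gaussian position
  noise is optional; track velocities come from finite differences of the
  (noisy) positions.  Reconstruction is per-frame cubic (Clough–Tocher)
  scattered interpolation onto the grid; nodes outside the sample hull
  are masked, frames with < 50 samples are masked entirely.
- **Measurement noise in the scenario suite**: additive Gaussian velocity
  noise, sd 0.02 cm/s (≈3 % of u_rms), 6 frames per case.  This stands in
  for PTV measurement scatter (not quantified in the laboratory pipeline)
  and gives the pure-shear case a finite, measurable noise floor
  (3 standard errors across frames) against which flux signs are judged.

What the generator does *not* emulate: near-body boundary layers (the
laboratory pipeline premasks the body region too), jet entrainment and
return flow in a thin fluid layer, and genuine PTV failure modes
(mismatches, clustering).  Passing tests therefore demonstrate the
correctness and sensitivity of the *analysis*, not the fidelity of any
particular laboratory dataset.

## Quasi-2D solver

Vorticity–streamfunction pseudo-spectral solver on a doubly periodic
square: 2/3-rule dealiasing, classical RK4 with exact integrating-factor
treatment of viscosity ν k² and Rayleigh friction α (the large-scale
energy sink of quasi-2D laboratory flows — dissipation proportional to
kinetic energy).  Velocities are derived from the streamfunction and are
divergence-free to spectral precision.  A single Fourier mode with no
nonlinear partner decays by exp(−(νk²+α)dt) per step exactly; with
ν = α = 0 the energy drift over 500 steps is below 1e−6 (both asserted).

**Shear forcing**: single-mode Kolmogorov force F·sin(2πx/D)·ŷ whose
laminar response v(x) = F sin(2πx/D)/(νk²+α) is the shear band; runs are
initialized at this analytic steady state plus seeded noise (amplitude
1e−6), so the no-jet flow is laminar by construction.

**Jet forcing**: a compact Gaussian momentum source at a controlled angle
to the band's extensional eigenvector (π/4 from the x-axis at the band
center), ramped over 0.2 s and pulsed by the exponential schedule.  Two
variants exist: a single blob (a dispensing needle injects momentum) and
a force-free pusher dipole (two opposed blobs separated by 1.5 jet
widths along the axis).  The geometry experiment defaults to the dipole:
a swimmer exerts no net force on the fluid, and at desk-scale amplitudes
the net momentum of a single blob drifts the band and contaminates the
gradient diagnostic with a common-mode bias that has nothing to do with
the flux geometry.

**Geometry-experiment conditions** (chosen once to keep the jet a weak
perturbation — in the laboratory analog the jets did not measurably alter
u_rms): 128² modes, domain 10 cm, ν = 0.01 cm²/s, α = 0.08 1/s, dt =
0.01 s, shear forcing 0.084 (band amplitude 1 cm/s, central gradient
0.63 1/s), jet amplitude 0.2 cm/s², width 0.5 cm (≈1/10 of the band
half-width, echoing the swimmer-to-shear scale ratio), mean pulse
interval 5 s, duration 30 s.  `P̃ = P_jet/P_ref` uses the mean of centered
differences of `v` over a window of half-width D/8 around the band
center, against a paired no-jet run from the same initial state.  The
experiment reproduces the sign structure (P̃ > 1 at θs = 0, < 1 at π/2,
nearest 1 at π/4); the magnitudes are solver-scale, not laboratory-scale.

## Numerical choices and degenerate inputs

- Filter cutoffs must satisfy 2·max(dx, dy) < L < domain extent.
- Eigenframe ties: isotropic tensors yield NaN angles and are excluded
  from alignment statistics rather than assigned an arbitrary axis.
- The effective viscosity ν_e = Q/(2 S:S) masks nodes where S:S falls
  below 1e−14 of its mean.
- `P` uses the mean of centered differences (the endpoint secant for
  exactly linear data); a least-squares slope estimator is provided and
  reported alongside, since the diagnostic is estimator-sensitive on
  curved profiles.
- Scenario runs are bitwise reproducible from (config, seed); every
  bundle carries a manifest with the config hash and versions.

## Problem sizes

Default analyses use the 101×101 laboratory-scale grid with 6 frames per
scenario and 8 filter scales (0.5–6 cm); the solver experiments use 128²
modes for 30 model seconds per run.  These sizes resolve the jet, the
band and the filter-scale sweep while keeping a full suite (tests plus
the acceptance script) to a few minutes on one CPU.

## Known limitations

- The laboratory flux magnitudes and P̃ values are properties of the
  physical tank (forcing strength, friction, swimmer vigor); the package
  reproduces the geometric sign structure and orderings at desk scale,
  not those magnitudes.
- Sharp-spectral filtering of non-periodic data relies on padding and is
  not a true projector there.
- The solver is doubly periodic with a single friction coefficient; no
  walls, no vertical structure, no magnetohydrodynamics.
- 2D only: the three-dimensional generalization of the alignment argument
  is outside the package's scope.
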