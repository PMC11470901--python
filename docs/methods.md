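# Methods

This note records the models implemented in `cortifield`, the numerical
choices behind them, and the limits of what the shipped tests demonstrate.

## Field model and conventions

The cortical sheet is a flat 2D lattice; a site `(i, j)` sits at
`origin + (i*dx, j*dy)` (row-major, 0-based).  The complex field
`phi = u_e + i*u_i` carries excitatory activity in its real part and
inhibitory activity in its imaginary part.  All quantities are
nondimensional; time and length units are chosen to minimise constants, so
the Klein–Gordon family is parameterised only by the wave speed `c >= 0`
and mass term `m >= 0` (the composite expansion constants are absorbed:
`c^2` is the negative-definite combination of connectivity gain and
sigmoid slope, `m^2 c^4` the intrinsic intracolumnar restoring term).
Because every governing equation is second order in time, a state is the
pair `(phi, phi_dot)`.

Five families share one right-hand-side convention (see README table).
`QuarticParams.c0` bundles the constant restoring terms (`a0^2 + a1`);
contributions from higher sigmoid-expansion orders enter the dispersion
with the same powers of `k` and are folded additively into the same
coefficients, so the API carries a single effective set.  `a2, a3 >= 0` is
enforced so `omega^2 >= 0` at all wavenumbers.

## Discretization and integration

* Space: 5-point Laplacian; the biharmonic operator is that stencil applied
  twice (bit-for-bit), i.e. a 13-point effective stencil.  Boundaries are
  periodic (default, matching plane-wave analysis) or reflecting
  (zero-flux mirror), selected per grid.  Long-wavelength regimes keep the
  O(dx^2) stencil error subdominant.
* Time: explicit Störmer–Verlet (leapfrog) on `(phi, phi_dot)`; second
  order, symplectic for the linear/Hamiltonian families.  The nonlinear
  cubic/quintic terms are evaluated explicitly at the current step; a
  divergence detector reports the first blow-up time (|phi| > 1e6).
* Stability: leapfrog is stable for `dt * omega_max <= 2`;
  `stable_dt` evaluates `omega_max` from the largest stencil eigenvalue
  `4/dx^2 + 4/dy^2` (shifted by the spectral norm of `G` for tessellated
  runs) and applies a safety factor of 0.5.  "auto" time steps are
  `stable_dt / 4`.  A free field (no restoring or propagating term) gets a
  fallback step of 1.0.
* The first-order complex form (pure intrinsic rotation `-i*phi`) is not a
  separate integrator: the second-order forms are the implemented models,
  and the `c = 0` Klein–Gordon limit recovers frozen/decoupled sites.

The discrete energy is the integrator's shadow invariant: evaluated in the
staggered form `E_{n+1/2} = ||(phi_{n+1}-phi_n)/dt||^2 + Re<phi_{n+1}, A phi_n>`
(same spatial stencil as the integrator), it is conserved to roundoff for
the linear families — the package's primary conservation diagnostic.  The
instantaneous Legendre-transform energy is also available; it oscillates at
O(dt^2).  At stride 1 the leapfrog recursion satisfies the discrete field
equation exactly, so Euler–Lagrange residuals are evaluated on
coarser-sampled snapshots (stride >= 2) where they converge at second
order in the sampling interval.

## Spectra and units

The analytic power-over-frequency curve
`P(f) = 1/(c0 + (a2/c^2) f^2 + (a3/c^4) f^4)` has a plateau at `1/c0`, a
−2 log–log slope where the quadratic term dominates, and −4 where the
quartic term dominates; the crossover is `f* = c sqrt(a2/a3)`.  Slope
bands default to `[f*/100, f*/10]` and `[10 f*, 100 f*]`.  The shipped
spectral configuration uses the units map 1 model frequency unit = 1 Hz at
a propagation speed of 10 mm/s, with `a2/c^2 = 1` and `a3/c^4 = 1e-4`,
placing the crossover at 100 Hz; only the ratio is pinned, the individual
coefficients are a free choice recorded in the config.  The plateau
constant `c0 = 1e-4` keeps the plateau outside the fitted low band.

Empirical dispersion is measured by projecting each snapshot onto the known
spatial mode `e^{-i k.r}`, unwrapping the phase of the projection and
fitting a line against time; at least two full revolutions are required.
Plane-wave initial data use the discrete-stencil eigenvalue
`4 sin^2(k dx/2)/dx^2 + ...` so the wave is an exact travelling eigenmode
of the semi-discrete system.

## Stability of the limit cycle (important caveat)

The cubic field equation
`phi_tt = -phi + c1 Lap(phi) - i (c2 + c3 |phi|^2) phi` has homogeneous
relative equilibria `phi = r0 e^{i Omega t}` with `r0 = sqrt(-c2/c3)` and
`Omega = +-1`.  Linearising gives (besides the neutral global-phase mode)
the cubic `lambda^3 + 4 lambda + 4 Omega c3 r0^2 = 0`, which always has a
root with positive real part: the radius is **not** attracting — a radial
"breathing" perturbation grows at a rate of roughly `|c2|/2` and the
nonlinearity then drives blow-up rather than saturation.  The package
verifies this against a high-accuracy ODE integration of the homogeneous
system.  The origin of the instability is structural: the second-order
equation with a purely imaginary nonlinear coefficient lacks the
contracting (real) terms of the first-order oscillator flow it summarises.
Consequences for this package:

* `probe_stability` measures the actual growth/decay rate (per-cycle RMS
  envelope fit) instead of assuming decay; spatial coupling does not
  stabilise (large-`k` radial modes grow at least as fast).
* radius-constancy checks use short windows (~2 cycles) where
  truncation-seeded growth stays below tolerance; "radius recovery" from a
  10% perturbation does not occur, and the corresponding acceptance-level
  test documents this as an expected failure of the model, not of the
  implementation.
* polar-equation residual analyses use short windows for the same reason.

The polar decomposition `phi = r e^{i theta}` obeys

    r th_tt + 2 r_t th_t = c1 (r Lap th + 2 grad r . grad th) - (c2 r + c3 r^3)
    r_tt - r th_t^2      = -r + c1 (Lap r - r |grad th|^2)

(the factor-2 cross terms are required by the expansion and are verified
symbolically in the test suite).  At constant steady radius the phase
satisfies the wave equation `th_tt = c1 Lap th` and the constraint
`th_t^2 - c1 |grad th|^2 = +1`, consistent with the slope relation
`b1^2 = 1 + c1 (b2^2 + b3^2)`.  Phase unwrapping is row-major 1D unwrap
then column correction, valid for smooth long-wavelength phases; sites
with amplitude below `1e-6` of the typical radius carry a masked phase.
Polar residuals are reported on the interior lattice (the boundary ring is
excluded so unwrap seams cannot contaminate them) with central time
differences at the snapshot spacing.

A note on parameterisations: a rescaled variant of the phase system (with
`c1 = 1/2`) is used for the front analysis below; both parameterisations
are supported through the same `c1` parameter.

## Fronts and onsets

Half-plane experiments put quiescent tissue (`|phi| = eps << 1`) left of
the grid midline and the limit-cycle state (`|phi| = phi_l`) right of it,
with a one-cell linear interface ramp and a −pi/2 phase offset on the
quiescent side (low-amplitude activity locks a quarter cycle behind).
The bulk evolves under the cubic equation with a bistable quintic local
term whose radial polynomial is `-(r^2 - 0.2)(r^2 - 1)`: stable origin,
unstable cycle at `r = sqrt(0.2)`, stable cycle at `r = 1` (package
defaults `(A3, A4, A5) = (-0.2, 1.2, -1.0)`, recorded in config).

The boundary coupling that recruits quiescent tissue has maximal speed
`a2 * phi_l`.  It is implemented as a transport term — advection of the
sub-half-amplitude field toward the quiescent side at exactly that speed,
applied to `phi` and `phi_dot` under a one-cell-smoothed indicator — with
the 90-degree phase relation carried by the initial condition.  Applying
the gradient coupling with its literal phase factor instead overdrives the
interface and produces measured speeds above the very bound derived from
the same transport argument, so the transport reading is used; measured
speeds then sit at roughly 0.6 of the bound and increase monotonically
with the gain.  The advection split uses a Courant number of 0.1.  Front
position is the row-averaged leftmost half-maximum crossing; speed is a
least-squares fit over the last 60% of the run.  Runs default to ~10 time
units: the quintic bulk inherits the radial instability above, and longer
runs corrupt the field behind the front.

The phase discontinuity left behind a front obeys `th_tt = (1/2) Lap th`;
band-limiting the Heaviside phase step `pi(1/2 - Theta(x))` to
`|k| <= k_m` and advecting at `1/sqrt(2)` gives the exact closed form
`th(x, t) = -Si(k_m (x +- t/sqrt(2)))` (the step convolved with the
normalized sinc kernel; `Si` is the sine integral).  The onset waveform
`phi(t) = r0 e^{i th(t)} + r(t) e^{i a0 t}` combines the travelling-phase
carrier (frequency `sqrt(2)`, the plane-slope rate of the rescaled phase
system) plus the step relaxation with a logistic amplitude ramp
(`r(0) = 0`, monotone, saturating; midpoint and rise time configurable).
With `a0` well below the carrier this reproduces the stereotypical
fast-low-amplitude-then-slow-high-amplitude electrographic onset shape,
verified by spectral peak tracking.

## Tessellation

A `P x Q` tiling couples tiles through a Hermitian/symmetric matrix `G`
built from nearest-neighbour adjacency (open tile boundary by default,
matching a bounded sheet; periodic optional) or inverse-distance decay
(exponents 1 and 2, Euclidean distance between tile centres in units of
tile pitch, zero diagonal).  `G` acts on the tile index and as identity on
lattice sites.  Eigendecomposition uses `numpy.linalg.eigh` with a
deterministic convention: descending eigenvalue; within numerically
degenerate clusters (gap < 1e-9) columns are ordered by the index of their
largest-magnitude component with that component's phase fixed positive.
Each eigenvector is a self-contained pattern: linear evolution restricted
to its tile span stays there exactly, measured as the relative trajectory
norm outside the span (≈ 1e-12 in practice, asserted < 1e-8; exhaustively
on small tilings, sampled on 25x25 where the mode count is 625).

## Symmetries

The Lagrangian registry is closed (quadratic, quartic — including the
`a3 |Lap phi|^2` curvature term — multilayer quadratic form, tessellated
sum with `+phi^dag G phi`), so realness and exact U(1) invariance of every
density hold by construction and are asserted at machine precision.
Extremisation gives `phi_tt - c^2 Lap phi + dV/dphi* = 0`; the residual of
simulated trajectories against their matching density is the master
cross-module consistency check.  Decoupled multilayer densities are U(N)
invariant; a non-scalar layer coupling breaks the invariance exactly
unless the rotation commutes with it — both directions are tested.
Discrete symmetries of a modulated `G` are checked as permutation
invariance `P^T G P = G`; translations hold on periodic tilings and break
at open boundaries, central reflections survive both.

## Synthetic data and scope of the tests

All inputs are generated: plane waves (snapped to commensurate lattice
wavevectors), half-plane states, Heaviside phase steps, seeded random
Gaussian fields, and rendered phase-wave fields.  These fixtures emulate
idealised regimes — exact eigenmodes, sharp fronts, noiseless fields — and
deliberately omit features of real electrophysiology: measurement noise,
heterogeneous and anisotropic connectivity, curved cortical geometry,
dissipation, and finite electrode sampling.  Passing tests therefore
certify the mathematical structure (dispersion, conservation, symmetry,
self-containment, bounds) rather than fit to any recording.  Fitting the
spectral form to empirical EEG spectra is out of scope; a CSV reader for
user spectra is the supported entry point for comparisons.

Problem sizes in the shipped tests (lattices 16–64 per side, 3x3 and 25x25
tilings, a few thousand time steps) were chosen so that each acceptance
check isolates one property at comfortable numerical margins.

## Known limitations

* The limit-cycle and bistable-front regimes are usable only on short
  horizons (see the stability caveat) — a faithful property of the
  implemented equations, not a numerical artifact.
* Reflecting boundaries are first-order accurate at the wall; front speed
  fits discard the transient but retain some level-set jitter.
* The multilayer dispersion's sign convention for the eigen-offsets `D` is
  ambiguous in the source formulation; both signs are exposed and
  `omega^2 < 0` branches are flagged evanescent rather than raised.
* Curved cortical surfaces, directional (gradient) connectivity,
  stochastic driving, and implicit/spectral integrators are out of scope.
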