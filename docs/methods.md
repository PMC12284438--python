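# Methods

`pulmo1d` models pulsatile blood flow in the pulmonary arterial tree with a
one-dimensional fluid–structure-interaction (FSI) formulation, and uses it to
separate how the three canonical remodeling events of pulmonary hypertension
(PH) — distal resistance increase, vessel-wall stiffening, and reduced stroke
volume — each contribute to the elevated pulse pressure and altered impedance
seen at the main pulmonary artery (MPA).

## Wall model

Each vessel wall is a single incompressible hyperelastic layer of the
Holzapfel–Ogden family: a neo-Hookean ground matrix of stiffness `c` (kPa)
plus one symmetric pair of fiber families at an effective angle `β` (degrees,
measured in the circumferential–axial plane) with stiffness `k1` (kPa) and
exponential stiffening exponent `k2` (–).  The fiber invariant is

    α = λθ² cos²β + λz² sin²β − 1,

and the fiber Cauchy stress is `4 k1 α exp(k2 α²)` times the direction
projections, deviatorically projected so the three isochoric normal stresses
sum to zero.  Fibers carry load only in tension (`α > 0`); the switch is
exposed on every operation (`tension_only`).  Because the exponential fiber
term overflows quickly at unphysical stretches, stress routines carry an
explicit overflow guard that names the offending stretch instead of
returning infinities.

The pressure–area (tube) law follows from radial equilibrium: for a lumen
area `A`, the circumferential stretch profile through the wall is fixed by
wall incompressibility at a given axial stretch `λz`, and

    P(A) = ∫_{ri}^{ro} (σθθ − σrr)/r dr

is evaluated with 16-point Gauss–Legendre quadrature.  At `λz = 1` the law
passes exactly through `(π r0², 0)`.  `λz = 1` is the default during flow
simulation (in-vivo axial prestretch is not an input of the model);
it is configurable.  Tension-only fibers make the law's slope kink at the
reference area, so the "effective stiffness" of the linearized comparison
law is the inflation-side tangent.

Wall geometry is specified per segment as a thickness-to-radius ratio
(default 0.10 for control tissue; synthetic PH remodeling multiplies it by
1.3, reflecting medial thickening).  File radii are treated as the
zero-transmural-pressure reference configuration; when radii are measured in
a pressurized state this underestimates distensibility by at most a few
percent.

## Constitutive fitting

Uniaxial tests along the circumferential and longitudinal axes are reported
as 2nd-Piola–Kirchhoff stress vs Green–Lagrange strain.  The fit converts
each strain to a stretch `λ = √(2E+1)`, solves the plane-stress uniaxial
reduction (two zero lateral Cauchy stresses plus incompressibility determine
the lateral stretches and the hydrostatic multiplier), converts the
surviving Cauchy stress to 2nd-PK by `S = σ/λ²`, and minimizes the squared
misfit over both directions jointly with equal per-point weights.
Minimization is bounded trust-region least squares (`scipy least_squares`,
bounds `c ∈ (0, 10³]`, `k1 ∈ [0, 10⁴]` kPa, `k2 ∈ (0, 10²]`,
`β ∈ [0°, 90°]`) from 12 Latin-hypercube starts with a fixed seed, so fits
are reproducible.  The summary metrics of an experimental curve are the
local-quadratic slope at 60% Green strain ("stiffness") and the stress
interpolated at E = 0.625, the Green strain equivalent of a 50% stretch.

A deliberately independent oracle generates synthetic test data: it
minimizes the strain-energy density over the free lateral stretch (the
incompressibility multiplier eliminated algebraically) and differentiates
the energy via the envelope theorem, never calling the stress-tensor code.
Agreement between the two routes (relative discrepancy < 1e−6 over random
parameter sets) is itself a test, and parameter recovery from oracle data is
the package's headline acceptance check.

## 1D FSI solver

Cross-section-averaged conservation of mass and momentum on each segment,

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A + B(A))/∂x = −(2πνr/δ)(Q/A),

with `B(A) = (1/ρ)∫ a P'(a) da` (exact conservation form because segments
are untapered) and boundary-layer thickness `δ = √(νT/2π)`, `T` the cardiac
period taken from the inflow waveform.  Defaults `ρ = 1.055 g/mL`,
`ν = 0.046 cm²/s`.  The scheme is a finite-volume Richtmyer two-step
Lax–Wendroff: interior face states come from the half step; boundary faces
(inlet, bifurcations, outlets) are closed at the half time level by
outgoing-characteristic compatibility (`Q/A ± ∫c/a da` traced to a
first-order interpolated foot) solved together with the boundary condition
by vectorized Newton iteration.  Every cell — including boundary cells — is
updated in conservation form from face fluxes, so junction mass defects and
the cycle volume balance are exact to solver precision by construction;
both are recorded as diagnostics on every result.

The cycle loop has two interchangeable implementations: a vectorized numpy
reference and a numba-compiled kernel (the default) that reproduces the
reference trajectory to ~1e-12 relative; their agreement is itself a test.
Each segment's tube law is tabulated once on a uniform area grid
(`0.3–3 × A0`, 1000 nodes) together with `dP/dA`, the flux potential `B`,
the characteristic integral `I = ∫ c/a da`, and the wave speed
`c = √(A P'(A)/ρ)`; the solver interpolates linearly.  Tables are cached
process-wide, which matters in calibration sweeps where only the Windkessel
parameters change.  The time step divides the period exactly and is chosen
by a CFL condition (`Courant 0.5` by default) against a wave-speed estimate
on the expected operating band of areas; a runtime Courant check guards the
whole range, and `simulate` retries with a halved step if a transient
exceeds it.

Boundary conditions: the root face imposes a periodic flow waveform
(linearly interpolated); bifurcations enforce flow continuity and pressure
equality (the Newton residual is driven to ~1e−12 in scaled units, and the
parent face flux is then closed exactly on the children); terminals carry
three-element Windkessel (RCR) models, `dP/dt = R1 dQ/dt +
Q(R1+R2)/(R2 Cd) − P/(R2 Cd)`, discretized implicit-Euler, with the
convention `R1 = R2` and distal stiffness `Sd = 1/Cd`.  `R1 = R2 = 0`
degenerates to a zero-pressure outlet (used by the rigid-tube verification).
Junctions with more than two children in input files are binarized with
epsilon-length connectors.

Runs start from reference areas at rest and march cardiac cycles until the
pressure field's cycle-to-cycle relative L2 change falls below 1e−4 in every
segment (at most 40 cycles; non-convergence is flagged, not hidden).
Experiments warm-start the Windkessel pressures at their analytic steady
values `Q̄(R1+R2)`, which shortens the transient without changing the
periodic state.

Verification cases: a near-rigid tube under constant flow reproduces the
analytic viscous pressure gradient within 1% on interior cells (the
characteristic boundary closure is first order and perturbs the two end
cells); a single tube with an RCR outlet reaches mean outlet pressure
`Q(R1+R2)` and shows the classic impedance limits `Z(0) → R1+R2`,
`Z(∞) → R1`; halving the grid spacing moves systolic MPA pressure by < 1%.

## Impedance analysis

One period of MPA pressure and flow is Fourier-transformed; the input
impedance `Z(ω) = P̂(ω)/Q̂(ω)` is evaluated at the cardiac harmonics.
`Z0` is the 0 Hz (mean) ratio; `Zc` is the mean of `|Z|` over harmonics in
`(0, 250]` Hz — magnitude averaging keeps `Zc` real, the convention of the
pulmonary-impedance literature.  Harmonics whose flow magnitude falls below
1e−6 of the first harmonic's are masked to avoid division blow-up.  The
pulse-pressure convention (diastolic baseline subtracted from P before
transforming) is the default; it changes only `Z0`, never `Zc`.  Sampling
must place the Nyquist frequency above the `Zc` band edge; this is
validated.

## Remodeling deconvolution

The control model is calibrated so its simulated MPA pulse pressure
(ΔMPA = systolic − diastolic) matches a measured target, by secant iteration
on the total distal resistance with the total distal compliance held fixed.
When a mean-pressure target is also supplied, resistance is solved against
the mean and compliance against the pulse, alternating — the mean responds
almost purely to resistance, the pulse mostly to compliance.  A structural
caveat the calibrated model makes explicit: with the `R1 = R2` convention,
half the distal resistance lies proximal to the distal compliance, so pulse
pressure cannot fall below roughly the first flow harmonic's amplitude times
the parallel `R1`; jointly matching an arbitrary (mean, pulse) pair is
therefore not always feasible, and pulse-only calibration is the primary
mode.  Total resistance and compliance are allocated over terminals in
proportion to `r³` (Murray-consistent; an equal split is selectable), with
`R1 = R2` at each terminal.

Hypothetical remodeling states are then built from three knobs: `S_p` scales
the wall constants `(c, k1)` of every 1D segment (proximal stiffening),
`S_d` divides every terminal compliance (distal stiffening), `R_d`
multiplies every terminal resistance, and the inflow can be swapped for a
lower-stroke-volume PH waveform (default PH/control stroke-volume ratio
0.75).  Default PH-direction scales are `S_p = S_d = 2`, `R_d = 3`; the
scientific claims tested are orderings robust to ±25% perturbations of
these, never their magnitudes.  For each state the batch reports ΔMPA
pressure, systolic/diastolic pressure, `Z0` and `Zc` (pulse convention), and
an interaction index
`I = (combined − baseline) − Σ(single − baseline)`
quantifying non-additivity of the mechanisms.

## Synthetic data

The generators produce every input the pipeline needs, each a pure function
of its configuration and seed:

* **Trees** — self-similar binary trees at rat pulmonary scale (root radius
  0.2 cm, root length 0.6 cm, radius ratio 0.78 per generation, length 3 ×
  radius, optional per-junction radius asymmetry).  Defaults of 4–5
  generations (15–31 segments) keep a single simulation in the tens of
  seconds on one core while retaining generation-wise pressure-drop
  structure; real μCT trees are an order of magnitude larger, so absolute
  impedance levels are not comparable to measured rats — only directions
  and orderings are.
* **PH morphometry** — pruning of terminal sibling pairs (fraction of
  terminals, iteratively, newly exposed terminals eligible), narrowing of
  radii below a threshold, and wall thickening ×1.3.
* **Uniaxial data** — the independent energy-based oracle described above,
  with optional multiplicative Gaussian noise (default 2% relative when
  enabled, a load-cell-like error model).
* **Inflow** — a half-sine right-ventricular ejection pulse (no
  regurgitation), default 330 bpm, 0.25 mL stroke volume, ejection occupying
  40% of the cycle; per-cycle volume matches the stroke volume exactly under
  the waveform's own quadrature.  A measured waveform can be supplied as CSV
  instead.

What passing tests on synthetic data do and do not show: they verify the
solver's conservation and analytic limits, the fitting pipeline's
identifiability, and the direction of each remodeling mechanism's
hemodynamic signature.  They do not certify absolute pressures or
impedances for any real animal, because the synthetic trees are smaller and
more regular than real vasculature and the inflow shape is idealized.

One directional claim is out of reach of desk-scale trees and its test is
deliberately left failing rather than weakened: that stiffening raises the
characteristic impedance `Zc` more than distal resistance does.  In this
model class `Z(ω) → R1` at high frequency at each terminal, and a
self-similar tree of 5-7 generations (terminal radii ≥ 0.2 mm, per-junction
area expansion ≈ 1.2) transmits the 0-250 Hz band to its terminals almost
unattenuated — so scaling `R_d` lifts the whole band average.  Sweeps at 5,
6 and 7 generations over three seeds and ±25% scale perturbations
consistently show the resistance gain in `Zc` slightly exceeding the
stiffening gain.  Deep, strongly tapering vasculatures (hundreds of vessels
with sub-0.1-mm terminals, the regime of μCT-derived trees) viscously
decouple the terminal load from the band, which is what makes `Zc`
stiffness-dominated in vivo; reproducing that regime requires measured
geometry, not a self-similar generator.

## Numerical choices and limitations

* Tube-law tabulation range `0.3–3 × A0`; a state leaving it raises a
  described error rather than extrapolating silently.
* Junction Newton accepts a stalled residual below 1e−11 (scaled): linear
  interpolation of the law tables puts a floor under the attainable
  residual; mass closure is exact regardless.
* The boundary closure is first-order in space; end cells of a segment are
  excluded from profile-slope diagnostics.
* Single-layer wall, no viscoelasticity, no smooth-muscle tone, no residual
  stress, no vessel taper, Newtonian flow, no 3D features (vorticity, wall
  shear maps).
* Deep trees (hundreds of vessels) are supported by the data structures but
  not exercised by the default test problem sizes.
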