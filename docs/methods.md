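# Methods

`aeroring` models collective aerotactic migration of confined *Dictyostelium
discoideum* colonies: cells deplete the oxygen above them, build a
self-generated O2 gradient, and a dense ring of cells travels outward along
it at constant speed. The package implements three tiers of description —
a cellular Potts model of the assays, a mean-field continuum model, and an
analytically solvable "Go or Grow" caricature — plus the measurement
operators and the sensor-calibration pipeline used to quantify them, and
synthetic-data generators that provide every input with known ground truth.

## Continuum models

Cell density rho(t, x) (cells/mm^2) and oxygen C(t, x) (% O2, 0–21 scale)
obey

    d rho/dt = D lap(rho) - div( a(C, grad C) rho ) + r(C) rho
    d C/dt   = Doxy lap(C) - b(C) rho

in planar or radial symmetry. Defaults (units um, min): D = 30,
Doxy = 1.2e5, r0 = ln2/480 (8 h doubling), b0 = 0.01 %O2 min^-1 cell^-1,
thresholds C0 = 0.7 % and C0p = 0.1 %, boundary oxygen 21 %. Division
r(C) = r0 above C0 and 0 below. Consumption uses the capped ramp
b(C) = min(b0, b0*C/C0p), which vanishes with C and keeps oxygen
non-negative at the stated time step.

Two advection closures:

- **mean-field**: a = lambda(C) dC/dx with the sigmoidal sensitivity
  lambda(C) = A/(1 + exp((C - 0.7)/0.2)). The amplitude is published only
  in lattice-energy units; the continuum amplitude A (um^2 min^-1 %^-1) is
  fixed by requiring that the advection speed in the microfluidic reference
  gradient at C = 0.4 % equal the measured 1 um/min bias, giving
  A ≈ 1005 (`aeroring.params.meanfield_aero_amplitude`).
- **Go or Grow**: a = a0 sign(dC/dx) where C < C0, zero above ("go" below
  threshold, "grow" above, never both). The two-threshold variant
  additionally switches advection off below C0p.

### Discretization

Backward-Euler in time for both fields, each step two tridiagonal solves
(`scipy.linalg.solve_banded`): density first (implicit diffusion +
donor-cell upwind advection with velocities frozen at the old oxygen field
+ implicit growth), then oxygen (implicit diffusion, consumption
coefficient b(C^n) applied to the fresh density). The advection is the
conservative interface-flux (donor-cell) upwind scheme; the donor side of
each interface follows the sign of the one-sided oxygen difference. Mass
is conserved to solver round-off when growth is off (verified < 1e-8
relative per 1000 steps). Default mesh dt = 0.02 min, dx = 1 um; the
measured front speed changes by < 2 % under mesh halving.

Boundary conditions: no-flux for rho at both ends; C clamped to 21 % at
the outer boundary and no-flux at the symmetry axis. Radial grids are
cell-centred (first node at dx/2) so the axis carries no singular node.

The front is the rightmost linear-interpolated crossing of C through C0;
speeds are least-squares slopes of that trajectory over a stated window.

### Initial conditions and the oxygen reservoir

`synth.gen_initial_profiles` provides two initial states. "spot" is the
radial three-tier step profile matching the lattice seeding densities
(1667/833/500 cells/mm^2 out to 300/600/900 um) in saturated medium.
"near_wave" is the explicit traveling-wave density profile with its
threshold cusp at a chosen position, again in saturated medium (C = 21
everywhere), which is the experimental t = 0 state.

A note on domain size: the analytic wave's oxygen tail ahead of the front
relaxes over Doxy/sigma ≈ 11 cm, far beyond any simulated domain. If the
oxygen field is instead *pre-equilibrated* to the finite-domain steady
state with the boundary held at 21 %, the boundary over-supplies the front
(influx Doxy * dC/(L - x) far exceeds the traveling wave's own consumption
sigma * 21) and holds the threshold crossing back: measured planar speeds
drop to ~0.91–0.96 um/min and drift down as the front nears the boundary.
Starting from saturated medium lets the front harvest locally stored
oxygen exactly as on the infinite line; after the depletion transient
(~2–3 h) the planar Go-or-Grow front travels within 3 % of the closed-form
speed. All reported front speeds therefore use saturated-medium initial
states and post-transient measurement windows. The pulled (small-bias)
front additionally converges only logarithmically (Bramson-type
correction ~ 3/(2 lambda* t)); the small-bias runs use a coarser mesh
(dx = 2 um, dt = 0.05 min) and a 6000-min horizon, reaching the Fisher
speed from below to within ~8 %.

## Wave theory

In the co-moving frame z = x - sigma*t with the threshold pinned at z = 0,
the Go-or-Grow density solves a piecewise-constant-coefficient ODE with a
flux-matching kink at the threshold, D [rho'](0) = -a0 rho(0). The speed
obeys the dichotomy

    sigma = a0 + r0*D/a0  (a0 >= sqrt(r0*D), pushed)
    sigma = 2 sqrt(r0*D)  (a0 <= sqrt(r0*D), pulled Fisher front)

with phi = 2 sqrt(r0*D)/sigma the division/diffusion share of the speed.
At the default operating point (a0 = 1 um/min) sigma = 1.04 um/min and
phi = 40 %: aerotaxis dominates. A flux-balance estimate using only the
profile shape gives sigma ≈ r0 * L_ring * (rho_peak/rho_bulk) / 2, with
the ring length L taken at half peak (division stops roughly at half
height); at L = 300 um and ratio 4 this yields 0.9 um/min.

The explicit profiles use two sign conventions, following the respective
derivations: the elementary wave decays with the signed root
mu_- = -a0/D, the two-threshold wave with the positive rate
mu = (sigma + sqrt(sigma^2 - 4 D r0))/(2 D). They are not reconciled in
code; each variant implements its printed form.

### Two-threshold speed

With a second threshold C0p the wave speed solves an implicit equation:
for each candidate sigma, the threshold gap h follows from flux matching
at z = -h, the piecewise oxygen profile (consumption b0 constant, no
positivity constraint) is solved in closed form per unit amplitude, the
five matching constants come from a 5x5 linear system, and the residual is
C(-h) - C0p. The root lies between the Fisher and elementary speeds, but
exponentially close to the elementary end for most parameters (unresolvable
in sigma to double precision), so the dichotomy runs over h instead, with
the identity E*exp(lam*h) = -a0*B/sigma substituted analytically to keep
the residual conditioned. Limits: C0p -> C0 collapses the advection band
and gives the Fisher speed (h -> 0); C0p -> 0 sends h -> inf and recovers
the elementary speed. Over a0 in [0.2, 2] um/min and doubling times in
[4, 16] h (the ranges spanning the study's comparison) the speed deviates
from the elementary formula by at most ~0.2 %.

## Neutral labeling (pushed vs pulled)

Labels partition the wave without changing its dynamics; each fraction
obeys the same linear operator in the moving frame, with a(z), r(z) frozen
from the wave (a0 behind the threshold, r0 ahead) and an extra -sigma d/dz
drift. The window is 4 mm wide with advective outflow at the rear and
no-flux far ahead. The initial split is at the density peak (for the
monotone elementary profile, at the end of the plateau, z = 0).

Classification gates (the study's dichotomy is qualitative; these make it
testable): the rear label's front-window mass, normalized by its initial
mass, must exceed 1 % with a spatially uniform share (CV < 0.05 across the
front) for "pushed"; decay towards zero (below 1e-3, or monotonically by
an order of magnitude) for "pulled"; otherwise "undetermined". The pushed
verdict is quantitatively cross-checked against the conserved-quantity
prediction: asymptotic proportions equal <v0k, rho> / <rho, rho> in the
exp(U) weighted inner product with U(z) = (sigma - a(z)) z / D (agreement
within 2 % at defaults). The pulled case needs a long horizon (the share
decays algebraically); classification runs use 20000 min.

## Cellular Potts model

Cells are 2-pixel domains (1 px = 10 um) with quadratic volume energy
lambda_v (V - 2)^2, lambda_v = 800; one Monte Carlo step (0.1 s) is one
sweep of N*M single-pixel copy attempts with Metropolis acceptance.
Aerotaxis enters as the potential H = -lambda_aero(C_cell) * sum_px C(px):
an expanding cell gains -lambda*(C_target - C_source) (the printed copy
form), a cell displaced by medium pays +lambda*C_target for the lost
pixel. The sensitivity and the effective temperature are sigmoids of the
oxygen at the cell's centre of mass (amplitudes 800 and 85+105, midpoints
0.7 %); the temperature of the copy is the moving cell's own — aerokinesis
is a property of the cell, not of the lattice site.

Copy attempts use the Moore (8-neighbour) dialect by default; the
4-neighbour dialect is available as `neighborhood="vonneumann"`. The
choice is a calibration: with Moore, isolated cells in the microfluidic
gradient at C = 0.4 % drift up-gradient at ~0.8 um/min with activity
~65 um^2/min (measured: 1.1 ± 0.4 um/min and 40 ± 10 um^2/min); the
4-neighbour dialect undershoots the bias (~0.35). At saturating oxygen the
printed lambda_v and T(21 %) = 85 make volume excursions nearly frozen
(acceptance e^{-800/85}), so the simulated high-O2 activity is ~2–3
um^2/min rather than the measured 19; the aerokinetic *contrast* is
reproduced strongly, the absolute high-O2 value is not.

Oxygen: explicit diffusion (2 px^2/step split into stable substeps),
consumption min(0.1, C) per occupied pixel per step, leak
0.001*(21 - C)/21 everywhere, borders clamped at 21 % (spot). The
microfluidic field is frozen to C(x) = 21.38/(1 + exp(0.031(x - 200))).
Division: probability 1/288000 per cell per step (kept at full precision;
the printed value is the 1-significant-figure rounding 3e-6) where the
cell's local oxygen is >= 0.7 %; a division donates one pixel to a new
one-pixel cell that regrows through the volume term, inheriting its
lineage tag. Cells never die (copies that would empty a cell are
rejected).

Determinism: a single integer seed drives one xorshift64* stream for the
copy attempts and numpy's generator for divisions; runs are bit-identical
at fixed seed.

Seeding: three concentric tiers of 2-px cells at pitch (2+g) x (1+g) for
gaps 1/2/3 within radii 300/600/900 um. Every literal reading of this
packing yields 1863–1875 cells (continuum estimate 1885), slightly below
the reported 1900–2000; the discrepancy is ~1.5 % and left as is.

Desk scaling: default analysis runs use `scale=0.5` (250x250 grid, radii
halved, ~470 cells), which keeps an 8-h assay around five minutes of CPU.
At this scale the ring forms deeper inside the colony (the closer oxygen
boundary weakens depletion) and the transient before constant-speed motion
lasts ~4 h; ring speeds are measured on post-formation windows. The ring
over-compacts somewhat relative to the full-scale morphology (peak density
keeps creeping up), so morphology-stationarity checks at this scale gate
the ring position and width trend, not the peak height. The ablations are
read through their desk-scale signatures: without division the ring never
leaves the colony interior (stall), and without aerotactic modulation the
front starts moving outward immediately instead of spending hours building
a ring — the full-scale "no ring, quick outward dispersal" phenotype
compressed to the smaller colony.

## Measurement operators

Density profiles count cells in concentric annuli around the pooled
centre of mass of all detections and divide by annulus area; default bin
width 50 um (not printed in the source; configurable). Ring fits strip
bins below 500 cells/mm^2 and fit baseline + Gaussian; ring speed is the
slope of position vs time excluding fits inside the initial 900-um spot
(scaled accordingly). Radial bias projects displacements over a time lag
onto the outward radial direction; the per-track diffusion constant is the
study's end-to-end estimator |x(T) - x(0)|^2/(4T), which is unbiased for a
pure random walk but reports v^2 T/4 for pure drift — this caveat is
deliberate, the estimator is used as published.

## Oxygen-sensor calibration

Stern–Volmer model (I0 - Bg)/(I(C) - Bg) = 1 + K*C per ROI (default
64x64 px), with K and Bg free because film thickness and illumination vary
across the field. For covered films the pipeline reconstructs Bg =
alpha*I(21%) + beta (background line calibrated on an uncovered film) and
I0 = R*I(21%), derives the K map from the same reconstituted images
(K = ((I0-Bg)/(I21-Bg) - 1)/21), and inverts for C pixelwise. Deriving K
and C from the same I0 makes the reconstruction robust to the large
residual-oxygen uncertainty on I0 (a 1.75 factor moves C by < 10 % around
1 % O2 but > 50 % below 0.25 %). A directly measured I0* under nominal
nitrogen carries residual oxygen C0* ≈ 0.15 % and is corrected by
1 + K*C0*. Error bars are (max - min)/2 over one-at-a-time exploration of
the three stated error sources (Bg* by ±10 % or ±2 % per setup, I(21%) by
±2 % of its read-noise-corrected signal, I0 by the 1.75 factor both ways);
the resulting relative error stays below 0.3 in the 0.5–1.5 % band on the
HL5-like default scene.

## Synthetic data: what it does and does not emulate

Generators cover ring-morphology point clouds (inhomogeneous Poisson by
thinning, so expected counts are exactly the intensity integral), tracks
(Gaussian-step walks with optional drift fields; no persistence, which no
estimator under test needs), Stern–Volmer image pairs with spatially
varying film parameters and Gaussian noise, and the microfluidic gradient.
They reproduce the statistical structure the estimators assume — they do
not emulate detection/linking artefacts, cell shape, excluded volume in
point clouds, or non-Gaussian photon noise, so passing recovery tests
validates the operators, not the upstream image processing.

## Known limitations

- The finite-domain oxygen boundary couples weakly to front speeds (see
  above); reported windows avoid the boundary-dominated regime.
- The pulled-front verdicts (speed and labeling) are asymptotic statements
  checked at finite horizons chosen for monotone approach.
- The Potts high-oxygen activity underestimates the measured diffusion
  constant (dialect-independent; see the calibration discussion).
- The lattice model omits cell–cell adhesion and cAMP signalling, so
  late-time aggregation seen in experiments is out of scope by design.
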