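# Methods

`dpdgel` models a chemically cross-linked hydrogel sliding against a rigid
flat wall in explicit solvent with dissipative particle dynamics (DPD),
and reduces the resulting trajectories to the observables that
characterize soft lubrication: density and velocity profiles near the
wall, gel shear strain, and the friction coefficient as a function of the
Weissenberg number and the normal load.

## The DPD model

All quantities are in reduced DPD units (cutoff r_c = 1 is the unit of
length, bead mass m = 1, thermal energy k_BT = 1 the unit of energy).
Every pair of beads within r_c interacts through three forces directed
along the unit separation vector r̂_ij:

- conservative soft repulsion  F^C = a w(r) r̂,  w(r) = 1 − r/r_c,
- dissipative drag             F^D = −γ w²(r) (r̂·v_ij) r̂,
- random kicks                 F^R = σ w(r) ζ_ij Δt^(−1/2) r̂,

with the fluctuation–dissipation constraint σ² = 2 γ k_BT tying the noise
amplitude to the drag so the pair thermostat samples the target
temperature while conserving momentum (and therefore hydrodynamics).
Defaults: number density ρ0 = 3, a = 25, γ = 4.5, k_BT = 1, Δt = 0.01,
giving σ = 3.

ζ_ij is a zero-mean, unit-variance uniform draw generated from a
counter-based hash keyed by (seed, step, pair), identical for ij and ji.
This makes Newton's third law exact including the random term, makes
trajectories bitwise reproducible for a given seed, and needs no stored
per-pair state.

Polymer connectivity uses a harmonic bond U_bond = k_bond (r − r_eq)²
(k_bond = 16) and a bending term U_bend = k_bend (1 + cos θ) on every
three consecutive chain beads (k_bend = 10), whose minimum is the
straight chain.  The bond rest length matters more than it looks:
bonded neighbours also repel through the conservative force, so a
bonded pair equilibrates at (2 k_bond r_eq + a)/(2 k_bond + a), not at
r_eq.  The default rest length (0.0203) is chosen with
`BondedParams.for_spacing` so this equilibrium equals the 0.45 monomer
spacing the builder uses — chains are then genuinely unstrained as
built.  Setting r_eq equal to the spacing instead pre-compresses every
chain by the unbalanced repulsion and the network creeps toward a
swollen state for 10⁵+ steps.

Integration is the modified velocity-Verlet scheme standard in DPD with
velocity-prediction factor λ = 1/2: the dissipative force is evaluated
once per step at the half-kicked velocities.  At Δt = 0.01 and γ = 4.5
the measured kinetic temperature of a quiescent box is 1.000 ± 0.002.
Pair search uses a cell list rebuilt every step (half stencil, 13 + self
cells); an O(N²) path covers boxes narrower than three cells, and the
test suite checks the cell path against an all-pairs oracle.

## Network generator

The gel is a statistically isotropic random network built in three
steps: (1) cross-link points are placed uniformly at random with a
minimum spacing of 1.5 (rejection sampling); (2) all cross-link pairs
closer than the connection cutoff are enumerated, shuffled, and accepted
while both partners have fewer than four chains (the functionality cap);
(3) each accepted pair is joined by a straight chain of
N = round(d/r_eq) − 1 interior monomer beads spaced so bonds start
unstrained.  Boxes are periodic in x and y; a fully periodic variant
serves bulk-statistics measurements.  With the open z boundary the
outermost layer (about one mesh size) has fewer connections than the
bulk — the sparser, dangling-chain-rich surface expected for a swollen
gel boundary.

The generator's free constants are not independently meaningful; they
were calibrated jointly, once, so the emergent structure matches the
reference statistics of the material being modelled: porosity
ε ≈ 0.89 (solvent bead fraction at total density ρ0), mean chain length
N0 ≈ 6.2 monomers, and mean mesh size ξ0 ≈ 3.2.  The calibrated defaults
are cross-link density 0.027 per unit volume, connection cutoff 4.2, and
r_eq = 0.45.  With these, builds in a 20³ box give ε = 0.887 ± 0.001 and
N0 = 6.20 ± 0.06 across seeds.

## Mesh size

The mesh-size statistic is the largest-inscribed-sphere pore size: for a
random probe point, the diameter of the largest sphere that contains the
probe and overlaps no gel bead.  Candidate sphere centres live on a grid
(default pitch 0.3); each candidate's clearance (distance to the nearest
obstacle minus the obstacle radius) is precomputed with a KD-tree, and
scanning candidates in decreasing clearance order returns the exact
constrained maximum at grid resolution (the first candidate whose centre
lies within its own clearance of the probe).  The test suite validates
this early-exit scan probe-by-probe against an exhaustive scan and
against closed-form lattice geometry.

Soft DPD beads have no hard core, so an obstacle-radius convention is
required; the package treats gel beads as obstacles of effective
exclusion radius 0.74 r_c (a solvent-accessible convention — a solvent
bead that close to a monomer sits deep inside its repulsion zone —
calibrated once so the mean mesh size of the equilibrated default
network is 3.2; measured 3.34/3.16 at R = 0.70/0.75 over three seeds).
The measurement protocol builds the network fully periodic, solvates it
to ρ0, equilibrates 2 500 steps with the full DPD engine, and samples
≥10⁴ probes.  Relaxing the network *without* solvent is not
stationary — it slowly collapses for lack of osmotic support — which is
why the solvated protocol is the defined one.

## Shear cell

Geometry: the bottom plane z = 0 is the stationary rigid wall.  Solvent
obeys a bounce-back no-slip rule there (a bead crossing the plane is
reflected with all velocity components reversed), plus a one-sided
harmonic spring of strength 6.57 acting in the zone one cutoff above the
plane; gel feels a stiffer spring (strength 50) in the same zone.  The
in-zone springs matter: a bead touching a bare wall loses its wall-side
neighbours, and the unbalanced bulk repulsion would otherwise press both
species onto the plane (for the gel this would create an adsorbed layer
instead of the depleted interface the model is meant to produce).  The
top box boundary carries a strength-50 spring in the analogous zone.

The moving wall is a plane at height h(t): permeable to solvent (no
interaction), impermeable to gel (one-sided harmonic, strength 50, onset
at the plane — solvent exists on both sides, so no standoff is needed).
It carries the normal load F_n and slides at velocity V.  The gel's top
layer (within one ξ0 of the gel top at build time) is tethered to the
wall by stiff springs (k = 50) whose anchors advect with (V·t, h(t)).
The wall height follows an overdamped balance of F_n against the gel's
contact reaction plus the tether reaction; because both are stiff linear
springs in h, the update is semi-implicit (gain divided by
1 + Δt·mobility·k_eff), which is unconditionally stable and approaches
quasi-static force balance for large mobility (default 1.0).

The friction force F_f is the horizontal component of the total tether
force on the gel — the force the wall must apply to keep the gel
sliding — averaged over production; μ = ⟨F_f⟩/F_n with block-averaged
(5 blocks) errors.  When sliding starts, the whole cell is boosted to
velocity V: in steady state the gel and bulk solvent co-move with the
wall, so starting co-moving removes the slow whole-box momentum-diffusion
transient and only the near-wall boundary layer needs to develop.

Dimensionless groups: Wi = V η ξ0²/(k_BT) (polymer relaxation time over
shear time) and P = F_n/(A E).  The material constants η, ξ0, E are
measured by the package's own protocols (below), not assumed.

## Material calibration

- **Viscosity.** Periodic Poiseuille: two opposed body-force slabs in a
  fully periodic box drive counter-flowing parabolic profiles; η follows
  from the quadratic fit of the steady profile in each half
  (η = −ρ0 f / 2·curvature), with the halves averaged and their spread in
  the error.  Default f = 0.01 in an (8, 8, 10) box keeps the peak shear
  rate ≈ 0.09, below the 0.1 ceiling where the thermostat holds
  temperature within 1%.  Single-run estimates scatter by 3–4% even over
  10⁵ steps — the slow hydrodynamic modes set the correlation time, so
  the profile-fit covariance understates the error — and multi-seed
  averages centre at η ≈ 0.82–0.85; the packaged calibration value is
  0.84.  A wall-driven Couette variant
  (bounce-back plates, stress from the momentum absorbed by the
  stationary plate) is retained as a cross-check; it is noisier because
  the per-bounce momentum transfer is thermal.
- **Elastic modulus.** Quasi-static uniaxial compression through the
  loaded wall at V = 0.  All ladder stresses sit in the working load
  range (an unloaded reference is not used: near zero load the wall
  rides the soft dangling-chain fringe and its height is not a
  reproducible state); the ladder is time-symmetric (σ1..σn, σn..σ1) so
  averaging the mirrored visits of each stress cancels linear-in-time
  creep, and E is the tangent modulus −dσ/dh·h over the drift-corrected
  points, with residual hysteresis folded into the error.  At desk
  scale E is dominated by network-realization variance: a 10×10 slab
  holds only ~25 cross-links, and repeat builds span roughly 0.1–0.3
  (packaged nominal value 0.12).  A strain window confined to ≤10%
  would be unresolvable against this noise, so the desk protocol uses
  an extended window and reports the tangent slope.
- **Mesh size.** As above.

## Analysis

Profiles are z-binned time averages (default bin 0.1 ξ0): gel density
ρ_g(z)/ρ0 and solvent x-velocity v(z)/V.  The region partition fixes the
interface at [0, 0.3 ξ0]; the bulk plateau is the mean density over the
central half of the gel extent, and the transition edge z_t is the
smallest z where the profile reaches 95% of the plateau (threshold
configurable; 90% vs 95% moves z_t by less than 0.3 ξ0 on smooth
profiles).  ρ_b and ρ_i are means over the bulk and interface bands.

Shear strain γ is the slope of the time-averaged x-displacement (against
the reference configuration taken at the end of the transient, rigid
drift removed) versus reference height — the tangent of the tilt of
initially vertical material lines.  The simulation cell itself is not
deformed, so a box-shape estimator would measure nothing; the
displacement-slope definition is this package's declared estimator.

Friction curves collate per-run μ into μ(Wi; P); μ0 is the per-load mean
over runs with Wi < 0.01 (the thermal, Wi-independent window) and
normalizes the curves.  Scaling fits are weighted least squares, linear
or log–log for power laws, with optional bootstrap errors; coverage is
property-tested on synthetic data.

## Desk-scale study sizes and what they show

The production-scale study (60³ box, 10⁷-step transients) is outside a
workstation budget; the package's default test and acceptance sizes are:
viscometry in an (8, 8, 10) box over 0.8–1.5×10⁵ steps; generator
statistics and mesh size in 20³; modulus in a (10, 10, 13) cell; and a
friction sweep in 11³ cells with 1.2–1.4×10⁴-step transients and
1.6–1.8×10⁴-step production windows, covering Wi ∈ {10⁻³, 10⁻¹, 1} at
P = 0.14 and the high-Wi load comparison at P = 0.28 (two network
realizations at Wi = 1).  At this scale the friction assertions are
qualitative (μ > 0 and growing in the viscous regime, small in the
thermal regime, decreasing with load); quantitative targets tied to the
full-scale geometry — the ρ_b-vs-P slope, the μ-vs-P exponent −0.77,
the 2 ξ0 transition-edge position, the γ-vs-Wi trend — require the
production geometry and are left to cluster-scale reproduction via
`dpdgel run-sweep --scale 1.0`.

## Known limitations

- The as-built network is not at swelling equilibrium; slabs with a free
  surface swell several percent over 10⁴–10⁵ steps.  The modulus
  protocol pre-equilibrates and drift-cancels; the friction protocol
  tolerates the residual creep (μ is a force ratio dominated by
  interfacial drag), but very long low-Wi runs will show a slow wall
  rise.
- The bead-count porosity estimator equals the volume fraction only at
  uniform total density (exact by construction here).
- Desk-scale friction statistics carry O(20–30%) errors per run; the
  reduced sweep distinguishes regimes, not exponents.
- Wall constants (6.57/50) are taken as given for the standard fluid;
  the solvent density perturbation within one cutoff of the walls is not
  further flattened.
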