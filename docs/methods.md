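# Methods

`aortafrac` computes the driving force for tear propagation in aortic
dissection — the energy release rate G — from semi-analytical equilibrium
solutions of a pressurized hyperelastic aortic cross-section. This note
records the model, its assumptions, the numerical choices, and the places
where the design was genuinely open.

## Model

### Kinematics and scope

The aorta is treated as a two-dimensional cross-section in plane strain
(`lam_z = 1`), made of an incompressible hyperelastic material. The
stress-free section is an annulus of mean radius `R` and wall thickness
`H2` (true-lumen wall thickness, TLWT). A dissected section carries a tear
spanning the angle `2*alpha_lim`, over which only the false-lumen wall
remnant of thickness `H1` (FLWT) remains; the crack surface sits at radius
`R_c = R + H2/2 - H1` in the reference state. Blood pressure `P` acts on
every lumen-facing surface, including the false lumen; the intimal flap
between true and false lumen sees equal pressure on both sides, transmits no
force, and is excluded from the energy bookkeeping.

Out of scope by design: residual stress (opening angle), axial pre-stretch,
hemodynamics, flap contact/buckling, through-thickness crack growth, and
any finite-element replication.

### Constitutive laws

All laws reduce, under plane-strain incompressibility, to a single
circumferential stretch `lam` with `lam_r = 1/lam`:

* neo-Hookean: `W = (mu/2)(lam^2 + lam^-2 - 2)` — ideal entropic elasticity.
* Gent: `W = -(mu*Jm/2) ln(1 - (lam^2 + lam^-2 - 2)/Jm)` — strain stiffening
  with strain limit `Jm`; the admissible range is `lam < lam_max` with
  `lam_max = (sqrt(Jm) + sqrt(Jm + 4))/2` in closed form (e.g. the golden
  ratio for `Jm = 1`). `Jm -> inf` recovers neo-Hookean.
* HGO-type: neo-Hookean matrix plus an exponential collagen-fiber term
  `(K1/K2)(exp(K2 (I-1)^2) - 1)` with pseudo-invariant
  `I = lam^2 cos^2(beta) + sin^2(beta)`; fibers carry load only in tension
  (`I > 1`). Default fiber angle `beta = 45 deg` from the circumferential
  direction, for which `I = lam^2/2 + 1/2`; the general-angle form is
  implemented and tested. `K1 = 0` reduces exactly to neo-Hookean.

Units: all solvers run dimensionless (`mu = 1`, `R = 1`); dimensional inputs
are normalized on entry, and every result is reported as `G/(mu R)`,
`U/(mu R^2)`, `P/mu`.

### Intact section (thick-wall ring)

Incompressibility makes the deformation a one-parameter family,
`r(rho) = sqrt(a^2 - R_in^2 + rho^2)` with deformed inner radius `a`, and
radial equilibrium with tractions `-P` (inner) and `0` (outer) reduces to a
single quadrature condition on `a`. The total potential energy per unit
axial length is `U_I = W_SE - P * DeltaA_in`, with the strain energy
integrated over the reference annulus (equal to the deformed one by
incompressibility) and `DeltaA_in = pi (a^2 - R_in^2)`. Equilibrium is
exactly stationarity of `U_I(a)`, which the oracle suite verifies
independently. The neo-Hookean ring has a limit pressure
`P/mu = ln(R_out/R_in)` (~0.2007 at `H2/R = 0.2`); beyond it the solver
raises rather than returning a spurious state.

### Dissected section (two-segment membrane)

The dissected section is a closed thin membrane with two segments: intact
wall (`H2`, arc `L2 = (2 pi - 2 alpha_lim) R`) and FL wall (`H1`,
`L1 = 2 alpha_lim R_fl`, with `R_fl = R + H2/2 - H1/2` the segment
mid-surface). Because the flap is force-free, the junctions can balance only
with equal tension and tangent continuity, so the deformed shape is a single
circle of radius `rho` with piecewise-constant stretch. Per segment
`T = H_i W'(lam_i)`, the planar Laplace relation gives `T = P rho`, and the
closure of the circumference yields one scalar root problem in `T`. For a
uniform thickness this degenerates to the classical inflation solution
`P/mu = (H/R)(1 - lam^-4)`, with its limit point at `P/mu = H/R`; the Gent
material has no membrane limit point (the tension diverges at `lam_max`), so
the safety-map operating material (Gent, `Jm = 1`) is solvable at all
pressures.

Energy bookkeeping uses the areas enclosed by the *inner* wall surfaces in
both configurations (deformed thicknesses `h_i = H_i/lam_i`), while the
mechanical equilibrium is the stationary point of the membrane-consistent
functional whose pressure potential uses the mid-surface area `pi rho^2`
— at membrane order the two differ by `O(H/R)` and only the latter is
exactly consistent with `T = P rho`. The oracle minimizer therefore
minimizes the mid-surface functional and both routes report the energy with
the inner-surface formula.

Mixed fidelity: `U_I` comes from the exact thick-wall ring, `U_II` from the
membrane model (a `normal_model='membrane'` switch provides an all-membrane
consistency mode). One visible artifact: as `P -> 0` the two fidelities
leave a tiny relative offset, so the longitudinal G crosses zero near
`P/mu ~ 0.004` instead of exactly 0; on the studied range
(`P/mu >= 0.01`) G is positive.

### Energy release rates

* Longitudinal: `G = (U_I - U_II(alpha_lim)) / (R_c * 2 alpha_lim)` — the
  energy released per unit reference crack length when a slice of normal
  aorta converts to a dissected one.
* Circumferential: upwind (forward) difference in crack angle,
  `G = [U_II(alpha_lim) - U_II(alpha_lim + d_alpha)] / (R_c * 2 d_alpha)`
  with `d_alpha = 4 deg` by default (configurable; a centered-difference
  oracle and a 4/2/1-degree refinement study confirm first-order
  consistency). Crack lengths are always measured in the stress-free state.

Propagation is energetically favored when `G` exceeds the fracture energy
`Gamma`; the dimensionless comparison uses `Gamma/(mu R)` (about 0.024
longitudinal / 0.016 circumferential for the abdominal aorta: 76 and
51 J/m^2, `mu = 157 kPa`, `R = 20 mm`).

## Parameter studies

The `study` module encodes the trend figures as recipes: G versus pressure
with varying `H2/R`, `H1/H2`, `Jm`, `K1/mu`, `K2`, and G versus crack angle,
in both directions. Defaults worth knowing:

* Pressure grids run `P/mu = 0.01 ... 0.15` in steps of 0.005, but
  neo-Hookean recipes cap at 0.12-0.13 because their most compliant curve
  loses membrane equilibrium at `P/mu ~ 0.127` (`H2/R = 0.15`,
  `H1/H2 = 0.5`).
* "Tear depth" increases as `H1/H2` decreases (a deeper tear leaves a
  thinner FL wall). Depth grids cover `H1/H2 = 0.30 ... 0.90` step 0.05.
* The longitudinal G-versus-angle profile is non-monotonic (high at small
  angles, interior minimum, rising again) for `P/mu >~ 0.1`; at lower
  pressures the interior minimum migrates below 10 deg and the profile is
  effectively monotone, so the angle-figure recipe uses pressures
  0.10/0.125/0.15. The circumferential profile increases strictly with
  angle at all studied pressures.

The safety map evaluates `G/(mu R)` on the pressure x depth grid at the
operating point (Gent `Jm = 1`, `alpha_lim = 30 deg`, `H2/R = 0.2`) and
shades the region where G exceeds `Gamma/(mu R)`.

### Critical pressure: onset versus worst case

`critical_pressure` bisects on `P/mu` (tolerance 1e-3) for the smallest
pressure at which G reaches a threshold over a tear-depth grid, with two
scopes. `scope='onset'` (default) requires G >= threshold for *at least
one* depth: the pressure at which the G = Gamma contour first enters the
map, i.e. where any tear in the considered range can start to propagate.
`scope='all'` requires it at *every* depth; this is a far stronger
condition, and since G -> 0 continuously as `H1/H2 -> 1` (no thickness
contrast means no energy release), it is dominated by the shallowest tear
considered. The onset scope is the clinically meaningful reading of a
"high-risk blood pressure" threshold and is what the acceptance script
reports; at the operating point with the longitudinal threshold 0.024 it
evaluates to `P/mu ~ 0.112`.

## Numerics

* Quadrature: adaptive `scipy.integrate.quad` with `epsabs = epsrel = 1e-12`
  on dimensionless integrands, always in the reference radial variable.
* Root finding: bisection-safeguarded Brent on monotone residuals; ring
  bracket grows geometrically from `R_in` (creeping up to the Gent
  strain-limit radius `lam_max R_in` when applicable), membrane bracket
  doubles in tension until the closure residual changes sign. Missing sign
  change raises `NoEquilibriumError` naming the limit point.
* Tension inversion (`invert_tension`) brackets inside `(1, lam_max)` for
  Gent and doubles upward otherwise; HGO overflow during expansion is
  treated as "beyond the root". Round-trip accuracy is ~1e-10 relative.
* The oracle suite shares no equilibrium-solving code with the production
  path: Ritz grid evaluation of `U_I(a)`, deterministic multi-start
  L-BFGS-B minimization for the membrane, the incompressible Lamé closed
  form at `P/mu = 1e-4`, and centered differences for the circumferential
  rate. Everything is seed-free and bit-reproducible.

## Known limitations

* The membrane treatment of the dissected section smooths over the local
  bulge of the FL wall that a thick-wall computation exhibits; membrane-order
  bookkeeping conventions (mid-surface versus inner-surface radii) shift G
  by a few percent, which is the expected accuracy of quantities like the
  onset critical pressure (~0.112 here versus ~0.12 quoted from contour
  plots of the same model class). A pinned-bulge alternative (intact ring
  rigid, FL arc pinned at the crack edges) was evaluated and rejected: it
  ignores the junction force balance and produces smaller, even negative, G
  at shallow depths.
* `G >= Gamma` is a necessary-energy criterion, not a crack-dynamics model:
  no arrest, kinking, or mixed-mode partitioning.
* Material parameters are population-scale representatives; no
  patient-specific fitting is provided.
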