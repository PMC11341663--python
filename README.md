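# aortafrac

Semi-analytical fracture mechanics of **aortic dissection**: given the
geometry of a dissected aortic cross-section and a hyperelastic wall model,
`aortafrac` computes the **energy release rate** `G` driving tear
propagation in the longitudinal and circumferential directions, and compares
it with the tissue's fracture energy `Γ` to map out the conditions under
which a tear is energetically able to grow.

It is aimed at cardiovascular biomechanics researchers who want a fast,
fully deterministic alternative to finite-element crack analyses for
parameter studies: every solve is a one-dimensional root problem built on
exact incompressible plane-strain kinematics.

## Model in brief

A cross-section in plane strain (`λz = 1`) with an incompressible
hyperelastic wall (neo-Hookean, Gent with strain limit `Jm`, or an
HGO-type fiber-reinforced law with `K1`, `K2`, fiber angle `β`):

* **Normal section** — annulus, mean radius `R`, wall thickness `H2`, inner
  pressure `P`. Incompressibility reduces the deformation to one unknown
  (the deformed inner radius); radial equilibrium fixes it by quadrature.
  Total potential energy per unit length: `U_I = W_SE − P·ΔA_in`.
* **Dissected section** — a tear spanning angle `2α_lim` leaves a
  false-lumen wall of thickness `H1 ≤ H2` (crack surface at
  `R_c = R + H2/2 − H1`). With the pressurized false lumen and a force-free
  intimal flap, the section is a closed two-segment membrane deforming into
  a single circle with piecewise stretch; tension follows `T = H_i Ŵ'(λ_i)`
  and `T = P·ρ`, giving `U_II(α_lim)`.
* **Energy release rates** (crack lengths in the stress-free state):

      G_long = (U_I − U_II(α_lim)) / (R_c · 2α_lim)
      G_circ = (U_II(α_lim) − U_II(α_lim + Δα)) / (R_c · 2Δα),  Δα = 4°

  reported dimensionless as `G/(μR)`. Propagation is favored where
  `G ≥ Γ`, with `Γ/(μR) ≈ 0.024` (longitudinal) and `0.016`
  (circumferential) for the abdominal aorta (`Γ = 76 / 51 J/m²`,
  `μ = 157 kPa`, `R = 20 mm`).

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Solve the trend-study operating point (Gent `Jm = 1`, `H2/R = 0.2`,
`H1/H2 = 0.5`, `α_lim = 30°`, `P/μ = 0.1`):

```text
$ aortafrac solve --material gent --jm 1 --p-over-mu 0.1
normal ring:    a/R = 1.07525623  U_I/(mu R^2) = -0.04922958  residual = 8.88e-16
dissected:      rho/R = 1.20220477  U_II/(mu R^2) = -0.06015843  lam_fl = 1.30457474  lam_wall = 1.16868503
```

The intact ring inflates ~7.5%; the dissected section, with its thinner
false-lumen wall stretching more (`λ_fl > λ_wall`), sits at a lower
potential energy — the difference is what feeds the tear:

```text
$ aortafrac release-rate --material gent --jm 1 --p-over-mu 0.1
G/(mu R) [longitudinal] = 0.01043628
```

At this pressure `G/(μR) = 0.0104` is below the longitudinal threshold

```text
$ aortafrac threshold --gamma 76 --mu 157000 --radius 0.02
Gamma/(mu R) = 0.024204
```

so a mid-depth tear cannot advance longitudinally. Raising pressure moves
the safety-map contour: the smallest `P/μ` at which `G` reaches the
threshold for some tear depth in `H1/H2 = 0.3 … 0.9` is

```text
$ aortafrac critical-pressure --threshold 0.024204 --direction longitudinal
critical P/mu (onset) = 0.1117
```

i.e. above `P/μ ≈ 0.11` the deepest tears considered become able to
propagate — hypertension pushes the aorta into the unsafe region.

Other entry points: `aortafrac sweep --figure 4a` (trend studies with
built-in ordering checks), `aortafrac safety-map --plot map.svg`
(pressure × tear-depth contour map), `aortafrac verify` (independent
oracle suite: Ritz stationarity, constrained membrane minimization, Lamé
small-strain limit, finite-difference G).

All of this is available as a library, e.g.:

```python
from aortafrac import AortaGeometry, gent, energy_release_longitudinal
geom = AortaGeometry.from_ratios(h2_over_r=0.2, h1_over_h2=0.5, alpha_deg=30)
res = energy_release_longitudinal(geom, gent(Jm=1.0), p=0.1)
res.G_norm   # 0.010436...
```

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch through the full pipeline,
the critical normalized pressure at which the longitudinal energy release
rate reaches the abdominal-aorta fracture threshold over the tear-depth
grid `H1/H2 = 0.30 … 0.90` (Gent `Jm = 1`, `α_lim = 30°`, `H2/R = 0.2`):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The pipeline is deterministic; `--seed` is accepted for interface
uniformity only.
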