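# laasnap — left atrial appendage inversion mechanics

`laasnap` is a desk-scale computational study of **left atrial appendage
(LAA) inversion**: the rare event in which suction in the left atrium
(typically during de-airing after cardiac surgery, cardiopulmonary bypass or
LVAD implantation) turns the appendage sac inside-out so that its body
protrudes into the atrial chamber.  The package is aimed at cardiovascular
biomechanics researchers who want a fully scriptable, open re-creation of
that simulation pipeline: synthetic appendage-like geometries stand in for
(unpublished) patient CT reconstructions, and every stage — meshing,
constitutive model, loading, dynamics, event detection — is exposed as a
tested library.

## The model

**Tissue.** Nearly incompressible, isotropic, third-order Ogden hyperelastic:

```
W = Σᵢ (2μᵢ/αᵢ²) (λ̄₁^αᵢ + λ̄₂^αᵢ + λ̄₃^αᵢ − 3) + (1/D₁)(J − 1)²,
λ̄ₖ = J^(−1/3) λₖ,   J = λ₁λ₂λ₃
```

with the shipped coefficient card (MPa): μ = (−0.337741884, 0.217246844,
0.122674830), α = (2.00175982, 4.00139831, −1.99837808), and D₁ =
9.205880052 MPa⁻¹ derived from the shear set and an imposed Poisson's ratio
ν = 0.495 through K₀ = 2μ₀(1+ν)/(3(1−2ν)), D₁ = 2/K₀ (μ₀ = Σμᵢ =
2.17979·10⁻³ MPa; density ρ = 1120 kg/m³, dilatational wave speed ≈ 14 m/s).
Coefficients of this family are fitted to stretch/stress data by
Levenberg–Marquardt (`laasnap.ogden.fit_ogden`).

**Loading.** A four-stage cavity-pressure curve: (1) suction ramp 9 →
−225 mmHg (−30 kPa) in 6 s to provoke inversion; (2) ramp back to the
physiological 9 mmHg in 3 s; (3) a 0.5 s plateau at 9 mmHg to test for
spontaneous recovery; (4) a further ramp at the stage-2 slope (78 mmHg/s)
adding 100 mmHg (13.33 kPa) to force recovery.

**Mechanics.** Explicit central-difference dynamics on first-order
tetrahedra: follower pressure on the cavity facets, tension-only trabecula
cables acting as tie beams, frictionless penalty self-contact, linear/
quadratic bulk viscosity (b₁ = 0.06, b₂ = 1.2), element-by-element stable
time increment, and a smoothed nodal-pressure volumetric formulation that
relieves the locking of constant-strain tets at ν = 0.495.

**Readout.** Inversion proceeds by *eversion* (wall streaming through the
orifice) punctuated by *snap-through* events — jumps between equilibrium
branches that appear as abrupt changes in the strain-energy trace.
`laasnap.metrics` detects these events, reads off inversion and recovery
pressures, and classifies configurations (anatomical / initial
snapped-through / final snapped-through / recovered).

## Worked example

The clamped spherical cap (r = 10 mm, t = 1.5 mm, half-angle 50°) is the
classic bistable structure; driven through the four-stage protocol (pressures
scaled ×0.15 to the cap's critical loads, time compressed ×0.02):

```sh
python analysis/03_cap_snap_through.py
```

prints

```
cap: 1089 elements, 3247 steps
  stage 1: inversion at p = -86.5 mmHg (unscaled), energy jump +0.3421 mJ
  stage 1: inversion at p = -96.3 mmHg (unscaled), energy jump -0.2282 mJ
  stage 1: inversion at p = -125.5 mmHg (unscaled), energy jump +0.1407 mJ
  stage 1: inversion at p = -160.6 mmHg (unscaled), energy jump +0.0562 mJ
  stage 4: recovery at p = +102.5 mmHg (unscaled), energy jump +0.1596 mJ
  anatomical: tip protrusion -3.99 mm at t = 0.0001 s
  initial_snapped_through: tip protrusion +5.06 mm at t = 0.0490 s
  final_snapped_through: tip protrusion +4.95 mm at t = 0.0871 s
  recovered: tip protrusion -5.39 mm at t = 0.2140 s
  energy balance residual: 0.114% of peak strain energy
```

Read: the cap snaps through during the suction stage (a cascade of events,
the first at −86.5 mmHg on the unscaled axis, flipping the tip from
−3.99 mm inside to +5.06 mm protruding), does **not** recover at the
restored physiological plateau, and snaps back only under the stage-4
overpressure — the hysteresis signature that makes inverted appendages
stay inverted until pressure well above physiological is applied.

The same cycle on a full synthetic appendage (chicken-wing preset,
6 trabecula cables, unscaled protocol pressures):

```sh
python analysis/06_inversion_study.py
```

```
chicken_wing: 1863 elements, 6 trabeculae, 21333 steps, aborted=False
  first inversion snap at p = -178.2 mmHg, strain energy there 62.3 mJ
  peak strain energy 409 mJ at full suction; peak cable force 1.88 N
  tip protrusion: reference -23.6 mm, max +32.3 mm, at restored 9 mmHg +24.5 mm (stays inverted), final -31.7 mm
```

The other drivers generate the four morphology presets with quality reports
(`analysis/02_generate_geometries.py`), fit Ogden coefficients to synthetic
biaxial data (`01`), evert a closed tube through its orifice with
self-contact (`04`), and run the three-mesh convergence series (`05`).
All outputs land in `results/`.

A `laasnap` console command wraps the same library for shell use
(`laasnap generate|simulate|analyze|fit-material`).

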