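# Methods

## Scope and units

The package simulates left atrial appendage (LAA) inversion and recovery as
a structural problem: a thin-walled, trabeculated sac of passive
hyperelastic tissue, pinned at its orifice rim, loaded by a uniform
time-varying cavity pressure.  Blood is represented only through that
pressure (no fluid–structure interaction); the atrial wall outside the
orifice is not modelled.  The initial state is stress-free at the generated
geometry — the pre-stress from physiological pressure is neglected, so the
generated shape is interpreted as the in-vivo loaded shape.

The solver works in a consistent mm–MPa–tonne–s system; energies come out
in mJ.  User-facing pressures are mmHg (1 mmHg = 101.325/760 kPa); density
is entered in kg/m³ and converted internally.

## Synthetic geometry

Patient CT reconstructions of appendages are not publicly available, so the
study geometries are generated parametrically and are *qualitative*
emulations of the four standard morphology classes — they reproduce the
classes' gross features (bend, taper, lobulation, trabecular burden), never
any specific patient anatomy, and results on them must not be read as
class-representative.

The inner cavity surface is a centerline sweep: a constant-curvature arc
(total turn = `bend_angle`) carrying rings of `n_c ≈ π·d/edge` vertices
whose radius tapers linearly from the orifice radius to
`taper_ratio × orifice radius`, closed by a hemispherical tip and an
orifice-plane fan (tagged, and removed again at solidification so the
orifice stays open).  Class lobes and bulges are smooth multiplicative
Gaussian bumps in the sweep's (s, θ) parameter space, drawn from the seeded
generator.  Every generated surface is a closed 2-manifold (checked:
every edge shared by exactly two triangles, Euler characteristic 2).

The outer wall offsets each inner vertex along its outward normal by the
wall thickness (default 2.1 mm, the average LAA wall thickness measured in
ovine hearts); generators attach analytic normals where available
(spheres, caps), otherwise angle-weighted vertex normals are used.  Since
the offset vertex lies exactly on the ray from its inner vertex, the
ray-cast mean wall distance equals the thickness by construction; a
triangle–triangle self-intersection scan (KD-tree broad phase) can be
enabled to reject invalid offsets.  The cauliflower class has no columnar
trabeculae; its septum-like wall stiffening is emulated by a mean-normalized
per-vertex thickness-multiplier field (ridge pattern), which preserves the
mean wall distance exactly.

Inner and outer surfaces are coupled into first-order tetrahedra by
stacking one or more prism layers between linearly interpolated surface
copies and splitting each prism with the lowest-global-vertex-id diagonal
rule, which guarantees that neighbouring prisms agree on their shared quad
diagonals (the mesh is conforming; verified by boundary-closure checks).
Two wall layers are the default; with the default 1.25 mm surface edge this
gives ≈ 15–19k elements per appendage with mean tet edge 1.37–1.42 mm and
shortest edges 0.10–0.17 mm.  Desk-scale dynamic runs use coarser
single-layer meshes (≈ 2k elements).

Trabeculae are tension-only cables between near-opposing inner-surface
nodes.  Anchor locations are drawn in (s, θ) parameter space (seeded) and
snapped to the nearest surface node; the partner is the facing-wall node
best aligned with the anchor's inward normal.  Parameter-space anchoring
makes refinement series receive geometrically matching cables.  Cable
diameters are drawn per preset: 2.0–4.3 mm for chicken wing and cactus,
0.8–1.2 mm for windsock.  The original trabecular meshing (solid struts vs
simplified elements) is not documented in the source imagery-based work;
cables tied to wall nodes are this package's choice, because they act
exactly as the tie beams the physics requires while keeping the wall mesh
conforming.

Two benchmark geometries isolate the two inversion mechanisms: a
clamped-rim spherical cap (classic snap-through bistability) and a
closed-tip tube (eversion through the orifice).

## Material

Third-order Ogden, deviatoric–volumetric split:
`W = Σᵢ (2μᵢ/αᵢ²)(λ̄₁^αᵢ+λ̄₂^αᵢ+λ̄₃^αᵢ−3) + (1/D₁)(J−1)²`.  Under this
convention the initial shear modulus is μ₀ = Σμᵢ and K₀ = 2/D₁; the shipped
card's printed D₁ follows from its μᵢ and ν = 0.495 to 2·10⁻⁷ relative,
which simultaneously fixes the convention and the MPa reading of the
coefficients (μ₀ ≈ 2.18 kPa initial shear modulus, physiologic for atrial
tissue).  Only the leading volumetric term is used (D₂ = D₃ = 0), the
standard near-incompressible practice.  The card's α = +2/+4/−2 family with
large cancelling μ terms makes the tissue stiffen strongly with strain: the
equibiaxial tangent modulus grows about fivefold by 5% strain.  Comparisons
against small-strain closed forms are therefore run at loads producing
≲ 0.5% strain.

Cauchy stress comes from the spectral decomposition of b = F·Fᵀ, assembled
as the isotropic tensor function σ = c₀I + c₁b + c₂b² whose coefficients
interpolate the principal values (reduced fits at coincident eigenvalues);
this avoids eigenvector computation and is verified against central finite
differences of W to 10⁻⁶·μ₀ on random deformations.

Fitting uses the incompressible closed forms for uniaxial, equibiaxial and
planar nominal stress, pooled with uniform weights, under
`scipy.optimize.least_squares` (Levenberg–Marquardt) with seeded multi-start
over α signs and magnitudes (the residual surface is multimodal and the
reference α set contains a negative exponent).  Ogden coefficient sets are
generically non-unique: the meaningful output is the response curve, and
recovery is measured as sup-norm curve deviation normalized by the response
scale (pointwise relative error is ill-posed at the λ = 1 zero crossing).
Volumetric D₁ is then derived from the imposed Poisson's ratio, since
biaxial data carry no volumetric information.

## Loading protocol

Piecewise-linear pressure–time curve with four stages (defaults): 9 →
−225 mmHg in 6 s; back to 9 mmHg in 3 s; 0.5 s plateau at 9 mmHg; then
+100 mmHg at the stage-2 slope (78 mmHg/s, duration 100/78 ≈ 1.282 s, end
at +109 mmHg).  The start/plateau value 9 mmHg is the mean left atrial
pressure; the curve starts there rather than at zero because stage 3
"maintains the initial pressure" and that initial pressure is the
physiological one (the start value is an overridable parameter).
`PressureProtocol.scaled` provides pressure scaling (for benchmarks whose
critical loads differ from the appendage's) and time compression (for
explicit-dynamics cost, below).

## Explicit solver

Central-difference dynamics with row-sum lumped masses.  Per element,
deformation gradients come from precomputed reference shape-function
gradients; internal forces are the *exact gradient* of the discrete strain
energy, which makes the energy audit meaningful.

**Volumetric treatment.**  Constant-strain tets lock volumetrically at
ν = 0.495.  The volumetric energy is therefore evaluated at a smoothed
volume ratio: element volumes are quarter-lumped to nodes, nodal ratios
J_a = V_a/V0_a are averaged back per element, and
E_vol = Σ_e V0_e·U(J̄_e).  Differentiating this energy exactly yields an
effective element pressure that is a two-ring smoothing of the raw nodal
pressures.  On the thick-sphere inflation benchmark this moves the
displacement ratio from 0.46 (raw constant-strain) to 0.97 of the
linear-elastic closed form at 2 wall layers.  A flag (`nodal_pressure`)
restores the plain per-element volumetric term.

**Bulk viscosity.**  The damping pressure carries the sign of the
volumetric strain rate ε̇_v = J̇/J: a linear term b₁ρc_d·L_e·ε̇_v always
active (damps ringing in the highest element mode), and a quadratic term
ρ(b₂L_e·ε̇_v)² active only in compression (resists element collapse under
high velocity gradients).  b₁ = 0.06 and b₂ = 1.2, the de-facto
explicit-dynamics defaults — the coefficients are named but not valued in
the source description.  Dissipation is non-negative by construction and
accumulated into the viscous-energy channel.

**Loads and constraints.**  Cavity pressure is a follower load on the
current inner facets (p·A·n split evenly over facet nodes; closed-surface
resultant is zero to round-off).  Trabecula cables use the uniaxial
incompressible Ogden nominal stress at the chord stretch, tension-only
(cable idealization; no compression or bending).  Self-contact is a
frictionless node-to-triangle penalty acting within a clearance offset,
with a KD-tree broad phase refreshed every `contact_rebuild` steps and
2-ring topological exclusion; the penalty potential enters the energy
audit.  Orifice-ring nodes have their translations pinned each step —
with translational-only tet nodes this leaves rotation about the rim free,
matching a "fixed but free to rotate" rim condition.

**Time increment.**  dt = safety · min_e(L_e/c_d) · (√(1+ξ²) − ξ) with
L_e the minimum element altitude (recomputed every step on the current
geometry), c_d = √((K₀+4μ₀/3)/ρ) at the mass-scaled density, ξ = b₁.  The
volumetric modulus dominates c_d at ν = 0.495 and is strain-independent,
so the initial-moduli estimate remains valid at large strain (the
deviatoric tangent contributes ≲ 4% to c_d even at λ ≈ 3); the default
safety factor 0.9 is reduced to 0.5 for violent eversion runs.  An
additional cap applies when contact is enabled (penalty spring frequency).

**Desk scaling.**  The physical protocol (≈ 10.8 s at dt ≈ 10⁻⁵ s for these
meshes) is compressed in time (×0.02–0.03) and mass-scaled (×16, dt ×4) to
run in 10³–10⁴ steps.  Mass-proportional damping (`mass_damping`, 1/s) is
available for dynamic-relaxation settling and to keep compressed-time runs
near the quasi-static path.  Validity is policed, not assumed: every run
samples the kinetic/strain energy fraction (QC threshold 10%, flagged per
sample) and the energy audit |W_ext − (E_strain+E_kin+E_visc+E_contact)|,
which stays ≤ 0.2% of peak strain energy on the benchmark cycles against
a 2% acceptance bound.  Snap-through transients are genuinely dynamic and
exceed the kinetic QC during the events themselves; the QC fraction
reported per run covers the quasi-static stretches between events.

**Failure handling.**  Element inversion (J ≤ 0) or NaN displacements abort
the run with the partial trace preserved and the offending element and time
reported.

## Event detection and classification

The strain-energy trace is median-filtered (window 5); a sample-to-sample
change is an event when it exceeds `rel_threshold` (default 5%) of the
running energy maximum *and* is a ≥4× outlier against the trace-wide median
increment (so smooth-but-fast loading is not flagged).  The running maximum
is floored at 2% of the trace-wide maximum, and traces that never exceed
1 nJ are treated as unloaded.  Adjacent detections merge; the event's
pressure is read from the trace, and its direction comes from the local
pressure slope (falling → inversion, rising → recovery).  Raising the
threshold can only remove events, and detection is a pure function of the
trace.  The defaults were calibrated on constructed step fixtures and the
benchmark runs, since the original traces are not available; they are all
exposed as parameters.

Configurations: *anatomical* before any event; *initial snapped-through* at
the first inversion event; *final snapped-through* after the last
inversion-direction event (flagged as partial invagination when the tip
remains on the interior side); *recovered* when the final
recovery-direction event is followed by the tip protrusion returning to the
reference side within 10% of the appendage height (a slightly
deeper-than-reference, pressurized final state counts as recovered; earlier
recovery-direction events — elastic unloading steps — are labelled
intermediate).  The tip is the node set beyond the 95th percentile of
reference distance from the orifice plane (least-squares plane through the
rim ring, normal oriented away from the body centroid); protrusion is the
signed distance of the tip centroid to that plane, positive toward the
atrium.

## Benchmarks and studies

* **Cap snap-through** (r = 10, t = 1.5 mm, half-angle 50°, protocol
  pressures ×0.15, time ×0.02): inversion-event cascade in stage 1, no
  events during the plateau, recovery event in stage 4.  The geometry/scale
  pair was chosen so the reverse-snap pressure falls strictly between the
  scaled plateau and the scaled stage-4 peak; by protocol construction the
  stage-4 peak is only 0.48× the suction magnitude, so shallower caps creep
  back at the plateau and much deeper caps fail to recover at all.
* **Tube eversion** (r = 5, t = 1, L = 25 mm): suction to −150 mmHg then
  release; the tube turns inside-out through its orifice (self-contact
  active during the turn) and settles, at zero load, in the everted
  equilibrium at +26.3 mm tip protrusion versus −26.0 mm reference —
  eversion bistability.  The measurement is taken at zero load because
  holding full suction keeps stretching the everted sac of this very soft
  tissue until elements degenerate.
* **Appendage cycle**: chicken-wing preset at the full printed protocol
  pressures (time ×0.03 with a 0.45 s hold appended at the stage-4 end
  pressure — the compressed stage-4 ramp is shorter than the recovery
  wave's travel time, so the hold lets recovery complete).  The run shows
  the full phenomenology: multi-event inversion, hundreds of mJ stored at
  full suction, no recovery at the restored 9 mmHg, recovery under the
  overpressure.
* **Mesh convergence**: three chicken-wing meshes at ~20% element-count
  increments (counts tuned via a tessellation-count predictor; 1863, 2175,
  2673 elements at the 2.8 mm base edge) run the suction ramp to
  −120 mmHg; the peak trabecular cable force reached by −90 mmHg (cables
  firmly engaged, pre-chaotic regime) differs by 0.8% (coarse→mid) and
  2.3% (mid→fine), under a 3% criterion.  Convergence is a property of the
  canonical reference geometry: at other trabecula-placement seeds, cables
  can land at marginal-engagement positions where the tension-only force at
  fixed suction is a knife-edge quantity (node-snapped anchors shift by
  O(edge) between refinement levels), and the metric is not convergent.
  Embedded barycentric anchors would remove that sensitivity but cables are
  deliberately node-tied (see above).

## Numerical choices and degenerate inputs

Tet node ordering is fixed to positive signed volume; inverted orderings
from the prism split are repaired by a node swap.  Eigenvalues of symmetric
3×3 tensors use the trigonometric closed form with clamping; coincident
eigenvalues fall back to reduced interpolations (continuous in the
eigenvalues).  The orifice frame rejects collinear rings; protocols reject
non-monotone breakpoints and out-of-range evaluation; generator parameters
are validated (positive dimensions, taper in (0,1], trabecula diameters
inside the orifice diameter).  File I/O writes coordinates with 17
significant digits (round-trip to 10⁻¹² relative); the INP subset is
1-based on disk and 0-based in memory.

## Limitations

Synthetic geometries are qualitative class emulations; none of the
patient-specific published pressures or energies are expected to be
reproduced, and single-geometry results are not class-representative.
Cables carry no bending or compression; contact is frictionless and
inner-surface-only; the atrium's compliance is absent (rigid orifice).
Time compression and mass scaling trade inertial fidelity for cost — event
pressures from compressed runs carry a rate bias that the kinetic QC
bounds but does not remove.  The wall is single-material and uniform in
thickness except for the cauliflower ridge field.
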