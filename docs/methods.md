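# Methods

This note documents the model implemented by `ossify`, the assumptions
behind it, the default parameters and why they have the values they do,
and what the simulations can and cannot show.

## Geometry and mesh

The domain is an idealised axisymmetric half-model of an osteotomised long
bone: a cortical cylinder (outer radius 5 mm, wall 2.5 mm) with a
transverse gap (2.1 or 3.1 mm), a marrow canal, and an external callus
spindle bulging to a maximal radius of 8 mm (16 mm diameter) over the gap.
The axial coordinate is z; z = 0 is the transverse mirror plane through the
mid-gap, so only the upper half is meshed. The callus profile is an
elliptical arc from the periosteal surface to the maximal radius — a
documented free choice, since only the maximal diameter is constrained.

Meshing revolves a structured (r, z) grid (coordinate lines snapped to all
region interfaces) through `n_theta` sectors: hexahedra everywhere, wedges
at the axis. The default resolution (`mesh_target_h` = 0.9 mm,
`n_theta` = 8) gives ≈ 1.3k elements; meshing is deterministic and the
element count grows monotonically as the target size shrinks. Regions
(cortical bone, gap tissue, medullary canal, external callus), face
adjacency, boundary node sets and element volumes are computed at build
time and validated (symmetric self-free adjacency, positive volumes,
volume partition).

## Poroelastic daily load event

Tissue is a fluid-saturated porous solid: linear isotropic drained
elasticity, Darcy flow, Biot coupling with α = 1 and a storage term n/K_f
(fluid bulk modulus 2300 MPa, incompressible grains). Displacements and
pore pressure share the trilinear basis (equal-order u–p, as in ABAQUS'
C3D8P family); time integration is backward Euler. Units are mm–N–MPa–s;
permeabilities are stored in m⁴/(N·s) and converted internally.

Boundary conditions for the daily event: the loaded bone end face moves
rigidly and only axially (the fixator's bending/torsional stiffness is
effectively infinite); the mirror plane is fixed axially; pore fluid drains
freely (p = 0) through the periosteal callus surface and nowhere else
(mirror plane and cortical wall are impermeable, the cortical permeability
of 1e-17 m⁴/Ns makes the bone essentially sealing anyway).

The external fixator is a piecewise-linear axial spring between the bone
ends, acting in parallel with the tissue column. Because the FE problem is
linear for a given material state, each day needs exactly one transient
solve under a unit prescribed end displacement; the actual amplitude
follows from the scalar balance `k_t·u + F_fix(2u) = 500 N` (solved to
1e-10 by bracketed iteration) and all fields scale linearly. The fixator
base curve is a stiffening piecewise-linear shape whose force scale is
calibrated once per case by deterministic bisection so that the day-1
all-connective-tissue model reproduces the nominal IFM (0.25 / 1.25 mm)
within 1 %; the published curve is not numerically tabulated, so
calibration against the nominal IFM substitutes for digitisation.

The load event is a quasi-static ramp of the 500 N load over
`load_ramp_duration` = 8 s in 6 backward-Euler steps. The ramp duration is
a modelling knob: it sets the scale of the Darcy velocities (v ∝ 1/T in the
drained regime). 8 s was chosen so that the fully healed callus — woven
bone, whose Table permeability is ~37× that of connective tissue — has its
fluid-velocity stimulus floor safely below the physiological band; with
much shorter ramps the healed state never reads as mechanically quiet,
because v/b alone stays above any sensible band.

Per element the solver reports the octahedral shear strain
γ = (2/3)·√[(ε₁−ε₂)² + (ε₂−ε₃)² + (ε₃−ε₁)²] from the centroid strain at
peak load, and the Darcy speed |−k∇p| at the centroid, taking the peak over
the ramp. The stimulus is S = γ/a + v/b with a = 0.0375 and b = 3 μm/s.

### Stimulus sampling

The raw element-centroid stimulus is mesh-divergent at the re-entrant
corners (fragment edge, drainage/cortex junction): the maximum over
elements grows without bound under refinement. Differentiating cell
populations integrate their mechanical environment over a finite
neighbourhood, so the stimulus that drives the controller — and the
healing-day metric — is the volume-weighted average of S over a metric
neighbourhood of radius `stimulus_smoothing_radius` = 1.5 mm. With this
sampling the day-1 peak stimulus changes by < 2 % when the element count is
doubled. The raw field (with the exact identity S = γ/a + v/b) is kept and
exported alongside.

## Tissue model

Per element: volume fractions of connective tissue, cartilage and woven
bone (summing to 1; connective tissue is the slack component) plus a
perfusion level in [0, 1]. Pure-tissue constants (E in MPa, ν, permeability
in m⁴/Ns, porosity):

| tissue      | E     | ν    | k       | n    |
|-------------|-------|------|---------|------|
| connective  | 3     | 0.30 | 1e-14   | 0.8  |
| cartilage   | 200   | 0.45 | 5e-15   | 0.8  |
| woven bone  | 4000  | 0.36 | 3.7e-13 | 0.8  |
| cortical    | 10000 | 0.36 | 1e-17   | 0.04 |

Element properties: cubic rule of mixtures for E (after the experimental
stiffness–density relationship), linear rules for ν, k and n. Cortical
elements never remodel and use the cortical row directly.

## Fuzzy controller

A Mamdani system with six inputs (S, c_perfusion, c_adPerfusion,
c_cartilage, c_bone, c_adbone) and three outputs (daily changes of
perfusion, cartilage, bone). "Adjacent" inputs are the maxima of perfusion
and bone concentration over a metric neighbourhood of radius
`neighborhood_radius` = 1.3 mm around each element (cortical neighbours
included, so ossification can nucleate at the cortex). A metric rather than
topological neighbourhood keeps the propagation speed of the perfusion and
ossification fronts fixed in mm/day instead of elements/day; with literal
face adjacency the predicted healing day scales with the element size,
which contradicts the intended mesh insensitivity of the model. At the
default resolution the 1.3 mm ball essentially reproduces the face
neighbourhood in the (r, z) plane.

The 14 rules (see `ossify.fuzzy.transcribe_rule_table`) encode:
angiogenesis spreading from perfused neighbours (1–3), intramembranous
ossification at low stimulus, high perfusion and bony neighbourhood (4),
chondrogenesis at low/high stimulus (5–8), endochondral replacement of
cartilage by bone at low/medium stimulus with sufficient perfusion (9–12),
tissue destruction under overload (13), and a default "stay" rule (14).
Negated terms use the standard complement. Inference is min-activation,
min-clip implication, max aggregation and centroid defuzzification; the
centroid is integrated *exactly* on the piecewise-linear aggregate (all
trapezoid corners, clip crossings and pairwise segment intersections become
integration breakpoints), so results are deterministic and grid-free. A
dense-grid oracle (10⁴ samples) is used in the tests to verify the exact
integration.

### Membership calibration

Only the shapes (trapezoidal) and the linguistic structure of the
membership functions are fixed by the model; the breakpoint abscissae and
the output magnitudes are calibrated quantities. The defaults, shared by
both fixation cases, are:

* **Stimulus bands** (on the smoothed element-level scale, which carries
  the stress concentrations of the corner elements and therefore sits
  above the nominal-gap-strain scale of the classical shear/flow
  diagrams): low plateau to 0.8, foot 1.2; medium to ≈ 4 (±10 %); high to
  the destruction flank; destruction grading linearly over S = 18…28
  (`s_destruction` = 23, flank width 10). The broad flank makes overload
  damage proportional to severity instead of switching at a threshold.
* **Perfusion terms**: low (0, 0, 0.1, 0.3) — the 30 % boundary source
  reads as fully "not low" to its neighbours, seeding angiogenesis;
  medium (0.1, 0.3, 0.55, 0.75); high (0.25, 0.65, 1, 1), overlapping low
  enough that the chain self-accelerates.
* **Tissue-concentration terms**: as above but with the "low" foot at
  0.4. This foot is the cartilage level at which chondrogenesis saturates
  (rules 5–6 require "cartilage low"), i.e. the stiffness a purely
  chondral callus can reach (E ≈ 13 MPa); it must be high enough that the
  bridging ring of the unstable case can escape the high-stimulus regime.
* **Outputs**: changes per day on [−δ, δ] with the single global rate
  knob `rate_delta` δ = 0.09; "stay" is centred at zero, so the
  ever-active default rule damps all changes.

δ and the band edges were calibrated once, jointly for both cases, so that
the stable case heals near day 42; they are not re-tuned per case or per
mesh. With the defaults the simulated healing days are 36 (case A) and 60
(case B) at the default mesh, against the experiment-derived 42 and 56 —
within the week-level tolerance this model class supports, and with the
correct ordering and IFM-curve shapes (early plateau, rapid decrease, the
unstable case delayed by destruction).

## Healing loop

Day k: homogenise materials → daily FE solve → stimulus (smoothed) → fuzzy
update of every non-cortical element → add the daily changes, clamp to
[0, 1], rescale cartilage+bone proportionally if they exceed 1, set the
connective fraction to the remainder → re-impose the perfusion sources
(floors, not caps: the periosteal boundary at 30 % every day, the medullary
canal at 30 % from day 10, representing revascularisation from the marrow)
→ record IFM, stimulus and state. Initial state: connective tissue
everywhere in the callus, perfusion zero except the periosteal source
elements. One FE solve per simulated day; the loop is bitwise
deterministic.

Markers: the healing day is the first day the *peak* (smoothed) stimulus
over all soft elements enters the physiological band — S ≤ 1.2, sustained
for 3 consecutive days. The band is a definition, not a measurement: it was
placed above the healed-state fluid-velocity floor (≈ 0.3–0.4 at the
default mesh) and below the pre-healing range. The IFM-minimum day is the
first day the IFM is within 5 % of its final value.

## Study conditions and problem sizes

All inputs are generated; there is no external data. The packaged
`case_A.yaml` / `case_B.yaml` encode the two fixation conditions (gap and
nominal IFM per case, everything else shared). Default runs use the ≈1.3k
element mesh, 6 time steps per daily solve, and 70 days (the CLI default);
the acceptance script and the acceptance tests run 98 days so that the
chondral phase has fully resorbed by the end of the record. A full run
takes on the order of a minute per case at the default resolution.

## Numerical choices

* Equal-order u–p with backward Euler; small storage n/K_f regularises the
  undrained limit. No pressure stabilisation is applied; the Terzaghi
  benchmark (50-element column, three dimensionless times) is within 2 %
  L2 of the analytic series with the tested step sizes.
* Sparse LU (SuperLU) on the symmetric-form saddle system, one
  factorisation per day reused over the ramp steps.
* Patch tests on distorted single elements are exact to 1e-10 (these
  caught a Jacobian-orientation defect during development that axis-aligned
  meshes cannot see).
* The exact centroid integrator returns 0 for an empty aggregate; rules 13
  and 14 make that unreachable for in-universe inputs.
* Degenerate inputs are rejected loudly: geometry constraint violations,
  non-monotone fixator curves, unreachable calibration targets, tissue
  states off the unit simplex, unknown config keys.

## What passing tests do and do not show

The model reproduces, under a single shared calibration: day-1 IFMs by
construction (calibration); the week-level healing times and their ordering
between stable and unstable fixation; the qualitative spatiotemporal
pattern (day-1 stimulus peak in the gap, higher in the unstable case;
intramembranous onset at the cortex away from the gap; a transient
chondral phase that resorbs after bridging); conservation and bounds of
the tissue fractions; and stability of the healing day under a doubling of
the element count (±7 days). It does **not** validate against independent
animal data, does not resolve the corner singularities it averages over,
and its absolute healing days inherit the calibration freedom of the
membership breakpoints.

## Known limitations

* Small-strain kinematics despite gap strains up to ~40 % in the unstable
  case early on — a fidelity limit shared with the linear consolidation
  formulation it follows.
* Angiogenesis is a continuous field with front speed set by the
  neighbourhood radius, not discrete vessel sprouting.
* The fixator curve shape (beyond its calibrated scale) is a free choice;
  only axial behaviour is modelled.
* Meshes substantially *coarser* than the default (≲ 1k elements) are
  outside the validated range; the mesh-robustness property is established
  for refinement from the default resolution.
* No growth factors, cell populations or remodelling of cortical bone.
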