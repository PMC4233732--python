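# Methods

## Scope and modelling idiom

jawsim is an inverse quasi-static simulator of unilateral mastication and
incisor biting in a rabbit-scale mammalian skull.  The cranium is fixed;
the mandible is a single rigid body whose pose along the chew cycle is
*prescribed* (as in cineradiography-driven studies), so the unknowns at
each instant are the muscle activations and joint reactions that make the
six-degree-of-freedom force/moment balance close — not the motion itself.
This is the standard inverse-dynamics treatment of muscle redundancy,
specialised to a jaw with unilateral temporomandibular joint (TMJ)
contact and a deformable food bolus.

Units throughout: mm, N, N·mm, g, ms.  World frame: origin at the
midpoint between the condyles, +x anterior, +y toward the animal's left,
+z dorsal.  The working (chewing) side is the right side.

## Muscle architecture and strands

The shipped architecture table carries, per jaw-closer muscle: mass (g),
fibre length (cm), PCSA (cm²) and maximum force (N).  PCSA follows
mass·cos(pennation)/(density·fibre length) with density 1.05 g cm⁻³ and
zero pennation; maximum force is PCSA × muscle stress (reference
25 N cm⁻²).  The *printed maximum forces are authoritative*: three rows
of the table (temporalis, medial and lateral pterygoid) are not
internally consistent with the PCSA formula at any plausible density, so
the mass/fibre-length/PCSA columns are retained as provenance metadata
and the forces are used verbatim.  The temporalis total of 37.1 N is
split into a superficial part of 6.2 N and a deep part of 30.9 N.  The
digastric (jaw opener, architecture not tabulated) defaults to 10 N;
it only drives jaw opening and does not affect bite-force results.
Changing the muscle-stress configuration rescales every maximum force
proportionally, which makes the maximum-bite problem exactly homogeneous
in stress.

Each muscle part is discretised into strands.  The per-side budget of 75
strands (150 total) is allocated proportionally to maximum force with a
floor of 3 strands per part, the remainder going to the superficial
masseter; any explicit allocation summing to the budget is accepted.
Per-strand force shares are equal within a part, so the shares sum
exactly to the part's maximum force.

A strand's tension is `a·F_share + passive(ε)` with activation
`a ∈ [0, 1]`.  No force–length or force–velocity scaling and no
activation dynamics are modelled — the actuator has exactly the three
parameters the recruitment problem uses (maximum force, activation
factor, passive tension).  Passive tension is zero at or below rest
length (taken at the closed midline pose), rises as `e^{cε} − 1`
(shape c = 5, configurable) and saturates at 0.1 % of the strand's
maximum force at strain 0.5.  Both the cap fraction and the saturation
strain are configurable; the defaults make passive tension mechanically
negligible, and the test suite verifies that removing it shifts peak
activations by well under half a percentage point.

Strand paths run from a cranial origin through optional via points to a
mandibular insertion.  Via points model muscle wrapping (superficial
temporalis around the lateral skull margin, medial pterygoid around the
pterygoid flange) as fixed deflection points rather than true surface
wrapping — the classic via-point treatment.  Tension is uniform along the
path; forces act on the mandible at every mandible-frame path point (the
insertion pulls toward its neighbour; a mandible-frame interior point
receives the resultant of its two adjacent segment tensions).  This makes
the strand wrench exactly consistent with the virtual-work identity
d(length)/dq = −(moment arm), which the tests verify against central
finite differences over random strands and poses.

## Synthetic geometry

No coordinate set ships with the architecture table, so the default
geometry is generated: bilaterally mirrored attachment bars (origin and
insertion line segments per muscle part, fanned per strand), condyles
±9 mm from the midline, tooth bite points (incisor 55 mm anterior of the
condyle line; molar and premolar points on each side), and an ellipsoidal
mandible (density 1.05 g cm⁻³, ≈ 7 g).  The bars reproduce the
qualitative lines of action of the real adductors — a masseter sling from
the zygomatic arch to the angular region, vertical temporalis strands on
the coronoid and descending ramus, medially directed pterygoid pull, a
digastric running down and back from the cranial base to the chin — but
their dimensions are *calibration parameters of the package, not measured
anatomy*.  The insertion depths were calibrated once so that the
maximum incisor bite force at a 5.5 mm gape falls centrally within the
measured envelope (mean − 2 s.d. to absolute maximum, i.e. 42.5–95.2 N);
the default geometry yields 83.0 N.  An isotropic jaw-length scale and a
seeded Gaussian jitter option (for deliberately asymmetric models) are
exposed; with jitter off the model is exactly mirror-symmetric, which the
incisor-biting symmetry results rely on.

Geometry can instead be loaded from an attachment-coordinate CSV
(columns: muscle, side, strand, role ∈ {origin, via, insertion}, frame ∈
{cranium, mandible}, x, y, z, ordinal).  The dialect adds a `strand`
column to the obvious role/frame/coordinate schema so that multi-strand
muscles round-trip losslessly; `float_precision="round_trip"` is used on
read so written models reload bit-identically.

## Pose parameterisation and the TMJ

The jaw pose is (sagittal angle, frontal angle, condylar translation):
sagittal rotation about the transverse axis through both condyles
(positive opens the jaw), then frontal rotation about the anteroposterior
axis through the *balancing* condyle (positive swings the chin toward the
working side; the balancing condyle stays essentially stationary while
the working condyle displaces, matching cineradiographic descriptions of
the power stroke), then anteroposterior condylar translation (per-condyle
values; unequal values yaw the jaw).  The closed midline pose is the
identity.

The TMJ is two frictionless unilateral point contacts.  Each condyle can
receive a compressive reaction λ ≥ 0 along its fossa normal.  The normal
is tilted 25° posteriorly from vertical (configurable): a purely dorsal
normal would force the entire net anteroposterior muscle pull through the
bite point, whereas the articular eminence in fact reacts part of it.
An admissibility helper also supports a friction coefficient μ (default
0): candidate reactions are projected by clamping the normal at zero and
rescaling the tangential part onto the friction bound at fixed normal
magnitude.

Mandible inertia can come from a watertight surface mesh (volume
integrals at 1.05 g cm⁻³) or the default ellipsoid.  The default solve is
quasi-static; the inertial wrench (M·q̈ plus gyroscopic terms) is
available behind a `dynamic` flag but contributes ≪ 1 N·mm at chewing
accelerations and rabbit mandible mass, which is why the quasi-static
default is used for all reported quantities.

## Chewing kinematics

A reduction bite cycle has three phases with default durations 90 / 50 /
140 ms (opening, fast closing, slow closing; only the 140 ms power stroke
is an empirical datum — the others are literature-consistent free
parameters).  Angles follow cosine ramps through the waypoints: opening
0→12° sagittal; fast closing 12°→contact angle with frontal 0→4° (0 for
incisor biting); slow closing contact→end angle with frontal 4°→0
(shearing), held at 4° (crushing), or 0 throughout (incisor).  The
contact angle is root-solved so the tooth–tooth separation at the bite
site equals the bolus height exactly at the fast/slow boundary, and the
end angle so vertical compression reaches half the bolus height exactly
at cycle end.  Default timestep 1 ms (281 poses per cycle).

## Food bolus

Two rigid plates tied to the opposing tooth points, joined by a tri-axial
linear spring with per-axis caps; past the cap the force plateaus rather
than unloading.  The vertical axis resists compression only; shear axes
act bidirectionally.  Vertical stiffness is cap/height, so full
compression develops exactly the cap (100 N crushing and incisor over
1.3 and 2.4 mm respectively; 60 N shearing) and the half-compression
power stroke peaks at exactly half of it (50 N for crushing and incisor).
The shearing mode's mediolateral stiffness is cap divided by the
mediolateral excursion of the bite point over the frontal return, so the
20 N shear resistance is fully developed exactly when the jaw regains the
midline.  All other shear axes use cap/height: the only stated fact about
shear is the 20 N resistance of the commanded return, and incidental
occlusal slip (a few tenths of a mm from the closing arc) should produce
proportionally small forces, not cap-saturated ones.  The rigid bolus for
maximum-bite simulations uses a stiffness that keeps compression below
1 µm at 500 N.

## The recruitment solve

At each timestep: minimise Σ aᵢ² subject to the 6-DOF equilibrium
(strand wrenches, linear in the activations, plus joint reactions, bolus
wrench, passive tension and gravity summing to zero), bounds 0 ≤ a ≤ 1
with a ≡ 0 outside the phase's allowed set, λ ≥ 0, and mirrored-pair
equality ties in incisor mode.  The quadratic-activation objective (not
force-weighted) deliberately biases load toward strong muscles, which is
what lets a strong adductor produce large forces at modest activation.

The allowed sets encode the two functional muscle groups: group 1
(working-side posterior deep masseter, both zygomaticomandibularis parts,
both temporalis parts; balancing-side superficial masseter and both
pterygoids) alone during fast closing; groups 1 ∪ 2 (i.e. all closers)
during slow closing; digastrics alone during opening; all closers with
symmetric ties throughout incisor biting.  Group 2 becomes *eligible* at
power-stroke onset and the optimiser sets its level — the solver is not
forced to use it.

Implementation: the bounded QP is solved as a stacked weighted linear
least-squares problem (`scipy.optimize.lsq_linear`, BVLS; weight 10⁶ on
the six equilibrium rows, unit weight on activations, a 10⁻⁹ regulariser
on the reactions for uniqueness), then polished by freezing variables at
their active bounds and re-solving the free block against the exact
constraint with a column-scaled pseudoinverse.  On attainable steps this
drives the equilibrium residual to ~10⁻¹⁰ N / N·mm, far inside the
declared feasibility tolerances (10⁻⁶ N force, 10⁻⁴ N·mm moment).  If the
bounds make equilibrium unattainable the solver returns the
least-residual recruitment and flags the step infeasible — never
silently.  Tied pairs are merged into single variables with doubled
objective weight, which is algebraically identical to the tied QP.

Two situations are structurally infeasible in the quasi-static setting
and are reported as such: the opening phase (the digastric and gravity
both act jaw-opening once passive closer tension is exceeded; residuals
≲ 1.6 N·mm) and parts of fast closing (passive closing tension slightly
exceeds gravity's opening moment and group 1 contains no opener;
residuals ≈ 0.03 N / 0.007 N·mm).  These imbalances are three to four
orders of magnitude below the chewing forces of interest and would be
absorbed by the inertial terms in a dynamic solve.  All power-stroke
(slow-closing) steps are feasible in all four modes.

## Reported statistics

* **Bite record** — the bolus spring force at the instant of peak
  resultant, resolved into anteroposterior/mediolateral/vertical
  components and unsigned percentages of the resultant (so the squared
  fractions sum to one).
* **Recruited fraction** — 100·Σ aᵢFᵢ / Σ Fᵢ over all closer strands on
  both sides (denominator 411.8 N for the default model; the digastric is
  excluded), evaluated at the instant of peak total recruited force.
* **Peak activation table** — per muscle part and side, the cycle
  maximum of the force-weighted mean strand activation (superficial and
  anterior deep masseter are one part by construction); incisor mode adds
  a side-averaged column.
* **Maximum incisor bite force** — all closers at full activation
  against the rigid bolus at a 5.5 mm incisal gape; the static balance is
  solved for the three-component bite reaction (the rigid, high-friction
  bolus transmits shear) and the two condylar magnitudes, and the result
  is compared with measured statistics (mean 69.1 ± 13.3 N, absolute
  maximum 95.2 N) via z-score, a within-±1-s.d. flag and a strict
  below-absolute-maximum flag.

On the default model: shearing develops (ap, ml, vertical) ≈
(12.5, 20, 30) N — the mediolateral cap plus half the vertical cap —
giving a 78.6 % vertical share; crushing and incisor biting are ≥ 99 %
vertical at ≈ 50 N; recruited fractions order shearing < crushing <
premolar < incisor (16.4, 21.6, 29.5, 56.8 %), reproducing the
characteristic result that molar chewing leaves a large strength reserve
while incisor biting, with its poor mechanical advantage, does not.

## What the synthetic model does and does not show

The synthetic geometry preserves the structural features the analysis
depends on (hinge-like condylar axis, tooth points at realistic
anteroposterior stations, adductor lines of action, exact bilateral
symmetry) but not any individual's anatomy.  Consequently the package
asserts *laws and orderings* on the default model — equilibrium residual
tolerances, virtual-work consistency, stress homogeneity, symmetry
zeroes, recruited-fraction and verticality orderings, the measured
maximum-bite envelope — rather than specimen-specific force values,
which depend on unpublished attachment coordinates and TMJ surfaces.
Passing tests therefore validate the mechanics and the pipeline, not the
anatomical fidelity of any particular rabbit.

## Numerical choices

* Timestep 1 ms; cosine ramps give C¹ waypoint interpolation.
* Root solves (contact/end angles, gape inversion) use Brent's method at
  1e-10 mm tolerance.
* Feasibility tolerances 1e-6 N / 1e-4 N·mm; bound-activity tolerance
  1e-9; final activations clamped to [0, 1] against ~1e-16 solver noise.
* The acceptance script derives any seed it uses modulo 2³¹; the default
  model contains no randomness (jitter is opt-in and seeded).
* Degenerate inputs raise typed errors (`ConfigError`, `SchemaError`,
  `GeometryError`, `SimulationSetupError`) which the CLI maps to
  distinct exit codes.

## Known limitations

* No activation dynamics or electromechanical delay: activation acts
  instantly, so predicted activation peaks lag measured EMG peaks in
  vivo; timing comparisons are ordinal only.
* Quasi-static recruitment makes the unloaded phases (opening, early
  fast closing) nearly effortless, so group 1's absolute activation
  levels during fast closing are much lower than a dynamic model would
  produce; the group-1-before-group-2 peak ordering survives, the
  magnitudes do not.
* No force–length/velocity properties, fatigue, or compliant TMJ disc;
  condylar translation is kinematic, not contact-resolved.
* The frontal-rotation axis placement (through the balancing condyle)
  is an interpretation of the cineradiographic description; alternatives
  (e.g. an incisor-referenced rotation) would change shear excursions by
  geometry-level factors.
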