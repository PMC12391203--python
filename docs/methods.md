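# Methods

## Models

Both full-body models are rooted kinematic trees: ground → pelvis via a
6-DoF free joint (three translations along the lab axes, then intrinsic
Z–X–Y rotations: tilt, list, axial rotation), then the limbs and torso
stack. The lab frame is X anterior, Y up, Z to the subject's right; all
segment frames are aligned with the lab frame at the default standing pose
and originate at the segment's proximal joint centre.

**Inherited structure** (identical in every variant): 7 bodies per leg
(femur, patella, tibia, fibula, talus, calcaneus, toes; the patella and
fibula are weld-attached) with 7 DoF (3 hip, 1 knee, 1 ankle, 1 subtalar,
1 metatarsophalangeal), and 3 bodies per arm (humerus, lumped
radius/ulna, hand) with 7 DoF (3 glenohumeral, 1 elbow, 1 forearm
pronation/supination, 2 wrist). With the 6 pelvis coordinates this gives
20 lower-body and 14 upper-limb DoF and 21 bodies.

**Baseline** (lumped torso): one torso body — the rigid composition of
abdomen, thorax, neck, head, clavicles and scapulae — on a 3-DoF
lumbosacral (L5–S1) joint. 22 bodies, 37 DoF.

**Augmented**: the lumped segment is split into eight bodies. The torso
is abdomen + thorax on 3-DoF joints at L5–S1 and T12–L1; the neck and
head ride on 3-DoF joints at C7–T1 and at the top of C1; each clavicle
connects to the thorax by a 2-DoF sternoclavicular joint
(protraction–retraction and elevation–depression) with the scapula welded
at the acromioclavicular joint. 29 bodies, 48 DoF.

Counting convention: `count_bodies` counts every body in the tree,
weld-attached ones included, matching the published tally of 29
"articulating" bodies (which itself includes the welded scapulae);
`merge_welds=True` collapses weld clusters instead.

### Coordinate coupling

Axial rotations are evenly split by linear coupling constraints: a single
independent driver coordinate (`head_rotation`, `torso_rotation`) sets
both joints' axial coordinates at ratio 0.5, so the two-joint neck adds
only two free coordinates (flexion and bending of the second joint) over
the one-joint neck — this bookkeeping is what makes the augmented total
exactly 48. Whether the two cervical joints' flexion/bending should also
be coupled is genuinely open; we keep them independent because only the
axial split is prescribed and the 48-DoF total confirms the choice.

The articulated-lumbar variants interpose five vertebral bodies whose
intervertebral rotations are coupled to three total-lumbar coordinates
with per-level ratios (default 0.25/0.23/0.20/0.17/0.15 from L1–L2 down
to L5–S1, a configuration value summing to one); coupling removes every
added DoF, so the articulated spine has the same mobility count as the
single lumbosacral joint.

Rotational joints compose intrinsically in the order
extension (Z), bending (X), axial (Y). The sternoclavicular axes are
built from the quoted construction — x from the sternoclavicular to the
acromioclavicular joint centre, z perpendicular to x and the global up
axis, y completing the right-handed frame — and frozen at the default
pose, which makes the posture-dependent definition well-posed.

### Geometry and inertia

No anatomical coordinates are hard-coded: all joint centres, marker
positions and inertial parameters live in a versioned geometry
configuration (`fullbody.geometry`, YAML-serializable) describing a
170 cm / 75 kg reference skeleton with proportions and segment-mass
fractions in the style of standard adjusted anthropometric tables. Tests
assert topology and closure properties, never specific anatomy.

The upper-body split uses a partition table of mass fractions (of the
lumped segment), com fractions along each segment span, and radii of
gyration as fractions of span length. Masses close exactly: the rounding
residual is assigned to the thorax, the largest piece. Because the
baseline's lumped torso is constructed as the rigid composition
(parallel-axis theorem) of the split pieces, total mass, composite com
and composite inertia agree between variants to machine precision, so
static inverse dynamics cannot distinguish them — exactly the intended
null.

Subject scaling is isotropic per segment by default (anisotropic factors
are accepted): geometry scales per-axis in each segment frame, masses by
the subject/generic mass ratio preserving relative distribution, inertia
entries by the mass ratio times the two axis factors of their indices.
Scale factors can be estimated from a static trial as measured/model
marker-pair distance ratios.

## Inverse kinematics

Per frame, the weighted least-squares marker objective is minimized over
the independent coordinates by a damped Gauss–Newton iteration
(Levenberg-style λ adaptation, analytic geometric Jacobian mapped through
the coupling matrix, gradient tolerance 1e-10, at most 100 iterations).
Occluded markers are dropped from the frame's objective. Frames are
solved sequentially, each warm-started from the previous solution (the
first from the model defaults). Rotational coordinates that drive no
coupling are wrapped into (−π, π] after each accepted step — a
pose-preserving operation that keeps solutions inside the declared
coordinate ranges. Coordinate ranges are not enforced as hard bounds
(transient out-of-range values are allowed during iteration); rank
deficiency is detected and reported per frame rather than raised.

The wrist markers (WRA, WRB) attach to the hand segment: with only one
finger marker, the wrist and pronation coordinates would otherwise be
unobservable and the noiseless round-trip guarantee could not hold.

## Inverse dynamics

Coordinates are low-pass filtered with a zero-phase (forward–backward)
4th-order Butterworth at 20 Hz (reflective padding; order and cutoff are
parameters), differentiated by second-order central differences
(second-order one-sided stencils at the ends), and expanded through the
coupling map. External loads get the identical filter by default and are
linearly interpolated to the kinematic frames — both choices are
configuration, made to avoid phase mismatch between kinematics and loads.

The recursion runs in the world frame: an outward pass propagates body
angular velocity and the angular/linear accelerations through each
joint's translation-then-rotation sequence, an inward pass accumulates
segment inertial wrenches (m(a−g); Iα + ω×Iω), external loads applied at
their centre of pressure with the free moment, and child-joint reactions,
projecting the transmitted wrench onto each coordinate's world axis.
No reserve actuators exist anywhere. Generalized forces are reported for
independent coordinates only; a coupling driver receives the
ratio-weighted sum of its joints' torques. The pelvis free joint's six
generalized forces are the residual forces (anterior–posterior,
superior–inferior, medial–lateral — the free joint's translation axes,
i.e. lab axes) and residual moments (pelvis tilt, list, rotation axes at
the current pose).

Two independent checks guard the recursion: body accelerations agree
with second differences of forward kinematics along the coordinate path,
and the pelvis residuals equal a closed-form whole-body momentum balance
(Σmᵢaᵢ − Mg − ΣF_ext and the matching moment sum) to machine precision.

## Synthetic trials

The generator manufactures the study conditions: cutting-style archetypes
(agility turn, v-cut, cone cut, quick stop, side shuffle, plus a static
pose) at 240 Hz. Oscillatory coordinates follow whole-number-of-cycle
sinusoids with seeded phases, so the commanded range of motion is met
exactly; defaults put every added upper-body DoF in the 9.6–22.5°
band with lumbar flexion/extension at 22.5° and lumbar bending at 18°.
The pelvis follows a smoothstep path (e.g. a 90° yaw change for the
v-cut); the swing-side hip and knee are flexed (ramped offsets of 30° and
60°) so the left distal-metatarsal markers stay far above the 110 mm
ground-clearance threshold throughout the stance window, which runs from
30 % to 75 % of the trial. Markers are forward kinematics plus isotropic
Gaussian noise (default 2 mm, typical of marker hardware) with optional
occlusion windows.

The ground-reaction load is built to be dynamically consistent with the
generating model: at every frame the whole-body wrench (force
Σmᵢaᵢ − Mg; the moment balance about the centre of pressure fixes the
free moment, kept as a full 3-vector) is attributed to the stance-side
calcaneus, with the cop progressing heel to toe on the floor during
stance. The load covers the whole trial rather than only the stance
window so that the zero-phase filter sees no step discontinuity; truth
coordinates are differentiated with the same central-difference scheme
the ID pipeline uses, so a consistent trial's residuals reflect
filter/differentiation numerics only (≈0.02 N and 0.02 N·m RMS at
240 Hz, against 1 N / 1 N·m pass bands).

What the trials do **not** emulate: soft-tissue artefact (noise is
white and isotropic), double support, ballistic flight phases (loads are
attributed to one body for the whole trial), foot–ground contact
mechanics, and muscle-driven coordination. Passing tests therefore show
that the algorithms are correct and that the model-comparison directions
follow from upper-body articulation alone — not that the magnitudes match
any particular athlete population.

## Model comparisons

Segment tests isolate one modelling choice with the base-10 / tested-1
marker-weight protocol (neck: torso base, head tested; shoulder: torso
base, arm tested; torso: pelvis base, torso tested); the trial is
generated with the most articulated candidate and 1 mm marker noise.
Full-body comparisons use uniform weight 1. The inverse-dynamics
comparison tracks a noiseless articulated trial with both full-body
models and feeds both the identical consistent loads; residual RMS is
taken over the stance window and compared as augmented/baseline ratios.
Noiseless markers isolate the modelling error that the ratio is meant to
measure; with the baseline unable to follow the upper body, its residual
moments are orders of magnitude above the augmented model's numerical
floor, so the synthetic ratios are far smaller than anything achievable
with real data — only their direction (< 1) is meaningful.

## Problem sizes and tolerances

The shipped test suite and `scripts/acceptance.py` use scaled-down trials
chosen to exercise every code path at comfortable numerical margins:
round-trip recovery runs 0.4 s at 60 Hz for each of the 24 variant
combinations (tolerances 0.5° / 0.5 mm against observed ≈1e-6°);
consistency and the ID comparison run 1.0–1.2 s at 120–240 Hz; the
oracle equivalence uses 100 random states at 1e-8 relative tolerance
against observed ≈1e-15. TRC files are written with 10 significant
digits so round trips are lossless to well below 1e-6 mm; MOT files
honour the inDegrees flag at the I/O boundary. The foot-in-air threshold
is strict (exactly 110 mm does not count as airborne) and configurable.
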