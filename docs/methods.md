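# Methods

This note documents the models implemented in `sabrebite`, their
assumptions, the tunable parameters that matter, and the numerical choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Finite-element model

All solves are linear static analyses of an assembled cranium + mandible
model.

**Elements.** Solids are four-noded constant-strain tetrahedra ("tet4
bricks") — the patch test is exact for them, and bending convergence is
first-order, which is why the cantilever validation is asserted at 15 % of
Euler–Bernoulli at the shipped refinement rather than tighter. Muscles are
two-node axial trusses whose *pretension* is applied as a pair of
equal-magnitude, opposite, collinear external forces along the current
element axis (no geometric stiffness update): muscle tension therefore does
not vary with jaw position by construction, i.e. the model deliberately
assumes maximal muscle performance at every gape. Beams are 3-D
Euler–Bernoulli elements with optional rotational end releases (condensed
out of the element matrix). Rigid links are imposed exactly by master–slave
elimination of the slave DOFs (a congruence transform of the stiffness), not
by penalties, so no conditioning parameter exists to tune.

**Degrees of freedom.** Tet nodes carry three translations; any node touched
by a beam, link, hinge, rotational support or applied moment is expanded to
six DOFs. The reduced system is factorised with a direct sparse LU
(symmetric mode) with one step of iterative refinement; the relative
residual is checked at 1e-8 and a singular or ill-conditioned system raises
a structured error naming the number of remaining zero-energy modes
(thresholded against the median diagonal stiffness — the matrix maximum is
inflated by rigid-link lever arms and would misclassify stiff modes).

**Materials.** The comparative analyses are material-relative (ratios and
linear scalings), so the defaults only set the stress scale: cortical bone
E = 20 000 MPa, ν = 0.30; dentine E = 21 000 MPa, ν = 0.31; enamel
E = 80 000 MPa, ν = 0.30. These are literature-order placeholder values,
configurable per run; no acceptance-level quantity depends on them.

**Jaw hinge.** Articular plates on the condyle (mandible) and cotyle
(cranium) are connected, per side, to a node on the joint axis by a rigid
spider plus a fine beam network tessellating the plate (the distributed
attachment avoids the stress singularity of a single-node pivot — a paired
solve in the test suite confirms the peak plate stress ordering). The two
coincident axis nodes per side are coupled by an exact revolute joint:
translations and the two off-axis rotations tied, rotation about the joint
axis free. Axle beams along the axis couple the left and right sides of
each body, so exactly one zero-energy mode remains with the jaw otherwise
unloaded: rigid jaw rotation about the hinge.

**Tooth attachment.** Canine roots are rigid-linked to a palate anchor node
("attached using rigid links"); short stiff beams from that anchor into the
surrounding cranial bone supply the rotational stiffness a single-point
spider lacks (without them a tooth could spin rigidly about its anchor).

**Supports and bite force.** Bite solves constrain the occipital-condyle
region (translations, over a surface patch wide enough never to degenerate
to a collinear node line) and the tips of each canine, upper and lower.
Two bite-force measures are reported:

* *adductor-driven* (jaw-muscle) bites: the working lever is the mandible,
  so the bite force is the component of the mandibular bite-point reactions
  perpendicular to the hinge-to-bite-point lever arm — the force available
  to drive the teeth into prey. The raw reaction magnitude would be
  contaminated by compression along the lever, which grows sharply as the
  bite point swings beneath the joint at wide gape.
* *head-depressor-driven* bites: the cranium rotates about the occiput and
  the bite force is the resultant reaction at the constrained upper canine
  tips.

Both are linear in the muscle forces, which is what the recruitment
back-calculation exploits: one solve at unit muscle forces, then
scale = target bite force / unit bite force.

## Muscle systems

**Jaw adductors.** Temporalis and a combined masseter complex, each a fan
of `n_trusses` (default 10) trusses from seeded anchor points on the origin
patch (cranium) to the insertion patch (mandible). Group force defaults to
the dry-skull estimate: the face-on silhouette area of the origin chamber
patch (projected-polygon union, so folded patches are not double-counted)
times a specific tension of 0.3 MPa — known to underestimate true forces
because pennation is ignored. Per-truss force is the group total divided by
the truss count, so the budget is conserved exactly. Anchors are sampled
area-stratified on the left half of each patch and mirrored across the
sagittal plane: bilateral muscles load symmetric models symmetrically
(bite-reaction asymmetry below 1 % in the tests). An optional via-point per
group ("hinge" in the muscle line of action) is a free intermediate node
joining two truss segments.

**Head depressors.** M. sternomastoideus (40 trusses) and M. obliquus
capitis (30 trusses), each truss at 25 N pretension — a 1 750 N scalar
budget. They run from mirrored mastoid-region anchors to the rims of two
attachment webs placed caudal to the occiput at half a skull length
(configurable): a circle (normal along x) and an ellipse (normal along y),
mutually perpendicular, dimensions per model (the demo profiles use
ellipse 40×26 / 36×25 / 30×20 mm and circle radius 30 / 26 / 23 mm). Web
rims are rigid-linked to a centre node fixed in all six DOFs; rim angles are
offset by half a step so the rim is mirror-symmetric with no midline point,
letting anchors and rim points pair bilaterally.

## Maximum-gape estimation

1. **Cartilage.** The articular facet surfaces are offset by
   `cartilage_mm` (default 1 mm, a median carnivoran articular value) along
   area-weighted vertex normals.
2. **Seating.** The mandible cartilage is registered onto the cranium
   cartilage by point-to-plane, translation-only ICP, then backed off along
   the mean articular normal until the layers just touch. Translation-only
   is deliberate: the rotational freedom of a condyle in its fossa *is* the
   hinge DOF, which the search explores separately, and the minimal-norm
   point-to-plane update has no tangential drift on flat-on-flat contact
   (where sliding is unobservable). The classic full-rigid ICP
   (`icp_register`) is exposed separately and validated against planted
   transforms.
3. **Axis.** Cartilage points with signed gap ≤ 0.05 mm are the contact
   set; their area centroids per side define the rotation axis.
4. **Bone contact.** The mandible surface (minus the cartilage-covered
   facet plus a 1 mm collar — covered bone cannot make bone contact) is
   swept about the axis by a Lipschitz-bounded march: a sample at radius ρ
   from the axis moves at most ρ·π/180 mm per degree, so stepping by
   0.8·min(d/rate) can never skip the first touch; the march terminates at
   0.01° resolution when the minimum unsigned surface distance falls below
   a touch threshold (0.25 × the contact tolerance). First-touch detection
   needs no signed distance, which proved fragile at grazing corner
   features of graded meshes.
5. **Back-off.** `backoff_deg` (default 2°, an explicit, arbitrary
   soft-tissue allowance) is subtracted; the result is reported through the
   2-D gape metric, the interior angle upper mesial incisor – jaw joint –
   lower mesial incisor, measured in 3-D on the landmark triplet.

## Canine arc-centre geometry

The distal margin of the upper canine is fit with a geometric least-squares
circle (algebraic Kåsa initialisation, Levenberg–Marquardt refinement;
order-invariant; collinear input rejected). The arc-centre ratio is
d/(d + r) where d is the fulcrum-to-centre distance and the far intersection
of the fulcrum→centre ray with the circle lies at d + r: 0 when the fulcrum
is the centre, 0.5 when the fulcrum lies on the circle. Radius recovery
from noisy short arcs is statistically hard: with 0.5 mm noise on a
60° arc the median radius error across noise realisations is above 1 mm
(a Cramér–Rao limitation, not an implementation one); on a 120° arc it is
comfortably below 1 mm, and the acceptance checks use that regime.

## Synthetic skulls

The generator builds stylised, non-anatomical geometry whose purpose is to
*plant recoverable ground truth*:

* wedge cranium and bar mandible as lateral-profile polygons extruded along
  the mediolateral axis (prism-split tet meshing with adaptive boundary
  seeding so thin features cannot pinch); conical canines (Delaunay-meshed,
  dentine core + enamel crown shell) mirrored exactly across the midline;
* the canine distal-margin points lie *exactly* on a circle whose centre
  sits at the configured fraction (default 0.17; 0.33 for the
  sparassodont-type profile) of the fulcrum-to-circumference distance;
* the articulation is a small condylar knob (radius 1 mm by default)
  resting on a cranial shelf with a bone-bone clearance of
  `cotyle_clearance` (default 2 mm = 2 × cartilage), so the cartilage
  layers touch exactly at the rest pose and the contact-derived axis
  coincides with the analytic touch line;
* the maximum gape is planted by an angular-process stop: the requested
  bone-contact gape angle is converted to a jaw rotation by a root solve of
  the exact gape metric, and the process apex is placed by back-rotating
  the planted contact point about the touch-line axis. The knob is kept
  small and the ramus bulged so that nothing else contacts first across
  the buildable range (roughly 15–105° of planted rotation);
* element budgets are met by calibrating the target edge length against
  the requested tet count (within ±20 % at the 5 000-element demo size;
  small budgets are floored by the fixed canine and thin-feature meshes).

What the generator does **not** emulate: real cranial curvature and
cross-sectional variation, trabecular bone, sutures, periodontal ligament,
tooth-row occlusion, condylar translation, or realistic muscle wrapping.
Passing tests therefore demonstrate that the *pipeline* (meshing, solving,
registration, contact search, scaling arithmetic) is correct and
deterministic — not that the stylised skulls predict stresses in real
crania. Absolute stress and force magnitudes on the synthetic models are
not comparable to published specimen values; ratios, scalings and planted
recoveries are the meaningful outputs.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `skull_length` | 300 | mm | overall scale; all profile dims proportional |
| `body_mass` | 259 | kg | allometric scaling input only |
| `canine_arc_ratio` | 0.17 | – | planted arc-centre fraction |
| `bone_contact_gape_deg` | 90 | deg | planted maximum-gape ground truth |
| `condyle_radius` | 1.0 | mm | knob size; rolling clearance margin |
| `cotyle_clearance` | 2.0 | mm | joint bone gap; gape is monotone in it |
| `cartilage_mm` | 1.0 | mm | articular offset thickness |
| `target_tets` | 5000 | – | element budget (±20 %) |
| specific tension | 0.3 | MPa | dry-skull force per unit area |
| depressor pretension | 25 | N | per-truss muscle force |
| `backoff_deg` | 2.0 | deg | soft-tissue gape allowance (arbitrary) |
| scaling exponent | 2/3 | – | bite-force allometry |

Problem sizes used by the shipped tests and the acceptance script —
2 000–5 000 tets per skull, 10 trusses per adductor group, 15–20 noise
realisations for the statistical checks — were chosen as the smallest sizes
at which every planted quantity is recovered within its stated tolerance;
all are configurable upward.

## Numerical choices and degenerate inputs

* Contact tolerance 0.05 mm and 0.01° angular resolution: below the mesh
  feature scale, above floating-point noise.
* Surface distance queries stratify candidate triangles by size octave,
  because a cluster of tiny corner triangles would otherwise crowd the
  k-nearest-centroid candidate set and hide the true nearest large face.
* Point-in-solid checks (used only to verify borderline signed distances)
  ray-cast along three skew directions with majority vote, to survive rays
  grazing shared edges of the semi-regular extrusion meshes.
* Zero-length trusses, collinear circle-fit input, empty regions or
  patches, under-constrained models, non-tet VTK cells, and unknown config
  keys all fail fast with structured errors naming the offending entity;
  a missing VTK `region` field degrades to all-bone with a warning.
* Seeds are explicit everywhere (generator, anchor sampling, noise); there
  is no hidden global random state, and rerunning any stage with the same
  config and seed is byte-identical.

## Known limitations

* tet4 bending stiffness: absolute deflections converge slowly; the
  comparative quantities (ratios, linear scalings) are insensitive to this.
* The revolute hinge is pure rotation — no condylar translation — matching
  the modelled joint, not real TMJ kinematics.
* Ligament, capsule and muscle-stretch limits on gape are not modelled; the
  bone-contact angle minus a fixed back-off is an upper-bound style
  estimate.
* The dry-skull default underestimates muscle force (no pennation
  correction), and holding tension constant with gape overestimates
  performance at wide gape; both biases are inherited deliberately.
* Published gape angles and absolute bite forces of the original specimens depend
  on their CT meshes and are not reproducible here; only the published
  arithmetic (allometric transfers, budgets, ratio blocks) is checked
  exactly.
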