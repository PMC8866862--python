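# Methods

## Scope and model

`mandifix` evaluates the primary (immediately post-operative) mechanical
stability of mandibular fracture fixation with miniplates made of titanium
alloy Ti-6Al-4V, magnesium alloy WE43, or polylactic acid (PLA), at two plate
thicknesses (1.0 and 1.5 mm), for four fracture sites (symphysis, body,
angle, condylar neck).  The quantities of interest are

* the dominant principal strain inside the fracture gap ("healing region"),
  the mechanobiological driver of early bone healing — strains below roughly
  15 % magnitude are considered compatible with bone formation, and
* the peak von Mises stress in plates and screws relative to the material's
  yield strength (880 / 162 / 70 MPa for Ti-6Al-4V / WE43 / PLA), the
  implant-failure criterion.

Everything is linear-elastic and quasi-static.  No contact, no screw
threads, no material degradation over healing time, no viscoelasticity: the
model asks how stiff each fixation construct is at time zero, not how it
evolves.

## Synthetic mandible

No patient geometry ships with the package; the mandible is a parametric,
desk-scale stand-in generated by `geometry.build_mandible`:

* a rectangular cross-section (body_width x body_height = 5.5 x 7 mm by
  default) swept along a circular arch (radius 9 mm, span 220 deg) in the
  transverse plane;
* vertical rami at both posterior ends (height 6 mm) carrying a condylar
  process (neck 3 mm + head 2.5 mm, posterior) and a coronoid process
  (2.5 mm, anterior) separated by a sigmoid notch;
* a cortical shell (elements within 0.95 mm of the free surface, widened to
  half a cell at very coarse resolutions so the outer layer is always
  cortical) subdivided into the six regional orthotropic property zones
  (symphysis / body / angle / ramus / condyle / coronoid process) by bands of
  the sweep parameter; a trabecular core; and a homogeneous teeth block in
  the crest over the central 45 % of the arch.

The solid is meshed by subdividing a chart-aligned structured hex lattice
into six tetrahedra per cell (Freudenthal decomposition, conforming) and
inserting midside nodes, giving straight-edged quadratic tetrahedra (TET10).
Grid lines are aligned to every region-band edge, so region labels never
straddle cells and region volume fractions are stable under refinement.

The dimensions are roughly half scale relative to a human mandible.  This
choice keeps the finest verification mesh (0.5 mm edges, ~470k DOF) solvable
on a single CPU.  The consequence, shared with any non-patient-specific
geometry, is that *absolute* strain and stress magnitudes are not comparable
to patient-derived models; only orderings and patterns across materials,
thicknesses and fracture sites are meaningful, and only those are asserted.

Coordinate frame: X mediolateral (+X = anatomical left, matching the sign
convention of the printed muscle direction cosines, so the right/working
side lies at x < 0), Y anteroposterior (+Y posterior), Z inferosuperior.
Units: mm, N, MPa throughout.

## Fracture model

A fracture is a 1.2 mm slab (configurable 1.0-2.0 mm) of elements around the
site's cut plane relabeled to granulation tissue (E = 3 MPa).  The mesh is
*not* topologically split: load crosses the gap through the soft tissue and
through the fixation hardware, which mirrors how healing-region strain is
defined (strain of the interfragmentary tissue volume).  The angle fracture
plane is restricted below the sigmoid notch so the coronoid process stays on
the posterior fragment; the condylar-neck fracture is a horizontal slab 40 %
up the neck.

## Materials

The packaged table (`data/materials_table1.csv`) holds the six orthotropic
cortical region cards (direction 1 longitudinal, 2 tangential, 3
transverse), isotropic trabecular bone (E = 300 MPa), teeth (17600 MPa),
granulation tissue (3 MPa), and the three device materials.  Minor Poisson
ratios follow from compliance symmetry (nu_ji = nu_ij Ej / Ei); every
stiffness build checks the compliance for symmetric positive definiteness.
Where the table prints a shear modulus it is used verbatim (granulation's
G = 1 MPa differs slightly from E/(2(1+nu)) ~ 1.07 MPa; WE43's printed
17000 MPa from ~17400 MPa); where it prints none (trabecular bone) the
isotropic relation supplies it.

Voigt order is (11, 22, 33, 12, 13, 23) with engineering shear strains.
Cortical stiffnesses are rotated per element into the local anatomical frame
(e1 along the arch tangent in the body, vertical in the ramus and processes;
e3 transverse/outward) via the plain fourth-order tensor rotation, which in
this convention equals the Bond transformation.

## Fixation devices

Miniplate configurations per site: two parallel 4-hole plates (symphysis,
body), one 6-hole plate (angle), one 2-hole plus one 4-hole plate with
center space (condylar neck).  Devices are scaled to the desk-scale
mandible: hole pitch 2.4 mm (1.8 at the angle, 1.6 at the neck), width
1.6 mm, screw shanks 0.8 mm across and 2.0 mm long — monocortical in
proportion (longer than the cortical shell, shorter than the section
half-width), since a literal 7 mm screw cannot fit this geometry.

Plates are generated directly in a surface chart (position along the plate
axis, position across the width, outward surface offset) so they wrap the
bone curvature.  Plate midsurfaces sit 0.75 mm above the bone surface for
*both* thicknesses, so the 1.0 and 1.5 mm variants overlap exactly and share
identical screw positions; the 1.0 mm plate's 0.25 mm stand-off is bridged
by the screw shanks.  Screws are fused into the plate (one conforming device
mesh), which realizes the plate-screw bond exactly; plate holes are
therefore not cut (each hole is occupied by its screw head).  The screw-bone
interface is a tie: every screw node at or below the bone surface is a slave
whose displacement equals the TET10 shape-function interpolation inside its
containing bone element (multipoint constraints eliminated through a
reduction matrix, not penalties — no tunable stiffness, and rigid-body
motion transmits force-free because interpolation weights sum to one).  The
bone mesh is not cut by the screws; the screw volume overlaps the bone
volume, an embedded-reinforcement simplification consistent with the
no-relative-motion bond.

## Loads and boundary conditions

Right unilateral clenching.  Seven muscle groups act per side
(`data/muscles_table2.csv`): superficial/deep masseter, anterior/medial/
posterior temporalis, medial pterygoid, inferior lateral pterygoid.  Each
patch resultant is scale x max_force x activation x direction cosines, with
scale = 0.2 by default (post-operative force reduction), working-side
activations on the right, balancing-side on the left, and only the X cosine
flipping sign between sides.  Resultants become consistent nodal loads of a
uniform traction on the quadratic boundary triangles (corner nodes carry
zero, midside nodes A/3 each — the classical consistent load vector).

Attachment patches are chart bands on the boundary: masseter on the lateral
angle/ramus, medial pterygoid medially, temporalis heads on the coronoid
process and notch, lateral pterygoid antero-medially under the condylar
head.  Both condylar head surfaces are fixed in all three translations
(continuum elements have no rotational DOFs; fixing the finite patch also
suppresses condylar rotation), and the occlusal patch over the right first
molar / second premolar is restrained vertically; its vertical reaction is
reported as the bite force.

## FE core and solvers

TET10 stiffness uses the 4-point Gauss rule, exact for the linear-strain
integrand of straight-edged quadratic tets; integration-point strain/stress
fields are evaluated at those four points.  Assembly is vectorized and
chunked (10k elements) to bound memory.  After tie elimination and
Dirichlet application the system is solved

* directly (sparse LU) below 25k free DOFs,
* otherwise by BiCGStab preconditioned with an incomplete LU of the
  symmetrically Jacobi-scaled matrix (drop tolerance 3e-3, fill factor 4;
  a stronger factorization is retried on breakdown).  The scaling is what
  makes the ILU effective across the ~10^4 stiffness contrast between
  granulation tissue and titanium.

Every solve enforces a relative residual below 1e-9 and global equilibrium
(sum of reactions + applied loads) below 1e-6 N.  All steps are
deterministic for a fixed mesh; the `seed` parameter is stored in manifests
but no stage of the default pipeline is stochastic.

## Verification

* Patch test: prescribed linear displacement fields reproduce constant
  strain to machine precision for all twelve material cards.
* Element stiffness matches an independent 11-point (degree-4) quadrature.
* A slender cantilever (L/h = 10) matches the Euler-Bernoulli tip deflection
  within 2 % (shear correction ~0.8 % at this aspect ratio).
* Mirror test: reflecting geometry and loads reflects the solution.
* Mesh convergence: with simplified isotropic bone (cortical 15000 MPa,
  trabecular 300 MPa, nu = 0.3) and the simplified masseter patch load
  (0, -50, +50) N — patch radius 2.5 mm, scaled to this geometry — the
  symphysis-region volume-averaged von Mises stress changes by ~1.2 %
  between 1.0 mm and 0.5 mm edge meshes, well under the 5 % acceptance
  threshold, so the 1.0 mm mesh is the working resolution.

## Statistics and reporting

Healing-region points are split by the sign of the dominant principal strain
(ties count as tensile); each subset is summarized by min/Q1/median/Q3/max
of the magnitude in percent, quartiles unweighted over integration points
(a volume-weighted variant exists behind a flag).  Device peak von Mises
excludes the top 0.1 % of integration-point values (constraint
singularities) and averages the 10 highest remaining values; the yield ratio
divides by the device material's yield strength.

## What the synthetic geometry does and does not show

The generator reproduces the lever-arm layout that drives mandibular
loading: occlusion anterior, muscle attachments and fixed condyles
posterior.  Passing tests therefore demonstrate the *relative* mechanics the
study design probes — softer devices admit more interfragmentary strain
(PLA > WE43 >= Ti), posterior fractures (angle, condylar neck) strain more
than anterior ones, plate thickness matters less than plate material, and no
device approaches yield at 20 % loading.  They do not validate absolute
strain or stress levels in a human mandible, tooth-level occlusal mechanics,
screw-thread load transfer, or behavior under full (100 %) bite forces.

## Known limitations

* Staircase geometry at band boundaries (structured lattice); mesh quality
  is reported (min scaled Jacobian ~0.4 at 1 mm) but boundary normals are
  axis-quantized at coarse resolutions.
* Tie slaves near the fracture can land in granulation elements at coarse
  resolution, locally softening the screw anchorage.
* Muscle patch areas quantize with the mesh; resultants are exact but their
  distribution footprint varies slightly across resolutions.
* The iterative solver's ILU preconditioner is deterministic but its cost
  grows quickly below 0.5 mm edges; sub-0.5 mm studies need a stronger
  (multigrid) preconditioner than this package ships.
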