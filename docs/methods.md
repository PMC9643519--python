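# Methods

## Problem and reference configuration

The package simulates the quasi-static mechanics of optic-nerve (ON)
tethering during ocular adduction.  The stress-free reference is the
26 deg-adducted pose at which the ON has just straightened: the globe is a
24 mm sphere at the origin, the ON runs along +z from the optic disc to
the orbital apex at z = 41 mm, +x is nasal and +y superior.  ON pretension
in the reference pose is taken as zero, so every reported load is the
effect of the additional 6 deg of adduction and of the applied pressures.
The forcing is a rigid rotation of the anterior scleral zone about the +y
axis through the globe centre (carrying the cornea nasally); the posterior
ends of ON and sheath are fully fixed at the apex; hemi-symmetry about the
horizontal plane is assumed.

## Constitutive models

All connective tissues use the isotropic reduced-polynomial family
U = sum C_i0 (I1bar - 3)^i + sum (1/D_i)(J - 1)^(2i) (order up to 6) with
the published regional coefficient set shipped verbatim in
`ontether/data/material_cards.csv`; the C30..C60 columns carry their
printed x1e3 display scaling and are rescaled on load.  Four regions
(posterior sclera, peripapillary sclera, ON sheath, ON connective tissue)
have average / stiff (95th percentile) / compliant (5th percentile)
levels; anterior sclera, equatorial sclera, and the lamina cribrosa (LC)
have average cards only; ON neural tissue is linear elastic
(E = 1.195 kPa, nu = 0.48) and runs through the same finite-strain code
path as an equivalent neo-Hookean card.

Cards without a volumetric coefficient are treated as nearly
incompressible with a penalty bulk modulus kappa = 1000 mu
(mu = 2 C10); cards with D1 use kappa = 2/D1, which for this coefficient
set corresponds to nu ~ 0.48 throughout.

Stress and tangent are exact analytic derivatives (second Piola-Kirchhoff
S = 2 dU/dC and the minor-symmetric material tangent 2 dS/dC), verified in
the test suite against finite differences of the energy and of the stress
for every card.

**Extrapolation safeguard.**  Percentile polynomial fits are reliable only
over the tested strain range; the 5th-percentile peripapillary card turns
non-monotone beyond ~12% strain (its uniaxial nominal stress peaks near
27 kPa and then falls, eventually becoming compressive at tensile
stretches), which is a fitting artifact, not tissue behaviour.  Scenario
runs therefore floor the deviatoric hardening dW/dI1bar at a smooth
minimum of 0.2 C10 (`SCENARIO_HARDENING_FLOOR`): the response is exactly
the published polynomial wherever the polynomial hardening exceeds the
floor — in particular over the whole fitted range — and merely stays
monotone-tensile beyond it.  The constitutive API itself never applies the
floor unless asked.

## ON composite

The ON interior is a composite of connective matrix and neural-tissue
channels in the histologically observed 9:16 area ratio (connective
fraction f = 9/25).  The rule of mixtures
E_ON = f E_conn + (1 - f) E_neural is implemented both forward (Voigt
homogenization of the ON interior for the 2-D mode, applied to the full
energy, which reduces to the modulus rule at small strain) and inverted
(recovering E_conn from a measured whole-ON modulus).  In 3-D mode the ON
interior is partitioned into prismatic connective and neural cell columns
("honeycomb"): mesh-aligned columns are marked neural in a deterministic
low-discrepancy (golden-ratio) order until the cross-sectional area
fraction reaches 16/25, which intermixes the channels through the cross
section and reproduces the ratio to within one cell at any density.

## Geometry and meshing

All printed anatomical dimensions are fields of `OcularGeometryConfig`
(YAML round trip provided).  Quantities the source leaves unstated are
explicit, documented choices:

* scleral zones: anterior < 60 deg and equatorial 60–120 deg polar angle
  from the corneal pole, posterior the remainder, peripapillary within
  4 mm geodesic of the disc centre;
* canal thinning: shell thickness tapers linearly to 0.5 mm over the 1 mm
  annulus adjacent to the canal;
* the corneal pole is tilted (fovea–disc angle − angle kappa) = 12 deg
  temporally from the −z axis, so the disc sits nasal to the posterior
  pole and the scleral thickness field is nasal/temporal asymmetric;
* the LC is a spherical cap coincident with the shell curvature, its
  inner surface flush with the thinned canal shell; the outer 0.2 mm of
  the canal plug is anterior-most ON tissue;
* the sheath attaches to the scleral surface over the band where its
  anterior annulus meets the sphere and to the apex plane posteriorly;
  the CSF gap is not meshed — its two wetted walls carry the ICP.

Meshes are mapped structured blocks of linear cells merged on shared
interfaces by coordinate deduplication, split into simplices, and elevated
to quadratic elements with one shared mid-edge node, which guarantees
conformity between independently generated blocks.  Geometry is
subparametric (straight-edged quadratic elements); curved boundaries are
resolved by density, with the fine target edge length (default 0.22 mm)
around the optic nerve head and grading toward the far field (1.2 mm arc,
up to 3 mm axially along the ON).  The 3-D mesh revolves the x >= 0 half
section about the ON axis (axis-degenerate cells are split with face/body
centres and zero-volume tetrahedra dropped) and uses the axisymmetric
thickness profile; zone labels still use the tilted pole.

## Loads in the plane-strain mode

The default analysis mode is the horizontal symmetry-plane cross section
under a plane-strain contract.  Two load adaptations compensate for what a
plane section cannot carry:

1. **Membrane equivalence (factor 1/2).**  A plane-strain ring under
   cavity pressure p carries hoop stress pR/t, twice the pR/(2t) of the
   sphere it represents.  Cavity pressures (IOP and ICP) are therefore
   applied at half their nominal value in 2-D mode, reproducing the
   membrane stress state at which the percentile cards operate; without
   this the 5th-percentile peripapillary annulus is loaded past its
   stress peak by normal IOP alone and has no equilibrium.  3-D mode uses
   the printed pressures unmodified.
2. **Sheath wall pressure.**  The sheath tube carries its CSF wall
   pressure by hoop stress (deflection ~5 um); a plane-strain strip has no
   hoop path and would balloon by millimetres.  In 2-D the ICP loads the
   ON lateral wall (the soft ON transmits CSF pressure to the retrolaminar
   tissue, preserving the translaminar gradient across the LC) and the
   anterior scleral cap of the CSF space, but not the sheath inner wall;
   3-D mode loads all three surfaces.

## Solution procedure

Full Newton on the total-Lagrangian residual with consistent material,
geometric, and follower-pressure stiffness; sparse LU for the linear
solves; slider (normal-displacement) constraints via per-node frame
rotation.  Defaults: 10 equal increments to the final angle with pressures
ramped within the first increment, relative residual tolerance 1e-8, at
most 25 iterations per increment.  Robustness machinery, all deterministic:

* a rigid-rotation predictor that starts each increment from the previous
  state rotated by the increment angle (tapered to zero along the ON so
  the apex stays fixed);
* nonmonotone backtracking line search (transient residual growth is a
  normal part of a healthy Newton path with stiff polynomial materials);
* automatic bisection of non-converging increments;
* Levenberg-style damping and proximal continuation across snap-through
  of softening material branches;
* a flagged stagnation acceptance at relative residual 1e-4 (about 50x
  tighter than the increment acceptance of common commercial implicit
  codes) when localization micro-branching in a softening region blocks
  the final Newton digits; accepted increments are marked in the
  convergence log.

Reported strain is the logarithmic (true) strain tensor ("principal
strain" = largest eigenvalue); stress is the Cauchy von Mises equivalent.

## Reported summaries

Local values follow the study's reduction rule: the mean over k = 14
(configurable 12–16) face-contiguous elements of the region of interest
nearest a named landmark, each element carrying its quadrature average.
Landmarks sit on the symmetry plane: the temporal and nasal canal rim at
the LC outer band (disc / ON junction), the temporal peripapillary
surface, the temporal sheath attachment, a point 1 mm behind the LC
(retrolaminar ON), and the mid sheath.  The LC edge displacement is
reported in the globe-fixed (co-rotating) frame — the deformed position is
rotated back by the applied adduction before differencing — because that
is what cross-section overlays anchored to the rigid anterior sclera and
eye-fixed clinical imaging measure; the laboratory-frame value is also
retained.  Mesh-convergence summaries use the volume-weighted mean (and
the max) of von Mises stress, which unlike the raw per-element mean does
not change when refinement subdivides elements unevenly.

## What the surrogate does and does not reproduce

The generator defaults are the study conditions: 6 deg incremental
adduction, IOP 15 / ICP 10 mmHg (40 / 4 mmHg extreme), the printed
geometry, and the published material levels.  At those conditions the 2-D
model reproduces: the LC edge moving nasally and posteriorly relative to
the globe in every tethering case with magnitudes in the published range
(hundreds of um); the sheath-insertion stress orderings across the
posterior-sclera halves of the sensitivity matrix; the retrolaminar-strain
orderings across sheath stiffness; the pressure-scenario ordering
(tethering at extreme pressures exceeds tethering at normal pressures);
and stable mesh convergence.

Known limitation: in a plane section the scleral ring is bending-soft
in-plane, so the tether reaction spreads around the posterior globe
instead of concentrating at the disc as it does in a membrane-stiff 3-D
shell.  The disc-junction summaries are consequently pressure-dominated,
and orderings that hinge on tether dominance right at the junction — the
temporal-vs-nasal asymmetry of the average case, the compliant-sheath
reroute of stress to the junction, the ON-stiffness sweep at the disc, and
the additivity of pressure and tether effects there — are not reproduced
in 2-D; the corresponding acceptance tests are left failing deliberately
and the effect is analyzed rather than patched.  Absolute summary
magnitudes are also smaller than a fine 3-D model's because a 14-element
patch on the default mesh averages over a larger area around the
concentrations.  The synthetic geometry further omits orbital fat,
extraocular muscles, globe translation, viscoelasticity, and anisotropy,
so passing tests demonstrate the mechanics of the idealized quasi-static
model, not a patient-specific prediction.
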