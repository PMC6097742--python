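# Methods

`vpatch` simulates patch angioplasty of a stenosed great artery — the
repair used, for example, to relieve main-pulmonary-artery (MPA) stenosis
in Tetralogy-of-Fallot surgery — as a sequence of quasi-static shell
mechanics problems, and evaluates the reconstruction with the
biomechanical and hemodynamic indices surgeons care about: residual
percent stenosis, patch area, wall/patch stress levels, suture-line
stress mismatch, centerline tortuosity, and a reduced-order Reynolds /
pressure-drop characterization of the lumen.

## Idealized vessel

The vessel is a straight tube of inner diameter D = 18 mm with a 1 mm
uniform wall (dimensions of a 9-year-old child's MPA), carrying an
axisymmetric area stenosis.  The lumen radius follows

    r(z) = r0 * sqrt(1 - s * w(z)),     w(z) = (1 + cos(2*pi*(z - z_c)/L))/2

inside the stenosed span of length L (default 50 mm, centered on a
100 mm segment) and r0 outside, so the throat lumen area is exactly
(1 - s) times the healthy area; s is the area-stenosis fraction (0.70 and
0.80 are the studied levels).  The cosine bump is a modeling choice — smooth,
symmetric, and qualitatively faithful to imaging reconstructions of
symmetric MPA stenoses.  The finite-element mesh is a structured
triangulation of the wall mid-surface (lumen radius + half thickness),
with diagonals flipped across both symmetry planes so the mesh itself is
mirror-symmetric, and a node column at azimuth 0 (and pi) so axial
incisions trace exactly along mesh lines.

## Shell finite elements

Flat 3-node shell, 6 DOF/node: constant-strain membrane + discrete-
Kirchhoff (DKT) bending, with a small artificial drilling stiffness
(1e-6 of the element diagonal).  The DKT stiffness is built directly from
the element definition (quadratic rotation interpolation with discrete
Kirchhoff constraints on the edges), which reproduces uniform-curvature
plate states exactly; the implementation is verified against the
simply-supported-plate series solution and the thin-wall tube closed
forms (hoop stress p·r/t, radial expansion p·r²/(E·t), both within a few
tenths of a percent at 2 mm meshes).

Moderate rotations (the opened slit lips rotate by tens of degrees) are
handled corotationally: each element stores its own flat reference
configuration and a co-moving frame filters rigid motion; nodal
orientations are rotation triads updated multiplicatively.  Because the
reference is per-element, a stress-free patch built in the opened
(deformed) configuration and a pre-stressed artery coexist in one model
after suturing.

The Newton tangent is the exact consistent element Jacobian obtained by
finite-differencing the corotational element force (19 vectorized force
evaluations per assembly), plus the follower-pressure load stiffness.
This matters: with the classical "rotated material stiffness" shortcut
the bending-dominated lip rotations stall the iteration irrecoverably.
Convergence tolerance is 1e-6 on the relative force residual; load
stages are ramped with automatic increment halving (floor 1/64), and a
Levenberg–Marquardt shift is applied on rejected steps near indefinite
(wrinkling) states.  Lumen pressure is a follower load re-evaluated every
iteration; edge tractions are followers whose direction is recomputed at
each load increment.

Materials are isotropic linear elastic (the constitutive model measured
for the patch fabrics and adopted for the nearly incompressible arterial
wall): Young's modulus, Poisson ratio and thickness per material, SI
units internally.  Mid-surface membrane von Mises stress is the reported
equivalent stress.

## The virtual surgery sequence

1. **Residual prestress.**  Arterial residual stress is represented by
   the pressure-equivalent technique: 5 mmHg applied to the intact,
   unloaded tube.  During the bypassed (zero lumen pressure) surgical
   stages this load is kept as a *dead* nodal force frozen at the
   pre-incision state.  Holding it as a live follower pressure on cut
   lips is ill-posed: the pressure moment on a freed lip exceeds the
   bending capacity of this very soft wall (p·R²/D is of order 1/R) and
   the lips evert without bound.
2. **Incision.**  The ideal straight or helical (5° oblique) cut curve is
   snapped to mesh nodes and converted to a zero-gap slit by duplicating
   interior path nodes; the slit edges become free boundaries.  Cutting
   transfers the solver state (duplicates inherit their source state).
3. **Slit release.**  The forces the cut connection used to carry are
   ramped away ("holding-force" continuation); the slit opens by
   releasing the stored residual stress.
4. **Controlled opening.**  The surgeon's pull is modeled as
   equal-and-opposite hold forces at every pair of opposing slit-edge
   nodes, directed normal to the cut faces and recomputed each
   increment.  The force magnitudes are load unknowns; the pair
   separations are constrained to a parabolic lens profile ramped until
   the mid-slit width reaches the prescribed slit stretch (16 mm).  A
   uniform-traction ramp has no stable path to 16 mm (measured: the gap
   runs away near tau ~ 1–2 N/m — a snap), and single-point control lets
   other lip sections snap; constraining the whole lens is the
   numerically sound formulation of "the gap is precisely controlled
   intra-operatively".  The reported traction magnitude is the mean hold
   force per unit edge length.  If even pair control snaps (double cuts
   free two strips whose common-mode flap is unconstrained), the ramp
   finishes with prescribed lip positions (Dirichlet), splitting each
   pair symmetrically about its floating midpoint.  The lip snap is a
   symmetry-breaking bifurcation: the converged lens can sit on a
   laterally shifted branch while its width profile stays symmetric.
5. **Tangent patch.**  Each transverse section of the patch is a cubic
   Hermite curve between opposing lip nodes whose end tangents continue
   the deformed artery surface (magnitude equal to the chord — the cubic
   that best continues a circular arc), producing the cambered "tangent
   patch".  Boundary vertices coincide exactly with the slit-edge nodes.
   Patch elements carry the patch material and thickness and are born
   stress-free in the opened configuration.
6. **Suture.**  A bonded connection: patch boundary nodes are merged with
   the artery edge nodes (shared 6-DOF), tagged as the suture line.  No
   stitch-scale mechanics.
7. **Post-operative pressurization.**  Lumen pressure ramps 0 → 25 (or
   45) mmHg as a follower load on artery and patch while the opening hold
   forces ramp to zero.  The patched vessel has a structural limit point
   near 31 mmHg (the curled suture lips unroll); above it the ramp
   switches to volume-driven continuation (enclosed volume as the control
   parameter, pressure as the unknown), which follows the equilibrium
   path through the fold.  Post-snap states can exhibit mesh-scale
   wrinkle chatter that pins the Newton residual near 1e-4; such path
   states are accepted only where explicitly allowed and the final
   state's achieved residual is reported (`FemState.final_residual`,
   with `converged` truthful).

## Performance indices

The centerline is extracted by iterative plane slicing: slice normal to
the current axis estimate, take section-contour centroids, refit a
smoothing spline, repeat.  Section areas (shoelace on the contour
polygon) are converted from mid-surface to lumen by shrinking the
equivalent radius by half the wall thickness.  Local percent stenosis is
100·(1 − A(s)/A_ref) with A_ref the *healthy reference section under the
same loading* (closed form r0 + p·r_mid²/(E·t) for the pressurized
post-op state; the unloaded healthy area pre-op).  Normalizing by the
healthy reference — rather than by the post-op model's own maximum
section — is what makes locally dilated (bulging) sections report
*negative* stenosis for sections dilated beyond the healthy
caliber; a profile with
no reference supplied falls back to its own maximum.  Residual stenosis
is the profile maximum (the throat); tortuosity is the centerline's
distance from the initial vessel axis at the throat.  Stress summaries
are max/area-weighted-mean von Mises per region; the suture-line stress
jump is the largest per-node difference between adjacent patch-side and
artery-side element stresses.

Hemodynamics is deliberately reduced-order (a ranking tool, not CFD):
Re(s) = rho·Q·D_eq/(mu·A) along the profile, and a pressure-drop estimate
composed of an integrated Poiseuille term plus a turbulent constriction
loss (coefficient 1.52) at the throat.  Blood properties default to
rho = 1060 kg/m³, mu = 3.5 mPa·s — standard literature values for
blood, which also reproduce the reference pre-operative peak Reynolds
number of 2607 at 4 L/min; both are configurable.

## Biaxial property extraction

The plane-stress law is linear in a = E/(1−nu²), b = nu·a, so (E, nu)
follow from an ordinary least-squares fit of both stress channels over
the arterial operating strain window (default 0–15%).  The synthetic
test generator reproduces the measurement protocol — sinusoidal
stretching of a 10 × 10 mm square to 20% strain on both axes — with a
phase offset between the axes, without which E and nu are not separately
identifiable (strictly proportional paths determine only E/(1−nu); the
fit warns and reports that combination).  Multiplicative Gaussian noise
is optional and seeded.

## Study sizes, tolerances and limitations

* **Mesh.**  The bundled scenario cases run at a 2.5 mm shell-mesh edge
  (ordering-only comparisons at 3.0 mm; unit oracles at 3–5 mm).  The
  reference computations behind the benchmark values used a 0.1 mm
  commercial-solver mesh; comparisons against them are scaled-down
  reproductions.  Measured
  target quantities move by ~1 stenosis point and ~1% patch area between
  2.0 and 3.0 mm.  Section areas carry the faceting deficit of the
  coarse mesh (~1.5% at 2.5 mm), which biases residual stenosis up by
  roughly one point.
* **What the generator emulates.**  An idealized axisymmetric stenosis
  with uniform wall and linear-elastic tissue.  Real vessels are
  tapered, curved, anisotropic, layered and surrounded by tissue;
  passing tests show the pipeline's internal consistency and its
  agreement with closed forms and printed summary values at desk scale,
  not patient-level prediction.
* **Known deviations from the reference results** (each kept red in
  the acceptance checks rather than tuned away):
  residual stenosis is insensitive to cut length here (the throat
  section is capped by the near-inextensible perimeter once the 16 mm
  lens is fixed), so the longer-cut case does not improve on the
  baseline; the double patches come out only slightly flatter than the
  single patch, overshooting the reported total-area increase; beyond
  the ~31 mmHg limit point the 45 mmHg equilibrium has a bulged,
  more-stenosed throat instead of the reported monotone improvement;
  and with mid-surface membrane stresses the suture-line jump ordering
  between PTFE and porcine xenopericardium inverts.
* **Numerical choices.**  Newton tolerance 1e-6 (relative); FD tangent
  steps 1e-6·element-size (translations) and 1e-7 rad (rotations);
  drilling stabilization 1e-6; default 6–10 increments per stage with
  halving to 1/64; volume-continuation steps of 0.5% enclosed volume;
  gap control tolerance 1% of the target width.  Degenerate inputs
  (zero-length cuts, unknown materials, paths touching the end rings,
  pinched lumen sections) raise typed errors naming the violation.
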