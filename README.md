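# vpatch — virtual patch angioplasty for stenosed great arteries

Surgeons relieving a main-pulmonary-artery (MPA) stenosis — the typical
situation in Tetralogy-of-Fallot repair — incise the narrowed segment,
pull the slit open, and suture in a patch of PTFE, Dacron or pericardium.
How long to cut, how wide to stretch, which material to use and how the
reconstruction behaves once the heart re-pressurizes the vessel are all
decided today by experience.  `vpatch` is a desk-scale planning tool that
executes this operation *in silico* on an idealized pediatric MPA and
reports the quantities that discriminate between strategies: residual
percent stenosis at the throat, patch surface area, arterial and patch
von Mises stress levels, suture-line stress mismatch, centerline
tortuosity, and a reduced-order Reynolds / pressure-drop characterization
of the reconstructed lumen.

The mechanical core is a geometrically nonlinear, corotational thin-shell
finite-element model (3-node flat shells: constant-strain membrane +
discrete-Kirchhoff bending, 6 DOF per node) that walks through the
surgical sequence as quasi-static load stages:

1. pressure-equivalent residual prestress (5 mmHg) on the intact tube;
2. incision → zero-gap slit (node duplication);
3. slit release at zero lumen pressure (bypass);
4. controlled opening of the slit to the prescribed slit stretch
   (hold forces normal to the cut faces, the gap profile driven to a
   16 mm-wide lens);
5. tangent-patch synthesis over the opening (cubic-Hermite sections
   continuing the artery surface) and bonded suturing;
6. post-operative pressurization to 25 or 45 mmHg (follower load), with
   volume-driven continuation through the structural limit point of the
   patched vessel.

The vessel is a tube of inner diameter D = 18 mm, wall 1 mm, with an
axisymmetric area stenosis `r(z) = r0*sqrt(1 - s*w(z))` (cosine bump
`w`), so an s = 0.70 vessel has exactly 30% of the healthy lumen area at
the throat.  Local percent stenosis along the extracted centerline is
`100*(1 - A(s)/A_ref)` against the pressurized healthy reference section,
and the lumen Reynolds profile is `Re(s) = rho*Q*D_eq/(mu*A(s))` with
blood at 1060 kg/m³ and 3.5 mPa·s.  Five measured materials ship in the
library (PTFE, Dacron, human and porcine pericardium, the 9-year-old MPA
wall), and a biaxial-test module recovers (E, nu) from planar
stress–strain records by linear least squares.

See `docs/methods.md` for the full model description, the numerical
choices, and the known desk-scale limitations.

## Worked example

Run the baseline scenario (50 mm straight cut over a 70% stenosis, 16 mm
slit stretch, PTFE patch, 25 mmHg post-operative pressure) at the
standard desk-scale mesh:

```bash
vpatch run --case Baseline --out out/baseline
```

which prints the report (abridged):

```json
{
  "case_name": "Baseline",
  "patch_area_mm2": 585.1,
  "postop_stenosis_pct": 26.1,
  "max_arterial_stress_kpa": 219.4,
  "max_patch_stress_kpa": 55.0,
  "avg_patch_stress_kpa": 33.9,
  "centerline_offset_mm": 10.4,
  "suture_stress_jump_kpa": 195.0,
  "reynolds_max": 1590.0,
  "delta_p_estimate_mmhg": 0.126,
  "preop_stenosis_pct": 69.2,
  "preop_reynolds_max": 2589.0,
  "preop_delta_p_estimate_mmhg": 2.31
}
```

Reading this: the surgery needed a 585 mm² PTFE patch; the 70% stenosis
is reduced to a 26% residual narrowing at the throat; the peak wall
stress (219 kPa) sits on the artery next to the suture line while the
compliant patch stays low-stressed (55 kPa max); the reconstructed
conduit's centerline bows 10 mm toward the patched side; and the peak
lumen Reynolds number drops from ~2600 (pre-op, transitional) to ~1600
with a correspondingly collapsed comparative pressure drop.  `out/...`
receives VTK meshes of the pre-/post-operative states, the area/stenosis
profile table, and the JSON report.

Other entry points: `vpatch matrix --out DIR` runs all ten parametric
scenarios (cut length 40/50/60 mm, oblique cut, double cut + double
patch, 80% stenosis, four patch materials, 45 mmHg) and writes a
combined performance table; `vpatch fit-material --data FILE` extracts
(E, nu) from a biaxial record.  Everything is importable as a library
(`vpatch.run_case`, `vpatch.ShellModel`, ...).

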