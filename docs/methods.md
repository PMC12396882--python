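# Methods

This note records the models, conventions and parameter choices behind
the package, and what the synthetic cohort does and does not emulate.

## Coordinate conventions and the anatomical frame

All coordinates are millimetres in a right-handed canonical frame:
+x anterior, +y superior, +z lateral toward the opened mastoid.
Left-sided specimens are mirrored (z → −z) when a landmark file is read,
so analysis code handles a single handedness; the mirror is undone on
write and the side is kept as metadata.

Every metric is computed in an *intrinsic* frame derived from the
landmarks themselves rather than from the global axes:

- superior = normal of the least-squares tegmen plane, oriented from P
  toward the tegmen;
- anterior = (anterior craniotomy border − posterior SS/dura anchor)
  with the superior component removed, normalized;
- lateral = anterior × superior.

This makes surgical freedom, both exposure angles, the angle of attack
and the presigmoid measures exactly invariant under common rigid
motions of a specimen (a property the test suite asserts to 1e-6
relative).  The frame uses only landmarks that no procedure displaces,
so it is identical across the TL-S/TL-R/TL-C states of one specimen and
cannot leak procedure effects into the cast directions.

Fitted plane normals are oriented to have a positive dot product with
+y when possible, else +x, so signed distances are reproducible.

## Lines of sight and surgical freedom

The six lines from P are operationalized as:

| line | rule | fallback |
| --- | --- | --- |
| 1 | anterior SS border directly lateral to the IAC middle (stored landmark) | — |
| 2 | sinodural angle | clipped to the tegmen plane if the angle lies above it |
| 3 | rim point angularly closest to anterior+superior | — |
| 4 | ray over the antero-lateral IAC, stopped by the facial nerve | craniotomy plane (clamped into the rim polygon) |
| 5 | rim point angularly closest to anterior+inferior | facial nerve, if the segment grazes it first |
| 6 | rim point angularly closest to posterior+inferior | sigmoid sinus, if the segment grazes it first |

Structures are the stored cross-section discs; because a single planar
disc cannot obstruct an out-of-plane ray, the facial nerve and sinus
obstruction volumes are the tubes spanned by their two stored
cross-sections (linear centre and radius interpolation, axis extended a
quarter-length past each end).  Obstruction is found by sampling the
segment and refining the first surface crossing with Brent's method
(tolerance 1e-12 of the segment parameter).

The craniotomy plane is the orthogonal least-squares fit to the rim
points (the original cadaveric workflow fits it interactively in 3D
modelling software; least squares is this package's documented choice).  The six
line–plane intersection points, taken in the anatomical order
posterior → superior → anterior → inferior, form a hexagon summed as
four Heron triangles A=(1,2,4), B=(2,3,4), C=(4,5,6), D=(1,4,6); for a
convex, correctly ordered hexagon this equals the shoelace polygon area
(tested at 1e-6 relative).  Vertex sets B–D complete the fan around the
1–4 diagonal; under a different triangulation only the per-triangle
attribution, not the convex-case total, would change.  Heron's formula is evaluated in the
numerically stable sorted-operand (Kahan) form; triangle-inequality
violations beyond 1e-9 × max side raise an error.  A self-intersecting
hexagon is *flagged* (`convex=False`, with a warning), never rejected:
the reported total is always the four-triangle sum.  Such notches occur
naturally when the sinus's anterior border (line 1, a point landmark)
projects less posteriorly than the tangent-limited lines 2 and 6 on
either side of it.

## Exposure angle

Both bounding lines live in the tegmen-parallel plane through P (IAC
level) or through the jugular-bulb top (bulb level):

- line A: common tangent touching the sinus on its lateral aspect and
  the facial nerve on its medial aspect;
- line B: tangent touching the sinus on its medial aspect and passing
  through the anterior craniotomy border.

A tangent with prescribed sides satisfies `n·(s−o) = ±r_s ∓ r_o` for a
unit normal n; the solution whose normal points laterally touches the
sinus on the stated anatomical side and is unique in realistic
configurations ("most horizontal" is kept only as the tie-break).
Overlapping discs, or an anchor inside a disc, raise a geometry error.

The EA is the wedge at the crossing of the two lines that contains the
deep (medial) instrument direction, i.e. 180° minus the angle between
the two into-field tangent directions.  This convention (a) reduces in
the point-structure limit to 90° for perpendicular anchor rays and to 0°
when the sinus lies between collinear anchors, (b) is monotonically
non-decreasing as the sinus moves posteriorly and the corridor opens,
and (c) produces values in the empirically reported 80–160° range.  A
vertex-fan convention fails (b).  Collapsed (radius-0) cross-sections
are handled by the same formulas: tangents to a point are lines through
it.

The anterior craniotomy border is a single stored landmark at the IAC
level; for the bulb-level EA it is projected into that level's plane.
No EA is attempted superior to the IAC, where the facial nerve enters
the canal.

## Angle of attack

AA is the angle between the ray from P toward the *anterior border* of
the IAC-level sinus cross-section and the distal IAC direction
(middle → most anterolateral point), both projected into the transverse
plane at P.  The ray orientation (P → sinus rather than sinus → P) is
chosen so that obtuse angles mean a more posterior approach is
available and AA increases as the sinus moves posteriorly, matching the
reported direction of the procedure effect.  The anterior border is the
relevant sinus feature here because collapse changes the lumen's
anteroposterior extent far more than its medial/lateral borders.

## Presigmoid window

depth = |P − medial SS border|.  The dural window is a trapezoid:
medial base = orthogonal distance from the jugular-bulb top to the
tegmen plane; lateral base = the stored pair of landmarks marking the
superior and inferior dural extent medial to the vertical sinus (the
lateral base is not computable from the other landmarks, so the schema
stores it explicitly); height = the presigmoid depth.

## Procedure models

**TL-R** (wedge retraction): posterior translation of the IAC-level
sinus landmarks by `wedge_count × wedge_thickness` (default 1.5 mm per
wedge, budget 13 wedges ≈ 20 mm of removable retrosigmoid bone).  The
bulb-level cross-section receives a compliance fraction (default 0.6)
of the displacement — the distal sinus is the least compliant — and the
lumen diameter shrinks multiplicatively (default 10 %/wedge), giving
the patency constraint a mechanism: patent while the diameter stays
above a configurable fraction (default 0.5) of the original.  With
defaults the maximal patent retraction is 6 wedges (9 mm).  These
constants are configuration, not anatomical claims; the displacement is
kinematic, not force-based.  The medial sinus border translates with
the sinus, so the modelled presigmoid depth grows under retraction —
the cadaveric observation that intact dura tethers the depth is *not*
modelled.

**TL-C** (collapse): each cross-section collapses onto its own
posterior border (radius 0), equivalently onto the dural line through
the posterior SS/dura intersection, and the anterior sinus border above
the IAC recedes by the full lumen diameter.  The operation is
idempotent, touches no non-sinus landmark, and by construction never
reduces surgical freedom relative to TL-S.  Vessel-wall thickness is
ignored, which overestimates TL-C exposure by that thickness; no
retro-mobilization of the collapsed sinus is modelled.

## Synthetic cohort

The generator samples latent anatomy and places landmarks consistently
(it is landmark-level, not volumetric, because the metrics consume only
landmarks):

| latent | distribution (defaults) | rationale |
| --- | --- | --- |
| presigmoid depth | truncated N(25, 5.8²) on [15, 38] mm | reported cohort distribution |
| sinus cross-section radius | truncated N(6.5, 0.8²) on [3.5, 9] mm | sets the TL-C displacement (2r); chosen so mean SF ordering TL-C > TL-R > TL-S holds while individual specimens can reverse |
| sinus lateral inclination | truncated N(35°, 7°) on [20°, 52°] | keeps the sinus lateral-posterior of P |
| medial trapezoid base | N(17.5, 2.5²) mm; high-riding bulb N(12.5, 1²) with probability 1/6 | bulb-to-tegmen distance; high-riding bulbs reach the IAC level |
| lateral trapezoid base | N(16, 3²), truncated per-specimen so the implied area lies in [283, 776] mm² | bounded area range without biasing the depth distribution |
| facial-nerve offset | N(4, 1²) mm anterior | corridor's anterior neurovascular limit |
| craniotomy scale | truncated N(1, 0.08²) | specimen-to-specimen mastoidectomy size |

The craniotomy rim is a jittered 16-vertex ellipse on a near-lateral
oblique plane whose position is tied to the anatomy: the plane sits just
lateral to the sinus surface (the mastoid cortex), the posterior rim
edge reaches a few millimetres behind the sinus (the mastoidectomy
exposes it), and the vertical extent spans tegmen to below the bulb.
Constants were chosen once so that baseline SF lands in the observed
250–650 mm² band (realized: mean ≈ 500 mm², range ≈ 270–960) and the
mean percent increases (≈ +36 % TL-R, +51 % TL-C) fall near the reported
values; they were not fitted to any test after the fact.  Joint
distributions (e.g. depth vs sinus size) are independent: no joint
distributional information is available, so independence is assumed
and documented.

Specimens are rejection-sampled for geometric validity (all landmark
invariants, castable lines, positive SF, all angles well inside
(0, 180)), with a 1000-retry cap; everything is reproducible bit-exactly
from the seed, and cohort sides alternate left/right.

`simulate_study` adds per-scan landmark re-measurement noise
(sd 0.15 mm, half a cone-beam CT voxel) to every procedure state,
emulating the re-scan and re-segmentation after each procedure.  The
TL-C state shares the TL-S scan noise because collapse measurements are
refitted inside the TL-S model — which also makes
SF(TL-C) ≥ SF(TL-S) hold record by record, not just in expectation.
TL-R is an independent re-scan.  A `null_effect` mode re-scans the
unmodified anatomy three times; it is the configuration used to verify
that the one-tailed paired *t* keeps its nominal type-I error
(measured rate ≈ 0.05 over 1000 cohorts of n = 10).

What passing tests on this cohort do **not** show about real data: the
generator contains no segmentation bias, no soft-tissue mobility, no
dural tethering of the sinus, no intracranial pressure, and circular
disc cross-sections instead of true lumen shapes; effect sizes are
config-dependent, so only effect *directions* and model *properties*
(monotonicity, dominance, calibration) carry over.

## Statistics

Paired *t* on per-specimen differences (treated − baseline), one-tailed
for exposure metrics against TL-S (retraction can only open the
corridor), two-tailed otherwise and for presigmoid depth; significance
at p < 0.05; no multiple-testing correction (the report carries the
number of tests run).  Specimens missing a procedure are excluded with
a warning, mirroring incomplete-dissection exclusions.  Percent
increases use the sample SD (n−1).  Pearson p-values use the
t-transform with n−2 df.

`required_sample_size` iterates the exact noncentral-*t* power of the
paired design — not a normal approximation — for a standardized effect
`detectable_effect_fraction / assumed_cv`.  The assumed coefficient of
variation of paired differences is a design assumption, not a measured
quantity; the default 0.12 yields n = 8 (one-tailed) / 9 (two-tailed)
at a 15 % detectable change, α = 0.05, power 0.9, and values in
0.125–0.135 yield 8–11.  Historically recommended cohort sizes of 9–10 specimens are
therefore reproducible only under particular variance assumptions, and
the package treats them as illustrative, not as a checked result.

## Numerical choices

- Plane fits: eigendecomposition of the 3×3 scatter matrix; collinearity
  rejected at a 1e-12 relative eigenvalue.
- Line–plane intersection requires |direction · normal| > 1e-12.
- Heron: Kahan sorted-operand form, tolerance 1e-9 × max side.
- Tube obstruction: 96-sample bracketing + Brent refinement.
- Tangent selection: anatomical side first (normal's lateral component
  > 1e-9), most-horizontal tie-break.
- Cohort CSV: floats written as shortest round-trip `repr` and parsed
  with `float_precision="round_trip"`, so file round trips are lossless
  and byte-reproducible across runs.
- The exported surgical-freedom cone is apex + base ring + base
  centroid (8 vertices, 12 faces for the hexagon base), watertight,
  with the base fan reproducing the SF area exactly.

## Known limitations

- The patency criterion and compliance constants are operational
  definitions; "threatened patency" has no standard quantitative
  definition.
- Eggshell fracturing and proximal deskeletonization events during
  retraction are not modelled.
- The EA/AA conventions fix ray orientations that the verbal
  definitions leave open; alternatives would shift absolute angles but
  not the procedure orderings.
- The trapezoidal presigmoid area is an approximation inherited from the
  measurement protocol, not a true dural surface area.
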