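# Methods

## Coordinate frame and tilt model

The pelvic frame is anchored on two structures that are robust to
segmentation noise: the inter-head axis and the anterior pelvic plane
(APP). The x-axis runs from the left to the right femoral head center;
the APP is the plane through both anterior superior iliac spines (ASIS)
and the midpoint of the pubic tubercles — the standard clinical
definition — with its normal signed anterior using the fact that the
femoral heads lie posterior to it. The z-axis is the in-APP direction
perpendicular to x, signed superior (toward the ASIS side of the pubic
midpoint), and y = z × x points anterior, giving a right-handed triad.
Degenerate inputs (collinear APP landmarks, coincident head centers, a
head-center line perpendicular to the APP) raise typed errors rather
than producing silent garbage.

APP tilt is modeled as a rigid rotation of the pelvis about the x-axis
line through the head-center midpoint. The pivot choice makes both
femoral heads fixed points, which matches the physical situation: the
femur holds its default posture (mechanical axis parallel to the
neutral z) while the pelvis rotates around the hip centers. Positive
tilt is anterior — the superior pelvis tips toward +y — the convention
under which ACEA increases with increasing tilt. Poses form a
one-parameter group (composition, inverse, identity), which the test
suite checks to 1e−9.

## Why the cutting planes are fixed in the world frame

The LCEA cutting plane is "parallel to the APP" and the ACEA plane
"parallel to the 65°-rotated APP". A genuine modelling choice hides
here: does the cutting plane follow the pelvis as it tilts, or stay
fixed with the femur/world frame? Both planes are realized **fixed in
the world frame** (normals ŷ and û × ẑ respectively). The reason is a
small theorem: a rotation about the x-axis preserves every point's
x-coordinate, so the most-lateral rim point is the *same material
point* at every tilt angle, and its components along the *tilted*
in-plane axes are rotation invariants — with a pelvis-following plane,
LCEA would be exactly constant in tilt, contradicting both the
closed-form behavior LCEA(φ) = arctan(tan θ / cos φ) of an axisymmetric
cup and the empirical fact that LCEA varies by several degrees across
the tilt range. The fixed-plane reading also matches radiographic
practice, where the imaging plane is fixed in the room and the pelvis
moves. The vertical reference in both planes is the world ẑ (the femur
mechanical axis), which lies in both cutting planes exactly.

A corollary worth stating: for a rigid bony rim, LCEA(φ) =
atan2(a, ρ·cos(φ+δ)) for fixed constants (a, ρ, δ) set by the lateral
material point, which is U-shaped in φ and cannot have an interior
maximum on a ±30° grid. Published cohorts that report an interior LCEA
maximum (near +10°) are measuring the *sclerotic sourcil edge* re-read
on each planar cut, not a fixed bony rim point; reproducing that would
require a subchondral-plate model, which is out of scope here. The
package therefore treats the rim edge as the sourcil edge, and its LCEA
tilt curves are U-shaped with extremes at the grid ends.

## Measurements

**Extremal rim points.** The rim is resampled arc-length-uniformly
(default 3,600 points, ~0.1° azimuthal spacing) and scanned by discrete
argmax; ties are broken toward the more superior point. The error is
bounded by rim curvature × spacing (well under 0.01° in the oracle
comparisons); discrete argmax is robust to the noisy, slightly
non-convex rims real segmentations produce, where a continuous
optimizer could ride a local ripple.

**Signed angles.** The center-to-edge vector is orthogonally projected
into the cutting plane (the head center generally lies slightly off the
plane) and measured against the in-plane vertical with atan2, so edges
medial to the vertical give negative angles — dysplastic configurations
are reported, not clamped to zero. An edge projecting onto the center
raises an undefined-angle error.

**Coverage.** The denominator is the projected superior hemisphere,
π r², with "superior" fixed in the world frame (z ≥ c_z) because the
femur, not the pelvis, defines the horizontal plane. The numerator
region — "covered by the acetabulum" — is the rim-bounded spherical
region containing the cup pole, where the pole direction is taken from
the head-center-to-rim-centroid vector; rim overhang past the equator
cannot add projected area. Integration uses a deterministic cell-center
grid over the projection disk (default 400×400 across the head
diameter); numerator and denominator are counted on the same grid so
the disk-boundary discretization cancels. Against closed forms the
default resolution is accurate to ~0.05 percentage points, and doubling
the resolution moves results by far less than the 0.5-point stability
the package promises. The rim-interpolation step assumes the rim is
star-shaped in azimuth about the cup axis, true for anatomical rims and
for the whole synthetic family.

All three measures handle laterality through a sign s = ±1 on the
lateral axis, and the suite verifies mirror symmetry and rigid-motion
invariance to 1e−6.

## Sphere fitting

The femoral head sphere is fitted in two stages: the linear algebraic
fit (|p|² = 2c·p + const) followed by Levenberg–Marquardt refinement of
the geometric residual Σ(|p−c|−r)². Rank deficiency of the algebraic
system (coplanar or near-coplanar points) is detected from the singular
values and rejected. Under 0.5% isotropic noise at 500 points the fit
recovers the center within ~0.02 mm and the radius within ~0.03%,
agreeing with an independent Nelder–Mead minimization to 1e−4 mm.

## Synthetic cohort

The generator emulates a bilateral CT cohort of normal adult hips (by
default 38 male and 33 female subjects, both sides: 142 hips, 76/66 by
sex). Each hip is a sphere plus a rim whose colatitude about the cup
axis is a two-harmonic function of azimuth ψ (measured from lateral
toward anterior):

θ(ψ) = θ0 + A1·cos(ψ − ψ1) + A2·cos(2(ψ − ψ2)) + noise.

Defaults: θ0 = 42° (male) / 39° (female) — the 3° margin is the sex
effect and is configurable; A1 = 12°/13° with ψ1 = −90°, i.e. deepest
coverage posterior and shallowest anterior, as in real acetabula;
A2 = 8°/8.5° at ψ2 = 45°; head radius 25.5/22.5 mm; between-subject
SDs of 2.5° (θ0), 1° (A1), 0.8° (A2), 5°/4° (phases), 1 mm (radius);
per-point rim jitter 0.3°; bilateral hips share subject parameters plus
0.5° independent left/right jitter (mirror-symmetric geometry
otherwise).

The two harmonics have distinct, deliberate roles. The first harmonic
tips the effective cup axis (the rim centroid direction) posteriorly,
which places the coverage maximum at a positive, anterior tilt angle
(+10° with the defaults). The second harmonic shifts the most-lateral
rim point anteriorly — its contribution to the rim centroid integrates
to zero — which places the LCEA argmax at the positive end of the tilt
grid. A single harmonic cannot do both: its lateral-point shift and its
cup-axis shift both scale with A1·sin ψ1 and cancel exactly against any
cup pre-tilt, a trade the development analysis confirmed numerically to
be knife-edge. `target_peak_angles` computes the generator-targeted
peak angles at run time by sweeping the noiseless mean-parameter male
and female hips and averaging the curves by hip counts; tests compare
cohort peaks against these computed targets, never against constants.

What the generator does **not** emulate: the absolute coverage level of
real hips (~0.84 of the superior hemisphere, which coexists with LCEA
≈ 35° only through strongly non-sinusoidal rim shapes; the synthetic
cohort sits near 0.42), left–right covariance structure beyond shared
parameters, non-spherical heads, and the sourcil/bony-rim distinction
above. Passing cohort tests therefore demonstrate that the pipeline
preserves generative structure (sex effects, monotonicities, peak
locations, positive CEA–coverage coupling), not that the synthetic
marginals match any real population.

## Statistics

Sex comparisons use the independent two-sample t-test, Student's
pooled-variance form by default (the classical default when nothing
else is stated) with Welch selectable; a summary-statistics variant
reproduces the raw-data statistic to 1e−12. Two groups with zero
variance return t = 0, p = 1 when their means agree and raise a
degenerate-variance error otherwise. Correlations are Pearson's r with
two-sided p; strength labels use the conventional inclusive ladder
|r| ≥ 0.8 very strong / 0.6 strong / 0.4 moderate / 0.2 weak. Hips are
treated as independent observations (n = 142 despite 71 subjects) —
this mirrors how such cohorts are usually tabulated and is a
faithful-reproduction choice, not a statistical endorsement; no
multiple-testing correction is applied for the same reason. Reliability
uses ICC(2,1) — two-way random effects, absolute agreement, single
measures — computed from the mean-squares decomposition and
cross-checked against pingouin in the tests.

The packaged `data/reference_cohort.csv` transcribes the per-angle
mean ± SD summary (overall and by sex) of a published 3D-CT reference
cohort of 142 normal adult hips. Only quantities that are exact
arithmetic on those printed means are derived from it — window ranges
such as ACEA 11.77°, LCEA 1.84° (1.52° men / 2.22° women), coverage 5
percentage points over −10°…+5°, and the +10° LCEA peak; its p-values
are not re-derivable from rounded summaries and are not reproduced.
Range statistics break argmax ties toward the smaller angle.

## Numerical and interface choices

Angles are degrees, lengths mm, coverage a fraction in [0, 1]. The
interchange format between pipeline stages is a long-format CSV
(hip, angle, measure, value); output files carry `# seed` and
`# config_hash` comment headers so reruns are verifiably identical.
Meshes are read via trimesh (STL/PLY/OBJ); rims are ordered point files
(CSV with x,y,z headers or JSON arrays) validated to lie within 2% of
the head radius of the fitted sphere and re-ordered counter-clockwise
viewed from superior. Problem sizes used by the default test and
acceptance runs — 3,600-point rim resampling, 400² coverage grids,
50-cup oracle sweeps, one 142-hip cohort — keep a full run in the tens
of seconds while holding discretization error an order of magnitude
below every stated tolerance.

## Known limitations

- The sourcil-edge/bony-rim distinction (above) bounds fidelity to
  cohorts measured on sclerotic landmarks; interior LCEA peaks are out
  of reach by construction.
- Coverage assumes a star-shaped rim about the cup axis and a spherical
  head; aspherical (cam-type) heads violate the model.
- The synthetic family is a stylized two-harmonic shape model, not a
  statistical shape atlas; its parameter effect sizes are plausibility
  choices, not population estimates.
- Automatic landmarking, segmentation and DICOM handling are explicitly
  out of scope; inputs are meshes, rim curves and landmark files.
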