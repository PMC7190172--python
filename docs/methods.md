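# Methods

## Coordinate frames and the transform model

Two frames are used throughout, both in millimetres. The **MRI frame** is
the frame of the scalp surface extracted from the participant's T1 image.
The **head frame** is the MEG device-independent head coordinate system
(conventionally: origin midway between the preauricular points, +x toward
the right preauricular, +y toward the nasion, +z superior). A
co-registration is a rigid-body transform `T` (4×4 homogeneous; rotation
`R`, `det R = +1`, no scaling or shear; bottom row exactly `(0,0,0,1)`)
mapping MRI coordinates into head coordinates. Distance computations
apply `T⁻¹` to the digitized points, bringing them into the surface's MRI
frame — equivalent to transforming the mesh, but cheaper.

Transforms are reported as six parameters: translations `tx, ty, tz` (mm)
and rotations `pitch, roll, yaw` (degrees) about the fixed x, y, z axes,
applied in that order: `R = Rz(yaw)·Ry(roll)·Rx(pitch)`. Under this
convention `roll ∈ [−90°, 90°]` and the decomposition is unique away from
gimbal lock (`|roll| = 90°`), where the convention `yaw = 0` is applied
and the result flagged. The Euler order is a genuine free choice — the
six reported numbers depend on it — but both methods of a comparison are
decomposed identically, so reliability statistics are unaffected.
Decompose∘recompose round-trips to better than 1e-9, and every transform
construction re-validates rigidity at 1e-9 tolerance.

## The error metric

The co-registration error of a transform is the **median distance from
each digitized headshape point to the nearest point on the scalp
surface**, with the 25th/75th percentiles (linear interpolation) as the
IQR. Distances are exact point-to-triangle-mesh distances: for each query
the closest point over every triangle (interior, edge, or vertex) is
found by barycentric-region clamping. A k-d tree over mesh vertices gives
each query an upper bound (nearest-vertex distance); every triangle with
a vertex within `bound + max triangle diameter` is then tested exactly.
By the triangle inequality no closer triangle can be missed, so the
pruning is lossless — the test suite verifies equality with an exhaustive
all-triangles computation at 1e-9. Distance to the vertex cloud alone
would be biased upward on coarse meshes, which is why the metric is
resolution-independent here.

Only **headshape-role** points enter the metric (and ICP); digitized
fiducials and HPI coil points are excluded. The primary error summaries
cover *all* headshape points, including any rejected as outliers during
fitting; the inlier-only median is reported as a secondary field.
A result with median error above the 2 mm quality heuristic carries a
`quality_flag`.

## The automated pipeline

1. **Template fiducial transfer** — average landmark coordinates on a
   template head are mapped through the (generally affine)
   template→subject registration to give starting estimates of the
   subject's MRI-frame fiducials.
2. **Landmark fit** — SVD-based orthogonal Procrustes (Kabsch) on the
   three digitized-vs-estimated fiducial pairs: centroids aligned,
   rotation from the SVD of the cross-covariance, reflections corrected
   by flipping the smallest singular vector. Degenerate (collinear or
   < 3-point) configurations raise an error.
3. **Initial ICP** — iterate: correspond each inverse-transformed
   headshape point with its exact nearest surface point; solve the rigid
   Procrustes problem to those correspondences; update the transform.
4. **Outlier rejection** — a single pass removing the headshape points
   strictly more than 5 mm from the surface under the current fit
   (points at exactly 5 mm are retained). Removed points do not re-enter
   fitting, but still enter the reported error.
5. **Final ICP** on the retained points.

### ICP numerics

The per-iteration objective is the **RMS** corresponded distance. With
exact nearest-surface correspondence, re-correspondence can only shrink
each point's distance and the Procrustes refit minimizes the summed
squared distance, so the RMS trace is non-increasing by construction (the
arithmetic mean carries no such guarantee and does occasionally rise
mid-descent; the recorded `iteration_trace` is therefore RMS). A guard
rejects any numerically increasing step. Iteration stops when the RMS
improves by less than `convergence_tol` (default 1e-6 mm) or at the stage
cap.

Plain point-to-point ICP converges linearly and — on smooth head
surfaces — very slowly along tangential-sliding modes (pitch coupled with
y/z translation is the classic case). Each iteration therefore applies
the pose-extrapolation acceleration from the original ICP literature:
when two successive update vectors in 6-parameter pose space align
(cosine > 0.7) with shrinking magnitude ratio ρ < 1, the pose is
extrapolated toward the geometric-series limit (Aitken step, gain
ρ/(1−ρ) capped at 1000) and kept only if the measured RMS improves.
Iteration caps default to 30 (initial stage) and 200 (final stage): on
noise-free data the final stage genuinely needs on the order of a hundred
accelerated iterations to drive the pose error below 0.1 mm/0.1°, while
on realistically noisy data the tolerance stops it after a few dozen.
Point-to-plane ICP variants, robust weighting, and scaling fits are out
of scope.

Given identical inputs and configuration the pipeline is deterministic
bit-for-bit; it contains no randomness.

## Reliability statistics

Two methods applied to the same subjects are compared per measure (error
plus the six decomposed parameters) by:

- medians and IQRs per method, and the mean ± SD of per-subject
  differences (method b − method a; conventionally a = manual,
  b = automated);
- **ICC(3,1)** — Shrout–Fleiss two-way mixed, consistency, single
  measures: `(MS_B − MS_E) / (MS_B + (k−1)·MS_E)` from the
  subjects×methods ANOVA mean squares. Consistency ICC is deliberately
  blind to a constant per-method offset. ICC(2,1) (absolute agreement) is
  available as a sensitivity option. An all-identical table raises an
  undefined-value error (inside `compare_methods`, degenerate measures
  report NaN / "undefined");
- **Pearson r** between the two methods' errors (scipy), converted to
  Cohen's `d = 2r/√(1−r²)` (±∞ reported at |r| = 1);
- Cicchetti bands: < 0.40 poor, 0.40–0.59 fair, 0.60–0.74 good, ≥ 0.75
  excellent, with boundary values assigned to the higher band;
- the **exclusion rerun**: the error ICC recomputed after dropping whole
  subjects whose method-b error exceeds 2.0 mm (strictly greater; ICC
  needs complete pairs, so the subject's row is removed);
- correlations between each method's error and the per-subject
  headshape-point count.

## The synthetic cohort generator

The generator reproduces the statistical structure of a real MEG–MRI
study so the comparison can be validated with known ground truth.

**Head surfaces.** A subdivided icosphere (default subdivision 4: 2562
vertices, 5120 triangles — the error metric is resolution-independent
because distances are to triangles) is radially shaped:
`r(u) = ellipsoid(u) + nose + brow + occiput`, the features being angular
Gaussian bumps. Default half-axes (75, 95, 110) mm follow standard head
breadth/length/height proportions; the y–z eccentricity and the 9 mm
occipital protuberance matter — a more spherical profile leaves pitch
nearly unidentifiable from scalp points, which no real head does. Nose
amplitude 22 mm (σ 10°, pointing 20° below anterior), brow 6 mm (σ 18°,
18° above), occiput 9 mm (σ 25°, 5° below posterior). The nasion is the
vertex nearest the nose-root direction; the preauriculars are the lateral
extreme vertices — all exactly on the mesh. Geometry depends only on the
shape parameters, never on the seed. Per-subject variation: half-axes
±3%, feature amplitudes ±15% (1 SD).

**Digitization.** Points are sampled by area over the region a technician
digitizes: faces above the fiducial plane, plus nose-bridge (12° around
the nasion direction) and brow (20°) patches — the nose tip (cartilage)
stays excluded. Counts are drawn from a rounded triangular distribution
on [83, 229] with mode 132 (median ≈ 143, matching the target count
statistics). Digitizer jitter is isotropic Gaussian, default σ = 1.5 mm
(Polhemus-style error is approximately isotropic, so the frame in which
it is applied is immaterial). A default 5% of points are displaced 10 mm
radially outward — the stray readings the pipeline's 5 mm rejection step
exists for. The three fiducials (noise-perturbed) and four HPI-style
points are included with their roles. Sampled MRI-frame points are
carried into head coordinates with the subject's ground-truth transform.

**Transforms.** Ground-truth MRI→head transforms are sampled in parameter
space around translation (−2, −5, −70) mm and rotation (14, 1, −0.5)°,
the regime of seated MEG head coordinates (large negative z, ~14° pitch),
with 5 mm / 5° between-subject SDs. The "MNI-estimated" fiducials handed
to the pipeline are the true ones plus 5 mm jitter, standing in for
template-transfer error. The **manual operator** is simulated by
perturbing each decomposed ground-truth parameter by N(0, 1 mm) /
N(0, 1°); perturbation in parameter space (rather than composing a
perturbing transform) keeps the per-parameter disagreement exactly at the
configured SDs, which is what the operator-noise magnitude means here.
Zero SDs return the ground truth unchanged.

**De-facing** removes every vertex (and incident triangle) anterior of
10 mm behind the nasion and inferior of 20 mm above it, in the
fiducial-aligned frame — a geometric stand-in for volume de-facing tools,
with configurable box extents. It is idempotent, never moves surviving
vertices, and errors out if more than 60% of vertices would go
(degenerate geometry).

All cohort randomness is spawned per-subject from a master seed
(`numpy.random.SeedSequence`); regeneration is bit-identical and any
subject can be rebuilt in isolation.

### What the generator does *not* emulate

- MRI artifacts, scalp-extraction error, and mesh-vs-skin mismatch: the
  digitized points are noisy samples of the *same* mesh the error is
  measured against. Real errors include a surface-model component, so
  real automated errors run somewhat higher than synthetic ones at equal
  digitizer noise.
- Structured (non-isotropic) digitizer error, skin deformation, hair.
- The automated arm re-fits the very noise realization it is scored on,
  while the "manual" arm is a perturbed ground truth; on synthetic data
  the automated method therefore tends to score *lower* error than the
  simulated manual operator — the opposite ordering of a real study,
  where an experienced technician can out-perform the automated fit.
  Direction-of-effect claims (e.g. de-facing increases error) and
  agreement structure transfer; absolute medians and signed differences
  do not.
- Per-subject noise heterogeneity: with a common σ across subjects, the
  between-subject variance of the *error* is small, so the error ICC is
  modest even when both methods are accurate. The transform-parameter
  ICCs are driven by the 5 mm/5° between-subject spread against ~1 mm/1°
  method disagreement and land in the excellent range.

## Problem sizes and tolerances

Validation runs use 30-subject cohorts at the defaults above (the
acceptance script: one cohort, three arms — automated intact, automated
de-faced, simulated manual — in about a minute on one CPU). Geometric
exactness is asserted at 1e-9 mm against exhaustive oracles; ICC at
1e-10 against an independent ANOVA implementation; statistical
calibrations (ICC vs variance ratio) at ±0.05 with n = 5000. File
round-trips are bit-exact for binary double-precision PLY and the
plain-text transform/headshape formats.

## Known limitations

- ICP convergence is to a local optimum; initialization quality rests on
  the three-landmark fit, and grossly wrong fiducial estimates (≫ 5 mm)
  can strand the fit. The pipeline reports the full iteration trace and a
  quality flag rather than attempting global search.
- The Euler decomposition flags but does not avoid gimbal lock; head
  transforms in practice sit ~75° away from it.
- De-facing is a surface-geometry emulation; voxel-space de-facing tools
  can alter the extracted surface differently.
- `template_fiducials_to_subject` accepts any invertible affine but the
  package does not itself perform template registration.
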