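# Methods

## Problem and model

Longitudinal MRI follow-up of erosive wrist disease needs the same carpal
bone, segmented from two acquisitions months apart, brought into a common
frame so that shape differences (erosion, regrowth, edema resorption) can
be read off directly.  Because any non-rigid warp would manufacture or hide
exactly the morphological changes being looked for, the registration is
rigid: rotations and translations only.

Each bone enters as a binary volume of interest `b(x, y, z) ∈ {0, 1}` on an
isotropic grid (coronal in-plane axes x, y; slice axis z).  Orientation is
described by the inertia matrix built from second-order central moments,

    I = [[M020 + M002,      −M110,      −M101],
         [     −M110, M200 + M002,      −M011],
         [     −M101,      −M011, M200 + M020]],

whose orthonormal eigenvector tern (e1, e2, e3) gives the principal axes of
the bone, and by the centroid (x_g, y_g, z_g) for position.

Instead of composing one rotation matrix, the method applies up to three
*elemental* rotations — about z (coronal plane), then y (axial), then x
(sagittal) — re-estimating centroid, inertia matrix and axes from the
current volumes before every step.  At each step the driving eigenvector is
projected onto the rotated plane; the two angles it forms with the in-plane
versors are compared and the smaller one selected; both volumes are rotated
so that their projections land on that same axis, and the follow-up
centroid is translated onto the initial centroid.  Overlap is scored after
every step, so 1-, 2- and 3-rotation configurations can be compared and the
best one kept per bone.

A classical single-matrix baseline (`R = E_I · E_IIᵀ`, the Direction Cosine
Matrix assembled from the two terns) is included for comparison.  Its known
failure mode — eigenvector signs are arbitrary, and an inconsistent sign
resolution registers the pair with one axis antiparallel, "bottom to top" —
is reproducible via a flag; the sequential method is structurally immune
because every step angle is at most 90° (alignment to an axis *line*).

## Eigenvalue ordering

The registration orders the tern *elongation first*: e1 is the eigenvector
of the **smallest** inertia eigenvalue, i.e. the long axis of the bone.
This is forced by the geometry of the first step: the moment of inertia
about the elongation axis is minimal, while the largest eigenvalue pairs
with the axis normal to the flattest extent — for a flat carpal bone (and
for the validation phantom) that is the coronal normal z, whose coronal
projection is null and therefore defines no first rotation angle at all.
`principal_axes` also offers the largest-first convention for descriptive
use.

## Sign disambiguation

Eigenvectors are defined up to sign.  The initial volume's tern is resolved
by making each axis's largest-magnitude component positive; the follow-up
tern is resolved against the initial tern (non-negative dot products);
handedness is restored by flipping e3 when needed.  Step angles are
additionally wrapped to ±π/2 (alignment to the target axis line): a sign
flip of an eigenvector carries no shape information, and an unwrapped
near-π angle would spin a volume half a turn on noise alone.  A true 180°
in-plane difference between the two bones is invisible to second-order
moments with or without this wrap; resolving it would need third-order
(skewness) information, which the method does not use.

## Step conditioning

For an orthonormal tern the second step (about y) can be driven
equivalently by e1 or e2: aligning e1's (x, z)-projection to the x line is,
in exact arithmetic, the same rotation as aligning e2's to the z line.
Their *estimates* differ sharply, though: after step 1, e1's axial
projection has norm ≈ 1 while e2's has norm ≈ |sin θx|, so the e2-based
angle inherits moment noise amplified by 1/|sin θx|.  By default each step
therefore uses the best-conditioned equivalent driver (the tern member with
the longest projection onto the rotated plane, judged on the initial
volume); `literal_schedule=True` fixes the drivers to e1, e2, e3.  On the
phantom study the default cuts the mean three-axis recovery error from
≈0.028 rad to ≈0.007 rad.

## Numerical realisation

* **Single resampling per state.**  Each intermediate volume is produced by
  one resampling of the original (embedded) mask under the accumulated
  rigid map, not by re-resampling the previous, already-thresholded state.
  The sequence of maps is exactly the rotate–translate–re-estimate loop;
  only the realisation differs, and it halves interpolation/threshold
  noise.
* **Mask interpolation** is trilinear on floats, thresholded at 0.5
  (nearest-neighbour behind a flag).  Grey volumes use plain trilinear.
* **Lattice exactness.**  Maps whose linear part is a signed permutation
  with an integral offset are executed by exact index gathering, so
  compositions of 90°-multiple rotations and integer translations
  round-trip bit-exactly; when the offset is fractional but the dominant
  interpolation weight exceeds ½, gathering at the rounded offset equals
  the thresholded trilinear result and is used for masks.
* **Rotation centres** are the current centroids rounded to the nearest
  voxel.  A shifted centre differs from the exact-centroid rotation only by
  a translation, which the mandatory post-step translation absorbs; integer
  centres keep quarter-turn registrations exactly lattice-preserving.
* **Degenerate projections.**  A driving eigenvector whose in-plane
  projection is shorter than `projection_tol` (default 0.05) defines no
  usable angle and yields a zero-angle step with a warning.  The default is
  ≈5× the eigenvector noise floor of binary-moment estimation at typical
  VOI sizes (component errors of order 1e-2 after thresholded resampling);
  below that, an estimated angle would be dominated by noise.  An
  axis-aligned volume is the degenerate case *par excellence* (its
  eigenvector already lies on a versor) and correctly receives zero-angle
  steps.
* **Minimum-angle skip** (`min_angle`, default 0 = disabled) suppresses
  rotations smaller than the interpolation error they would introduce.
* **Translations** are sub-voxel by default (trilinear + threshold for
  masks); integer translations are exact index moves.
* **Degeneracy of the inertia spectrum**: a relative eigenvalue gap below
  1e-6 flags the descriptor as unreliable (warning); registration proceeds.

## Synthetic validation phantom

`make_t_phantom` renders a t-shaped union of two cuboids — stem 20×6×6
voxels along x, crossbar 6×18×6 along y at the stem's end — on a 64³ grid
(1152 foreground voxels).  The shape has three distinct inertia
eigenvalues, coordinate-versor principal axes, mirror symmetry in y and z
but not x, and enough grid margin for clip-free rotation.  The study
rotates the phantom by known per-axis angles drawn uniformly in ±20°
(composed as `Rz·Ry·Rx`, the unique order the z→y→x sequential corrections
unwind exactly), registers the copy back onto the pristine phantom with
three rotations, and records overlap metrics and per-axis angle-recovery
errors (wrapped at π, since axis angles are direction-insensitive).

With 20 trials this takes about two seconds on one CPU; defaults (sizes,
angle range, trial count) are the study conditions, not tuning knobs.

What the phantom does **not** emulate: grey-level noise and bias fields,
segmentation errors, anisotropic acquisition, partial-volume boundaries of
real bone, or actual erosive change.  Passing the synthetic study shows the
estimator recovers known rigid motion on a clean, well-conditioned shape;
it does not certify accuracy on clinical data.

## Evaluation

Registered pairs are scored by the voxelwise confusion matrix with the
transformed initial bone as reference: sensitivity = |a∩b|/|a| (deviation
flags lost tissue, candidate erosion), precision = |a∩b|/|b| (deviation
flags voxels present only at follow-up).  A sensitivity-versus-(1−precision)
scatter table supports the per-bone configuration choice; the fusion
overlay labels overlap / initial-only / follow-up-only voxels for visual
reading.  The symmetric mean boundary-to-boundary distance (6-neighbour
boundary, exact Euclidean distance transform, mm) summarises residual
misalignment; it is a direct boundary distance, not a reconstruction of any
particular published distance estimate.

## Known limitations

* Second-order moments cannot resolve a near-180° in-plane flip of an
  (approximately) symmetric bone; both the sequential method and the
  baseline would register such a pair upside down.
* Angle estimates for the second and third steps are noisier than the
  first; with the literal e1/e2/e3 driver schedule the error is amplified
  by the inverse projection norm (see Step conditioning).
* The follow-up volume undergoes one more interpolation (the translation)
  than the initial volume; with 0.5-threshold resampling the voxel count is
  preserved to ~1%, so sensitivity and precision stay nearly symmetric.
  Pipelines whose mask interpolation dilates the moving volume will report
  systematically lower precision at equal alignment quality.
* The seeded band-threshold segmentation is a stand-in entry point; any
  externally produced mask can be supplied instead.
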