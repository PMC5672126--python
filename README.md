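# carpreg

Rigid registration of carpal-bone volumes via principal axes of inertia,
for longitudinal MRI monitoring of wrist-bone erosion.

When the same wrist is imaged months apart, each bone sits in a different
position and orientation.  To compare a bone's shape across time — and so
detect erosion or regression of rheumatoid arthritis — the two
segmentations must be aligned *rigidly*: any elastic warp would deform away
exactly the changes being looked for.  `carpreg` registers per-bone binary
volumes using their moment-based orientation descriptors: the centroid and
the inertia matrix

    I = [[M020 + M002,      −M110,      −M101],
         [     −M110, M200 + M002,      −M011],
         [     −M101,      −M011, M200 + M020]]

built from second-order central moments M_lmn of the mask, whose
eigenvector tern (e1, e2, e3) gives the principal axes.  Rather than one
3-D rotation matrix, the alignment is split into up to three *elemental*
rotations — coronal (about z), axial (about y), sagittal (about x) — with
centroid, inertia matrix and axes re-estimated from the current volumes
before each step, and a centroid translation after each step.  This bounds
every step angle to ±90°, confines interpolation error to one plane at a
time, and avoids the axis-orientation ambiguity that makes the classical
single-matrix (Euler / Direction-Cosine-Matrix) approach register bones
bottom-to-top; that baseline is included for comparison.  Registered pairs
are scored with a voxelwise confusion matrix: sensitivity |a∩b|/|a| (lost
tissue → candidate erosion) and precision |a∩b|/|b| (new voxels), plus
fusion overlays and a mean surface distance.

A synthetic t-shaped phantom with known applied rotations validates the
whole chain: overlap after re-registration and the error between applied
and recovered angles.

## Worked example

```python
import numpy as np
from carpreg import (make_t_phantom, apply_known_rotation, register_pair,
                     select_configuration, estimated_angles)

phantom = make_t_phantom()                      # 1152-voxel t-shape, 64³ grid
moved, truth = apply_known_rotation(phantom, np.deg2rad([12.0, -8.0, 5.0]))

result = register_pair(phantom, moved, n_rotations=3)
best = select_configuration(result, criterion="jaccard")
m = result.metrics[best]
print(f"selected configuration: {best} rotations")
print(f"estimated angles (deg): {np.round(np.rad2deg(estimated_angles(result)), 2)}")
print(f"sensitivity = {m.sensitivity:.3f}, precision = {m.precision:.3f}")
```

prints

```
selected configuration: 3 rotations
estimated angles (deg): [11.75 -7.73  4.98]
sensitivity = 0.986, precision = 1.000
```

The phantom was rotated by (12, −8, 5) degrees about (z, y, x); the three
sequential steps recover those angles to a fraction of a degree, and after
registration 98.6 % of the reference volume is covered by the re-aligned
copy (sensitivity), which itself contains no spurious extra voxels
(precision 1.0).

The same pipeline runs from the shell on NIfTI masks or DICOM series:

```sh
carpreg convert  --in series_dir --iso --out vol.nii.gz
carpreg segment  --in vol.nii.gz --seed 120,140,12 --band 90,255 --out bone.nii.gz
carpreg describe --mask bone.nii.gz --json axes.json
carpreg register --mask1 bone_t1.nii.gz --mask2 bone_t2.nii.gz \
                 --rotations auto --baseline euler --out-dir results/
carpreg simulate --trials 20 --max-angle-deg 20 --seed 42 --out-dir sim/
```

`carpreg register` writes the transformed masks, the transform chains
(JSON), a metrics CSV (per configuration) and a fusion-overlay label map
(1 = overlap, 2 = initial-only/red, 3 = follow-up-only/green).

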