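"""Overlap metrics, ROC scatter data, fusion overlays and surface distances.

Registered pairs are scored with a voxelwise confusion matrix in which the
transformed initial bone is the reference and the transformed follow-up bone
is the test: TP is the intersection count, FN the initial-only count, FP the
follow-up-only count (TN is grid-dependent and not used).  Sensitivity
``|a & b| / |a|`` flags loss of bone tissue (candidate erosion); precision
``|a & b| / |b|`` flags voxels present only at follow-up (e.g. reabsorbed
edema, or processing error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, GridMismatchError
from .volume import BinaryVolume

#: fusion overlay labels and the display colours used in longitudinal reading
OVERLAY_LEGEND = {
    0: "background",
    1: "overlap (yellow)",
    2: "initial-only (red, candidate erosion)",
    3: "followup-only (green, candidate new tissue / processing error)",
}


@dataclass(frozen=True)
class OverlapMetrics:
    """Confusion-matrix counts and derived ratios for a registered pair."""

    n_initial: int
    n_followup: int
    n_intersection: int
    sensitivity: float
    precision: float

    def as_tuple(self) -> tuple[float, float]:
        return self.sensitivity, self.precision


def _check_grids(a: BinaryVolume, b: BinaryVolume) -> None:
    if a.shape != b.shape:
        raise GridMismatchError(f"grids differ: {a.shape} vs {b.shape}")


def intersection_volume(a: BinaryVolume, b: BinaryVolume) -> BinaryVolume:
    """Voxelwise AND of two masks on a common grid."""
    _check_grids(a, b)
    return BinaryVolume(a.data & b.data, a.spacing)


def overlap_metrics(a: BinaryVolume, b: BinaryVolume) -> OverlapMetrics:
    """Sensitivity and precision of follow-up ``b`` against initial ``a``."""
    _check_grids(a, b)
    n_a, n_b = a.count, b.count
    if n_a == 0 or n_b == 0:
        raise EmptyMaskError("overlap metrics need two non-empty masks")
    n_x = int((a.data & b.data).sum())
    return OverlapMetrics(n_a, n_b, n_x, n_x / n_a, n_x / n_b)


def roc_point(m: OverlapMetrics) -> tuple[float, float]:
    """(1 - precision, sensitivity); perfect registration maps to (0, 1)."""
    return 1.0 - m.precision, m.sensitivity


def roc_table(results: list[tuple[str, int, OverlapMetrics]]) -> pd.DataFrame:
    """Scatterplot table of labelled results (bone, n_rotations, metrics)."""
    rows = []
    for bone, n_rot, m in results:
        x, y = roc_point(m)
        rows.append(
            {
                "bone": bone,
                "n_rotations": n_rot,
                "one_minus_precision": x,
                "sensitivity": y,
                "n_initial": m.n_initial,
                "n_followup": m.n_followup,
                "n_intersection": m.n_intersection,
            }
        )
    return pd.DataFrame(rows)


def fusion_overlay(a: BinaryVolume, b: BinaryVolume) -> BinaryVolume | np.ndarray:
    """Label volume fusing a registered pair: 1 overlap, 2 initial-only, 3 followup-only."""
    _check_grids(a, b)
    out = np.zeros(a.shape, dtype=np.uint8)
    out[(a.data == 1) & (b.data == 1)] = 1
    out[(a.data == 1) & (b.data == 0)] = 2
    out[(a.data == 0) & (b.data == 1)] = 3
    return out


_FACE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one 6-neighbour background voxel."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE, border_value=0)
    return mask.astype(bool) & ~eroded


def mean_surface_distance(a: BinaryVolume, b: BinaryVolume) -> float:
    """Symmetric mean boundary-to-boundary distance in mm.

    For each boundary voxel of one mask the Euclidean distance (scaled by the
    voxel spacing) to the nearest boundary voxel of the other mask is taken;
    the two directed means are averaged.  Identical masks give 0.
    """
    _check_grids(a, b)
    a.require_nonempty()
    b.require_nonempty()
    if a.spacing != b.spacing:
        raise GridMismatchError("masks must share voxel spacing")
    sa = _boundary(a.data)
    sb = _boundary(b.data)
    d_to_b = ndimage.distance_transform_edt(~sb, sampling=a.spacing)
    d_to_a = ndimage.distance_transform_edt(~sa, sampling=a.spacing)
    return 0.5 * (float(d_to_b[sa].mean()) + float(d_to_a[sb].mean()))
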