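"""Low-level rigid resampling primitives.

All maps act on voxel coordinates in the package axis order ``(x, y, z)``.
Rotation matrices follow the right-handed convention: a positive angle about
``+z`` turns ``+x`` towards ``+y``.

Two exactness fast paths matter for the method's guarantees:

* a map whose linear part is a signed permutation and whose offset is
  integral is realised by exact index gathering — compositions of
  90-degree-multiple rotations and integer translations therefore round-trip
  a mask bit-exactly;
* a signed-permutation map with a constant fractional offset applied to a
  *mask* is realised by gathering at the rounded offset whenever the
  dominant interpolation weight exceeds one half — in that regime the
  gather equals trilinear-interpolate-then-threshold bit-exactly.

Everything else goes through ``scipy.ndimage.affine_transform`` with
trilinear interpolation; masks are resampled as floats and thresholded at
0.5.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

_AXES = {"x": 0, "y": 1, "z": 2}


def basic_rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """Elemental (basic) rotation matrix about one coordinate axis."""
    c, s = np.cos(angle), np.sin(angle)
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    raise ValueError(f"unknown axis {axis!r}")


def compose_rotations(axes_angles: list[tuple[str, float]]) -> np.ndarray:
    """Single matrix equivalent to applying the listed rotations in order.

    ``axes_angles`` is given in application order (first rotation first), so
    the returned product is ``R_n @ ... @ R_2 @ R_1``.
    """
    m = np.eye(3)
    for axis, angle in axes_angles:
        m = basic_rotation_matrix(axis, angle) @ m
    return m


def _signed_permutation(m: np.ndarray, tol: float = 1e-9) -> np.ndarray | None:
    """Return the exact signed permutation equal to ``m`` within tol, else None."""
    r = np.rint(m)
    if np.abs(m - r).max() > tol:
        return None
    if not np.isin(r, (-1, 0, 1)).all():
        return None
    if np.abs(np.abs(r).sum(axis=0) - 1).max() > 0 or np.abs(np.abs(r).sum(axis=1) - 1).max() > 0:
        return None
    return r.astype(np.int64)


def _gather(
    data: np.ndarray,
    perm: np.ndarray,
    offset: np.ndarray,
    output_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Exact evaluation of ``out[o] = in[perm @ o + offset]`` (integer map)."""
    shape = output_shape or data.shape
    grids = np.indices(shape)
    coords = np.einsum("ij,j...->i...", perm, grids) + offset.reshape(3, 1, 1, 1)
    valid = np.ones(shape, dtype=bool)
    for i in range(3):
        valid &= (coords[i] >= 0) & (coords[i] < data.shape[i])
    cc = [np.clip(coords[i], 0, data.shape[i] - 1) for i in range(3)]
    out = data[cc[0], cc[1], cc[2]]
    out = np.where(valid, out, 0)
    return out.astype(data.dtype)


def resample_affine(
    data: np.ndarray,
    matrix: np.ndarray,
    offset: np.ndarray,
    *,
    binary: bool,
    threshold: float = 0.5,
    nearest: bool = False,
    output_shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Resample under ``out[o] = in[matrix @ o + offset]``.

    ``matrix``/``offset`` describe the *inverse* (output-to-input) map, the
    same convention as :func:`scipy.ndimage.affine_transform`.
    """
    offset = np.asarray(offset, dtype=np.float64)
    perm = _signed_permutation(matrix)
    if perm is not None:
        frac = np.abs(offset - np.rint(offset))
        if frac.max() <= 1e-9:
            # exact lattice map: gather, no interpolation at all
            return _gather(data, perm, np.rint(offset).astype(np.int64), output_shape)
        if binary and not nearest:
            # constant sub-voxel offset: every sample sits at the same
            # fractional position, so thresholding the trilinear value picks
            # the dominant corner whenever its weight exceeds 1/2 — in that
            # case rounding the offset reproduces the interpolated result
            # bit-exactly and we can gather instead
            if np.prod(np.maximum(frac, 1.0 - frac)) > 0.5 + 1e-12:
                return _gather(data, perm, np.rint(offset).astype(np.int64), output_shape)
    order = 0 if nearest else 1
    out = ndimage.affine_transform(
        data.astype(np.float64), matrix, offset=offset, order=order,
        mode="constant", cval=0.0, prefilter=False,
        output_shape=output_shape,
    )
    if binary:
        return (out >= threshold).astype(np.uint8)
    return out


def rotate_about(
    data: np.ndarray,
    rotation: np.ndarray,
    centre: np.ndarray,
    *,
    binary: bool,
    nearest: bool = False,
) -> np.ndarray:
    """Rotate the volume content by ``rotation`` about ``centre`` (same grid)."""
    inv = rotation.T  # rigid rotation: inverse is the transpose
    centre = np.asarray(centre, dtype=np.float64)
    offset = centre - inv @ centre
    return resample_affine(data, inv, offset, binary=binary, nearest=nearest)


def shift_volume(
    data: np.ndarray,
    delta: np.ndarray,
    *,
    binary: bool,
    subvoxel: bool = True,
    nearest: bool = False,
) -> np.ndarray:
    """Translate the volume content by ``delta`` voxels (same grid).

    Integer shifts (or ``subvoxel=False``, which rounds) are exact index
    moves; fractional shifts use trilinear interpolation, thresholded at 0.5
    for masks.
    """
    delta = np.asarray(delta, dtype=np.float64)
    if not subvoxel:
        delta = np.rint(delta)
    if np.abs(delta - np.rint(delta)).max() <= 1e-9:
        return _gather(
            data, np.eye(3, dtype=np.int64), -np.rint(delta).astype(np.int64)
        )
    out = ndimage.shift(
        data.astype(np.float64), delta, order=0 if nearest else 1,
        mode="constant", cval=0.0, prefilter=False,
    )
    if binary:
        return (out >= 0.5).astype(np.uint8)
    return out
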