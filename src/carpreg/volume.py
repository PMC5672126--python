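"""Domain containers for tomographic volumes and bone masks.

Axis convention (used throughout the package): arrays are indexed
``data[x, y, z]`` where ``x`` is the in-plane column, ``y`` the in-plane row
(so a coronal slice is ``data[:, :, k]``), and ``z`` the coronal slice index,
``0 .. N-1``.  Voxel indices are 0-based; ``spacing = (dx, dy, dz)`` is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyMaskError

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)  # type: ignore[assignment]
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive lengths, got {spacing!r}")
    return spacing


@dataclass
class GreyVolume:
    """A 3D grey-level acquisition with intensities in [0, 255].

    Parameters
    ----------
    data:
        3D scalar grid indexed ``[x, y, z]``.
    spacing:
        Voxel size ``(dx, dy, dz)`` in mm.
    """

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("GreyVolume requires a non-empty 3D array")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-9 or hi > 255 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 255]; found [{lo}, {hi}]")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def isotropic(self, tol: float = 1e-9) -> bool:
        dx, dy, dz = self.spacing
        return abs(dx - dy) <= tol and abs(dx - dz) <= tol


@dataclass
class BinaryVolume:
    """A 3D occupancy mask (one bone VOI); values are exactly 0 or 1."""

    data: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        values = np.unique(arr)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"mask values must be 0/1; found {values[:10]}")
        self.data = arr.astype(np.uint8)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("BinaryVolume requires a non-empty 3D array")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def isotropic(self, tol: float = 1e-9) -> bool:
        dx, dy, dz = self.spacing
        return abs(dx - dy) <= tol and abs(dx - dz) <= tol

    def require_nonempty(self) -> "BinaryVolume":
        if self.count == 0:
            raise EmptyMaskError("mask has no foreground voxel")
        return self


Volume = GreyVolume | BinaryVolume


def _interp_z(data: np.ndarray, new_z: np.ndarray, nearest: bool) -> np.ndarray:
    """Linear (or nearest) interpolation along the slice axis only.

    ``new_z`` holds fractional source-slice positions for each output slice.
    """
    if nearest:
        idx = np.clip(np.rint(new_z).astype(int), 0, data.shape[2] - 1)
        return data[:, :, idx]
    k = np.clip(np.floor(new_z).astype(int), 0, data.shape[2] - 2)
    w = new_z - k
    return (1.0 - w) * data[:, :, k] + w * data[:, :, k + 1]


def resample_isotropic(v: Volume, *, nearest: bool | None = None) -> Volume:
    """Resample onto a cubic voxel grid with side equal to the in-plane spacing.

    Coronal acquisitions are typically anisotropic only across slices, so
    slices are interpolated along ``z`` while in-plane samples are preserved.
    The number of output slices is ``floor((N - 1) * dz / s) + 1`` with
    ``s`` the in-plane spacing, which preserves the physical z extent to
    within one voxel.  An already-isotropic volume is returned unchanged.

    ``nearest`` selects nearest-neighbour interpolation; it defaults to linear
    for grey volumes and to linear-plus-threshold for masks (pass ``True`` to
    force pure nearest-neighbour for masks).
    """
    if v.isotropic():
        return v
    dx, dy, dz = v.spacing
    if abs(dx - dy) > 1e-9:
        raise ValueError("in-plane spacing must be square (dx == dy)")
    s = dx
    is_mask = isinstance(v, BinaryVolume)
    nz = v.data.shape[2]
    new_n = int(np.floor((nz - 1) * dz / s)) + 1
    new_z = np.arange(new_n) * (s / dz)
    if nearest is None:
        nearest = False
    out = _interp_z(v.data.astype(np.float64), new_z, nearest)
    if is_mask:
        return BinaryVolume((out >= 0.5).astype(np.uint8), (s, s, s))
    return GreyVolume(np.clip(out, 0.0, 255.0), (s, s, s))


def pad_to_common(a: BinaryVolume, b: BinaryVolume) -> tuple[BinaryVolume, BinaryVolume]:
    """Zero-pad two origin-aligned masks to the elementwise-max shape."""
    shape = tuple(max(sa, sb) for sa, sb in zip(a.shape, b.shape))

    def _pad(m: BinaryVolume) -> BinaryVolume:
        if m.shape == shape:
            return m
        out = np.zeros(shape, dtype=np.uint8)
        out[: m.shape[0], : m.shape[1], : m.shape[2]] = m.data
        return BinaryVolume(out, m.spacing)

    return _pad(a), _pad(b)
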