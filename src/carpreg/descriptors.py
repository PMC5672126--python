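"""Moment-based shape description of a bone mask.

The orientation descriptor of a binary volume is the orthonormal tern of
eigenvectors of its inertia matrix, built from second-order central moments
with negated products of inertia off-diagonal:

    I = [[Ixx, -Ixy, -Ixz],
         [-Ixy, Iyy, -Iyz],
         [-Ixz, -Iyz, Izz]]

with ``Ixx = M020 + M002`` etc. and ``Ixy = M110`` etc.  Two orderings of the
tern are supported:

``largest_first``
    ``e1`` is paired with the *largest* inertia eigenvalue.
``elongation_first``
    ``e1`` is paired with the *smallest* inertia eigenvalue, i.e. the
    physical elongation (long) axis of the body, which is the axis the
    sequential registration aligns first.

Eigenvectors of a symmetric matrix are defined only up to sign;
:func:`orient_axes` disambiguates them either with a fixed rule
(largest-magnitude component positive) or against a reference tern
(non-negative dot products), always restoring a right-handed tern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError
from .volume import BinaryVolume

DEGENERACY_TOL = 1e-6


@dataclass
class ShapeDescriptor:
    """Centroid, inertia matrix and ordered, sign-disambiguated axes.

    ``axes`` holds the unit eigenvectors as columns ``(e1, e2, e3)``;
    ``eigenvalues`` are the matching inertia eigenvalues in the same order.
    ``degenerate`` flags a near-equal eigenvalue pair, in which case the
    corresponding axes are not reliable orientation features.
    """

    centroid: np.ndarray
    inertia: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray
    order: str
    degenerate: bool = False


def _foreground(b: BinaryVolume) -> tuple[np.ndarray, ...]:
    b.require_nonempty()
    return np.nonzero(b.data)


def centroid(b: BinaryVolume) -> np.ndarray:
    """Foreground-weighted mean voxel index ``(x_g, y_g, z_g)``."""
    coords = _foreground(b)
    return np.array([c.mean() for c in coords])


def central_moment(
    b: BinaryVolume, l: int, m: int, n: int, centre: np.ndarray | None = None
) -> float:
    """Central moment ``M_lmn``: sum over foreground of ``dx^l dy^m dz^n``."""
    if min(l, m, n) < 0:
        raise ValueError("moment orders must be non-negative")
    coords = _foreground(b)
    if centre is None:
        centre = np.array([c.mean() for c in coords])
    dx = coords[0] - centre[0]
    dy = coords[1] - centre[1]
    dz = coords[2] - centre[2]
    return float(np.sum(dx**l * dy**m * dz**n))


def inertia_matrix(b: BinaryVolume) -> np.ndarray:
    """3x3 inertia matrix of the mask about its own centroid."""
    coords = _foreground(b)
    centre = np.array([c.mean() for c in coords])
    dx = coords[0] - centre[0]
    dy = coords[1] - centre[1]
    dz = coords[2] - centre[2]
    m200 = float(np.sum(dx * dx))
    m020 = float(np.sum(dy * dy))
    m002 = float(np.sum(dz * dz))
    m110 = float(np.sum(dx * dy))
    m011 = float(np.sum(dy * dz))
    m101 = float(np.sum(dx * dz))
    return np.array(
        [
            [m020 + m002, -m110, -m101],
            [-m110, m200 + m002, -m011],
            [-m101, -m011, m200 + m020],
        ]
    )


def principal_axes(
    inertia: np.ndarray,
    order: str = "largest_first",
    degeneracy_tol: float = DEGENERACY_TOL,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Eigen-decomposition of the inertia matrix in the requested order.

    Returns ``(eigenvalues, axes, degenerate)`` where ``axes`` has the unit
    eigenvectors as columns.  A relative gap between consecutive eigenvalues
    below ``degeneracy_tol`` raises a warning and sets the flag: the affected
    directions are arbitrary within their eigenspace.
    """
    inertia = np.asarray(inertia, dtype=np.float64)
    if not np.allclose(inertia, inertia.T, atol=1e-9):
        raise ValueError("inertia matrix must be symmetric")
    w, v = np.linalg.eigh(inertia)  # ascending
    if order == "elongation_first":
        idx = np.arange(3)
    elif order == "largest_first":
        idx = np.array([2, 1, 0])
    else:
        raise ValueError(f"unknown ordering {order!r}")
    w, v = w[idx], v[:, idx]
    scale = max(abs(w).max(), 1.0)
    gaps = np.abs(np.diff(np.sort(w))) / scale
    degenerate = bool((gaps < degeneracy_tol).any())
    if degenerate:
        warnings.warn(
            "near-degenerate inertia eigenvalues: principal axes unreliable",
            stacklevel=2,
        )
    return w, v, degenerate


def orient_axes(axes: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Resolve the sign ambiguity of an orthonormal eigenvector tern.

    Without a reference each column is flipped so that its largest-magnitude
    component is positive; with a reference tern each column is flipped so
    that ``e_i . ref_i >= 0``.  If the resulting tern is left-handed the
    third axis is flipped to restore handedness.
    """
    out = np.array(axes, dtype=np.float64, copy=True)
    for i in range(3):
        col = out[:, i]
        if reference is None:
            j = int(np.argmax(np.abs(col)))
            if col[j] < 0:
                out[:, i] = -col
        else:
            if float(col @ reference[:, i]) < 0:
                out[:, i] = -col
    if np.linalg.det(out) < 0:
        out[:, 2] = -out[:, 2]
    return out


def describe(
    b: BinaryVolume,
    order: str = "largest_first",
    reference: np.ndarray | None = None,
) -> ShapeDescriptor:
    """Full shape descriptor of a mask (centroid, inertia, oriented axes)."""
    if b.count == 0:
        raise EmptyMaskError("cannot describe an empty mask")
    inertia = inertia_matrix(b)
    w, axes, degenerate = principal_axes(inertia, order=order)
    axes = orient_axes(axes, reference=reference)
    return ShapeDescriptor(
        centroid=centroid(b),
        inertia=inertia,
        eigenvalues=w,
        axes=axes,
        order=order,
        degenerate=degenerate,
    )
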