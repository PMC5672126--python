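"""Per-bone VOI extraction.

The registration contract only needs a binary occupancy mask per bone.
Masks produced by any external segmentation tool enter through
:func:`load_mask`; :func:`segment_seeded` is a simple band-threshold region
growing from a user seed for self-contained use — it keeps the connected
component (26-connectivity by default) of voxels inside the intensity band
that contains the seed.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import SeedError
from .io import read_mask
from .volume import BinaryVolume, GreyVolume

__all__ = ["segment_seeded", "load_mask"]


def segment_seeded(
    v: GreyVolume,
    seed: tuple[int, int, int],
    low: float,
    high: float,
    *,
    keep_connected: bool = True,
    connectivity: int = 26,
) -> BinaryVolume:
    """Grow the bone VOI from a seed voxel within an intensity band.

    Returns the mask of voxels with intensity in ``[low, high]``; with
    ``keep_connected`` (the default) only the connected component containing
    the seed survives.  ``connectivity`` is 26 (vertex) or 6 (face).
    """
    seed = tuple(int(s) for s in seed)
    if any(s < 0 or s >= n for s, n in zip(seed, v.shape)):
        raise SeedError(f"seed {seed} outside volume of shape {v.shape}")
    value = float(v.data[seed])
    if not (low <= value <= high):
        raise SeedError(
            f"seed intensity {value} outside band [{low}, {high}]"
        )
    band = (v.data >= low) & (v.data <= high)
    if not keep_connected:
        return BinaryVolume(band.astype(np.uint8), v.spacing)
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    labels, _ = ndimage.label(band, structure=structure)
    return BinaryVolume((labels == labels[seed]).astype(np.uint8), v.spacing)


def load_mask(path) -> BinaryVolume:
    """Load an externally produced segmentation mask (NIfTI)."""
    return read_mask(path)
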