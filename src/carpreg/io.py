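"""Reading and writing volumes in NIfTI and DICOM-series form.

NIfTI is the working format for grey volumes, masks and label overlays;
DICOM series directories are accepted as acquisition input.  Array axis
order on disk follows the nibabel convention (i, j, k), which this package
maps onto its (x, y, z) convention directly; grey intensities are linearly
rescaled onto [0, 255] at ingest when the source range differs (e.g. 12-bit
DICOM).
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom

from .errors import EmptyMaskError, FormatError, SeriesError
from .volume import BinaryVolume, GreyVolume


def _rescale_0_255(data: np.ndarray) -> np.ndarray:
    lo, hi = float(data.min()), float(data.max())
    if lo >= 0.0 and hi <= 255.0:
        return data.astype(np.float64)
    if hi == lo:
        return np.zeros_like(data, dtype=np.float64)
    return (data.astype(np.float64) - lo) * (255.0 / (hi - lo))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various error types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_volume(path: str | os.PathLike, format: str | None = None) -> GreyVolume:
    """Read a grey volume from a NIfTI file or a DICOM series directory.

    ``format`` is ``'nifti'`` or ``'dicom_series'``; by default directories
    are treated as DICOM series and files as NIfTI.  Intensities outside
    [0, 255] are min-max rescaled onto that range.
    """
    p = Path(path)
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        data, spacing = _read_nifti(p)
        return GreyVolume(_rescale_0_255(data), spacing)
    if format == "dicom_series":
        return _read_dicom_series(p)
    raise ValueError(f"unknown format {format!r}")


def _read_dicom_series(directory: Path) -> GreyVolume:
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    slices = []
    for name in sorted(os.listdir(directory)):
        fp = directory / name
        if not fp.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(fp))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FormatError(f"no readable DICOM images under {directory}")

    ref = slices[0]
    for ds in slices[1:]:
        if (ds.Rows, ds.Columns) != (ref.Rows, ref.Columns):
            raise SeriesError("series slices differ in matrix size")
        if [float(v) for v in ds.PixelSpacing] != [float(v) for v in ref.PixelSpacing]:
            raise SeriesError("series slices differ in pixel spacing")
        if hasattr(ds, "ImageOrientationPatient") and hasattr(ref, "ImageOrientationPatient"):
            if not np.allclose(
                [float(v) for v in ds.ImageOrientationPatient],
                [float(v) for v in ref.ImageOrientationPatient],
                atol=1e-6,
            ):
                raise SeriesError("series slices differ in orientation")

    def _slice_pos(ds) -> float:
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    slices.sort(key=_slice_pos)
    positions = [_slice_pos(ds) for ds in slices]
    if len(slices) > 1:
        steps = np.diff(positions)
        if np.ptp(steps) > 1e-3 or steps[0] == 0:
            raise SeriesError("series slice positions are not uniformly spaced")
        dz = float(abs(steps[0]))
    else:
        dz = float(getattr(ref, "SliceThickness", 1.0) or 1.0)
    # pixel arrays are (row, col) = (y, x); package order is data[x, y, z]
    stack = np.stack([ds.pixel_array.T for ds in slices], axis=2)
    dy, dx = (float(v) for v in ref.PixelSpacing)  # PixelSpacing is (row, col)
    return GreyVolume(_rescale_0_255(stack), (dx, dy, dz))


def write_volume(v: GreyVolume, path: str | os.PathLike) -> None:
    """Write a grey volume as NIfTI; read_volume(write_volume(v)) round-trips."""
    affine = np.diag([*v.spacing, 1.0])
    img = nib.Nifti1Image(v.data.astype(np.float64), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_mask(b: BinaryVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI (uint8, values 0/1, lossless round-trip)."""
    values = np.unique(b.data)
    if not np.isin(values, (0, 1)).all():  # defensive: dataclass enforces this
        raise ValueError("mask must contain only 0/1 values")
    affine = np.diag([*b.spacing, 1.0])
    img = nib.Nifti1Image(b.data.astype(np.uint8), affine)
    img.header.set_zooms(b.spacing)
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, spacing, path: str | os.PathLike,
                 legend: dict[int, str] | None = None) -> None:
    """Write a label volume (e.g. a fusion overlay) plus a JSON colour legend."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(labels.astype(np.uint8), affine), str(path))
    if legend is not None:
        side = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
        with open(f"{side}.json", "w") as fh:
            json.dump({str(k): v for k, v in legend.items()}, fh, indent=2)


def read_mask(path: str | os.PathLike) -> BinaryVolume:
    """Read a binary mask from NIfTI; values > 0 are binarised with a warning."""
    data, spacing = _read_nifti(Path(path))
    values = np.unique(data)
    if not np.isin(values, (0, 1)).all():
        warnings.warn(
            f"mask {path} holds values other than 0/1; binarising (> 0)",
            stacklevel=2,
        )
    binary = (data > 0).astype(np.uint8)
    if binary.sum() == 0:
        raise EmptyMaskError(f"mask {path} has no foreground voxel")
    return BinaryVolume(binary, spacing)
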