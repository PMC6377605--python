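"""CT volume and segmentation-mask I/O.

Arrays are indexed ``(x, y, z)`` with ``z`` the cranio-caudal slice axis;
NIfTI data arrays map onto this convention directly, DICOM slices are
transposed from ``(row, col) = (y, x)`` and stacked along ``z``.  All
geometry is in millimetres.  By default no resampling is performed: native
anisotropic voxels (slice thickness 1-10 mm is typical for abdominal CT)
are analysed as acquired, with :func:`resample_isotropic` available as an
explicit opt-in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AlignmentError, DataError, EmptySegmentationError, GeometryError

__all__ = [
    "CTVolume",
    "SegmentationMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
]

_SPACING_TOL_MM = 1e-3


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield Units with voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise GeometryError("CT volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        if not np.isfinite(self.voxels).all():
            raise DataError("CT volume contains non-finite voxel values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """A binary tumor mask sharing shape/spacing with its paired CTVolume."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or arr.size == 0:
            raise GeometryError("mask must be a non-empty 3D grid")
        self.voxels = (arr > 0).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.foreground_count == 0

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def require_nonempty(self) -> None:
        if self.is_empty:
            raise EmptySegmentationError("segmentation mask has no foreground voxels")


def _nifti_geometry(img) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    zooms = img.header.get_zooms()[:3]
    spacing = tuple(float(z) for z in zooms)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return spacing, origin


def _read_nifti(path: str | os.PathLike) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    spacing, origin = _nifti_geometry(img)
    if not np.isfinite(data).all():
        raise DataError(f"non-finite voxels in {path}")
    return CTVolume(data, spacing, origin)


def _read_dicom_series(path: str | os.PathLike) -> CTVolume:
    import pydicom

    files = sorted(Path(path).glob("*.dcm")) or sorted(
        p for p in Path(path).iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    orientations = {tuple(round(float(v), 6) for v in s.ImageOrientationPatient) for s in slices}
    if len(orientations) != 1:
        raise GeometryError("DICOM slices do not share a single orientation")
    spacings = {tuple(round(float(v), 6) for v in s.PixelSpacing) for s in slices}
    if len(spacings) != 1:
        raise GeometryError("DICOM slices do not share in-plane pixel spacing")

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zpos = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zpos) < 2:
        raise GeometryError("a DICOM series needs at least two slices")
    gaps = np.diff(zpos)
    if gaps.min() <= 0:
        raise GeometryError("duplicate or non-monotone DICOM slice positions")
    if (gaps.max() - gaps.min()) / gaps.mean() > 0.01:
        raise GeometryError(
            f"inconsistent DICOM slice spacing (range {gaps.min():g}-{gaps.max():g} mm)"
        )
    dz = float(gaps.mean())
    dy, dx = (float(v) for v in slices[0].PixelSpacing)  # PixelSpacing = (row, col)

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr.T * slope + intercept)  # (row, col) -> (x, y)
    data = np.stack(planes, axis=2)
    if not np.isfinite(data).all():
        raise DataError(f"non-finite voxels in DICOM series {path}")
    ipp = slices[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(ipp[2]))
    return CTVolume(data, (dx, dy, dz), origin)


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    DICOM voxel values have RescaleSlope/Intercept applied so the result is
    in Hounsfield Units; ``dz`` is the inter-slice distance, and a slice-gap
    variation above 1% raises :class:`GeometryError`.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if format is None:
        format = "dicom_series" if p.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti(p)
    if format == "dicom_series":
        return _read_dicom_series(p)
    raise ValueError(f"unknown format {format!r}")


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a CTVolume as NIfTI, with spacing/origin in the affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.voxels, affine), str(path))


def write_mask(mask: SegmentationMask, path: str | os.PathLike) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


def read_mask(path: str | os.PathLike, reference: CTVolume) -> SegmentationMask:
    """Read a segmentation mask and enforce alignment with ``reference``.

    Any value > 0 is foreground.  Shape must match exactly and spacing within
    1e-3 mm; an empty mask raises :class:`EmptySegmentationError`.
    """
    import nibabel as nib

    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(p))
    data = np.asarray(img.get_fdata())
    spacing, origin = _nifti_geometry(img)
    if data.shape != reference.shape:
        raise AlignmentError(
            f"mask shape {data.shape} does not match volume shape {reference.shape}"
        )
    if any(abs(a - b) > _SPACING_TOL_MM for a, b in zip(spacing, reference.spacing)):
        raise AlignmentError(
            f"mask spacing {spacing} does not match volume spacing {reference.spacing}"
        )
    mask = SegmentationMask(data, reference.spacing, origin)
    mask.require_nonempty()
    return mask


def resample_isotropic(
    volume: CTVolume, mask: SegmentationMask, target_mm: float
) -> tuple[CTVolume, SegmentationMask]:
    """Resample volume (trilinear) and mask (nearest-neighbor) to cubic voxels.

    Disabled by default throughout the pipeline; native-resolution analysis is
    the standard path and resampling is an explicit option.
    """
    from scipy import ndimage

    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    extents = [s * n for s, n in zip(volume.spacing, volume.shape)]
    if any(target_mm > e for e in extents):
        raise GeometryError(
            f"target spacing {target_mm} mm exceeds a volume extent {extents}"
        )
    factors = [s / target_mm for s in volume.spacing]
    vox = ndimage.zoom(volume.voxels, factors, order=1, mode="nearest")
    msk = ndimage.zoom(mask.voxels, factors, order=0, mode="nearest")
    spacing = (target_mm, target_mm, target_mm)
    return (
        CTVolume(vox, spacing, volume.origin),
        SegmentationMask(msk, spacing, mask.origin),
    )
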