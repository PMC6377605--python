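"""Shape and size features of the segmented tumor.

Volume is voxel count times voxel volume; surface area comes from a
marching-cubes triangulation of the binary mask; the maximum 3D diameter is
the largest pairwise distance between boundary voxel centers (computed on
the convex hull, since the diameter is attained at hull vertices).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage import measure

from ..errors import EmptySegmentationError
from ..imaging import SegmentationMask

__all__ = ["shape_features", "sphericity_from_volume_area"]


def sphericity_from_volume_area(volume: float, area: float) -> float:
    """pi^(1/3) (6V)^(2/3) / A — equals 1 for a perfect sphere."""
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


#: pre-mesh smoothing in voxel units; regularizes the staircase artifact of
#: meshing a binary grid (which inflates surface area by ~9% on a sphere)
_MESH_SIGMA_VOX = 0.8


def _surface_area_mm2(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    padded = np.pad(mask.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, _MESH_SIGMA_VOX)
    # tiny structures can be smoothed below the iso-level; mesh them binary
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _max_diameter_mm(mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    # boundary voxels: foreground with at least one face-adjacent background
    eroded = ndimage.binary_erosion(mask, ndimage.generate_binary_structure(3, 1))
    boundary = mask & ~eroded
    pts = np.argwhere(boundary).astype(np.float64) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets: brute force below
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def shape_features(mask: SegmentationMask, spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Compute the 9 shape/size descriptors from a binary mask."""
    mask.require_nonempty()
    sp = tuple(spacing) if spacing is not None else mask.spacing
    m = mask.as_bool()
    voxvol = float(np.prod(sp))
    volume = mask.foreground_count * voxvol
    area = _surface_area_mm2(m, sp)
    sphericity = sphericity_from_volume_area(volume, area)
    r_eq = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return {
        "volume": volume,
        "surface_area": area,
        "sphericity": sphericity,
        "compactness1": volume / (math.sqrt(math.pi) * area ** 1.5),
        "compactness2": 36.0 * math.pi * volume ** 2 / area ** 3,
        "spherical_disproportion": area / (4.0 * math.pi * r_eq ** 2),
        "surface_to_volume_ratio": area / volume,
        "max_diameter_3d": _max_diameter_mm(m, sp),
        "equivalent_diameter": 2.0 * r_eq,
    }
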