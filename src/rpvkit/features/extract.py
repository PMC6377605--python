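"""Full feature-vector extraction.

Shape features are computed once from the mask; first-order, GLCM, GLRLM,
NGTDM and fractal families are computed on the original image and each of
the 8 wavelet sub-bands, every image discretized at the registry's fixed
bin width (anchored at its own masked minimum).  The output is ordered per
registry and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ExtractionError, GeometryError
from ..imaging import CTVolume, SegmentationMask
from ..preprocess import BAND_CODES, discretize_fixed_binwidth, wavelet_decompose
from . import firstorder, fractal, shape, texture
from .registry import FeatureRegistry, build_default_registry

__all__ = ["FeatureVector", "extract_all", "extract_rpv_features"]


@dataclass
class FeatureVector:
    """Ordered feature_name -> value map with its extraction provenance."""

    values: "pd.Series"
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def to_frame(self) -> pd.DataFrame:
        return self.values.rename("value").rename_axis("feature_name").reset_index()


def _per_image_features(
    data: np.ndarray,
    mask_bool: np.ndarray,
    bin_width: float,
    voxel_volume: float,
) -> dict[str, float]:
    out: dict[str, float] = {}
    vals = data[mask_bool]
    fos = firstorder.first_order_features(vals, bin_width=bin_width, voxel_volume=voxel_volume)
    out.update({("FOS", k): v for k, v in fos.items()})
    disc = discretize_fixed_binwidth(data, mask_bool, bin_width)
    out.update({("GLCM", k): v for k, v in texture.glcm_features(disc).items()})
    out.update({("GLRLM", k): v for k, v in texture.glrlm_features(disc).items()})
    out.update({("NGTDM", k): v for k, v in texture.ngtdm_features(disc).items()})
    out.update({("FD", k): v for k, v in fractal.fractal_features(disc).items()})
    return out


def extract_all(
    volume: CTVolume,
    mask: SegmentationMask,
    registry: FeatureRegistry | None = None,
    wavelet: str = "coif1",
    boundary_mode: str = "reflect",
) -> FeatureVector:
    """Extract the full registry-ordered feature vector (657 by default)."""
    if registry is None:
        registry = build_default_registry()
    if volume.shape != mask.shape:
        raise GeometryError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    mask.require_nonempty()
    m = mask.as_bool()
    voxvol = volume.voxel_volume_mm3
    bw = registry.bin_width

    computed: dict[tuple[str, str, str], float] = {}
    for stat, value in shape.shape_features(mask, volume.spacing).items():
        computed[("Shape", stat, "orig")] = value

    images = {"orig": volume.voxels}
    bands = wavelet_decompose(volume, wavelet=wavelet, boundary_mode=boundary_mode)
    images.update({code: bands.bands[code] for code in BAND_CODES})
    for band_name, data in images.items():
        for (family, stat), value in _per_image_features(data, m, bw, voxvol).items():
            computed[(family, stat, band_name)] = value

    names = []
    values = []
    for entry in registry.entries:
        name = entry.name(bw)
        value = computed[(entry.family, entry.stat, entry.band)]
        if not np.isfinite(value):
            raise ExtractionError(f"non-finite value for feature {name}")
        names.append(name)
        values.append(float(value))
    series = pd.Series(values, index=names, dtype=float)
    provenance = {
        "bin_width": bw,
        "wavelet": bands.wavelet_name,
        "boundary_mode": boundary_mode,
        "n_directions": len(texture.DIRECTIONS_13),
        "bands": ("orig",) + BAND_CODES,
    }
    return FeatureVector(values=series, provenance=provenance)


def extract_rpv_features(
    volume: CTVolume,
    mask: SegmentationMask,
    bin_width: float = 25.0,
    wavelet: str = "coif1",
    boundary_mode: str = "reflect",
    bands=None,
) -> dict[str, float]:
    """Compute only the four RPV component features (fast path).

    ``bands`` may carry a precomputed :class:`WaveletBands` for the volume
    (the decomposition is mask-independent), which makes repeated scoring
    under mask perturbations cheap.
    """
    mask.require_nonempty()
    m = mask.as_bool()
    if bands is None:
        bands = wavelet_decompose(volume, wavelet=wavelet, boundary_mode=boundary_mode)
    tag = f"{bin_width:g}HUgl"

    disc_orig = discretize_fixed_binwidth(volume.voxels, m, bin_width)
    fd = fractal.fractal_features(disc_orig)["max"]

    disc_lll = discretize_fixed_binwidth(bands.bands["LLL"], m, bin_width)
    srlgle = texture.glrlm_features(disc_lll)["SRLGLE"]

    disc_hll = discretize_fixed_binwidth(bands.bands["HLL"], m, bin_width)
    contra = texture.ngtdm_features(disc_hll)["Contra"]

    imedian = float(np.median(bands.bands["LHH"][m]))

    return {
        f"FD_max_{tag}": float(fd),
        f"GLRLM_SRLGLE_LLL_{tag}": float(srlgle),
        f"NGTDM_Contra_HLL_{tag}": float(contra),
        "FOS_Imedian_LHH": imedian,
    }
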