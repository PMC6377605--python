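"""The 657-entry feature registry.

Feature names follow the grammar ``FAMILY_stat[_band][_<b>HUgl]``: the band
token is omitted for the original (unfiltered) image, and the discretization
tag (``25HUgl`` at the default 25-unit bin width) is attached only to
statistics computed on the quantized gray levels.  The registry enumerates

* 9 shape/size features (mask only, no band, no tag), and
* 72 per-image features on the original image and each of the 8 wavelet
  sub-bands: 22 first-order, 26 co-occurrence (GLCM), 16 run-length
  (GLRLM), 5 neighborhood gray-tone difference (NGTDM) and 3 box-counting
  fractal statistics,

for a total of 9 + 9 x 72 = 657.  The registry object is the source of
truth for feature count and ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..preprocess import BAND_CODES

__all__ = [
    "FeatureRegistry",
    "build_default_registry",
    "RPV_FEATURE_NAMES",
    "SHAPE_STATS",
    "FOS_RAW_STATS",
    "FOS_HIST_STATS",
    "GLCM_STATS",
    "GLRLM_STATS",
    "NGTDM_STATS",
    "FD_STATS",
]

SHAPE_STATS = (
    "volume",
    "surface_area",
    "sphericity",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "surface_to_volume_ratio",
    "max_diameter_3d",
    "equivalent_diameter",
)

# First-order statistics on raw masked values (no discretization tag) ...
FOS_RAW_STATS = (
    "Imean",
    "Imedian",
    "Imin",
    "Imax",
    "Irange",
    "Ivariance",
    "Isd",
    "Iskewness",
    "Ikurtosis",
    "Ienergy",
    "Itotalenergy",
    "Irms",
    "Imad",
    "Irmad",
    "Iiqr",
    "Ip10",
    "Ip25",
    "Ip75",
    "Ip90",
    "Icov",
)
# ... and on the discretized histogram (tagged).
FOS_HIST_STATS = ("Ientropy", "Iuniformity")

GLCM_STATS = (
    "autocorrelation",
    "joint_average",
    "joint_max",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "id",
    "idn",
    "idmn",
    "inverse_variance",
    "imc1",
    "imc2",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "sum_squares",
    "mcc",
)

GLRLM_STATS = (
    "SRE",
    "LRE",
    "GLN",
    "GLNN",
    "RLN",
    "RLNN",
    "RP",
    "LGLRE",
    "HGLRE",
    "SRLGLE",
    "SRHGLE",
    "LRLGLE",
    "LRHGLE",
    "GLV",
    "RLV",
    "RE",
)

NGTDM_STATS = ("Coarse", "Contra", "Busy", "Complex", "Strength")

FD_STATS = ("max", "mean", "sd")

RPV_FEATURE_NAMES = (
    "FD_max_25HUgl",
    "GLRLM_SRLGLE_LLL_25HUgl",
    "NGTDM_Contra_HLL_25HUgl",
    "FOS_Imedian_LHH",
)


@dataclass(frozen=True)
class RegistryEntry:
    family: str  # Shape / FOS / GLCM / GLRLM / NGTDM / FD
    stat: str
    band: str  # "orig" or one of the 8 sub-band codes
    tagged: bool  # True if the statistic uses the discretized levels

    def name(self, bin_width: float = 25.0) -> str:
        parts = [self.family, self.stat]
        if self.band != "orig":
            parts.append(self.band)
        if self.tagged:
            parts.append(f"{bin_width:g}HUgl")
        return "_".join(parts)


@dataclass
class FeatureRegistry:
    """Ordered enumeration of the feature set; defines names and ordering."""

    entries: tuple[RegistryEntry, ...]
    bin_width: float = 25.0

    def __post_init__(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            raise ValueError("registry contains duplicate feature names")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name(self.bin_width) for e in self.entries]


def build_default_registry(bin_width: float = 25.0) -> FeatureRegistry:
    """Build the default 657-feature registry."""
    entries: list[RegistryEntry] = []
    for stat in SHAPE_STATS:
        entries.append(RegistryEntry("Shape", stat, "orig", False))
    for band in ("orig",) + BAND_CODES:
        for stat in FOS_RAW_STATS:
            entries.append(RegistryEntry("FOS", stat, band, False))
        for stat in FOS_HIST_STATS:
            entries.append(RegistryEntry("FOS", stat, band, True))
        for stat in GLCM_STATS:
            entries.append(RegistryEntry("GLCM", stat, band, True))
        for stat in GLRLM_STATS:
            entries.append(RegistryEntry("GLRLM", stat, band, True))
        for stat in NGTDM_STATS:
            entries.append(RegistryEntry("NGTDM", stat, band, True))
        for stat in FD_STATS:
            entries.append(RegistryEntry("FD", stat, band, True))
    return FeatureRegistry(entries=tuple(entries), bin_width=bin_width)
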