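"""Gray-level discretization and 3D wavelet sub-band decomposition.

Two preprocessing steps feed every texture feature:

* fixed-bin-width discretization of masked intensities (default 25 HU per
  bin, anchored at the masked minimum, half-open bins ``[edge, edge + b)``),
  giving integer gray levels ``1..Ng``;
* a single-level undecimated (shift-invariant) separable wavelet transform
  with the coiflet-1 filter pair, producing 8 sub-bands named by the filter
  applied along each axis in ``(x, y, z)`` order -- e.g. ``HLL`` is
  high-pass along x and low-pass along y and z.  Sub-bands keep the input
  shape so the original segmentation applies voxelwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from .errors import EmptySegmentationError, GeometryError
from .imaging import CTVolume, SegmentationMask

__all__ = [
    "DiscretizedVolume",
    "WaveletBands",
    "BAND_CODES",
    "discretize_fixed_binwidth",
    "wavelet_decompose",
]

#: The 8 sub-band codes, letter order (x, y, z).
BAND_CODES = tuple("".join(c) for c in product("LH", repeat=3))  # LLL ... HHH


@dataclass
class DiscretizedVolume:
    """Integer gray levels 1..Ng inside the mask, 0 outside.

    ``level(v) = floor((I(v) - anchor) / bin_width) + 1`` with the anchor at
    the masked minimum, so a voxel exactly on an upper bin edge belongs to
    the higher bin.
    """

    levels: np.ndarray
    bin_width: float
    anchor: float
    ng: int

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0

    @property
    def masked_voxel_count(self) -> int:
        return int(np.count_nonzero(self.levels))


@dataclass
class WaveletBands:
    """The 8 filtered sub-bands of a volume, keyed by {L,H}^3 code."""

    bands: dict[str, np.ndarray]
    wavelet_name: str = "coiflet-1"
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if set(self.bands) != set(BAND_CODES):
            raise ValueError(f"expected bands {BAND_CODES}, got {sorted(self.bands)}")
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise ValueError("all sub-bands must share one shape")


def discretize_fixed_binwidth(
    volume: CTVolume | np.ndarray,
    mask: SegmentationMask | np.ndarray,
    bin_width: float = 25.0,
) -> DiscretizedVolume:
    """Quantize masked intensities into fixed-width bins.

    Accepts either a :class:`CTVolume` or a raw array (wavelet sub-bands are
    discretized with the same rule and bin width, anchored at their own
    masked minimum).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    data = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume, float)
    m = mask.as_bool() if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    if data.shape != m.shape:
        raise GeometryError(f"volume shape {data.shape} != mask shape {m.shape}")
    if not m.any():
        raise EmptySegmentationError("cannot discretize an empty segmentation")
    vals = data[m]
    anchor = float(vals.min())
    levels = np.zeros(data.shape, dtype=np.int32)
    levels[m] = np.floor((vals - anchor) / bin_width).astype(np.int64) + 1
    ng = int(levels.max())
    return DiscretizedVolume(levels=levels, bin_width=float(bin_width), anchor=anchor, ng=ng)


def _separable_filter(data: np.ndarray, taps: tuple[np.ndarray, ...], mode: str) -> np.ndarray:
    out = data
    for axis, h in enumerate(taps):
        out = ndimage.convolve1d(out, h, axis=axis, mode=mode)
    return out


def wavelet_decompose(
    volume: CTVolume | np.ndarray,
    wavelet: str = "coif1",
    boundary_mode: str = "reflect",
) -> WaveletBands:
    """Single-level undecimated separable 3D wavelet transform.

    Band ``XYZ`` applies filter X along x, Y along y and Z along z, by true
    convolution with symmetric (mirror) boundary extension; the output grids
    keep the input shape.  The default filter pair is coiflet-1 (6 taps).
    """
    data = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume, float)
    wav = pywt.Wavelet(wavelet)
    lo = np.asarray(wav.dec_lo, dtype=np.float64)
    hi = np.asarray(wav.dec_hi, dtype=np.float64)
    flen = len(lo)
    if any(n < flen for n in data.shape):
        raise GeometryError(
            f"every dimension must be >= filter length {flen}, got shape {data.shape}"
        )
    filt = {"L": lo, "H": hi}
    bands = {
        code: _separable_filter(data, tuple(filt[c] for c in code), boundary_mode)
        for code in BAND_CODES
    }
    name = "coiflet-1" if wavelet == "coif1" else wavelet
    return WaveletBands(bands=bands, wavelet_name=name, boundary_mode=boundary_mode)
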