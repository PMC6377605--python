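"""Box-counting fractal dimension of thresholded gray-level sets.

For each occupied gray level t the binary set {level >= t} inside the mask
bounding box is box-counted over dyadic box sizes 1, 2, 4, ... and the
dimension is the least-squares slope of log N(eps) against log(1/eps).
FD_max / FD_mean / FD_sd summarize the per-threshold dimensions — the
reading under which a "maximal fractal dimension" feature is well defined.
"""

from __future__ import annotations

import numpy as np

from ..errors import EmptySegmentationError
from ..preprocess import DiscretizedVolume

__all__ = ["box_counting_dimension", "fractal_features"]


def _box_count(binary: np.ndarray, eps: int) -> int:
    """Number of eps-sized grid boxes containing at least one set voxel."""
    padded = binary
    pads = [(0, (-n) % eps) for n in binary.shape]
    if any(p[1] for p in pads):
        padded = np.pad(binary, pads)
    view = padded.reshape(
        padded.shape[0] // eps, eps, padded.shape[1] // eps, eps, padded.shape[2] // eps, eps
    )
    return int(view.any(axis=(1, 3, 5)).sum())


def box_counting_dimension(binary: np.ndarray, min_sizes: int = 3) -> float:
    """Least-squares slope of log N(eps) vs log(1/eps) over dyadic sizes.

    Returns NaN when fewer than ``min_sizes`` box sizes are usable (set or
    bounding box too small) — the caller decides how to flag that.
    """
    binary = np.asarray(binary, bool)
    if not binary.any():
        return float("nan")
    sizes = []
    eps = 1
    limit = max(binary.shape)
    while eps <= limit // 2 or eps == 1:
        sizes.append(eps)
        eps *= 2
    if len(sizes) < min_sizes:
        return float("nan")
    counts = np.array([_box_count(binary, e) for e in sizes], dtype=np.float64)
    x = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    y = np.log(counts)
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def fractal_features(disc: DiscretizedVolume) -> dict[str, float]:
    """FD max/mean/sd over the per-threshold box-counting dimensions.

    Degenerate regions (too small for 3 dyadic box sizes) yield NaN, which
    the extraction layer reports as an error naming the feature.
    """
    m = disc.mask
    if not m.any():
        raise EmptySegmentationError("fractal features need a non-empty mask")
    idx = np.argwhere(m)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    lv = disc.levels[box]
    dims = []
    for t in range(1, disc.ng + 1):
        binary = lv >= t
        if not binary.any():
            continue  # unoccupied upper threshold
        dims.append(box_counting_dimension(binary))
    dims = np.asarray(dims, dtype=np.float64)
    return {
        "max": float(np.max(dims)) if dims.size else float("nan"),
        "mean": float(np.mean(dims)) if dims.size else float("nan"),
        "sd": float(np.std(dims)) if dims.size else float("nan"),
    }
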