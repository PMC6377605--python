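"""First-order (intensity distribution) statistics.

Raw-value statistics use the masked sample directly; entropy and uniformity
are computed on the fixed-bin-width histogram (the same 25-unit quantization
used by the texture families).  Population (n-denominator) moments are used
throughout so single-voxel regions stay finite.  Degenerate conventions:
coefficient of variation is 0 for a zero-mean sample, entropy 0 and
uniformity 1 for a single occupied bin.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["first_order_features", "histogram_probabilities"]


def histogram_probabilities(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Occupancy probabilities of fixed-width bins anchored at the minimum."""
    v = np.asarray(values, dtype=np.float64).ravel()
    levels = np.floor((v - v.min()) / bin_width).astype(np.int64)
    counts = np.bincount(levels)
    return counts[counts > 0] / v.size


def first_order_features(
    values: np.ndarray,
    bin_width: float = 25.0,
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("first-order features need at least one value")
    mean = float(v.mean())
    sd = float(v.std())  # population
    p10, p25, p75, p90 = (float(np.percentile(v, q)) for q in (10, 25, 75, 90))
    core = v[(v >= p10) & (v <= p90)]
    p = histogram_probabilities(v, bin_width)
    out = {
        "Imean": mean,
        "Imedian": float(np.median(v)),
        "Imin": float(v.min()),
        "Imax": float(v.max()),
        "Irange": float(v.max() - v.min()),
        "Ivariance": float(v.var()),
        "Isd": sd,
        "Iskewness": float(stats.skew(v)) if sd > 0 else 0.0,
        "Ikurtosis": float(stats.kurtosis(v, fisher=False)) if sd > 0 else 0.0,
        "Ienergy": float(np.sum(v * v)),
        "Itotalenergy": float(voxel_volume * np.sum(v * v)),
        "Irms": float(np.sqrt(np.mean(v * v))),
        "Imad": float(np.mean(np.abs(v - mean))),
        "Irmad": float(np.mean(np.abs(core - core.mean()))) if core.size else 0.0,
        "Iiqr": p75 - p25,
        "Ip10": p10,
        "Ip25": p25,
        "Ip75": p75,
        "Ip90": p90,
        "Icov": sd / mean if abs(mean) > 1e-12 else 0.0,
        "Ientropy": float(-np.sum(p * np.log2(p))),
        "Iuniformity": float(np.sum(p * p)),
    }
    return out
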