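"""The Radiomic Prognostic Vector (RPV).

RPV is the weighted sum of four radiomic features of the primary ovarian
tumor — the maximal fractal dimension, short-run low-gray-level emphasis of
the LLL sub-band, NGTDM contrast of the HLL sub-band, and the median
intensity of the LHH sub-band — with published coefficients
(-0.0876, 0.0869, 0.165, 0.250).  Patients are stratified into low /
medium / high risk at the published score boundaries 0.0950 and 0.658
(half-open intervals; a score exactly at 0.658 is high risk).  For
bilateral tumors the patient's score is the higher of the two tumor RPVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .features.registry import RPV_FEATURE_NAMES

__all__ = [
    "RPVModel",
    "DEFAULT_RPV_MODEL",
    "compute_rpv",
    "assign_risk_group",
    "select_bilateral",
    "standardize_cohort",
]


@dataclass(frozen=True)
class RPVModel:
    """The 4 feature names, their coefficients and the risk boundaries."""

    features: tuple[str, ...] = RPV_FEATURE_NAMES
    coefficients: tuple[float, ...] = (-0.0876, 0.0869, 0.165, 0.250)
    boundaries: tuple[float, ...] = (0.0950, 0.658)
    group_labels: tuple[str, ...] = ("low", "medium", "high")

    def __post_init__(self) -> None:
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients must have equal length")
        if list(self.boundaries) != sorted(self.boundaries) or len(set(self.boundaries)) != len(
            self.boundaries
        ):
            raise ValueError("boundaries must be strictly increasing")
        if len(self.group_labels) != len(self.boundaries) + 1:
            raise ValueError("need one more group label than boundaries")


DEFAULT_RPV_MODEL = RPVModel()


def compute_rpv(features, model: RPVModel = DEFAULT_RPV_MODEL) -> float:
    """Score = sum of coefficient_i * feature_i over the model's features.

    ``features`` may be a FeatureVector, a mapping, or a pandas Series.
    Missing features raise a KeyError naming all absent keys.
    """
    if hasattr(features, "values") and isinstance(features.values, pd.Series):
        features = features.values
    missing = [f for f in model.features if f not in features]
    if missing:
        raise KeyError(f"feature vector is missing RPV features: {missing}")
    return float(
        sum(c * float(features[f]) for f, c in zip(model.features, model.coefficients))
    )


def assign_risk_group(score: float, model: RPVModel = DEFAULT_RPV_MODEL) -> str:
    """Half-open risk intervals; the top group includes its lower boundary."""
    if not np.isfinite(score):
        raise ValueError(f"risk group undefined for non-finite score {score}")
    idx = int(np.searchsorted(model.boundaries, score, side="right"))
    return model.group_labels[idx]


def select_bilateral(scores: Mapping) -> tuple[float, object]:
    """Pick the higher-RPV tumor for a patient; ties break on sorted tumor id."""
    if not scores:
        raise ValueError("select_bilateral needs at least one tumor score")
    best_id = max(sorted(scores, key=str), key=lambda k: scores[k])
    return float(scores[best_id]), best_id


def standardize_cohort(
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-wise (x - mean) / sd with the cohort's own statistics (sd uses n-1).

    Constant columns pass through as 0 with a warning.  Returns the
    standardized table and a (mean, sd) per-feature summary.
    """
    if len(features) < 2:
        raise ValueError("standardization needs at least two rows")
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=1)
    zero = sd <= 0
    if zero.any():
        warnings.warn(
            f"constant features passed through as 0: {list(features.columns[zero])}",
            stacklevel=2,
        )
    safe_sd = sd.mask(zero, 1.0)
    out = (features - mean) / safe_sd
    out.loc[:, zero] = 0.0
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return out, stats
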