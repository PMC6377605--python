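"""Reliability analyses: segmentation-perturbation stability of RPV,
feature-wise reproducibility between cohorts, and PCA batch screening.

Mask deformations are |k| iterations of binary erosion (k < 0) or dilation
(k > 0) with the 6-connected (face-adjacent) structuring element, so
"k voxels" means k morphological steps.  Erosion down to an empty mask is
flagged, never a crash, and flagged tumors are excluded from per-k summary
statistics with an explicit count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .features.extract import extract_rpv_features
from .imaging import CTVolume, SegmentationMask
from .preprocess import wavelet_decompose
from .rpv import DEFAULT_RPV_MODEL, RPVModel, compute_rpv

__all__ = [
    "PerturbationSpec",
    "StabilityReport",
    "perturb_mask",
    "rpv_stability",
    "cohort_stability",
    "featurewise_reproducibility",
    "pca_batch_check",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Deformation range in voxels: negative = erosion, positive = dilation."""

    k_min: int = -4
    k_max: int = 4

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise ValueError("k_min must not exceed k_max")

    @property
    def ks(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))


def perturb_mask(mask: SegmentationMask, k: int) -> SegmentationMask:
    """Erode (k<0) or dilate (k>0) by |k| 6-connected morphological steps."""
    if int(k) != k:
        raise ValueError("k must be an integer number of voxels")
    k = int(k)
    if k == 0:
        return SegmentationMask(mask.voxels.copy(), mask.spacing, mask.origin)
    struct = ndimage.generate_binary_structure(3, 1)
    m = mask.as_bool()
    if k > 0:
        out = ndimage.binary_dilation(m, struct, iterations=k)
    else:
        out = ndimage.binary_erosion(m, struct, iterations=-k)
    return SegmentationMask(out.astype(np.uint8), mask.spacing, mask.origin)


@dataclass
class StabilityReport:
    """Per-(tumor, k) RPV differences plus per-k summary statistics."""

    rows: pd.DataFrame  # tumor, k, rpv, delta_rpv, flag
    summary: pd.DataFrame  # k, mean_delta, sd_delta, n, n_empty

    @property
    def delta_vs_k_rank_correlation(self) -> float:
        """Spearman correlation between deformation step and RPV change.

        Reported as a diagnostic of how the score responds to boundary
        growth/shrinkage; its sign depends on the contrast between tumor
        and surrounding tissue.
        """
        ok = self.rows[(self.rows["flag"] == "") & (self.rows["k"] != 0)]
        if len(ok) < 3:
            return float("nan")
        return float(stats.spearmanr(ok["k"], ok["delta_rpv"])[0])

    @staticmethod
    def summarize(rows: pd.DataFrame) -> pd.DataFrame:
        recs = []
        for k, grp in rows.groupby("k"):
            ok = grp[grp["flag"] == ""]
            recs.append(
                {
                    "k": k,
                    "mean_delta": float(ok["delta_rpv"].mean()) if len(ok) else float("nan"),
                    "sd_delta": float(ok["delta_rpv"].std(ddof=0)) if len(ok) else float("nan"),
                    "n": len(ok),
                    "n_empty": int((grp["flag"] == "empty").sum()),
                }
            )
        return pd.DataFrame(recs)


def rpv_stability(
    volume: CTVolume,
    mask: SegmentationMask,
    spec: PerturbationSpec = PerturbationSpec(),
    model: RPVModel = DEFAULT_RPV_MODEL,
    tumor: str = "tumor",
    bin_width: float = 25.0,
) -> StabilityReport:
    """Recompute the four RPV features under each mask deformation.

    The wavelet decomposition is mask-independent and computed once.
    """
    bands = wavelet_decompose(volume)
    base = compute_rpv(
        extract_rpv_features(volume, mask, bin_width=bin_width, bands=bands), model
    )
    rows = []
    for k in spec.ks:
        deformed = perturb_mask(mask, k)
        if deformed.is_empty:
            rows.append(
                {"tumor": tumor, "k": k, "rpv": float("nan"), "delta_rpv": float("nan"), "flag": "empty"}
            )
            continue
        score = compute_rpv(
            extract_rpv_features(volume, deformed, bin_width=bin_width, bands=bands), model
        )
        rows.append(
            {"tumor": tumor, "k": k, "rpv": score, "delta_rpv": score - base, "flag": ""}
        )
    df = pd.DataFrame(rows)
    return StabilityReport(rows=df, summary=StabilityReport.summarize(df))


def cohort_stability(
    tumors: dict[str, tuple[CTVolume, SegmentationMask]],
    spec: PerturbationSpec = PerturbationSpec(),
    model: RPVModel = DEFAULT_RPV_MODEL,
) -> StabilityReport:
    """Stack per-tumor stability rows and summarize per deformation step."""
    frames = [
        rpv_stability(vol, msk, spec=spec, model=model, tumor=name).rows
        for name, (vol, msk) in tumors.items()
    ]
    rows = pd.concat(frames, ignore_index=True)
    return StabilityReport(rows=rows, summary=StabilityReport.summarize(rows))


def featurewise_reproducibility(
    cohort_a: pd.DataFrame, cohort_b: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Correlation of feature-feature correlation structure across cohorts.

    Computes the feature-by-feature Pearson matrix within each cohort,
    vectorizes the strict upper triangles, and returns their Pearson
    correlation together with the paired scatter table.  Constant features
    in either cohort are excluded with a warning.
    """
    common = [c for c in cohort_a.columns if c in cohort_b.columns]
    if len(common) < 2:
        raise ValueError("cohorts must share at least two features")
    if len(cohort_a) < 3 or len(cohort_b) < 3:
        raise ValueError("each cohort needs at least three samples")
    a = cohort_a[common].to_numpy(float)
    b = cohort_b[common].to_numpy(float)
    keep = (a.std(axis=0) > 0) & (b.std(axis=0) > 0)
    if not keep.all():
        dropped = [c for c, k in zip(common, keep) if not k]
        warnings.warn(f"excluding constant features: {dropped}", stacklevel=2)
    names = [c for c, k in zip(common, keep) if k]
    ca = np.corrcoef(a[:, keep], rowvar=False)
    cb = np.corrcoef(b[:, keep], rowvar=False)
    iu = np.triu_indices(len(names), k=1)
    table = pd.DataFrame(
        {
            "feature_i": [names[i] for i in iu[0]],
            "feature_j": [names[j] for j in iu[1]],
            "corr_a": ca[iu],
            "corr_b": cb[iu],
        }
    )
    r = float(stats.pearsonr(ca[iu], cb[iu])[0])
    return r, table


def pca_batch_check(
    features: pd.DataFrame,
    batch_labels,
    n_components: int = 5,
) -> pd.DataFrame:
    """Association of leading PCs with batch (Kruskal-Wallis, BH-adjusted).

    Features are standardized before PCA; constant features are dropped.
    Returns per-PC variance explained, raw and adjusted p-values.
    """
    from sklearn.decomposition import PCA

    from .discovery import benjamini_hochberg

    labels = np.asarray(batch_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("batch check needs at least two batches")
    if counts.min() < 3:
        raise ValueError("each batch needs at least three samples")
    x = features.to_numpy(float)
    keep = x.std(axis=0) > 0
    x = x[:, keep]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    k = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k, random_state=0)
    pcs = pca.fit_transform(x)
    pvals = [
        float(stats.kruskal(*(pcs[labels == g, i] for g in uniq)).pvalue)
        for i in range(k)
    ]
    qvals, _ = benjamini_hochberg(pvals, q=0.05)
    return pd.DataFrame(
        {
            "pc": [f"PC{i+1}" for i in range(k)],
            "variance_explained": pca.explained_variance_ratio_[:k],
            "p": pvals,
            "q": qvals,
        }
    )
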