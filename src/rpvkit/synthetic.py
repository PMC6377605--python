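"""Deterministic synthetic data: tumor-like CT phantoms and survival cohorts.

The phantom emulates a segmented tubo-ovarian mass on contrast-enhanced CT:
an ellipsoidal tumor with an enhancing solid rim (~60 HU) around a cystic
fluid core (~10 HU), embedded in fatty/parenchymal background (~-80 HU),
with a smooth Gaussian-random-field texture superimposed.  The cohort
generator draws block-correlated feature vectors, plants a sparse linear
signature in an exponential proportional-hazards model, censors with a
uniform administrative window, and gives a fraction of patients two highly
correlated bilateral tumor rows — the statistical shape of the discovery
problem (42 screened candidates reduced to a 4-feature signature).

Every artifact draws from its own pseudo-random stream derived from the
user seed by stable sub-seeding, so adding a generator call never perturbs
existing fixtures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import SpecError
from .imaging import CTVolume, SegmentationMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "default_phantom",
    "default_cohort",
    "CohortTable",
]


def _rng(seed: int, label: str) -> np.random.Generator:
    """Stable per-artifact stream: user seed + artifact label."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


# ---------------------------------------------------------------------------
# phantom


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center: tuple[float, float, float] | None = None  # default: grid center
    semi_axes: tuple[float, float, float] = (20.0, 22.0, 18.0)
    rim_hu_mean: float = 60.0
    rim_hu_sd: float = 15.0
    core_hu_mean: float = 10.0
    core_hu_sd: float = 8.0
    core_fraction: float = 0.4  # volume fraction of the cystic core
    background_hu: float = 30.0  # soft-tissue parenchyma around the mass
    texture_sd: float = 20.0
    texture_corr_length: float = 2.0  # voxels
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.center if self.center is not None else tuple((n - 1) / 2 for n in self.shape)
        self.center = tuple(float(v) for v in c)
        for ci, ai, ni in zip(self.center, self.semi_axes, self.shape):
            if ci - ai < -0.5 or ci + ai > ni - 0.5:
                raise SpecError(f"tumor (center {self.center}, semi-axes {self.semi_axes}) exceeds grid {self.shape}")
        for hu in (self.rim_hu_mean, self.core_hu_mean, self.background_hu):
            if not -1000.0 <= hu <= 3000.0:
                raise SpecError(f"HU mean {hu} outside [-1000, 3000]")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise SpecError("core_fraction must be in [0, 1]")


def _gaussian_random_field(rng, shape, corr_length, sd) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr_length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr_length, mode="reflect")
        noise /= noise.std()
    return noise * sd


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, SegmentationMask]:
    """Generate a (CTVolume, SegmentationMask) pair from a PhantomSpec."""
    rng = _rng(spec.seed, "phantom")
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in spec.shape), indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, spec.center, spec.semi_axes))
    rho = np.sqrt(rho2)
    mask = rho <= 1.0
    core = rho <= spec.core_fraction ** (1.0 / 3.0)  # equal-volume-fraction shell cut

    image = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    rim = mask & ~core
    image[rim] = rng.normal(spec.rim_hu_mean, spec.rim_hu_sd, size=int(rim.sum()))
    image[core] = rng.normal(spec.core_hu_mean, spec.core_hu_sd, size=int(core.sum()))
    image += _gaussian_random_field(rng, spec.shape, spec.texture_corr_length, spec.texture_sd)

    return (
        CTVolume(image, spec.spacing),
        SegmentationMask(mask.astype(np.uint8), spec.spacing),
    )


def default_phantom(seed: int = 20) -> tuple[CTVolume, SegmentationMask]:
    """The shipped 64^3 phantom fixture (deterministic for a given seed)."""
    return generate_phantom(PhantomSpec(seed=seed))


# ---------------------------------------------------------------------------
# cohort


@dataclass
class CohortTable:
    """Patient/tumor-level cohort: one row per tumor, survival per patient.

    Columns: patient_id, tumor_id, laterality, time (months), event (0/1),
    stage (ordinal 1-4), age (years), residual_disease (0/1),
    slice_thickness (mm), neoadjuvant (0/1), plus the feature columns.
    """

    data: pd.DataFrame
    feature_columns: list[str]
    time_column: str = "time"
    event_column: str = "event"

    def __post_init__(self) -> None:
        df = self.data
        required = {"patient_id", "tumor_id", self.time_column, self.event_column}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table is missing columns {sorted(missing)}")
        if (df[self.time_column] < 0).any():
            raise ValueError("survival times must be non-negative")
        if not df[self.event_column].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")
        per_patient = df.groupby("patient_id").size()
        if (per_patient > 2).any():
            raise ValueError("at most two tumors per patient")

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def n_events(self) -> int:
        return int(
            self.data.drop_duplicates("patient_id")[self.event_column].sum()
        )


@dataclass
class CohortSpec:
    n: int = 400
    n_features: int = 42
    block_size: int = 6
    rho: float = 0.3  # within-block feature correlation
    signature_indices: tuple[int, ...] = (0, 6, 12, 18)  # one per block
    signature_log_hrs: tuple[float, ...] = (0.8, -0.8, 0.6, -0.6)
    baseline_rate: float = float(np.log(2) / 36.0)  # median 36 months
    censor_window: float = 72.0  # uniform administrative censoring, months
    bilateral_fraction: float = 0.15
    bilateral_noise_sd: float = 0.2
    feature_prefix: str = "feat"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.signature_indices) != len(self.signature_log_hrs):
            raise SpecError("signature indices and log-HRs must have equal length")
        if any(i >= self.n_features for i in self.signature_indices):
            raise SpecError("signature index outside feature range")
        if self.censor_window <= 0:
            raise SpecError("censoring window must be positive")
        m = min(self.block_size, self.n_features)
        if m > 1 and self.rho < -1.0 / (m - 1) or self.rho >= 1.0:
            raise SpecError(
                f"block correlation {self.rho} is not positive semidefinite for block size {m}"
            )

    @property
    def feature_names(self) -> list[str]:
        width = len(str(self.n_features))
        return [f"{self.feature_prefix}_{i + 1:0{width}d}" for i in range(self.n_features)]

    def beta(self) -> np.ndarray:
        b = np.zeros(self.n_features)
        for i, lh in zip(self.signature_indices, self.signature_log_hrs):
            b[i] = lh
        return b


def _block_correlated_features(rng, n: int, spec: CohortSpec) -> np.ndarray:
    """Draw N(0, Sigma) with Sigma block-diagonal, off-diagonal rho per block."""
    x = np.empty((n, spec.n_features))
    for start in range(0, spec.n_features, spec.block_size):
        m = min(spec.block_size, spec.n_features - start)
        cov = np.full((m, m), spec.rho)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        x[:, start : start + m] = rng.standard_normal((n, m)) @ chol.T
    return x


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a proportional-hazards cohort with a planted sparse signature."""
    rng = _rng(spec.seed, "cohort")
    n = spec.n
    x = _block_correlated_features(rng, n, spec)
    beta = spec.beta()
    eta = x @ beta

    # exponential PH survival with uniform administrative censoring
    t_event = rng.exponential(1.0 / (spec.baseline_rate * np.exp(eta)))
    t_cens = rng.uniform(0.0, spec.censor_window, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.10, 0.55, 0.30])
    age = rng.normal(62.0, 10.0, size=n)
    residual = rng.binomial(1, 0.45, size=n)
    thickness = rng.choice([1.0, 2.0, 3.0, 5.0], size=n, p=[0.2, 0.3, 0.3, 0.2])
    neoadjuvant = rng.binomial(1, 0.25, size=n)
    bilateral = rng.random(n) < spec.bilateral_fraction

    rows = []
    for i in range(n):
        base = {
            "patient_id": f"P{i + 1:04d}",
            "time": float(time[i]),
            "event": int(event[i]),
            "stage": int(stage[i]),
            "age": float(age[i]),
            "residual_disease": int(residual[i]),
            "slice_thickness": float(thickness[i]),
            "neoadjuvant": int(neoadjuvant[i]),
            "true_linear_predictor": float(eta[i]),
        }
        n_tumors = 2 if bilateral[i] else 1
        for t in range(n_tumors):
            row = dict(base)
            row["tumor_id"] = "AB"[t]
            row["laterality"] = ["left", "right"][t]
            feats = x[i] + (
                rng.normal(0.0, spec.bilateral_noise_sd, size=spec.n_features) if t == 1 else 0.0
            )
            row.update(dict(zip(spec.feature_names, feats)))
            rows.append(row)
    df = pd.DataFrame(rows)
    return CohortTable(data=df, feature_columns=spec.feature_names)


def default_cohort(seed: int = 11) -> CohortTable:
    """The shipped n=400 cohort fixture: 4 planted effects among 42 candidates."""
    return generate_cohort(CohortSpec(seed=seed))
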