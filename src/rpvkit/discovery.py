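"""Signature discovery: the pipeline that produces an RPV-style model.

The stages mirror the published procedure: an adjusted univariate Cox
screen over all radiomic features with Benjamini-Hochberg FDR control,
L1-penalized Cox regression (lambda at minimum 10-fold cross-validated
partial-likelihood deviance) to reduce the screened set to a sparse
weighted signature, 1D k-means to cut the score distribution into three
risk groups, and prognostic evaluation (Cox hazard ratios, concordance
index, log-rank, Kaplan-Meier).  Bilateral tumors enter screening and
LASSO as separate rows; at scoring/evaluation each patient keeps the
higher-RPV tumor.

Cross-validated deviance follows Verweij & van Houwelingen:
dev_k(lambda) = -2 [pl(beta_-k; all) - pl(beta_-k; train_-k)], with the
Breslow partial likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import RpvKitError
from .rpv import select_bilateral
from .synthetic import CohortTable

__all__ = [
    "ScreenResult",
    "SignatureModel",
    "EvaluationResult",
    "DEFAULT_ADJUSTERS",
    "benjamini_hochberg",
    "univariate_cox_screen",
    "lasso_cox_select",
    "kmeans_groups",
    "evaluate_model",
    "sample_size_survival",
    "hierarchical_cluster",
    "similarity_profile_cluster",
    "patient_level_scores",
]

DEFAULT_ADJUSTERS = ("stage", "slice_thickness", "residual_disease")


# ---------------------------------------------------------------------------
# multiple testing


def benjamini_hochberg(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH q-values (monotone) and strict pass flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, qvals < q


# ---------------------------------------------------------------------------
# univariate screen


@dataclass
class ScreenResult:
    """Per-feature hazard ratios, p-values, BH q-values and pass flags."""

    table: pd.DataFrame  # columns: feature, hr, p, q, passed, converged
    q_threshold: float
    adjusters: tuple[str, ...]

    @property
    def passing_features(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "feature"])


def _fit_single_cox(time, event, exog) -> tuple[float, float, bool]:
    """Wald HR and p for the first column of ``exog`` in a PH fit."""
    from statsmodels.duration.hazard_regression import PHReg

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = PHReg(time, exog, status=event, ties="efron").fit(
                method="lbfgs", disp=False
            )
        beta = float(res.params[0])
        se = float(res.bse[0])
        if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
            return float("nan"), 1.0, False
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        return math.exp(beta), float(p), True
    except Exception:
        return float("nan"), 1.0, False


def univariate_cox_screen(
    cohort: CohortTable,
    endpoint_time: str | None = None,
    endpoint_event: str | None = None,
    adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS,
    q: float = 0.05,
    features: list[str] | None = None,
) -> ScreenResult:
    """Adjusted univariate Cox screen with BH-FDR over all features.

    Each feature is fit in a model containing the feature plus the
    adjusters; the feature's Wald p-value is BH-corrected across features.
    All tumor rows (including both bilateral tumors) enter as rows.
    """
    df = cohort.data
    tcol = endpoint_time or cohort.time_column
    ecol = endpoint_event or cohort.event_column
    feats = features if features is not None else cohort.feature_columns
    if int(df.drop_duplicates("patient_id")[ecol].sum()) < 2:
        raise RpvKitError("univariate screen needs at least two events")
    time = df[tcol].to_numpy(float)
    event = df[ecol].to_numpy(float)
    adj = df[list(adjusters)].to_numpy(float) if adjusters else np.empty((len(df), 0))

    rows = []
    for f in feats:
        exog = np.column_stack([df[f].to_numpy(float), adj])
        hr, p, ok = _fit_single_cox(time, event, exog)
        rows.append({"feature": f, "hr": hr, "p": p, "converged": ok})
    table = pd.DataFrame(rows)
    bad = ~table["converged"]
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} features did not converge; p set to 1", stacklevel=2
        )
    table["q"], table["passed"] = benjamini_hochberg(table["p"].to_numpy(), q)
    return ScreenResult(table=table, q_threshold=q, adjusters=tuple(adjusters))


# ---------------------------------------------------------------------------
# penalized Cox selection


def _breslow_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    order = np.argsort(-time, kind="stable")  # decreasing time
    eta_o = eta[order]
    t_o = time[order]
    e_o = event[order]
    log_risk = np.logaddexp.accumulate(eta_o)
    # ties: every death at time t uses the risk set {j : t_j >= t}
    # -> within tied times, use the last cumulative value of the tie block
    _, inverse, counts = np.unique(-t_o, return_inverse=True, return_counts=True)
    block_end = np.cumsum(counts) - 1
    log_risk_tied = log_risk[block_end[inverse]]
    deaths = e_o > 0
    return float(np.sum(eta_o[deaths] - log_risk_tied[deaths]))


@dataclass
class SignatureModel:
    """Selected features and coefficients at the CV-optimal penalty."""

    features: list[str]
    coefficients: np.ndarray
    lambda_: float
    alphas: np.ndarray
    cv_deviance: np.ndarray  # mean over folds, one entry per alpha
    folds: int
    seed: int
    candidate_features: list[str] = field(default_factory=list)

    def score(self, features: pd.DataFrame) -> np.ndarray:
        """Linear predictor of the signature on a feature table."""
        if not self.features:
            return np.zeros(len(features))
        return features[self.features].to_numpy(float) @ self.coefficients


def _event_stratified_folds(event: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold labels stratified by event status so no fold is event-free."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(event), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(event == value)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def lasso_cox_select(
    cohort: CohortTable,
    candidate_features: list[str],
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> SignatureModel:
    """L1-penalized Cox over a descending penalty path, lambda at min CV deviance."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if not candidate_features:
        raise ValueError("need at least one candidate feature")
    df = cohort.data
    time = df[cohort.time_column].to_numpy(float)
    event = df[cohort.event_column].to_numpy(float)
    n_events = int(event.sum())
    if n_events == 0:
        raise RpvKitError("penalized Cox selection needs uncensored events")
    if n_events < folds:
        raise RpvKitError(f"need at least {folds} events for {folds}-fold CV")
    x = df[candidate_features].to_numpy(float)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio
    )
    full.fit(x, y)
    alphas = np.asarray(full.alphas_)

    fold_of = _event_stratified_folds(event, folds, seed)
    dev = np.zeros((folds, len(alphas)))
    for k in range(folds):
        tr = fold_of != k
        cv_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_fit.fit(x[tr], y[tr])
        coefs = cv_fit.coef_  # (n_features, n_alphas_fit)
        fit_alphas = np.asarray(cv_fit.alphas_)
        for a_idx, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fit_alphas - alpha)))
            beta = coefs[:, j]
            pl_all = _breslow_partial_loglik(x @ beta, time, event)
            pl_train = _breslow_partial_loglik(x[tr] @ beta, time[tr], event[tr])
            dev[k, a_idx] = -2.0 * (pl_all - pl_train)
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    beta = full.coef_[:, best]
    nz = np.flatnonzero(beta)
    if nz.size == 0:
        warnings.warn("penalized Cox selected an empty model", stacklevel=2)
    return SignatureModel(
        features=[candidate_features[i] for i in nz],
        coefficients=beta[nz].copy(),
        lambda_=float(alphas[best]),
        alphas=alphas,
        cv_deviance=mean_dev,
        folds=folds,
        seed=seed,
        candidate_features=list(candidate_features),
    )


# ---------------------------------------------------------------------------
# risk grouping and evaluation


def kmeans_groups(
    scores, k: int = 3, seed: int = 0, labels: tuple[str, ...] | None = None
) -> tuple[np.ndarray, list[str]]:
    """1D k-means risk grouping; returns (boundaries, per-sample labels).

    Clusters are ordered by center; boundaries are midpoints between the
    maximum of one cluster and the minimum of the next, so group
    assignment is monotone in score.
    """
    from sklearn.cluster import KMeans

    s = np.asarray(scores, dtype=float)
    if len(s) < k:
        raise ValueError(f"k-means with k={k} needs at least {k} scores")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(s.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    ordered = rank[raw]
    boundaries = np.array(
        [
            0.5 * (s[ordered == g].max() + s[ordered == g + 1].min())
            for g in range(k - 1)
        ]
    )
    if labels is None:
        labels = ("low", "medium", "high") if k == 3 else tuple(f"group{i+1}" for i in range(k))
    return boundaries, [labels[g] for g in ordered]


@dataclass
class EvaluationResult:
    univariate: pd.DataFrame  # variable, hr, ci_low, ci_high, p
    multivariable: pd.DataFrame
    c_index: float
    logrank_statistic: float | None
    logrank_p: float | None
    km_curves: dict  # label -> DataFrame(time, survival, at_risk)
    ties_method: str = "efron"


def concordance(time, event, score) -> float:
    """C-index of a risk score (higher score = earlier failure expected)."""
    from lifelines.utils import concordance_index

    return float(concordance_index(time, -np.asarray(score, float), event))


def evaluate_model(
    cohort: pd.DataFrame,
    scores,
    groups,
    covariates: tuple[str, ...] = ("stage", "age", "residual_disease"),
    time_column: str = "time",
    event_column: str = "event",
) -> EvaluationResult:
    """Uni-/multivariable Cox of the score, C-index, log-rank and KM curves."""
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = cohort.copy()
    df["_score"] = np.asarray(scores, float)
    groups = np.asarray(groups)
    if int(df[event_column].sum()) < 2:
        raise RpvKitError("evaluation needs at least two events")

    def _cox(cols: list[str]) -> pd.DataFrame:
        cph = CoxPHFitter()
        cph.fit(
            df[[time_column, event_column] + cols],
            duration_col=time_column,
            event_col=event_column,
        )
        summ = cph.summary
        return pd.DataFrame(
            {
                "variable": summ.index,
                "hr": summ["exp(coef)"].to_numpy(),
                "ci_low": summ["exp(coef) lower 95%"].to_numpy(),
                "ci_high": summ["exp(coef) upper 95%"].to_numpy(),
                "p": summ["p"].to_numpy(),
            }
        ).reset_index(drop=True)

    uni = _cox(["_score"])
    multi = _cox(["_score"] + list(covariates))
    cidx = concordance(df[time_column], df[event_column], df["_score"])

    present = pd.unique(groups)
    lr_stat = lr_p = None
    if len(present) >= 2:
        lr = multivariate_logrank_test(df[time_column], groups, df[event_column])
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
    else:
        warnings.warn("log-rank skipped: fewer than two non-empty groups", stacklevel=2)

    km = {}
    for g in present:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[sel, time_column], df.loc[sel, event_column])
        tbl = kmf.event_table
        km[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    return EvaluationResult(
        univariate=uni,
        multivariable=multi,
        c_index=cidx,
        logrank_statistic=lr_stat,
        logrank_p=lr_p,
        km_curves=km,
    )


def patient_level_scores(
    cohort: CohortTable, tumor_scores: pd.Series
) -> pd.DataFrame:
    """Collapse tumor-level scores to one row per patient (higher-RPV rule)."""
    df = cohort.data
    records = []
    for pid, grp in df.groupby("patient_id", sort=False):
        per_tumor = {tid: float(tumor_scores[i]) for i, tid in zip(grp.index, grp["tumor_id"])}
        score, tumor_id = select_bilateral(per_tumor)
        row = grp.iloc[0].drop(labels=[c for c in cohort.feature_columns]).to_dict()
        row.update({"tumor_id": tumor_id, "score": score})
        records.append(row)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# sample size


def sample_size_survival(
    hr: float,
    alpha: float = 0.05,
    power: float = 0.75,
    prop_high: float = 0.316,
    median_low: float = 5.0,
    follow_up: float = 5.0,
) -> int:
    """Log-rank (Schoenfeld) sample size for a two-group survival comparison.

    Required events ``d = (z_{1-alpha/2} + z_power)^2 / (pe (1-pe) ln^2 HR)``
    where ``pe`` is the expected proportion of events occurring in the
    high-risk group; the event probability in each group assumes
    exponential survival at the stated medians with follow-up uniform on
    (0, follow_up).  Cases ``n = ceil(d / overall event probability)``.
    """
    if hr <= 0 or hr == 1.0:
        raise ValueError("hazard ratio must be positive and != 1")
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if not 0 < prop_high < 1:
        raise ValueError("prop_high must lie in (0, 1)")
    lam_low = math.log(2.0) / median_low
    lam_high = hr * lam_low

    def p_event(lam: float) -> float:
        return 1.0 - (1.0 - math.exp(-lam * follow_up)) / (lam * follow_up)

    p_low = p_event(lam_low)
    p_high = p_event(lam_high)
    p_overall = (1.0 - prop_high) * p_low + prop_high * p_high
    pe = prop_high * p_high / p_overall
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    d = z**2 / (pe * (1.0 - pe) * math.log(hr) ** 2)
    return int(math.ceil(d / p_overall))


# ---------------------------------------------------------------------------
# unsupervised clustering


def hierarchical_cluster(features: pd.DataFrame, k: int) -> np.ndarray:
    """Complete-linkage clustering on 1 - Pearson correlation between rows."""
    x = features.to_numpy(float)
    if len(x) < k:
        raise ValueError(f"need at least {k} rows")
    sds = x.std(axis=1)
    if (sds == 0).any():
        bad = list(features.index[sds == 0])
        raise ValueError(f"constant rows have undefined correlation: {bad}")
    z = linkage(pdist(x, metric="correlation"), method="complete")
    return fcluster(z, t=k, criterion="maxclust")


def similarity_profile_cluster(features: pd.DataFrame, k: int = 3) -> np.ndarray:
    """Cluster patients by the Euclidean geometry of their Spearman
    similarity profiles (row i of the patient-by-patient Spearman matrix)."""
    x = features.to_numpy(float)
    if len(x) < k:
        raise ValueError(f"need at least {k} rows")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    sds = ranks.std(axis=1)
    if (sds == 0).any():
        bad = list(features.index[sds == 0])
        raise ValueError(f"constant profiles have undefined Spearman correlation: {bad}")
    sim = np.corrcoef(ranks)  # Pearson on ranks == Spearman
    z = linkage(pdist(sim, metric="euclidean"), method="complete")
    return fcluster(z, t=k, criterion="maxclust")
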