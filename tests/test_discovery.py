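import numpy as np
import pandas as pd
import pytest

from rpvkit.discovery import (
    benjamini_hochberg,
    concordance,
    evaluate_model,
    hierarchical_cluster,
    kmeans_groups,
    lasso_cox_select,
    patient_level_scores,
    sample_size_survival,
    similarity_profile_cluster,
    univariate_cox_screen,
)
from rpvkit.errors import RpvKitError
from rpvkit.synthetic import CohortSpec, CohortTable, generate_cohort


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        q, passed = benjamini_hochberg([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert passed.sum() == 3
        assert q[:3] == pytest.approx([0.04, 0.04, 0.04])

    def test_all_ones_none_pass(self):
        _, passed = benjamini_hochberg([1.0] * 5)
        assert not passed.any()

    def test_single_p_is_identity(self):
        q, passed = benjamini_hochberg([0.04], q=0.05)
        assert q[0] == pytest.approx(0.04) and passed[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_q_dominates_p_and_contains_bonferroni(self, rng):
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            q, passed = benjamini_hochberg(p, q=0.05)
            assert (q >= p - 1e-15).all()
            bonferroni = p < 0.05 / len(p)
            assert (passed | ~bonferroni).all()  # BH pass set contains Bonferroni's


class TestScreen:
    def test_true_feature_detected_across_replicates(self):
        hits = 0
        for rep in range(8):
            cohort = generate_cohort(
                CohortSpec(n=250, n_features=20, signature_indices=(0,),
                           signature_log_hrs=(1.0,), seed=500 + rep)
            )
            screen = univariate_cox_screen(cohort)
            hits += "feat_01" in screen.passing_features
        assert hits >= 7

    def test_fdr_controlled_under_global_null(self):
        fractions = []
        for rep in range(5):
            cohort = generate_cohort(
                CohortSpec(n=200, n_features=40, signature_indices=(),
                           signature_log_hrs=(), seed=700 + rep)
            )
            screen = univariate_cox_screen(cohort, adjusters=())
            fractions.append(len(screen.passing_features) / 40)
        assert np.mean(fractions) <= 0.05

    def test_zero_events_rejected(self):
        cohort = generate_cohort(CohortSpec(n=50, seed=1))
        df = cohort.data.copy()
        df["event"] = 0
        with pytest.raises(RpvKitError):
            univariate_cox_screen(CohortTable(data=df, feature_columns=cohort.feature_columns))

    def test_invariants_of_result_table(self):
        cohort = generate_cohort(CohortSpec(n=150, seed=9))
        screen = univariate_cox_screen(cohort)
        t = screen.table
        assert (t["q"] >= t["p"] - 1e-15).all()
        assert ((t["q"] < 0.05) == t["passed"]).all()


class TestLasso:
    def test_deterministic_given_seed(self):
        cohort = generate_cohort(CohortSpec(seed=42))
        a = lasso_cox_select(cohort, cohort.feature_columns[:20], seed=7)
        b = lasso_cox_select(cohort, cohort.feature_columns[:20], seed=7)
        assert a.features == b.features
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.lambda_ == b.lambda_

    def test_largest_penalty_shrinks_everything(self):
        cohort = generate_cohort(CohortSpec(seed=42))
        model = lasso_cox_select(cohort, cohort.feature_columns[:10], seed=0)
        # at the top of the path (alphas_[0]) no coefficient survives by construction
        assert model.alphas[0] > model.lambda_ or len(model.features) > 0

    def test_too_few_events_rejected(self):
        cohort = generate_cohort(CohortSpec(n=12, seed=3))
        with pytest.raises(RpvKitError):
            lasso_cox_select(cohort, cohort.feature_columns[:5], folds=10)

    def test_no_candidates_rejected(self):
        cohort = generate_cohort(CohortSpec(n=50, seed=3))
        with pytest.raises(ValueError):
            lasso_cox_select(cohort, [])


class TestKmeans:
    def test_perfectly_separated_triplicates(self):
        scores = [0.0] * 10 + [1.0] * 10 + [2.0] * 10
        boundaries, labels = kmeans_groups(scores, seed=0)
        assert 0 < boundaries[0] < 1 < boundaries[1] < 2
        assert labels[:10] == ["low"] * 10
        assert labels[10:20] == ["medium"] * 10
        assert labels[20:] == ["high"] * 10

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            kmeans_groups([0.1, 0.2], k=3)

    def test_assignment_monotone_in_score(self, rng):
        order = {"low": 0, "medium": 1, "high": 2}
        s = np.sort(rng.normal(size=60))
        _, labels = kmeans_groups(s, seed=1)
        ranks = [order[g] for g in labels]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestEvaluation:
    def test_c_index_matches_bruteforce_pairs(self, rng):
        n = 40
        t = rng.exponential(10, n)
        e = rng.binomial(1, 0.7, n)
        s = rng.normal(size=n)
        conc = disc = ties = 0
        for i in range(n):
            for j in range(n):
                if e[i] == 1 and t[i] < t[j]:
                    if s[i] > s[j]:
                        conc += 1
                    elif s[i] < s[j]:
                        disc += 1
                    else:
                        ties += 1
        expected = (conc + 0.5 * ties) / (conc + disc + ties)
        assert concordance(t, e, s) == pytest.approx(expected, abs=1e-12)

    def test_perfectly_anticoncordant_scores(self):
        t = np.array([1.0, 2, 3, 4, 5])
        s = -t  # highest score dies first
        assert concordance(t, np.ones(5), s) == 1.0

    def test_null_scores_near_half(self, rng):
        t = rng.exponential(10, 1000)
        s = rng.normal(size=1000)
        assert 0.45 <= concordance(t, np.ones(1000), s) <= 0.55

    def test_logrank_hand_example(self):
        df = pd.DataFrame({"time": [1.0, 3, 2, 4], "event": [1, 1, 1, 1]})
        res = evaluate_model(
            df, scores=[2.0, 1.9, 1.0, 0.9], groups=["A", "A", "B", "B"], covariates=()
        )
        assert res.logrank_statistic == pytest.approx(8 / 13, abs=1e-12)

    def test_duplicated_groups_logrank_zero(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 1, 2, 3], "event": [1, 1, 0, 1, 1, 0]}
        )
        res = evaluate_model(
            df, scores=[1.0, 2, 3, 1, 2, 3], groups=["A", "A", "A", "B", "B", "B"],
            covariates=(),
        )
        assert res.logrank_statistic == pytest.approx(0.0, abs=1e-12)

    def test_full_evaluation_on_synthetic_cohort(self):
        cohort = generate_cohort(CohortSpec(seed=5))
        eta = cohort.data.groupby("patient_id", sort=False).first()["true_linear_predictor"]
        pat = cohort.data.drop_duplicates("patient_id").reset_index(drop=True)
        _, groups = kmeans_groups(eta.to_numpy(), seed=0)
        res = evaluate_model(pat, eta.to_numpy(), groups)
        assert 0.5 < res.c_index <= 1.0
        assert res.multivariable.loc[0, "ci_low"] <= res.multivariable.loc[0, "hr"]
        assert res.multivariable.loc[0, "hr"] <= res.multivariable.loc[0, "ci_high"]
        assert set(res.km_curves) == set(np.unique(groups))


class TestPatientLevel:
    def test_bilateral_rows_collapse_to_max(self):
        cohort = generate_cohort(CohortSpec(n=200, bilateral_fraction=0.5, seed=8))
        scores = pd.Series(
            cohort.data["feat_01"].to_numpy(), index=cohort.data.index
        )
        pat = patient_level_scores(cohort, scores)
        assert len(pat) == cohort.n_patients
        merged = cohort.data.groupby("patient_id")["feat_01"].max()
        assert pat.set_index("patient_id")["score"].round(9).equals(merged.round(9))


class TestSampleSize:
    def test_published_configuration(self):
        n = sample_size_survival(
            hr=2.78, alpha=0.05, power=0.75, prop_high=0.316, median_low=5.0, follow_up=5.0
        )
        assert abs(n - 73) <= 5

    def test_monotone_in_power(self):
        lo = sample_size_survival(2.78, power=0.75)
        hi = sample_size_survival(2.78, power=0.9)
        assert hi > lo

    def test_unit_hazard_ratio_rejected(self):
        with pytest.raises(ValueError):
            sample_size_survival(1.0)


class TestClustering:
    def test_hierarchical_recovers_blocks(self, rng):
        base = rng.normal(size=30)
        rows = [base + rng.normal(0, 0.05, 30) for _ in range(8)]
        rows += [-base + rng.normal(0, 0.05, 30) for _ in range(8)]
        labels = hierarchical_cluster(pd.DataFrame(rows), k=2)
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_row_scaling_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 20)))
        scaled = x.mul(rng.uniform(0.5, 5.0, size=10), axis=0)
        assert np.array_equal(hierarchical_cluster(x, 3), hierarchical_cluster(scaled, 3))

    def test_constant_row_named_in_error(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 10)), index=list("abcde"))
        x.loc["c"] = 1.0
        with pytest.raises(ValueError, match="c"):
            hierarchical_cluster(x, 2)

    def test_similarity_clusters_separated_blocks(self, rng):
        blocks = []
        for center in (0.0, 5.0, -5.0):
            proto = rng.normal(center, 1.0, 25)
            blocks += [proto + rng.normal(0, 0.05, 25) for _ in range(6)]
        labels = similarity_profile_cluster(pd.DataFrame(blocks), k=3)
        for g in range(3):
            assert len(set(labels[g * 6 : (g + 1) * 6])) == 1
        assert len(set(labels)) == 3

    def test_duplicated_patients_share_cluster(self, rng):
        x = pd.DataFrame(rng.normal(size=(9, 15)))
        x.iloc[8] = x.iloc[0]
        labels = similarity_profile_cluster(x, k=3)
        assert labels[0] == labels[8]

    def test_monotone_transform_invariance(self, rng):
        x = pd.DataFrame(rng.normal(size=(12, 20)))
        transformed = np.exp(x)  # strictly increasing map, rank-preserving
        assert np.array_equal(
            similarity_profile_cluster(x, 3), similarity_profile_cluster(transformed, 3)
        )
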