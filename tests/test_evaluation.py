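import numpy as np
import pytest

import patsim as ps
from patsim.evaluation import ComparisonMatrix, ModelSpec, RunResult
from patsim.matrices import SimilarityMatrix

from conftest import naive_auroc


class TestAuroc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5], [1, 0], 0.5),
            ([0.3, 0.5, 0.9], [1, 0, 1], 0.5),
        ],
    )
    def test_examples(self, scores, labels, expected):
        assert ps.auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.auroc([0.1, 0.9], [1, 1])

    def test_equals_naive_pairwise_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            # coarse score grid forces frequent ties
            scores = rng.integers(0, 5, size=n) / 4
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert ps.auroc(scores, labels) == pytest.approx(
                naive_auroc(scores, labels)
            )

    def test_invariant_under_strictly_increasing_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert ps.auroc(scores, labels) == pytest.approx(
            ps.auroc(np.exp(3 * scores), labels)
        )


class TestBinaryMetrics:
    def test_perfect_scores(self):
        f1, p, sens, spec = ps.binary_metrics([0.9, 0.8, 0.1], [1, 1, 0], 0.5)
        assert (f1, p, sens, spec) == (1.0, 1.0, 1.0, 1.0)

    def test_all_predicted_negative(self):
        f1, p, sens, spec = ps.binary_metrics([0.1, 0.2], [1, 0], 0.5)
        assert (f1, sens, spec) == (0.0, 0.0, 1.0)

    def test_hand_confusion_table(self):
        f1, p, sens, spec = ps.binary_metrics(
            [0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0], 0.5
        )
        assert (f1, p, sens, spec) == (0.5, 0.5, 0.5, 0.5)


def _separable_cohort(n_per_class=12):
    """Cohort whose outcome equals the latent class, plus perfect matrices."""
    patients = [
        ps.PatientRecord(
            patient_id=f"p{i:02d}",
            demographics=ps.DemographicVector(),
            mortality=1 if i < n_per_class else 0,
        )
        for i in range(2 * n_per_class)
    ]
    cohort = ps.Cohort(patients, feature_registry=["S_lab-edit", "S_rad-edit",
                                                   "S_pro-edit", "S_dem", "S_lab"])
    y = np.array(cohort.outcomes("mortality"))
    M = np.where(y[:, None] == y[None, :], 0.9, 0.1).astype(float)
    np.fill_diagonal(M, 1.0)
    perfect = SimilarityMatrix(cohort.patient_ids, M)
    fss = ps.FeatureSimilaritySet({f: perfect for f in cohort.feature_registry})
    return cohort, fss


class TestLooEvaluate:
    def test_separable_cohort_reaches_auroc_one(self):
        cohort, fss = _separable_cohort()
        spec = ModelSpec(variant="kNN_E", k=5)
        result = ps.loo_evaluate(spec, cohort, seed=0, fss=fss)
        assert result.auroc == 1.0
        assert result.f1 == 1.0

    def test_same_seed_reproduces_run_exactly(self, small_cohort):
        spec = ModelSpec(variant="kNN_ED", k=8)
        fss = ps.compute_feature_similarities(small_cohort)
        a = ps.loo_evaluate(spec, small_cohort, seed=4, fss=fss)
        b = ps.loo_evaluate(spec, small_cohort, seed=4, fss=fss)
        assert np.array_equal(a.scores, b.scores)
        assert a.weights == b.weights

    def test_labels_independent_of_features_near_chance(self):
        # outcome probability identical in both classes -> no feature carries signal
        config = ps.GeneratorConfig(
            n_patients=200, seed=11, mortality_probs=(0.25, 0.25)
        )
        cohort = ps.generate_cohort(config)
        fss = ps.compute_feature_similarities(cohort)
        result = ps.loo_evaluate(ModelSpec(variant="kNN_ED", k=30), cohort, seed=0, fss=fss)
        assert abs(result.auroc - 0.5) < 0.1

    def test_temporal_variant_refuses_admission(self, small_cohort):
        adm = ps.truncate_cohort(small_cohort, ps.ADMISSION)
        with pytest.raises(ps.ValidationError, match="admission"):
            ps.loo_evaluate(ModelSpec(variant="kNN_H", k=5), adm, seed=0)

    def test_admission_cross_sectional_model_runs(self, small_cohort):
        adm = ps.truncate_cohort(small_cohort, ps.ADMISSION)
        result = ps.loo_evaluate(ModelSpec(variant="kNN_E", k=5), adm, seed=0)
        assert set(result.weights.features) == {"S_dem", "S_lab"}

    def test_day7_short_stays_excluded_from_training(self):
        # the only positive patient has a short stay; once excluded from
        # training, no neighbor is positive and every score is 0
        patients = [
            ps.PatientRecord(
                patient_id=f"p{i}",
                demographics=ps.DemographicVector(),
                mortality=1 if i == 0 else 0,
                length_of_stay=3 if i == 0 else 10,
            )
            for i in range(8)
        ]
        cohort = ps.truncate_cohort(ps.Cohort(patients), ps.DAY7)
        assert cohort.patients[0].excluded
        y = np.array(cohort.outcomes("mortality"))
        M = np.full((8, 8), 0.5)
        np.fill_diagonal(M, 1.0)
        fss = ps.FeatureSimilaritySet(
            {f: SimilarityMatrix(cohort.patient_ids, M)
             for f in ("S_lab-edit", "S_rad-edit", "S_pro-edit", "S_dem", "S_lab")}
        )
        train_mask = np.array([not p.excluded for p in cohort.patients])
        scores = [
            ps.knn_predict(fss["S_dem"], y, i, 3, train_mask.copy())
            for i in range(8)
        ]
        assert all(s == 0.0 for s in scores)


class TestMultiRun:
    def test_single_run_summary_matches_run(self, small_cohort):
        fss = ps.compute_feature_similarities(small_cohort)
        spec = ModelSpec(variant="kNN_EH", k=8)
        results, summary = ps.multi_run(spec, small_cohort, n_runs=1, base_seed=2, fss=fss)
        assert len(results) == 1
        assert summary.loc["kNN_EH", "auroc"] == f"{results[0].auroc:.3f} (0.000)"

    def test_fixed_base_seed_bitwise_reproducible(self, small_cohort):
        fss = ps.compute_feature_similarities(small_cohort)
        spec = ModelSpec(variant="kNN_ED", k=8)
        r1, _ = ps.multi_run(spec, small_cohort, n_runs=4, base_seed=9, fss=fss)
        r2, _ = ps.multi_run(spec, small_cohort, n_runs=4, base_seed=9, fss=fss)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.scores, b.scores)
            assert a.auroc == b.auroc

    def test_subsampling_varies_across_runs(self, small_cohort):
        fss = ps.compute_feature_similarities(small_cohort)
        spec = ModelSpec(variant="kNN_ED", k=8)
        results, _ = ps.multi_run(spec, small_cohort, n_runs=8, base_seed=0, fss=fss)
        scores = [tuple(r.scores) for r in results]
        assert len(set(scores)) > 1


def _fake_results(values):
    return [
        RunResult(i, i, np.zeros(1), np.zeros(1), None, v, 0, 0, 0, 0)
        for i, v in enumerate(values)
    ]


class TestPairwiseWinMatrix:
    def test_97_wins_significant(self):
        a = _fake_results([0.8] * 97 + [0.1] * 3)
        b = _fake_results([0.5] * 100)
        cm = ps.pairwise_win_matrix({"A": a, "B": b})
        assert cm.wins[0, 1] == pytest.approx(0.97)
        assert cm.significant[0, 1]

    def test_94_wins_not_significant_and_95_is(self):
        b = _fake_results([0.5] * 100)
        for wins, expected in ((94, False), (95, True)):
            a = _fake_results([0.8] * wins + [0.1] * (100 - wins))
            cm = ps.pairwise_win_matrix({"A": a, "B": b})
            assert cm.wins[0, 1] == pytest.approx(wins / 100)
            assert bool(cm.significant[0, 1]) is expected

    def test_model_never_beats_itself(self):
        a = _fake_results([0.7, 0.8])
        cm = ps.pairwise_win_matrix({"A": a, "B": _fake_results([0.1, 0.9])})
        assert cm.wins[0, 0] == 0.0 and not cm.significant.diagonal().any()

    def test_ties_count_for_neither(self):
        a = _fake_results([0.5, 0.8])
        b = _fake_results([0.5, 0.1])
        cm = ps.pairwise_win_matrix({"A": a, "B": b})
        assert cm.wins[0, 1] + cm.wins[1, 0] <= 1.0
        assert cm.wins[0, 1] == pytest.approx(0.5)

    def test_unequal_run_counts_rejected(self):
        with pytest.raises(ps.ValidationError):
            ps.pairwise_win_matrix({"A": _fake_results([1]), "B": _fake_results([1, 2])})


def _mini_cohort_for_baseline():
    p1 = ps.PatientRecord(
        patient_id="a",
        demographics=ps.DemographicVector(1, 0, 0, 0),
        series={"cr": ps.LabTimeSeries("cr", (2.0, 4.0, 6.0), (1, 2, 3))},
    )
    p2 = ps.PatientRecord(
        patient_id="b",
        demographics=ps.DemographicVector(0, 1, 0, 0),
        series={"cr": ps.LabTimeSeries("cr", (1.0, 2.0), (1, 2))},
    )
    p3 = ps.PatientRecord(
        patient_id="c",
        demographics=ps.DemographicVector(0, 0, 1, 0),
        series={"cr": ps.LabTimeSeries("cr", (1.0, 1.0, 1.0, 1.0), (1, 2, 3, 4))},
    )
    return ps.Cohort([p1, p2, p3])


class TestBaselineFeatures:
    def test_six_statistics_of_symmetric_series(self):
        table = ps.baseline_features(_mini_cohort_for_baseline(), mode="stats")
        row = table.loc["a"]
        assert row["cr:min"] == 2 and row["cr:max"] == 6 and row["cr:mean"] == 4
        assert row["cr:sd"] == pytest.approx(2.0)  # sample SD
        assert row["cr:skew"] == 0.0 and row["cr:len"] == 3

    def test_missing_series_zeros_with_presence_flag(self):
        cohort = _mini_cohort_for_baseline()
        cohort.patients[1].series = {}
        table = ps.baseline_features(cohort, mode="stats")
        row = table.loc["b"]
        assert row["cr:present"] == 0.0
        assert all(row[f"cr:{s}"] == 0.0 for s in ("min", "max", "mean", "sd", "skew", "len"))

    def test_flatten_zero_pads_to_cohort_maximum(self):
        table = ps.baseline_features(_mini_cohort_for_baseline(), mode="flatten")
        assert list(table.loc["b", ["cr:v0", "cr:v1", "cr:v2", "cr:v3"]]) == [1, 2, 0, 0]


class TestEuclideanKnnBaseline:
    def test_duplicate_patient_is_nearest_neighbor(self):
        cohort = _mini_cohort_for_baseline()
        dup = ps.PatientRecord(
            patient_id="d",
            demographics=ps.DemographicVector(1, 0, 0, 0),
            series={"cr": ps.LabTimeSeries("cr", (2.0, 4.0, 6.0), (1, 2, 3))},
            mortality=1,
        )
        cohort = ps.Cohort(cohort.patients + [dup])
        table = ps.baseline_features(cohort, mode="stats")
        labels = [0, 0, 0, 1]
        assert ps.euclidean_knn_baseline(table, labels, 1, 0) == 1.0

    def test_ranking_matches_one_minus_normalized_distance_similarity(self, rng):
        import pandas as pd

        X = rng.normal(size=(10, 4))
        ids = [f"p{i}" for i in range(10)]
        table = pd.DataFrame(X, index=ids)
        labels = rng.integers(0, 2, size=10)
        Z = (X - X.mean(0)) / X.std(0)
        D = np.linalg.norm(Z[:, None] - Z[None, :], axis=2)
        S = SimilarityMatrix(ids, np.clip(1 - D / D.max(), 0, 1))
        for i in range(10):
            assert ps.euclidean_knn_baseline(table, labels, 3, i) == pytest.approx(
                ps.knn_predict(S, labels, i, 3)
            )
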