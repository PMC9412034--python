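"""SVM training, metrics, CV, lead search, feature ranking, PCA, scenarios."""

import numpy as np
import pytest

from otva.classify import (
    ScenarioSpec,
    SVMBeatClassifier,
    balanced_accuracy,
    cross_validate_accuracy,
    encode_chamber,
    exhaustive_lead_search,
    pca_cumulative_variance,
    rank_features_extratrees,
    run_scenario,
)
from otva.preprocess import raw10_matrix
from otva.synthetic_ecg import (
    GeneratorConfig,
    generate_clinical_like,
    generate_database,
)


@pytest.fixture(scope="module")
def toy_xy():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(80, 5))
    y = (X[:, 0] + 0.2 * rng.normal(size=80) > 0).astype(int)
    return X, y


class TestSVM:
    def test_separable_toy_reaches_training_accuracy_one(self):
        X = np.array([[0.0, 0], [0, 1], [5, 5], [5, 6]] * 5)
        y = np.array([0, 0, 1, 1] * 5)
        clf = SVMBeatClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_half_weight_duplication_equivalence(self, toy_xy):
        """Duplicating every sample at weight 1/2 leaves the decision
        function numerically unchanged."""
        X, y = toy_xy
        m1 = SVMBeatClassifier(scale=False).fit(X, y)
        m2 = SVMBeatClassifier(scale=False).fit(
            np.vstack([X, X]), np.concatenate([y, y]),
            sample_weight=np.full(2 * len(y), 0.5))
        g = np.random.default_rng(2).normal(size=(40, 5))
        assert np.allclose(m1.decision_function(g), m2.decision_function(g),
                           atol=1e-2)

    def test_row_permutation_invariance(self, toy_xy):
        X, y = toy_xy
        perm = np.random.default_rng(3).permutation(len(y))
        a = SVMBeatClassifier(scale=False).fit(X, y)
        b = SVMBeatClassifier(scale=False).fit(X[perm], y[perm])
        g = np.random.default_rng(4).normal(size=(40, 5))
        assert np.array_equal(a.predict(g), b.predict(g))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class|single-class|single"):
            SVMBeatClassifier().fit(np.ones((5, 2)), np.zeros(5))


class TestBalancedAccuracy:
    def test_perfect_prediction(self):
        assert balanced_accuracy([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_constant_predictor_two_classes(self):
        assert balanced_accuracy([0, 0, 1, 1, 1], [1, 1, 1, 1, 1]) == 0.5

    def test_contingency_arithmetic(self):
        # TP=9, FN=1 (positive recall 0.9); TN=3, FP=7 (negative recall 0.3)
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1] * 7 + [0] * 3
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(0.6)

    def test_equals_plain_accuracy_when_balanced(self):
        rng = np.random.default_rng(5)
        y_true = np.array([0] * 50 + [1] * 50)
        y_pred = rng.integers(0, 2, 100)
        plain = (y_true == y_pred).mean()
        # equality holds when the per-class recalls average to the pooled rate
        ba = balanced_accuracy(y_true, y_pred)
        r0 = (y_pred[:50] == 0).mean()
        r1 = (y_pred[50:] == 1).mean()
        assert ba == pytest.approx((r0 + r1) / 2)
        assert abs(ba - plain) < 1e-12 or len(set([r0, r1])) > 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([], [])


class TestCrossValidation:
    def test_folds_partition_and_stratify(self, toy_xy):
        from sklearn.model_selection import StratifiedKFold

        X, y = toy_xy
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        seen = np.zeros(len(y), dtype=int)
        for _, test_idx in skf.split(X, y):
            seen[test_idx] += 1
            frac = y[test_idx].mean()
            assert abs(frac * len(test_idx) - y.mean() * len(test_idx)) <= 1.01
        assert (seen == 1).all()

    def test_high_cv_accuracy_on_well_separated_beats(self):
        cfg = GeneratorConfig(n_anatomies=6, n_electrode_configs=4, seed=7,
                              class_separation=2.0)
        ds = generate_database(cfg)
        X, y, _ = raw10_matrix(ds)
        cv = cross_validate_accuracy(X, encode_chamber(y), folds=5, seed=0)
        assert cv.mean_accuracy > 0.9
        assert len(cv.fold_accuracies) == 5

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([0] * 8 + [1] * 2)
        with pytest.raises(ValueError):
            cross_validate_accuracy(X, y, folds=5)


class TestLeadSearch:
    def test_two_lead_toy_has_three_subsets(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 2, 4))
        y = (X[:, 0, 0] > 0).astype(int)
        res = exhaustive_lead_search(X, y, {"t": (X, y)}, fast=True)
        assert res.n_subsets == 3
        assert res.masks.shape == (3, 2)

    def test_membership_counts(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4, 3))
        y = (X[:, 1, 0] > 0).astype(int)
        res = exhaustive_lead_search(X, y, {"t": (X, y)}, fast=True)
        assert res.n_subsets == 2 ** 4 - 1
        for lead in range(4):
            assert len(res.lead_distribution(lead, "t")) == 2 ** 3

    def test_informative_lead_wins(self):
        rng = np.random.default_rng(9)
        n = 120
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 3, 4)) * 0.5
        X[:, 2, :] += (2 * y - 1)[:, None]  # only lead 2 carries signal
        res = exhaustive_lead_search(X, y, {"t": (X, y)}, fast=True)
        medians = [np.median(res.lead_distribution(l, "t")) for l in range(3)]
        assert np.argmax(medians) == 2


class TestFeatureRanking:
    def test_importances_sum_to_one(self, toy_xy):
        X, y = toy_xy
        rk = rank_features_extratrees(X, y, n_trees=50, seed=0)
        assert rk.importances.sum() == pytest.approx(1.0)
        assert (rk.importances >= 0).all()

    def test_planted_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 51))
        X[:, 17] = 2 * y - 1 + rng.normal(0, 0.05, n)
        rk = rank_features_extratrees(X, y, n_trees=200, seed=0)
        assert rk.names[0] == "f17"

    def test_top_k_descending(self, toy_xy):
        X, y = toy_xy
        rk = rank_features_extratrees(X, y, n_trees=50, seed=1)
        top = rk.top(3)
        assert len(top) == 3
        assert np.all(np.diff(rk.importances) <= 1e-12)

    def test_constant_matrix_warns_zero_importance(self):
        with pytest.warns(UserWarning, match="constant"):
            rk = rank_features_extratrees(np.ones((20, 4)),
                                          np.array([0, 1] * 10), n_trees=10)
        assert np.allclose(rk.importances, 0.0)


class TestPCA:
    def test_monotone_and_ends_at_one(self, small_db):
        X, _, _ = raw10_matrix(small_db)
        curve = pca_cumulative_variance(X)
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] == pytest.approx(1.0, abs=1e-9)

    def test_single_lead_rank_bound(self, small_db):
        X, _, _ = raw10_matrix(small_db)
        v2 = X[:, 70:80]  # one lead's 10 bins: rank <= 10
        curve = pca_cumulative_variance(v2)
        assert curve[min(9, len(curve) - 1)] == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_column_leaves_curve_unchanged_beyond_rank(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 4))
        Xd = np.column_stack([X, X[:, 0]])
        a = pca_cumulative_variance(X)
        b = pca_cumulative_variance(Xd)
        assert b[3] == pytest.approx(1.0, abs=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            pca_cumulative_variance(np.ones((1, 4)))


@pytest.fixture(scope="module")
def scenario_data():
    sim = generate_database(GeneratorConfig(
        n_anatomies=4, n_electrode_configs=3, seed=61))
    ctr = generate_clinical_like(40, 0.3, GeneratorConfig(
        n_anatomies=4, n_electrode_configs=3, seed=62, noise_sd=0.1))
    cte = generate_clinical_like(120, 0.25, GeneratorConfig(
        n_anatomies=4, n_electrode_configs=3, seed=63, noise_sd=0.1))
    from otva.augment import MixupConfig, augment_dataset

    aug = augment_dataset(sim, MixupConfig(ratio=3, seed=64))
    return {"simulated": sim, "clinical_train": ctr,
            "clinical_test": cte, "augmented": aug}


class TestScenarios:

    def test_overlapping_train_test_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ScenarioSpec("bad", ("simulated",), ("simulated",))

    def test_sc1_augmented_composition(self, scenario_data):
        spec = ScenarioSpec("Sc1", ("simulated", "augmented"),
                            ("clinical_test",))
        res = run_scenario(spec, scenario_data, seed=0, folds=3)
        n = len(scenario_data["simulated"])
        assert res.n_train == n + 3 * n

    def test_sc3_training_size(self, scenario_data):
        spec = ScenarioSpec("Sc3", ("simulated", "clinical_train"),
                            ("clinical_test",))
        res = run_scenario(spec, scenario_data, seed=0, folds=3)
        assert res.n_train == (len(scenario_data["simulated"])
                               + len(scenario_data["clinical_train"]))
        cm = np.array(res.confusion["clinical_test"])
        assert cm.sum() == len(scenario_data["clinical_test"])

    def test_unknown_dataset_key_rejected(self, scenario_data):
        spec = ScenarioSpec("x", ("nope",), ("clinical_test",))
        with pytest.raises(KeyError):
            run_scenario(spec, scenario_data)

    def test_top10_selects_ten_features(self, scenario_data):
        from otva.synthetic_ecg import Dataset

        small = Dataset(records=scenario_data["simulated"].records[::3],
                        provenance="simulated_style")
        data = {"sim": small, "test": scenario_data["clinical_test"]}
        spec = ScenarioSpec("Sc1", ("sim",), ("test",),
                            representation="top10", top_k=10)
        res = run_scenario(spec, data, seed=0, folds=3)
        assert len(res.selected_features) == 10

    def test_hybrid_not_worse_than_small_clinical_only(self):
        """The qualitative finding: adding the simulated database to a small
        clinical-like training set does not hurt held-out performance
        (well-separated classes, fixed seed)."""
        sep = 2.0
        sim = generate_database(GeneratorConfig(
            n_anatomies=6, n_electrode_configs=4, seed=50,
            class_separation=sep))
        ctr = generate_clinical_like(31, 77 / 334, GeneratorConfig(
            n_anatomies=6, n_electrode_configs=4, seed=150, noise_sd=0.1,
            class_separation=sep))
        cte = generate_clinical_like(200, 77 / 334, GeneratorConfig(
            n_anatomies=6, n_electrode_configs=4, seed=250, noise_sd=0.1,
            class_separation=sep))
        data = {"simulated": sim, "clinical_train": ctr, "clinical_test": cte}
        r2 = run_scenario(ScenarioSpec("Sc2", ("clinical_train",),
                                       ("clinical_test",)),
                          data, seed=0, folds=3)
        r3 = run_scenario(ScenarioSpec("Sc3", ("simulated", "clinical_train"),
                                       ("clinical_test",)),
                          data, seed=0, folds=3)
        assert (r3.test_balanced_accuracy["clinical_test"]
                >= r2.test_balanced_accuracy["clinical_test"])
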