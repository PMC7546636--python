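"""COWE weights, segment classification, vote fusion, LOO cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rubeoscan.ensemble import (
    COWEClassifier,
    RUSBoostClassifier,
    SgnKVoteClassifier,
    UNDECIDED,
    classify_segment,
    cowe_weights,
    loo_xv,
    majority_vote,
    unsupervised_sgn_classifier,
)
from rubeoscan.pipeline import cohort_features_dataframe
from rubeoscan.synthgen import CohortSpec, generate_cohort_features


@pytest.fixture(scope="module")
def cohort_features():
    """Feature table of a clean 8 DM / 6 C feature-level cohort."""
    spec = CohortSpec(n_dm=8, n_c=6, mixture=0.0, esd_samples_per_segment=800, seed=42)
    return cohort_features_dataframe(generate_cohort_features(spec))


class TestCoweWeights:
    def test_single_learner_gets_unit_weight(self, rng):
        y = rng.integers(0, 2, 50)
        w = cowe_weights(y[None, :].astype(float), y)
        np.testing.assert_allclose(w, [1.0])

    def test_perfect_learner_dominates_coin_flip(self, rng):
        y = rng.integers(0, 2, 400).astype(float)
        perfect = y
        coin = rng.random(400)
        P = np.stack([perfect, coin])
        w = cowe_weights(P, y)
        w_grid = cowe_weights(P, y, solver="grid")
        np.testing.assert_allclose(w, [1.0, 0.0], atol=0.05)
        np.testing.assert_allclose(w, w_grid, atol=0.02)

    def test_identical_learners_tie_broken_to_uniform(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        p = 0.7 * y + 0.15
        w = cowe_weights(np.stack([p, p]), y)
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_weights_live_on_the_simplex(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        P = rng.random((5, 300))
        w = cowe_weights(P, y)
        assert np.all(w >= -1e-9)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-9)

    def test_optimal_weights_beat_every_single_learner(self, rng):
        y = rng.integers(0, 2, 300).astype(float)
        P = np.clip(np.stack([y + 0.3 * rng.standard_normal(300) for _ in range(4)]), 0, 1)
        w = cowe_weights(P, y)
        mse_opt = np.mean((P.T @ w - y) ** 2)
        for i in range(4):
            mse_single = np.mean((P[i] - y) ** 2)
            assert mse_opt <= mse_single + 1e-6

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            cowe_weights(np.random.rand(2, 20), np.zeros(20))


class TestClassifiers:
    def test_separable_toy_problem_fit_perfectly(self, rng):
        X = np.concatenate([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        model = COWEClassifier(random_state=0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0
        assert np.sum(model.weights_) == pytest.approx(1.0, abs=1e-9)

    def test_same_data_and_seed_give_identical_predictions(self, rng):
        X = rng.standard_normal((60, 2))
        y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0).astype(int)
        preds = []
        for _ in range(2):
            model = COWEClassifier(random_state=7).fit(X, y)
            preds.append(model.decision_scores(X))
        np.testing.assert_array_equal(preds[0], preds[1])

    def test_rusboost_deterministic_and_valid_probabilities(self, rng):
        X = rng.standard_normal((80, 2))
        y = np.array([0] * 60 + [1] * 20)  # imbalanced, as in the study
        a = RUSBoostClassifier(random_state=3).fit(X, y).predict_proba(X)
        b = RUSBoostClassifier(random_state=3).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(a, b)
        assert np.all((a >= 0) & (a <= 1))
        np.testing.assert_allclose(a.sum(axis=1), 1.0)

    def test_segment_accuracy_on_clean_cohort(self, cohort_features):
        X = cohort_features[["k", "sigma"]].to_numpy()
        y = (cohort_features["label"] == "DM").astype(int).to_numpy()
        model = COWEClassifier(random_state=0).fit(X, y)
        assert np.mean(model.predict(X) == y) >= 0.9

    def test_published_parameter_pairs_classified_to_their_groups(self):
        # cohort built on the published DM GP feature scale, so the printed
        # (k, sigma) pairs land inside their group's feature cluster
        from rubeoscan.synthgen import DM_SEGMENT_GP_PARAMS

        spec = CohortSpec(
            n_dm=8,
            n_c=6,
            mixture=0.0,
            esd_samples_per_segment=800,
            dm_tail_family="gp",
            dm_tail_params=DM_SEGMENT_GP_PARAMS,
            seed=42,
        )
        features = cohort_features_dataframe(generate_cohort_features(spec))
        X = features[["k", "sigma"]].to_numpy()
        y = (features["label"] == "DM").astype(int).to_numpy()
        model = COWEClassifier(random_state=0).fit(X, y)
        label_c, _ = classify_segment(model, [0.0869, 0.0001])
        label_dm, _ = classify_segment(model, [-0.378, 0.156])
        assert (label_c, label_dm) == ("0", "1")

    def test_boundary_score_half_maps_to_dm(self):
        class Half:
            classes_ = np.array(["C", "DM"])

            def decision_scores(self, X):
                return np.array([0.5])

        label, score = classify_segment(Half(), [0.0, 1.0])
        assert label == "DM" and score == 0.5

    def test_sgn_rule_estimator_predicts_from_shape_sign(self):
        clf = SgnKVoteClassifier().fit(np.zeros((2, 2)))
        out = clf.predict(np.array([[0.1, 1.0], [-0.2, 1.0], [0.0, 1.0]]))
        assert list(out) == ["C", "DM", "C"]


class TestMajorityVote:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["DM"] * 4 + ["C"] * 2, "DM"),
            (["DM"] * 3 + ["C"] * 3, UNDECIDED),
            (["C"] * 5 + ["DM"], "C"),
            (["DM", "DM", "C"], "DM"),  # strict majority below 6 segments
            (["DM", "C"], UNDECIDED),
            (["C"], "C"),
        ],
    )
    def test_fusion_rule(self, labels, expected):
        assert majority_vote(labels).final == expected

    def test_empty_vote_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])

    def test_vote_monotonicity(self):
        # flipping one segment toward DM never moves the decision away from DM
        order = {"C": 0, UNDECIDED: 1, "DM": 2}
        for labels in itertools.product(["C", "DM"], repeat=6):
            before = majority_vote(list(labels)).final
            for i, lbl in enumerate(labels):
                if lbl == "C":
                    flipped = list(labels)
                    flipped[i] = "DM"
                    after = majority_vote(flipped).final
                    assert order[after] >= order[before]


class TestLooXV:
    def test_fold_count_matches_subject_count(self, cohort_features):
        result = loo_xv(cohort_features, random_state=0)
        assert result["n_folds"] == cohort_features["subject"].nunique()

    def test_clean_cohort_reaches_perfect_subject_metrics(self, cohort_features):
        result = loo_xv(cohort_features, random_state=0)
        assert result["metrics"]["sensitivity"] == 100.0
        assert result["metrics"]["specificity"] == 100.0
        assert result["metrics"]["undecided"] == 0

    def test_too_few_subjects_per_class_rejected(self, cohort_features):
        subset = cohort_features[cohort_features["subject"] != "C01"]
        subset = subset[~subset["subject"].isin(["C02", "C03", "C04", "C05"])]
        with pytest.raises(ValueError, match="2 subjects"):
            loo_xv(subset)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            loo_xv(pd.DataFrame({"subject": [], "k": []}))


class TestUnsupervisedRule:
    def test_all_positive_shape_subject_is_control(self):
        from rubeoscan.tails import GPParams, TailFitReport, sgn_k_verdict

        reports = []
        for k in [0.2, 0.4, 0.1, 0.3, 0.6, 0.05]:
            gp = GPParams(k=k, sigma=0.01)
            reports.append(TailFitReport(gp=gp, verdict=sgn_k_verdict(gp)))
        decisions = unsupervised_sgn_classifier({"S1": reports})
        assert decisions[0].final == "C"

    def test_missing_fits_rejected(self):
        with pytest.raises(ValueError, match="no tail fits"):
            unsupervised_sgn_classifier({"S1": []})
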