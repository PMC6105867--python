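"""Evaluation schemes, user lift, permutation test, importances."""

import numpy as np
import pandas as pd
import pytest

import gaitmood as gm
from gaitmood.evaluation import (
    CVScheme,
    EvalResult,
    ModelSpec,
    emotion_block_cv,
    evaluate_personal,
    fit_baseline,
    leave_one_user_out,
    normalized_importance,
    permutation_test_mean_lift,
    split_by_participant,
    user_lift,
)
from gaitmood.sensor_io import META_COLUMNS, FeatureMatrix


def _matrix(X, y, pid="p00"):
    """Assemble a FeatureMatrix from raw arrays (one contiguous walk per class)."""
    X = np.asarray(X, dtype=float)
    names = [f"f{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "participant", pid)
    frame.insert(1, "emotion", y)
    order = np.concatenate(
        [np.arange(np.sum(np.asarray(y) == cls)) for cls in pd.unique(pd.Series(y))]
    )
    frame.insert(2, "window_index", order)
    frame.insert(3, "window_center_s", np.arange(len(frame), dtype=float))
    return FeatureMatrix(frame, names)


def _separable_user(n_per_class=60, gap=10.0, pid="p00", seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    b = rng.normal(gap, 1.0, size=(n_per_class, n_features))
    X = np.vstack([a, b])
    y = ["happy"] * n_per_class + ["sad"] * n_per_class
    return _matrix(X, y, pid)


class TestBaseline:
    def test_predicts_modal_label(self):
        clf = fit_baseline(["happy"] * 51 + ["sad"] * 49)
        assert set(clf.predict(np.zeros((5, 1)))) == {"happy"}

    def test_tie_breaks_lexicographically(self):
        clf = fit_baseline(["sad", "happy", "sad", "happy"])
        assert clf.majority_ == "happy"

    def test_accuracy_equals_test_frequency_of_training_majority(self, rng):
        """Baseline identity: accuracy is exactly the majority-class test rate."""
        train = ["happy"] * 60 + ["sad"] * 40
        test = np.array(["happy"] * 13 + ["sad"] * 37)
        clf = fit_baseline(train)
        pred = clf.predict(np.zeros((len(test), 1)))
        assert np.mean(pred == test) == np.mean(test == "happy") == 0.26

    def test_constant_scores_give_auc_half(self):
        m = _separable_user()
        res = evaluate_personal(m, ModelSpec("baseline_majority"), CVScheme(repeats=1))
        assert res.mean_auc == pytest.approx(0.5)

    @pytest.mark.parametrize("a,k", [(0.513, 2), (0.343, 3), (0.9, 2), (0.5, 4)])
    def test_closed_form_macro_f1(self, a, k):
        """All-one-class prediction: macro-F1 = (2a/(1+a))/k to 1e-12."""
        n = 1000
        n_major = int(round(a * n))
        labels = [f"c{i}" for i in range(k)]
        y = np.array([labels[0]] * n_major + list(
            np.repeat(labels[1:], (n - n_major) // (k - 1))
        ))
        a_exact = np.mean(y == labels[0])
        from sklearn.metrics import f1_score

        pred = np.full(len(y), labels[0])
        f1 = f1_score(y, pred, labels=labels, average="macro", zero_division=0)
        assert f1 == pytest.approx((2 * a_exact / (1 + a_exact)) / k, abs=1e-12)


class TestEvaluatePersonal:
    def test_separable_features_give_perfect_accuracy_and_auc(self):
        res = evaluate_personal(
            _separable_user(), ModelSpec("logistic_l2"), CVScheme(repeats=1)
        )
        assert res.mean_accuracy == 1.0
        assert res.mean_auc == 1.0
        assert len(res.per_fold) == 10

    def test_shuffled_labels_hover_at_chance(self, rng):
        n = 400
        X = rng.normal(size=(n, 8))
        y = rng.permutation(["happy"] * (n // 2) + ["sad"] * (n // 2))
        res = evaluate_personal(
            _matrix(X, list(y)), ModelSpec("logistic_l2"), CVScheme(repeats=2)
        )
        assert 0.4 < res.mean_accuracy < 0.6
        assert 0.4 < res.mean_auc < 0.6

    def test_class_smaller_than_k_is_explicit_error(self):
        m = _separable_user(n_per_class=5)
        with pytest.raises(ValueError, match="fewer than k"):
            evaluate_personal(m, ModelSpec("logistic_l2"), CVScheme(k=10))

    def test_fold_count_is_k_times_repeats(self):
        res = evaluate_personal(
            _separable_user(), ModelSpec("baseline_majority"),
            CVScheme(k=5, repeats=3),
        )
        assert len(res.per_fold) == 15

    def test_metrics_bounded(self, tiny_matrix):
        users = split_by_participant(tiny_matrix.select_labels(["happy", "sad"]))
        res = evaluate_personal(
            next(iter(users.values())), ModelSpec("logistic_l2"), CVScheme(repeats=1)
        )
        pf = res.per_fold
        assert ((pf["accuracy"] >= 0) & (pf["accuracy"] <= 1)).all()
        assert ((pf["f1"] >= 0) & (pf["f1"] <= 1)).all()


class TestEmotionBlockCV:
    def test_balanced_baseline_scores_zero_on_every_fold(self):
        """Removing a whole block flips the training majority against the fold."""
        m = _separable_user(n_per_class=50)
        res = emotion_block_cv(m, ModelSpec("baseline_majority"))
        assert len(res.per_fold) == 10
        assert (res.per_fold["accuracy"] == 0.0).all()

    def test_stationary_separable_features_match_random_cv(self):
        m = _separable_user(n_per_class=60)
        block = emotion_block_cv(m, ModelSpec("logistic_l2"))
        rand = evaluate_personal(m, ModelSpec("logistic_l2"), CVScheme(repeats=1))
        assert block.mean_accuracy == pytest.approx(rand.mean_accuracy, abs=0.02)

    def test_fold_f1_is_held_out_class_f1(self):
        m = _separable_user(n_per_class=50)
        res = emotion_block_cv(m, ModelSpec("logistic_l2"))
        acc = res.per_fold["accuracy"]
        f1 = res.per_fold["f1"]
        assert np.allclose(f1, 2 * acc / (1 + acc))

    def test_requires_binary_labels(self, tiny_matrix):
        users = split_by_participant(tiny_matrix)
        with pytest.raises(ValueError, match="binary"):
            emotion_block_cv(next(iter(users.values())), ModelSpec("logistic_l2"))

    def test_too_few_windows_per_class_rejected(self):
        m = _separable_user(n_per_class=3)
        with pytest.raises(ValueError, match="blocks"):
            emotion_block_cv(m, ModelSpec("logistic_l2"))

    def test_drifting_features_score_below_random_cv(self):
        """Within-class drift: block CV punishes what random CV rewards."""
        rng = np.random.default_rng(3)
        diffs = []
        for user in range(8):
            n = 120
            drift_a = np.cumsum(rng.normal(0, 0.6, size=(n, 4)), axis=0)
            drift_b = np.cumsum(rng.normal(0, 0.6, size=(n, 4)), axis=0)
            X = np.vstack([
                rng.normal(0.0, 1.0, size=(n, 4)) + drift_a,
                rng.normal(0.8, 1.0, size=(n, 4)) + drift_b,
            ])
            y = ["happy"] * n + ["sad"] * n
            m = _matrix(X, y, f"p{user:02d}")
            rand = evaluate_personal(m, ModelSpec("logistic_l2"), CVScheme(repeats=1))
            block = emotion_block_cv(m, ModelSpec("logistic_l2"))
            diffs.append(rand.mean_accuracy - block.mean_accuracy)
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 7  # sign test at p < 0.05


class TestLeaveOneUserOut:
    def test_identical_users_generalize_like_within_user(self):
        users = {f"p{i:02d}": _separable_user(pid=f"p{i:02d}", seed=0) for i in range(3)}
        res = leave_one_user_out(users, ModelSpec("logistic_l2"))
        assert res.mean_accuracy == 1.0
        assert len(res.per_fold) == 3

    def test_swapped_classes_score_below_chance(self):
        a = _separable_user(pid="p00", seed=1)
        flipped = a.frame.copy()
        flipped["emotion"] = np.where(flipped["emotion"] == "happy", "sad", "happy")
        flipped["participant"] = "p01"
        b = FeatureMatrix(flipped, a.feature_names)
        res = leave_one_user_out({"p00": a, "p01": b}, ModelSpec("logistic_l2"))
        assert res.mean_accuracy < 0.5

    def test_single_user_rejected(self):
        with pytest.raises(ValueError, match="2 users"):
            leave_one_user_out({"p00": _separable_user()}, ModelSpec("logistic_l2"))


class TestUserLift:
    def _result(self, acc, scheme="stratified_kfold_repeated"):
        pf = pd.DataFrame({"accuracy": [acc], "f1": [acc], "roc_auc": [np.nan]})
        return EvalResult(pf, scheme, "logistic_l2")

    def test_table_value(self):
        assert user_lift(self._result(0.854), self._result(0.513)) == pytest.approx(
            0.341
        )

    def test_model_equals_baseline_gives_zero(self):
        assert user_lift(self._result(0.7), self._result(0.7)) == 0.0

    def test_bounds(self):
        assert user_lift(self._result(1.0), self._result(0.0)) == 1.0

    def test_scheme_mismatch_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            user_lift(self._result(0.8), self._result(0.5, scheme="emotion_block"))


class TestPermutationTest:
    def test_all_positive_lifts_exact_p(self):
        assert permutation_test_mean_lift([0.3] * 10) == pytest.approx(1 / 1024)

    def test_symmetric_pair_counts_ties_conservatively(self):
        # sign-flip means of {+x, -x} enumerate to {0, +x, -x, 0}; with the
        # conservative convention every tie counts toward the alternative,
        # so p = 3/4 (near, and never below, the intuitive 1/2)
        assert permutation_test_mean_lift([0.2, -0.2]) == pytest.approx(0.75)

    def test_all_zero_lifts_give_one(self):
        assert permutation_test_mean_lift([0.0] * 8) == 1.0

    def test_monte_carlo_path_add_one_correction(self):
        lifts = np.full(25, 0.4)  # 2^25 >> n_perm forces Monte-Carlo
        p = permutation_test_mean_lift(lifts, n_perm=999, seed=5)
        assert p == pytest.approx(1 / 1000)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_mean_lift([])


class TestNormalizedImportance:
    def test_single_fold_direct_normalization(self):
        prof = normalized_importance([[0.2, 0.1, 0.1]], ["a", "b", "c"])
        assert prof.tolist() == [1.0, 0.5, 0.5]

    def test_identical_folds_match_single_fold(self):
        one = normalized_importance([[0.3, 0.6, 0.1]])
        many = normalized_importance([[0.3, 0.6, 0.1]] * 5)
        assert np.allclose(one, many)
        assert many.max() == 1.0

    def test_all_zero_importances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalized_importance([[0.0, 0.0]])
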