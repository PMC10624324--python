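import numpy as np
import pytest

from movequal import classify as cl
from movequal.errors import (ConfigurationError, DegenerateLabelsError,
                             InsufficientDataError)


# --- independent reference AdaBoost (plain loops, exhaustive stumps) -----

def reference_adaboost_predict(X, y, X_probe, n_rounds=10, lr=1.0):
    """Loop-based discrete AdaBoost with exhaustive min-error stumps.

    Candidate order mirrors the documented tie-breaks: features
    ascending, thresholds ascending (one below the minimum, then
    midpoints), left-class 0 before 1; first strict minimum wins.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    n, d = X.shape
    w = [1.0 / n] * n
    stumps = []
    for _ in range(n_rounds):
        best = None
        for f in range(d):
            uniq = sorted(set(X[:, f]))
            thresholds = [uniq[0] - 1.0] + [(uniq[i] + uniq[i + 1]) / 2
                                            for i in range(len(uniq) - 1)]
            for thr in thresholds:
                for left_cls in (0, 1):
                    err = 0.0
                    for i in range(n):
                        pred = left_cls if X[i, f] <= thr else 1 - left_cls
                        if pred != y[i]:
                            err += w[i]
                    if best is None or err < best[0] - 1e-15:
                        best = (err, f, thr, left_cls)
        err, f, thr, left_cls = best
        if err >= 0.5:
            break
        err_c = min(max(err, 1e-10), 1 - 1e-10)
        alpha = lr * np.log((1 - err_c) / err_c)
        stumps.append((alpha, f, thr, left_cls))
        if err == 0.0:
            break
        for i in range(n):
            pred = left_cls if X[i, f] <= thr else 1 - left_cls
            if pred != y[i]:
                w[i] *= np.exp(alpha)
        total = sum(w)
        w = [wi / total for wi in w]

    out = []
    for x in np.asarray(X_probe, float):
        score = 0.0
        for alpha, f, thr, left_cls in stumps:
            h = left_cls if x[f] <= thr else 1 - left_cls
            score += alpha * (2 * h - 1)
        out.append(1 if score > 0 else 0)
    return np.array(out)


class TestStratifiedSplit:
    def test_exact_proportions(self):
        y = np.array([1] * 20 + [0] * 80)
        train, val, test = cl.stratified_split(y, cl.BoostParams())
        assert (len(train), len(val), len(test)) == (80, 15, 5)
        assert (y[train].sum(), y[val].sum(), y[test].sum()) == (16, 3, 1)

    def test_largest_remainder_on_cohort_size(self):
        # 46 rows: 36.8 / 6.9 / 2.3 rounds to 37 / 7 / 2
        y = np.array([1] * 14 + [0] * 32)
        train, val, test = cl.stratified_split(y, cl.BoostParams())
        assert (len(train), len(val), len(test)) == (37, 7, 2)

    def test_disjoint_and_exhaustive(self):
        y = np.array([0, 1] * 23)
        parts = cl.stratified_split(y, cl.BoostParams())
        joined = np.concatenate(parts)
        assert len(joined) == len(y)
        assert len(np.unique(joined)) == len(y)

    def test_deterministic(self):
        y = np.array([1] * 14 + [0] * 32)
        a = cl.stratified_split(y, cl.BoostParams(seed=5))
        b = cl.stratified_split(y, cl.BoostParams(seed=5))
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1, s2)

    def test_starved_split_merges_test_into_validation(self):
        y = np.array([1] * 3 + [0] * 9)  # 3 positives cannot reach all splits
        with pytest.warns(UserWarning, match="absorbs"):
            train, val, test = cl.stratified_split(y, cl.BoostParams())
        assert test.size == 0
        assert len(train) + len(val) == len(y)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            cl.stratified_split(np.zeros(10, int), cl.BoostParams())


class TestTrainAdaboost:
    def test_separable_data_first_learner_suffices(self, rng):
        x = np.concatenate([rng.uniform(-5, -1, 30), rng.uniform(1, 5, 30)])
        y = (x > 0).astype(int)
        model = cl.train_adaboost(x[:, None], y,
                                  cl.BoostParams(base_learner="stump",
                                                 feature_subset="all"))
        assert len(model.trees) == 1  # zero-error round stops boosting
        assert np.array_equal(model.predict(x[:, None]), y)

    def test_weak_learner_weight_formula(self):
        # best stump errs on exactly 1 of 4 points: eps = 0.25,
        # alpha = lr * ln((1 - eps) / eps) = 0.1 * ln 3
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 0])
        model = cl.train_adaboost(
            X, y, cl.BoostParams(n_learners=1, learning_rate=0.1,
                                 base_learner="stump", feature_subset="all"))
        assert model.alphas[0] == pytest.approx(0.1 * np.log(3), abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            cl.train_adaboost(np.arange(8, dtype=float)[:, None],
                              np.ones(8, int), cl.BoostParams())

    def test_tree_depth_bounded(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        params = cl.BoostParams(n_learners=10, max_depth=3)
        model = cl.train_adaboost(X, y, params)
        from movequal.classify import _node_depth
        assert all(_node_depth(t) <= 3 for t in model.trees)

    def test_row_permutation_leaves_predictions_unchanged(self, rng):
        X = rng.normal(size=(40, 6))
        y = (X[:, 1] - X[:, 3] > 0).astype(int)
        probe = rng.normal(size=(25, 6))
        params = cl.BoostParams(n_learners=15, seed=3)
        base = cl.train_adaboost(X, y, params).predict(probe)
        perm = rng.permutation(40)
        permuted = cl.train_adaboost(X[perm], y[perm], params).predict(probe)
        assert np.array_equal(base, permuted)

    def test_matches_reference_on_small_datasets(self, rng):
        """Label-for-label equivalence with the loop-based exhaustive-stump
        reference across random datasets of at most 8 points x 2 features."""
        params = cl.BoostParams(n_learners=10, learning_rate=1.0,
                                max_depth=1, base_learner="stump",
                                feature_subset="all")
        checked = 0
        for _ in range(60):
            n = int(rng.integers(3, 9))
            X = np.round(rng.normal(size=(n, 2)) * 5, 2)
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            probe = np.round(rng.normal(size=(20, 2)) * 5, 2)
            model = cl.train_adaboost(X, y, params)
            got = model.predict(probe)
            want = reference_adaboost_predict(X, y, probe, n_rounds=10, lr=1.0)
            assert np.array_equal(got, want)
            checked += 1
        assert checked >= 40

    def test_ensemble_beats_best_single_learner_when_separable(self, rng):
        X = rng.normal(size=(50, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)  # needs more than one stump
        params = cl.BoostParams(n_learners=30, learning_rate=1.0,
                                base_learner="stump", feature_subset="all")
        model = cl.train_adaboost(X, y, params)
        ensemble_err = (model.predict(X) != y).mean()
        single = cl.EnsembleModel(trees=[model.trees[0]], alphas=[1.0],
                                  n_features=2)
        assert ensemble_err <= (single.predict(X) != y).mean()


class TestPredict:
    def leaf_model(self, leaves, alphas):
        return cl.EnsembleModel(trees=[{"leaf": v} for v in leaves],
                                alphas=alphas, n_features=2)

    def test_single_learner_vote(self):
        model = self.leaf_model([1], [0.7])
        assert model.predict(np.zeros((3, 2))).tolist() == [1, 1, 1]

    def test_weighted_vote_combination(self):
        # alphas (1.0, 0.4) voting (1, 0): net score +0.6 -> class 1
        model = self.leaf_model([1, 0], [1.0, 0.4])
        assert model.predict(np.zeros((1, 2)))[0] == 1

    def test_zero_score_tie_breaks_to_non_faulty(self):
        model = self.leaf_model([1, 0], [0.0, 0.0])
        assert model.predict(np.zeros((1, 2)))[0] == 0

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        y = (X[:, 0] > 0).astype(int)
        model = cl.train_adaboost(X, y, cl.BoostParams(n_learners=3))
        with pytest.raises(ValueError, match="dimensionality"):
            model.predict(rng.normal(size=(5, 3)))


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = cl.evaluate_predictions([0, 1, 0, 1], [0, 1, 0, 1])
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (1.0, 1.0, 1.0)
        assert rep.undefined == []

    def test_direct_ratios(self):
        rep = cl.EvaluationReport(tp=3, fn=1, tn=30, fp=2)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.9375)
        assert rep.accuracy == pytest.approx(0.9167, abs=1e-4)
        assert rep.n == 36

    def test_undefined_sensitivity_flagged_not_zeroed(self):
        rep = cl.evaluate_predictions([0, 0, 0], [0, 1, 0])
        assert np.isnan(rep.sensitivity)
        assert rep.undefined == ["sensitivity"]
        assert rep.specificity == pytest.approx(2 / 3)

    def test_empty_test_set_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = (X[:, 0] > 0).astype(int)
        model = cl.train_adaboost(X, y, cl.BoostParams(n_learners=2))
        with pytest.raises(InsufficientDataError):
            cl.evaluate(model, np.empty((0, 2)), np.empty(0, int))


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 2] > 0.2).astype(int)
        model = cl.train_adaboost(X, y, cl.BoostParams(n_learners=8))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = cl.EnsembleModel.from_json(path)
        assert np.array_equal(back.predict(X), model.predict(X))
        np.testing.assert_allclose(back.alphas, model.alphas)
        assert back.params == model.params


class TestBoostParams:
    @pytest.mark.parametrize("kwargs", [
        {"n_learners": 0},
        {"learning_rate": 0.0},
        {"split": (0.5, 0.3, 0.1)},
        {"base_learner": "forest"},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            cl.BoostParams(**kwargs)

    def test_sqrt_subset_size(self):
        p = cl.BoostParams()
        assert p.subset_size(15) == 3  # floor(sqrt(15))
        assert p.subset_size(1) == 1


class TestCrossValidate:
    def test_aggregates_out_of_fold_predictions(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        rep = cl.cross_validate(X, y, cl.BoostParams(n_learners=5), k=5)
        assert rep.n == 40
        assert rep.accuracy > 0.8

    def test_deterministic_for_seed(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        p = cl.BoostParams(n_learners=5, seed=11)
        a = cl.cross_validate(X, y, p, k=3)
        b = cl.cross_validate(X, y, p, k=3)
        assert a.as_row() == b.as_row()
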