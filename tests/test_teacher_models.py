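"""Teacher zoo, hyperparameter search, cross-validation, oversampling."""

import numpy as np
import pytest

from fluidsim.teacher_models import (
    ARCHITECTURES,
    cross_validate,
    cv_folds,
    load_bundle,
    make_classifier,
    optimize_hyperparameters,
    oversample_minority,
    save_bundle,
    train_teacher,
)


def _blobs(n=80, seed=0, separation=4.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([
        rng.normal(0, 1, size=(half, 5)),
        rng.normal(separation, 1, size=(n - half, 5)),
    ])
    y = np.array([0] * half + [1] * (n - half))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestZoo:
    EXPECTED = {"gnb", "sgd", "dt", "rf", "et", "knn", "mlp", "ab", "gb", "svc", "xgb"}

    def test_zoo_contains_the_eleven_architectures(self):
        assert set(ARCHITECTURES) == self.EXPECTED

    @pytest.mark.parametrize("arch", sorted(EXPECTED))
    def test_uniform_contract_fit_and_probability(self, arch):
        X, y = _blobs(60, seed=1)
        clf = make_classifier(arch, seed=0)
        clf.fit(X, y)
        proba = clf.predict_proba(X)
        assert proba.shape == (60, 2)
        assert np.all(proba >= 0) and np.all(proba <= 1)
        assert np.allclose(proba.sum(axis=1), 1.0)
        # separable blobs: every architecture should be far above chance
        assert (clf.predict(X) == y).mean() > 0.9

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError, match="zoo"):
            make_classifier("deep_transformer")


class TestOversample:
    @pytest.mark.parametrize(
        "n_neg, n_pos, target, expected_pos",
        [
            (90, 10, 1.0, 90),    # 9x replication
            (100, 30, 1.0, 90),   # 3x: closest without exceeding
            (50, 50, 1.0, 50),    # balanced input unchanged
            (100, 40, 0.5, 40),   # already beyond target
        ],
    )
    def test_integer_replication(self, n_neg, n_pos, target, expected_pos):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n_neg + n_pos, 3))
        y = np.array([0] * n_neg + [1] * n_pos)
        Xo, yo = oversample_minority(X, y, target_ratio=target)
        assert int((yo == 1).sum()) == expected_pos
        assert int((yo == 0).sum()) == n_neg  # majority untouched

    def test_rows_are_replicated_not_synthesized(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.array([0] * 8 + [1] * 2)
        Xo, yo = oversample_minority(X, y)
        minority_rows = {tuple(r) for r in X[y == 1]}
        assert {tuple(r) for r in Xo[yo == 1]} == minority_rows

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            oversample_minority(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestCrossValidate:
    def test_bookkeeping_counts(self):
        X, y = _blobs(100, seed=2)
        rep = cross_validate(X, y, architecture="dt", k=5, repeats=10, seed=0)
        assert len(rep.folds) == 50
        assert rep.mean["balanced_accuracy"] <= 1.0

    def test_separable_data_hits_ceiling(self):
        X, y = _blobs(100, seed=3, separation=8.0)
        rep = cross_validate(X, y, architecture="knn", k=5, repeats=2, seed=0)
        assert rep.mean["balanced_accuracy"] == pytest.approx(1.0)

    def test_stratified_folds_preserve_class_ratio(self):
        # 80/20 labels, k=5: every test fold holds 20% +/- 1 positives
        rng = np.random.default_rng(4)
        y = np.array([0] * 80 + [1] * 20)
        rng.shuffle(y)
        for tr, te in cv_folds(y, "stratified", k=5, repeats=2, seed=0):
            assert abs(int(y[te].sum()) - 4) <= 1

    def test_each_record_tested_once_per_repeat(self):
        y = np.array([0, 1] * 30)
        folds = cv_folds(y, "random", k=5, repeats=3, seed=1)
        counts = np.zeros(60, dtype=int)
        for _, te in folds:
            counts[te] += 1
        assert np.all(counts == 3)

    def test_fold_assignment_independent_of_architecture(self):
        y = np.array([0, 1] * 25)
        a = cv_folds(y, "stratified", 5, 2, seed=3)
        b = cv_folds(y, "stratified", 5, 2, seed=3)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb) and np.array_equal(tra, trb)

    def test_small_class_under_stratified_rejected(self):
        y = np.array([0] * 57 + [1] * 3)
        with pytest.raises(ValueError, match="class 1"):
            cv_folds(y, "stratified", k=5, repeats=1, seed=0)


class TestHPO:
    def test_single_configuration_returned(self):
        X, y = _blobs(50, seed=5)
        res = optimize_hyperparameters(
            X, y, architecture="dt", budget=5, k=5, n_repeats=1, seed=0,
            space={"max_depth": [3]},
        )
        assert res.best_params == {"max_depth": 3}

    def test_sensitivity_breaks_balanced_accuracy_ties(self):
        import pandas as pd
        from fluidsim.teacher_models import select_best_trial

        # two configs, equal balanced accuracy, sensitivities 0.6 vs 0.8:
        # the 0.8 one must win
        trials = pd.DataFrame({
            "params": ['{"a": 1}', '{"a": 2}', '{"a": 3}'],
            "balanced_accuracy": [0.9, 0.9, 0.85],
            "sensitivity": [0.6, 0.8, 0.99],
        })
        assert select_best_trial(trials) == 1
        # outside tolerance: raw balanced accuracy still rules
        assert select_best_trial(trials, tolerance=1e-6) != 2

    def test_depth_search_prefers_unlimited_on_interleaved_data(self):
        # XOR-like data: a depth-1 stump cannot separate, unlimited depth can;
        # exhaustive evaluation of both candidates must pick unlimited
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(200, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        res = optimize_hyperparameters(
            X, y, architecture="dt", budget=2, k=5, n_repeats=1, seed=0,
            space={"max_depth": [1, None]},
        )
        assert res.best_params == {"max_depth": None}

    def test_degenerate_inputs_rejected(self):
        X, y = _blobs(40, seed=7)
        with pytest.raises(ValueError, match="budget"):
            optimize_hyperparameters(X, y, architecture="dt", budget=0)
        with pytest.raises(ValueError, match="single class"):
            optimize_hyperparameters(X, np.zeros_like(y), architecture="dt", budget=1)

    def test_deterministic_given_seed(self):
        X, y = _blobs(60, seed=8)
        kw = dict(architecture="dt", budget=4, k=3, n_repeats=1, seed=5)
        assert (optimize_hyperparameters(X, y, **kw).best_params
                == optimize_hyperparameters(X, y, **kw).best_params)


class TestTrainTeacher:
    def test_memorizing_learner_recovers_training_labels(self, tiny_world):
        train = tiny_world.partner_train["P0"].features
        t = train_teacher(train, architecture="knn",
                          hyperparameters={"n_neighbors": 1}, seed=0)
        assert np.array_equal(t.predict(train), train.labels)

    def test_deterministic_given_seed(self, tiny_world):
        train = tiny_world.partner_train["P0"].features
        probe = tiny_world.partner_test["P0"].features
        a = train_teacher(train, architecture="sgd", seed=3)
        b = train_teacher(train, architecture="sgd", seed=3)
        assert np.array_equal(a.predict_proba_positive(probe),
                              b.predict_proba_positive(probe))

    def test_training_space_reference_attached(self, tiny_world):
        train = tiny_world.partner_train["P0"].features
        t = train_teacher(train, architecture="gnb", seed=0)
        assert t.training_fingerprints.shape == train.fingerprints.shape

    def test_single_class_rejected(self, tiny_world, fm_factory):
        fm = fm_factory(np.zeros((10, 3)), np.zeros((10, 8)), labels=[1] * 10)
        with pytest.raises(ValueError, match="single class"):
            train_teacher(fm, architecture="gnb")

    def test_config_hash_mismatch_rejected_at_predict(self, tiny_world, fm_factory):
        t = train_teacher(tiny_world.partner_train["P0"].features,
                          architecture="gnb", seed=0)
        alien = fm_factory(np.zeros((2, 16)), np.zeros((2, 2048)), labels=[0, 1],
                           config_hash="other")
        with pytest.raises(ValueError, match="mismatch"):
            t.predict_proba_positive(alien)

    def test_bundle_round_trip(self, tiny_world, tmp_path):
        train = tiny_world.partner_train["P0"].features
        probe = tiny_world.partner_test["P0"].features
        t = train_teacher(train, architecture="sgd", seed=1)
        save_bundle(t, tmp_path / "b")
        back = load_bundle(tmp_path / "b")
        assert back.architecture == "sgd"
        assert np.array_equal(back.predict_proba_positive(probe),
                              t.predict_proba_positive(probe))
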