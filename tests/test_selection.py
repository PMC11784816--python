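"""Wrapper feature selection: fitness, masking, the selector estimator,
and the end-to-end split/select/retrain/evaluate driver."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

import qgafs.selection as sel
from qgafs import FSConfig, QGAFeatureSelector, apply_mask, run_selection
from qgafs.qga import QGAConfig
from qgafs.selection import FeatureMask, FeatureMatrix, subset_fitness


class TestFeatureMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="contiguous"):
            FeatureMatrix(values=np.zeros((4, 2)), labels=[0, 0, 2, 2])
        with pytest.raises(ValueError, match="non-finite"):
            FeatureMatrix(values=np.array([[np.nan, 1.0]] * 4), labels=[0, 0, 1, 1])
        with pytest.raises(ValueError, match="at least 2"):
            FeatureMatrix(values=np.zeros((3, 2)), labels=[0, 0, 1])

    def test_csv_round_trip(self, tmp_path, two_class_matrix):
        path = tmp_path / "m.csv"
        two_class_matrix.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert np.allclose(back.values, two_class_matrix.values)
        assert np.array_equal(back.labels, two_class_matrix.labels)
        assert back.feature_names == two_class_matrix.feature_names

    def test_npz_round_trip(self, tmp_path, two_class_matrix):
        path = tmp_path / "m.npz"
        two_class_matrix.to_npz(path)
        back = FeatureMatrix.from_npz(path)
        assert np.array_equal(back.values, two_class_matrix.values)
        assert np.array_equal(back.informative_mask, two_class_matrix.informative_mask)

    def test_missing_label_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n3,4\n")
        with pytest.raises(ValueError, match="label"):
            FeatureMatrix.from_csv(path)


class TestApplyMask:
    def test_all_ones_is_identity(self, two_class_matrix):
        out = apply_mask(two_class_matrix, FeatureMask(np.ones(6, dtype=np.int8)))
        assert np.array_equal(out.values, two_class_matrix.values)
        assert out.feature_names == two_class_matrix.feature_names

    def test_column_subset_keeps_names_and_labels(self):
        m = FeatureMatrix(
            values=np.arange(12, dtype=float).reshape(4, 3),
            labels=[0, 0, 1, 1],
            feature_names=["f0", "f1", "f2"],
        )
        out = apply_mask(m, FeatureMask([1, 0, 1]))
        assert out.feature_names == ["f0", "f2"]
        assert np.array_equal(out.values, m.values[:, [0, 2]])
        assert np.array_equal(out.labels, m.labels)

    def test_all_zero_mask_rejected(self, two_class_matrix):
        with pytest.raises(ValueError, match="empty"):
            apply_mask(two_class_matrix, FeatureMask(np.zeros(6, dtype=np.int8)))

    def test_length_mismatch_rejected(self, two_class_matrix):
        with pytest.raises(ValueError, match="length"):
            apply_mask(two_class_matrix, FeatureMask([1, 0]))


class TestSubsetFitness:
    def test_all_zero_mask_scores_zero(self, two_class_matrix):
        m = two_class_matrix
        assert subset_fitness(m.values, m.labels, np.zeros(6)) == 0.0

    def test_separable_matrix_scores_high(self, two_class_matrix):
        m = two_class_matrix
        lam = 0.01
        score = subset_fitness(
            m.values, m.labels, np.ones(6), sparsity_weight=lam, random_state=0
        )
        assert score >= 0.95 - lam

    def test_duplicate_columns_score_identically(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 3))
        X[:, 0] += 3.0 * (np.arange(80) % 2)
        X[:, 2] = X[:, 0]  # exact copy
        y = np.arange(80) % 2
        f_orig = subset_fitness(X, y, [1, 0, 0], random_state=5)
        f_copy = subset_fitness(X, y, [0, 0, 1], random_state=5)
        assert f_orig == f_copy

    def test_degenerate_class_errors(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="class"):
            subset_fitness(X, y, [1, 1])


class TestQGAFeatureSelector:
    def test_sklearn_api_compliance(self, two_class_matrix):
        selector = QGAFeatureSelector(max_generations=3, random_state=0)
        cloned = clone(selector)
        assert cloned.get_params()["max_generations"] == 3
        m = two_class_matrix
        selector.fit(m.values, m.labels)
        assert selector.support_.shape == (6,)
        Xt = selector.transform(m.values)
        assert Xt.shape == (m.n, selector.support_.sum())

    def test_composes_with_pipeline(self, two_class_matrix):
        m = two_class_matrix
        pipe = Pipeline(
            [
                ("fs", QGAFeatureSelector(max_generations=3, random_state=0)),
                ("clf", LogisticRegression(max_iter=200)),
            ]
        )
        pipe.fit(m.values, m.labels)
        assert pipe.score(m.values, m.labels) > 0.9

    def test_rejects_single_feature(self):
        X = np.random.default_rng(0).normal(size=(40, 1))
        y = np.arange(40) % 2
        with pytest.raises(ValueError):
            QGAFeatureSelector().fit(X, y)

    def test_informative_feature_beats_noise_across_seeds(self):
        # d=2: one strongly informative column, one pure-noise column.
        # Exhaustive comparison of the three non-empty masks shows the
        # informative one must win; the selector should agree in >=18/20
        # seeded runs.
        rng = np.random.default_rng(10)
        n = 120
        y = np.arange(n) % 2
        X = rng.normal(size=(n, 2))
        X[:, 0] += 4.0 * y
        wins = 0
        for seed in range(20):
            selector = QGAFeatureSelector(
                population_size=10, max_generations=10, random_state=seed
            )
            selector.fit(X, y)
            wins += bool(selector.support_[0])
        assert wins >= 18

    def test_fitness_trajectory_is_monotone(self, separable_matrix):
        m = separable_matrix
        selector = QGAFeatureSelector(max_generations=8, random_state=1)
        selector.fit(m.values, m.labels)
        assert (np.diff(selector.fitness_history_) >= 0).all()

    def test_best_fitness_matches_reported_mask(self, separable_matrix):
        # The reported mask must reproduce the best recorded fitness.
        m = separable_matrix
        selector = QGAFeatureSelector(max_generations=6, random_state=2)
        selector.fit(m.values, m.labels)
        refit = subset_fitness(
            m.values,
            m.labels,
            selector.support_,
            cv=selector.cv,
            sparsity_weight=selector.sparsity_weight,
            random_state=selector.random_state,
        )
        assert refit == pytest.approx(selector.best_fitness_, abs=1e-12)


def _exhaustive_best(X, y, lam=0.0, seed=0):
    d = X.shape[1]
    best = -np.inf
    for bits in itertools.product((0, 1), repeat=d):
        if not any(bits):
            continue
        best = max(
            best,
            subset_fitness(
                X, y, np.array(bits), sparsity_weight=lam, random_state=seed
            ),
        )
    return best


class TestOracleProperties:
    def test_noise_features_never_raise_the_exhaustive_optimum(self):
        # Strongly separable 2-class data: the informative-only optimum is
        # already perfect, so appending pure-noise columns cannot improve
        # the best achievable (unpenalized) fitness.
        rng = np.random.default_rng(3)
        n = 100
        y = np.arange(n) % 2
        informative = rng.normal(size=(n, 2))
        informative[:, 0] += 8.0 * y
        informative[:, 1] -= 8.0 * y
        noise = rng.normal(size=(n, 4))
        base = _exhaustive_best(informative, y, lam=0.0)
        widened = _exhaustive_best(np.hstack([informative, noise]), y, lam=0.0)
        assert widened <= base + 1e-12

    def test_selector_matches_small_exhaustive_optimum(self):
        rng = np.random.default_rng(4)
        n, d = 150, 6
        y = np.arange(n) % 2
        X = rng.normal(size=(n, d))
        X[:, 1] += 2.5 * y
        X[:, 4] += 2.5 * y
        best = _exhaustive_best(X, y, lam=0.01, seed=0)
        selector = QGAFeatureSelector(
            max_generations=20, sparsity_weight=0.01, random_state=0
        )
        selector.fit(X, y)
        assert selector.best_fitness_ >= best - 0.02


@pytest.fixture(scope="module")
def small_config():
    return FSConfig(
        qga=QGAConfig(population_size=10, max_generations=5),
        head={"max_epochs": 15},
        seed=0,
    )


class TestRunSelection:
    def test_holdout_is_consumed_exactly_once(
        self, separable_matrix, small_config, monkeypatch
    ):
        calls = []
        original = sel._evaluate_holdout

        def spy(model, X_test, y_test, class_names):
            calls.append((X_test.shape, y_test.shape))
            return original(model, X_test, y_test, class_names)

        monkeypatch.setattr(sel, "_evaluate_holdout", spy)
        result = run_selection(separable_matrix, small_config)
        assert len(calls) == 1
        n_test = calls[0][1][0]
        assert n_test == round(0.2 * separable_matrix.n)
        assert result.report.confusion.sum() == n_test

    def test_same_seed_reproduces_everything(self, separable_matrix, small_config):
        r1 = run_selection(separable_matrix, small_config)
        r2 = run_selection(separable_matrix, small_config)
        assert r1.to_dict() == r2.to_dict()

    def test_result_is_serializable_and_consistent(
        self, separable_matrix, small_config
    ):
        result = run_selection(separable_matrix, small_config)
        d = result.to_dict()
        assert d["n_selected"] == len(d["selected_names"])
        assert d["mask_bits"].count("1") == d["n_selected"]
        assert 0.0 <= d["metrics"]["accuracy"] <= 1.0
        assert result.to_json()  # valid JSON string
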