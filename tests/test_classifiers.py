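"""Naive Bayes / random forest / KNN behavior and serialization."""

import numpy as np
import pandas as pd
import pytest

from radhist.classifiers import (GaussianNaiveBayes, positive_scores,
                                 train_classifier, train_knn,
                                 train_naive_bayes, train_random_forest)
from radhist.evaluation import auc
from radhist.io import split_xy
from radhist.serialize import load_model, save_model
from radhist.simulate import (TableSimConfig, informative_feature_names,
                              simulate_feature_tables)

from _oracles import naive_bayes_odds


def toy_frame(X, cols=None):
    X = np.asarray(X, dtype=float)
    cols = cols or [f"f{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, columns=cols)


class TestNaiveBayes:
    def test_closed_form_posterior_one_feature(self):
        # class+ ~ N(1,1), class- ~ N(-1,1), equal priors: log-odds at x is 2x
        nb = GaussianNaiveBayes()
        nb.classes_ = np.array([0, 1])
        nb.theta_ = np.array([[-1.0], [1.0]])
        nb.sigma_ = np.array([[1.0], [1.0]])
        nb.class_prior_ = np.array([0.5, 0.5])
        p = nb.predict_proba(np.array([[1.0]]))[0, 1]
        assert p == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)
        mid = nb.predict_proba(np.array([[0.0]]))[0, 1]
        assert mid == pytest.approx(0.5, abs=1e-12)

    def test_prior_only_limit(self):
        nb = GaussianNaiveBayes()
        nb.classes_ = np.array([0, 1])
        nb.theta_ = np.zeros((2, 2))
        nb.sigma_ = np.ones((2, 2))
        nb.class_prior_ = np.array([0.3, 0.7])
        p = nb.predict_proba(np.array([[0.4, -1.2]]))[:, 1]
        assert p == pytest.approx(0.7, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_posterior_matches_odds_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.6).astype(int)
        y[:2] = [0, 1]
        nb = GaussianNaiveBayes().fit(X, y)
        queries = rng.normal(size=(10, 3))
        got = nb.predict_proba(queries)[:, 1]
        for q, g in zip(queries, got):
            want = naive_bayes_odds(
                q, nb.theta_[1], nb.sigma_[1], nb.theta_[0], nb.sigma_[0],
                nb.class_prior_[1])
            assert g == pytest.approx(want, abs=1e-10)

    def test_zero_variance_feature_is_floored_not_crashing(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = np.repeat([0, 1], 5)
        nb = GaussianNaiveBayes().fit(X, y)
        assert nb.sigma_[0, 0] == pytest.approx(1e-9)
        assert np.isfinite(nb.predict_proba(X)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            GaussianNaiveBayes().fit(np.zeros((5, 2)), np.zeros(5))

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(8)
        X = toy_frame(rng.normal(size=(30, 2)))
        y = np.tile([0, 1], 15)
        m_pos = train_naive_bayes(X, y)
        m_neg = train_naive_bayes(X, 1 - y)
        s_pos = positive_scores(m_pos, X)
        s_neg = positive_scores(m_neg, X)
        assert np.allclose(s_pos + s_neg, 1.0, atol=1e-10)

    def test_informative_features_give_high_validation_auc(self):
        hits = 0
        for seed in range(10):
            cfg = TableSimConfig(n_train=200, n_valid=150, n_informative=5,
                                 effect_size_d=1.2, seed=seed)
            train, valid = simulate_feature_tables(cfg)
            names = informative_feature_names(cfg)
            Xt, yt = split_xy(train)
            Xv, yv = split_xy(valid)
            model = train_naive_bayes(Xt[names], yt)
            hits += auc(positive_scores(model, Xv[names]), yv) >= 0.85
        assert hits >= 9


class TestRandomForest:
    def test_hundred_trees_and_seed_determinism(self):
        rng = np.random.default_rng(0)
        X = toy_frame(rng.normal(size=(40, 3)))
        y = np.tile([0, 1], 20)
        m1 = train_random_forest(X, y, seed=5)
        m2 = train_random_forest(X, y, seed=5)
        assert len(m1.trees_) == 100
        assert np.array_equal(positive_scores(m1, X), positive_scores(m2, X))
        m3 = train_random_forest(X, y, seed=6)
        assert not np.array_equal(positive_scores(m1, X), positive_scores(m3, X))

    def test_separable_data_training_scores(self):
        rng = np.random.default_rng(1)
        n = 30
        X = np.vstack([rng.normal(-3, 0.5, (n, 2)), rng.normal(3, 0.5, (n, 2))])
        y = np.repeat([0, 1], n)
        model = train_random_forest(toy_frame(X), y, seed=0)
        scores = positive_scores(model, toy_frame(X))
        assert np.all(scores[y == 1] >= 0.9)
        assert np.all(scores[y == 0] <= 0.1)

    def test_local_weighted_voting_mode(self):
        rng = np.random.default_rng(2)
        X = toy_frame(rng.normal(size=(60, 3)))
        y = (X["f0"] > 0).astype(int).to_numpy()
        model = train_random_forest(X, y, seed=0, local_k=10)
        scores = positive_scores(model, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert auc(scores, y) > 0.9


class TestKNN:
    def test_neighbor_fraction_score(self):
        # 5 positives / 4 negatives among the 9 nearest -> 5/9
        X = np.arange(9.0)[:, None]
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
        model = train_knn(toy_frame(X), y, k=9)
        assert positive_scores(model, toy_frame([[4.0]]))[0] == pytest.approx(5 / 9)

    def test_k1_returns_nearest_label(self):
        X = toy_frame([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 1, 0, 1])
        model = train_knn(X, y, k=1)
        assert positive_scores(model, toy_frame([[1.01]]))[0] == 1.0
        assert positive_scores(model, toy_frame([[2.01]]))[0] == 0.0

    def test_coincident_positives_score_one(self):
        X = toy_frame(np.zeros((12, 2)))
        y = np.array([1] * 9 + [0] * 3)
        # 9 positives at the origin plus far negatives
        X.iloc[9:] = 50.0
        model = train_knn(X, y, k=9)
        assert positive_scores(model, toy_frame([[0.0, 0.0]]))[0] == 1.0

    def test_k_larger_than_n_rejected(self):
        X = toy_frame(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError):
            train_knn(X, np.array([0, 1, 0, 1, 0]), k=9)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        X = toy_frame(rng.normal(size=(40, 3)))
        y = np.tile([0, 1], 20)
        s_pos = positive_scores(train_knn(X, y), X)
        s_neg = positive_scores(train_knn(X, 1 - y), X)
        assert np.allclose(s_pos + s_neg, 1.0, atol=1e-12)


class TestCommonContracts:
    @pytest.mark.parametrize("kind", ["naive_bayes", "random_forest", "knn"])
    def test_scores_in_unit_interval_and_feature_check(self, kind):
        rng = np.random.default_rng(10)
        X = toy_frame(rng.normal(size=(50, 4)))
        y = np.tile([0, 1], 25)
        model = train_classifier(X, y, kind, seed=1)
        s = positive_scores(model, X)
        assert np.all((s >= 0) & (s <= 1))
        with pytest.raises(ValueError, match="features"):
            positive_scores(model, X[list(X.columns[::-1])])

    def test_string_labels_positive_is_adeno(self):
        X = toy_frame([[0.0], [0.1], [5.0], [5.1]])
        y = np.array(["SQUAMOUS", "SQUAMOUS", "ADENO", "ADENO"])
        model = train_naive_bayes(X, y)
        s = positive_scores(model, X)
        assert s[2] > 0.9 and s[0] < 0.1

    @pytest.mark.parametrize("kind", ["naive_bayes", "random_forest", "knn"])
    def test_json_serialization_roundtrip(self, kind, tmp_path):
        rng = np.random.default_rng(11)
        X = toy_frame(rng.normal(size=(30, 3)))
        y = np.tile([0, 1], 15)
        model = train_classifier(X, y, kind, seed=2)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        want = positive_scores(model, X)
        got = loaded.predict_proba(X.to_numpy())[:, 1]
        assert np.allclose(got, want, atol=1e-12)
        assert loaded.feature_names_ == ["f0", "f1", "f2"]
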