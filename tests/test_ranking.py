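"""The 24 filter ranking methods: hand values, oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

from radhist.io import split_xy
from radhist.ranking import (RANKING_METHODS, RELIEF_METHODS, Ranking,
                             RankingSelector, ReliefFConfig, contingency_table,
                             discretize, hellinger_impurity_score,
                             impurity_score, rank_features, relieff_weights,
                             select_top)
from radhist.simulate import (TableSimConfig, informative_feature_names,
                              simulate_feature_tables)

from _oracles import relieff_bruteforce

DIAGONAL = [[5, 0], [0, 5]]


class TestDiscretize:
    def test_eight_values_four_bins(self):
        assert discretize(np.arange(1, 9), 4).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]

    def test_constant_input_single_bin(self):
        assert set(discretize(np.full(10, 3.3), 4)) == {0}

    def test_normal_draws_quartile_occupancy(self):
        x = np.random.default_rng(0).standard_normal(1000)
        counts = np.bincount(discretize(x, 4))
        assert len(counts) == 4
        assert all(abs(c - 250) <= 1 for c in counts)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            discretize([], 4)


class TestImpurityScores:
    def test_diagonal_hand_values(self):
        assert impurity_score("InfGain", DIAGONAL) == pytest.approx(1.0, abs=1e-9)
        assert impurity_score("GainRatio", DIAGONAL) == pytest.approx(1.0, abs=1e-9)
        assert impurity_score("Gini", DIAGONAL) == pytest.approx(0.5, abs=1e-9)
        assert impurity_score("DKM", DIAGONAL) == pytest.approx(1.0, abs=1e-9)
        expected_mdl = (np.log2(252) + np.log2(11) - 2 * np.log2(6)) / 10
        assert impurity_score("MDL", DIAGONAL) == pytest.approx(expected_mdl, abs=1e-9)
        assert expected_mdl == pytest.approx(0.6267, abs=5e-5)
        assert impurity_score("Accuracy", DIAGONAL) == pytest.approx(0.5, abs=1e-9)

    def test_single_value_column_scores_zero(self):
        t = [[4], [6]]
        assert impurity_score("MDL", t) == pytest.approx(0.0, abs=1e-12)
        assert impurity_score("InfGain", t) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_degenerate_scores_zero(self):
        assert impurity_score("InfGain", [[3, 4], [0, 0]]) == 0.0
        assert hellinger_impurity_score("ImpurityHellinger", [[3, 4], [0, 0]]) == 0.0

    @pytest.mark.parametrize("method,prior", [
        ("InfGain", lambda p: -(p * np.log2(p) + (1 - p) * np.log2(1 - p))),
        ("Gini", lambda p: 1 - p ** 2 - (1 - p) ** 2),
        ("DKM", lambda p: 2 * np.sqrt(p * (1 - p))),
        ("Accuracy", lambda p: 1 - max(p, 1 - p)),
    ])
    def test_pure_split_equals_prior_impurity(self, method, prior):
        t = [[6, 0], [0, 4]]  # pure partition, priors 0.6/0.4
        assert impurity_score(method, t) == pytest.approx(prior(0.6), abs=1e-12)

    def test_class_independent_split_scores_zero(self):
        t = [[6, 3], [4, 2]]  # p(class|value) equals p(class) in every column
        for method in ("InfGain", "GainRatio", "Gini", "DKM", "Accuracy"):
            assert impurity_score(method, t) == pytest.approx(0.0, abs=1e-12)
        for method in ("ImpurityHellinger", "ImpurityEuclid"):
            assert hellinger_impurity_score(method, t) == pytest.approx(0.0, abs=1e-12)

    def test_equal_gini_diagonal(self):
        assert hellinger_impurity_score("EqualGini", DIAGONAL) == pytest.approx(0.5)

    def test_uniform_distribution_unchanged_by_split_scores_zero(self):
        t = [[3, 3], [3, 3]]
        for v in ("ImpurityHellinger", "EqualHellinger", "ImpurityEuclid"):
            assert hellinger_impurity_score(v, t) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("pair", [
        ("EqualHellinger", "ImpurityHellinger"),
        ("EqualInf", "InfGain"),
        ("EqualGini", "Gini"),
        ("EqualDKM", "DKM"),
    ])
    def test_equal_weights_match_probability_weights_on_balanced_columns(self, pair):
        equal, weighted = pair
        rng = np.random.default_rng(4)
        for _ in range(10):
            # both columns hold the same number of samples
            a = rng.integers(0, 6, size=2)
            t = np.column_stack([a, a[::-1] + rng.integers(0, 3)])
            if t.sum() < 2 or t.sum(axis=0).min() == 0 or (t.sum(axis=1) > 0).sum() < 2:
                continue
            if t.sum(axis=0)[0] != t.sum(axis=0)[1]:
                continue
            e = hellinger_impurity_score(equal, t)
            w = (impurity_score(weighted, t) if weighted in
                 ("InfGain", "Gini", "DKM") else
                 hellinger_impurity_score(weighted, t))
            if weighted == "Gini":
                # both are purity gains with identical weights here
                assert e == pytest.approx(w, abs=1e-12)
            elif weighted in ("InfGain", "DKM"):
                assert e == pytest.approx(w, abs=1e-12)
            else:
                assert e == pytest.approx(w, abs=1e-12)

    def test_value_relabeling_invariance(self):
        t = np.array([[5, 1, 2], [0, 4, 3]])
        perm = t[:, [2, 0, 1]]
        for m in ("InfGain", "GainRatio", "Gini", "MDL", "DKM", "Accuracy"):
            assert impurity_score(m, t) == pytest.approx(impurity_score(m, perm))
        for m in ("ImpurityHellinger", "EqualHellinger", "ImpurityEuclid"):
            assert hellinger_impurity_score(m, t) == pytest.approx(
                hellinger_impurity_score(m, perm))


class TestReliefF:
    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(20, 2.0), rng.normal(size=20)])
        y = np.repeat([0, 1], 10)
        w = relieff_weights(X, y, "ReliefFequalK", ReliefFConfig(k=3))
        assert w[0] == 0.0

    def test_label_copy_feature_weight_one(self):
        y = np.tile([0, 1], 10)
        X = y[:, None].astype(float)
        w = relieff_weights(X, y, "ReliefFequalK", ReliefFConfig(k=5))
        assert w[0] == pytest.approx(1.0)

    def test_twelve_sample_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 3))
        y = np.array([0, 1] * 6)
        for variant in ("ReliefFequalK", "ReliefFdistance", "ReliefFbestK"):
            got = relieff_weights(X, y, variant, ReliefFConfig(k=2))
            want = relieff_bruteforce(X, y, variant, k=2)
            assert np.max(np.abs(got - want)) <= 1e-12, variant

    @pytest.mark.parametrize("variant", [v for v in RELIEF_METHODS
                                         if v != "ReliefFsmp"])
    @pytest.mark.parametrize("seed", range(7))
    def test_random_datasets_match_oracle(self, variant, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(8, 21))
        p = int(rng.integers(2, 6))
        X = rng.normal(size=(n, p))
        y = np.concatenate([np.zeros(n // 2), np.ones(n - n // 2)]).astype(int)
        rng.shuffle(y)
        if min((y == 0).sum(), (y == 1).sum()) < 2:
            y[:2] = 0
            y[2:4] = 1
        got = relieff_weights(X, y, variant, ReliefFConfig(k=3))
        want = relieff_bruteforce(X, y, variant, k=3)
        assert np.max(np.abs(got - want)) <= 1e-12

    def test_sampled_variant_matches_oracle_given_same_references(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        y = np.array([0, 1] * 7 + [0])
        cfg = ReliefFConfig(k=3, seed=5)
        got = relieff_weights(X, y, "ReliefFsmp", cfg)
        refs = np.random.default_rng(5).integers(0, 15, size=15)
        want = relieff_bruteforce(X, y, "ReliefFsmp", k=3, refs=list(refs))
        assert np.max(np.abs(got - want)) <= 1e-12

    def test_small_class_falls_back_to_available_members(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        y = np.array([0, 0, 1, 1, 1, 1, 1, 1])
        w = relieff_weights(X, y, "ReliefFequalK", ReliefFConfig(k=5))
        assert np.all(np.isfinite(w))


class TestRankingFrontend:
    def test_registry_exposes_24_documented_methods(self):
        assert len(RANKING_METHODS) == 24
        for name in ("ReliefFdistance", "ReliefFbestK", "ReliefFmerit",
                     "ReliefFsqrDistance", "GainRatio", "ImpurityHellinger",
                     "EqualHellinger"):
            assert name in RANKING_METHODS

    def test_unknown_method_rejected(self, small_signal_table):
        _, train, _ = small_signal_table
        X, y = split_xy(train)
        with pytest.raises(ValueError, match="unknown ranking method"):
            rank_features(X, y, "Lasso")

    @pytest.mark.parametrize("method", ["InfGain", "ReliefFdistance", "MDL",
                                        "ImpurityHellinger", "ReliefFsmp"])
    def test_complete_deterministic_ranking(self, small_signal_table, method):
        _, train, _ = small_signal_table
        X, y = split_xy(train)
        r1 = rank_features(X, y, method, seed=3)
        r2 = rank_features(X, y, method, seed=3)
        assert r1 == r2
        assert sorted(r1.features) == sorted(X.columns)
        scores = [s for _, s in r1.entries]
        assert scores == sorted(scores, reverse=True)

    def test_feature_order_permutation_invariance(self, small_signal_table):
        _, train, _ = small_signal_table
        X, y = split_xy(train)
        shuffled = X[list(X.columns[::-1])]
        for method in ("InfGain", "ReliefFequalK", "EqualHellinger"):
            a = rank_features(X, y, method)
            b = rank_features(shuffled, y, method)
            assert a.entries == b.entries

    def test_informative_features_outrank_noise(self):
        cfg = TableSimConfig(n_train=500, n_valid=10, n_blocks=5, block_size=3,
                             n_noise=10, n_informative=5, effect_size_d=1.2,
                             seed=9)
        train, _ = simulate_feature_tables(cfg)
        X, y = split_xy(train)
        informative = informative_feature_names(cfg)
        noise = [c for c in X.columns if c not in informative]
        for method in ("InfGain", "ReliefFdistance"):
            scores = rank_features(X, y, method).scores
            median_noise = np.median([scores[c] for c in noise])
            for f in informative:
                assert scores[f] > median_noise, (method, f)

    def test_null_table_rankings_well_defined(self):
        cfg = TableSimConfig(n_train=80, n_valid=10, effect_size_d=0.0, seed=13)
        train, _ = simulate_feature_tables(cfg)
        X, y = split_xy(train)
        for method in RANKING_METHODS:
            r = rank_features(X, y, method, seed=1)
            assert np.isfinite([s for _, s in r.entries]).all()

    def test_infgain_monotone_in_effect_size(self):
        scores = []
        for d in (0.0, 0.5, 1.0, 1.5):
            cfg = TableSimConfig(n_train=400, n_valid=10, n_informative=1,
                                 n_noise=5, effect_size_d=d, seed=17)
            train, _ = simulate_feature_tables(cfg)
            X, y = split_xy(train)
            name = informative_feature_names(cfg)[0]
            scores.append(rank_features(X, y, "InfGain").scores[name])
        assert all(b >= a for a, b in zip(scores, scores[1:]))

    def test_select_top_sizes_and_capping(self, small_signal_table):
        _, train, _ = small_signal_table
        X, y = split_xy(train)
        r = rank_features(X, y, "Gini")
        assert len(select_top(r, 5)) == 5
        assert select_top(r, len(r.entries)) == r.features
        with pytest.warns(UserWarning):
            capped = select_top(r, 10_000)
        assert capped == r.features
        assert select_top(r, 5) == select_top(r, 5)

    def test_sklearn_selector(self, small_signal_table):
        cfg, train, _ = small_signal_table
        X, y = split_xy(train)
        sel = RankingSelector(method="ReliefFdistance", n_features=4).fit(X, y)
        out = sel.transform(X)
        assert out.shape == (len(X), 4)
        assert isinstance(sel.ranking_, Ranking)
        informative = set(informative_feature_names(cfg))
        assert informative & set(out.columns)
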