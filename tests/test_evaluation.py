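"""AUC, permutation significance, FDR, cutoffs and the univariate screen."""

import numpy as np
import pandas as pd
import pytest

from radhist.evaluation import (auc, confusion_metrics, fdr_adjust,
                                optimal_cutoff, permutation_pvalue, roc_result,
                                univariate_screen)
from radhist.io import split_xy
from radhist.simulate import TableSimConfig, simulate_feature_tables

from _oracles import auc_pair_counting


class TestAUC:
    def test_hand_example(self):
        assert auc([1, 3, 2, 4], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        assert auc(np.ones(10), np.tile([0, 1], 5)) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 2], [1, 1])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        scores = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], size=n)
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1
        assert auc(scores, y) == pytest.approx(auc_pair_counting(scores, y),
                                               abs=1e-14)


class TestPermutation:
    def test_perfect_separation_attains_addone_floor(self):
        y = np.repeat([0, 1], 20)
        scores = y.astype(float)
        p = permutation_pvalue(scores, y, n_iter=1000, seed=0)
        assert p == pytest.approx(1 / 1001)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = np.tile([0, 1], 20)
        assert permutation_pvalue(s, y, seed=3) == permutation_pvalue(s, y, seed=3)

    def test_invalid_iterations_rejected(self):
        with pytest.raises(ValueError):
            permutation_pvalue([1, 2], [0, 1], n_iter=0)


class TestFDR:
    def test_stepup_hand_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.9])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.9])

    def test_equal_pvalues_unchanged(self):
        q = fdr_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_q_dominates_p(self):
        p = np.random.default_rng(0).random(50)
        assert np.all(fdr_adjust(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([-0.1, 0.5])


class TestROCResult:
    def test_ci_brackets_auc_and_clipped(self):
        rng = np.random.default_rng(2)
        y = np.tile([0, 1], 30)
        s = rng.normal(size=60) + y
        for method in ("hanley-mcneil", "delong"):
            r = roc_result(s, y, n_iter=200, seed=0, ci_method=method)
            assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0
            assert 0 < r.p_perm <= 1


class TestCutoffMetrics:
    def test_confusion_hand_counts(self):
        # TP=11 FP=4 FN=9 TN=16
        scores = np.concatenate([np.ones(11), np.ones(4), np.zeros(9), np.zeros(16)])
        labels = np.concatenate([np.ones(11), np.zeros(4), np.ones(9), np.zeros(16)])
        m = confusion_metrics(scores, labels, cutoff=0.5)
        assert (m.tp, m.fp, m.fn, m.tn) == (11, 4, 9, 16)
        assert m.sensitivity == pytest.approx(0.55)
        assert m.specificity == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.733, abs=5e-4)
        assert m.npv == pytest.approx(0.64)
        assert m.accuracy == pytest.approx(0.675)

    def test_perfect_separation_perfect_metrics(self):
        y = np.repeat([0, 1], 10)
        s = y.astype(float)
        c = optimal_cutoff(s, y)
        m = confusion_metrics(s, y, c)
        assert m.sensitivity == m.specificity == m.accuracy == 1.0

    def test_cutoff_above_all_scores(self):
        y = np.tile([0, 1], 10)
        m = confusion_metrics(np.zeros(20), y, cutoff=1.0)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_tied_j_resolves_to_lowest_cutoff(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        assert optimal_cutoff(s, y) == pytest.approx(0.8)

    def test_single_class_validation_flagged(self):
        m = confusion_metrics([0.2, 0.8], [1, 1], cutoff=0.5)
        assert not m.defined
        assert np.isnan(m.specificity)


class TestUnivariateScreen:
    def test_label_copy_feature_maximally_significant(self):
        rng = np.random.default_rng(3)
        y = np.tile([0, 1], 30)
        X = pd.DataFrame({"signal": y + rng.normal(0, 0.05, 60),
                          "noise": rng.normal(size=60)})
        screen = univariate_screen(X, y, n_permutations=500, seed=1)
        assert screen.loc["signal", "auc"] > 0.99
        assert bool(screen.loc["signal", "significant"])
        assert screen.loc["signal", "direction"] == 1

    def test_orientation_free_auc_reported(self):
        rng = np.random.default_rng(4)
        y = np.tile([0, 1], 40)
        X = pd.DataFrame({"inverted": -3.0 * y + rng.normal(0, 0.3, 80)})
        screen = univariate_screen(X, y, n_permutations=300, seed=2)
        assert screen.loc["inverted", "auc"] > 0.95
        assert screen.loc["inverted", "direction"] == -1

    def test_null_table_rarely_flags_anything(self):
        flagged = 0
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(60, 50)),
                             columns=[f"f{i}" for i in range(50)])
            y = np.tile([0, 1], 30)
            screen = univariate_screen(X, y, n_permutations=300, seed=seed)
            flagged += int(screen["significant"].sum() > 0)
        assert flagged <= 2  # FDR at 5% keeps null discoveries rare

    def test_planted_signal_all_flagged(self):
        cfg = TableSimConfig(n_train=500, n_valid=10, n_informative=5,
                             effect_size_d=1.2, n_noise=10, seed=6)
        train, _ = simulate_feature_tables(cfg)
        X, y = split_xy(train)
        from radhist.simulate import informative_feature_names

        screen = univariate_screen(X, y, n_permutations=500, seed=0)
        for name in informative_feature_names(cfg):
            assert bool(screen.loc[name, "significant"])
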