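import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

import sparpaf as sp
from sparpaf.exceptions import ParameterError, SrrsError
from sparpaf.ml import EnsembleModel, METRIC_NAMES

from conftest import make_gaussian_table


def _blobs(n_maj=90, n_min=10, sep=6.0, d=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_maj, d)), rng.normal(sep, 1, (n_min, d))])
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


class TestAsuwo:
    def test_balanced_input_untouched(self):
        X, y = _blobs(20, 20)
        Xa, ya, mask = sp.asuwo_oversample(X, y)
        assert mask.sum() == 0 and np.array_equal(Xa, X)

    def test_balances_and_preserves_real_rows(self):
        X, y = _blobs(90, 10)
        Xa, ya, mask = sp.asuwo_oversample(X, y, sp.AsuwoConfig(seed=1))
        assert np.bincount(ya).tolist() == [90, 90]
        assert np.array_equal(Xa[: len(y)], X)
        assert mask.sum() == 80 and not mask[: len(y)].any()

    def test_synthetic_rows_are_convex_combinations(self):
        X, y = _blobs(90, 10)
        Xa, ya, mask = sp.asuwo_oversample(X, y, sp.AsuwoConfig(seed=1))
        Xmin = X[y == 1]
        for s in Xa[mask]:
            found = False
            for i, j in itertools.combinations_with_replacement(range(len(Xmin)), 2):
                d = Xmin[j] - Xmin[i]
                if np.allclose(d, 0):
                    found = found or np.allclose(s, Xmin[i], atol=1e-9)
                    continue
                k = int(np.argmax(np.abs(d)))
                lam = (s[k] - Xmin[i][k]) / d[k]
                if -1e-9 <= lam <= 1 + 1e-9 and np.allclose(s, Xmin[i] + lam * d, atol=1e-8):
                    found = True
                    break
            assert found

    def test_seeded_determinism(self):
        X, y = _blobs(50, 8)
        a = sp.asuwo_oversample(X, y, sp.AsuwoConfig(seed=3))[0]
        b = sp.asuwo_oversample(X, y, sp.AsuwoConfig(seed=3))[0]
        assert np.array_equal(a, b)

    def test_single_minority_rejected(self):
        X, y = _blobs(10, 1)
        with pytest.raises(ParameterError):
            sp.asuwo_oversample(X, y)


class TestEnsemble:
    def test_separable_blobs_perfect_members(self):
        X, y = _blobs(40, 40, sep=8.0)
        model = sp.train_ensemble(X, y, sp.EnsembleConfig(seed=0))
        post = model.member_posteriors(X)
        for m in range(3):
            assert np.mean((post[:, m] >= 0.5) == y) == 1.0

    def test_training_determinism(self):
        X, y = _blobs(30, 30, sep=2.0)
        p1, l1 = sp.score_substrip(sp.train_ensemble(X, y, sp.EnsembleConfig(seed=4)), X)
        p2, l2 = sp.score_substrip(sp.train_ensemble(X, y, sp.EnsembleConfig(seed=4)), X)
        assert np.array_equal(p1, p2) and np.array_equal(l1, l2)

    def test_zero_variance_feature_warns(self):
        X, y = _blobs(20, 20)
        X = np.column_stack([X, np.ones(len(X))])
        with pytest.warns(UserWarning, match="zero-variance"):
            sp.train_ensemble(X, y)

    def test_k_exceeding_training_size_rejected(self):
        X, y = _blobs(4, 4, d=2)
        with pytest.raises(ParameterError):
            sp.train_ensemble(X, y, sp.EnsembleConfig(k=9))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ParameterError):
            sp.train_ensemble(X, np.zeros(20, dtype=int))


class _StubModel(EnsembleModel):
    """Fixed member posteriors, for exercising the vote logic in isolation."""

    def __init__(self, posteriors):
        self._post = np.asarray(posteriors, dtype=float)
        self.cfg = sp.EnsembleConfig()

    def member_posteriors(self, X):
        n = len(np.atleast_2d(np.asarray(X)))
        return np.tile(self._post, (n, 1))


class TestVoteLogic:
    def test_member_majority_all_combinations(self):
        for combo in itertools.product([0, 1], repeat=3):
            post = [0.9 if c else 0.1 for c in combo]
            _, label = sp.score_substrip(_StubModel(post), np.zeros(4))
            assert label == int(sum(combo) >= 2)

    def test_combined_posterior_is_member_mean(self):
        post, label = sp.score_substrip(_StubModel([1.0, 1.0, 1.0]), np.zeros(4))
        assert post == 1.0 and label == 1
        post, _ = sp.score_substrip(_StubModel([0.2, 0.4, 0.9]), np.zeros(4))
        assert np.isclose(post, 0.5)

    def test_subject_majority_all_combinations(self):
        for combo in itertools.product([0, 1], repeat=9):
            score, label = sp.classify_subject(list(combo))
            assert score == sum(combo) / 9
            assert label == int(sum(combo) > 4.5)

    def test_subject_threshold_examples(self):
        assert sp.classify_subject([1, 1, 1, 1, 1, 0, 0, 0, 0]) == (5 / 9, 1)
        assert sp.classify_subject([1, 1, 1, 1, 0, 0, 0, 0, 0]) == (4 / 9, 0)

    def test_empty_subject_rejected(self):
        with pytest.raises(ParameterError):
            sp.classify_subject([])


class TestMetrics:
    def test_perfect_predictions(self):
        m = sp.compute_metrics([1, 0, 1, 0], [1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert m["accuracy"] == 100 and m["sensitivity"] == 100 and m["specificity"] == 100
        assert m["roc_auc"] == 1.0 and m["f1_paf"] == 100 and m["f1_ctr"] == 100

    def test_hand_computed_confusion_table(self):
        # TP=3 FN=1 TN=8 FP=2
        true = [1] * 4 + [0] * 10
        pred = [1, 1, 1, 0] + [0] * 8 + [1, 1]
        m = sp.compute_metrics(true, pred)
        assert np.isclose(m["sensitivity"], 75.0)
        assert np.isclose(m["specificity"], 80.0)
        assert np.isclose(m["accuracy"], 78.5714, atol=1e-3)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(0)
        true = np.array([1] * 50 + [0] * 50)
        aucs = [
            sp.compute_metrics(true, true, rng.uniform(size=100))["roc_auc"]
            for _ in range(200)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_single_class_auc_missing(self):
        m = sp.compute_metrics([1, 1], [1, 0], [0.6, 0.4])
        assert np.isnan(m["roc_auc"])


class TestSrrs:
    def test_metric_schema_and_interval_order(self):
        table = make_gaussian_table(n_control=16, n_paf=4, effect=2.0)
        cfg = sp.SrrsConfig(10, 12, 3, 4, 1, seed=0)
        cv = sp.srrs_crossvalidate(table, cfg)
        for level in ("substrip", "subject"):
            for metric in METRIC_NAMES:
                mean, lo, hi = cv.aggregate.loc[(level, metric)]
                if np.isfinite(mean):
                    assert lo - 1e-9 <= mean <= hi + 1e-9

    def test_interval_contains_run_median(self):
        table = make_gaussian_table(n_control=16, n_paf=4, effect=1.0, seed=3)
        cv = sp.srrs_crossvalidate(table, sp.SrrsConfig(20, 12, 3, 4, 1, seed=1))
        sub = cv.per_run[cv.per_run.level == "subject"]
        med = sub["accuracy"].median()
        _, lo, hi = cv.aggregate.loc[("subject", "accuracy")]
        assert lo <= med <= hi

    def test_mismatched_cohort_counts_rejected(self):
        table = make_gaussian_table(n_control=10, n_paf=4)
        with pytest.raises(SrrsError):
            sp.srrs_crossvalidate(table, sp.SrrsConfig(5, 12, 3, 4, 1, seed=0))

    def test_n_runs_beyond_distinct_splits_rejected(self):
        table = make_gaussian_table(n_control=5, n_paf=4)
        # C(5,4) * C(4,3) = 20 distinct training sets
        with pytest.raises(SrrsError, match="20"):
            sp.srrs_crossvalidate(table, sp.SrrsConfig(21, 4, 3, 1, 1, seed=0))

    def test_unknown_feature_rejected(self):
        table = make_gaussian_table()
        with pytest.raises(ParameterError):
            sp.srrs_crossvalidate(table, sp.SrrsConfig(2, 12, 3, 4, 1), ["nope"])


class TestForwardSelection:
    def test_planted_feature_found_first(self):
        rng = np.random.default_rng(0)
        table = make_gaussian_table(n_control=16, n_paf=4, n_features=1, effect=0.0, seed=1)
        table = table.rename(columns={"g0": "noise0"})
        for k in range(1, 4):
            table[f"noise{k}"] = rng.normal(size=len(table))
        table["planted"] = rng.normal((table.label == "paf") * 4.0, 0.5)
        cfg = sp.SrrsConfig(6, 12, 3, 4, 1, seed=2)
        selected = sp.forward_feature_select(table, cfg, max_features=3)
        assert selected[0] == "planted"

    def test_rerun_same_seed_identical(self):
        table = make_gaussian_table(n_control=12, n_paf=4, n_features=3, effect=1.5, seed=5)
        cfg = sp.SrrsConfig(4, 9, 3, 3, 1, seed=7)
        assert sp.forward_feature_select(table, cfg, max_features=2) == sp.forward_feature_select(
            table, cfg, max_features=2
        )
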