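import numpy as np
import pytest
from scipy import stats

from dtwfc import (
    CVProtocol,
    FeatureTable,
    derive_seed,
    evaluate_metrics,
    fold_safe_pca,
    inner_tune,
    nested_cv,
    optimistically_biased_cv,
    plain_kfold_cv,
    run_cv,
    stratified_kfold,
)
from dtwfc.cv import RankCappedPCA, fit_outer_fold, fold_indices
from dtwfc.models import ModelSpec, model_spec
from dtwfc.synth import pure_noise_dataset


def make_table(X, y, measure="noise"):
    n, p = X.shape
    return FeatureTable(
        X=X,
        feature_names=[f"f{i}" for i in range(p)],
        labels=np.asarray(y, dtype=int),
        subject_ids=[f"s{i}" for i in range(n)],
        measure=measure,
    )


def oracle_table(n=24, p=10, seed=0):
    """First feature encodes the label with a wide margin; the rest is
    low-amplitude noise, so any sensible classifier separates perfectly."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = 0.3 * rng.standard_normal((n, p))
    X[:, 0] = y * 8.0 - 4.0
    return make_table(X, y)


class TestFolds:
    def test_perfect_stratification(self):
        spec = stratified_kfold([1, 1, 1, 0, 0, 0], k=3, seed=0)
        for _, test in fold_indices(spec):
            labels = np.array([1, 1, 1, 0, 0, 0])[test]
            assert sorted(labels) == [0, 1]

    def test_fold_sizes_99_into_15(self):
        labels = np.repeat([0, 1], [50, 49])
        spec = stratified_kfold(labels, k=15, seed=1)
        sizes = sorted(np.bincount(spec.assignments), reverse=True)
        assert sizes == [7] * 9 + [6] * 6

    def test_loocv_singleton_folds(self):
        labels = np.repeat([0, 1], [50, 49])
        with pytest.warns(UserWarning, match="unstratified"):
            spec = stratified_kfold(labels, k=99, seed=0)
        assert not spec.stratified
        assert np.bincount(spec.assignments).tolist() == [1] * 99

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold([0, 1, 0, 1], k=5, seed=0)

    def test_fold_accounting(self):
        """Every subject is held out exactly once; folds partition the sample."""
        labels = (np.arange(40) % 2).astype(int)
        spec = stratified_kfold(labels, k=5, seed=3)
        seen = np.concatenate([test for _, test in fold_indices(spec)])
        assert sorted(seen) == list(range(40))
        sizes = np.bincount(spec.assignments)
        assert sizes.max() - sizes.min() <= 1


class TestMetrics:
    @pytest.mark.parametrize(
        "y_true,y_pred,expected",
        [
            ([1, 1, 0, 0], [1, 0, 0, 0], (0.75, 0.5, 1.0)),
            ([1, 0, 1, 0], [1, 0, 1, 0], (1.0, 1.0, 1.0)),
            ([1, 1, 0, 0], [1, 1, 1, 1], (0.5, 1.0, 0.0)),
        ],
    )
    def test_counting(self, y_true, y_pred, expected):
        assert evaluate_metrics(y_true, y_pred) == pytest.approx(expected)

    def test_missing_class_gives_nan_rate(self):
        acc, sens, spec = evaluate_metrics([0, 0], [0, 1])
        assert acc == 0.5 and np.isnan(sens) and spec == 0.5

    def test_metric_identity_on_pooled_result(self):
        table = oracle_table(n=30)
        res = plain_kfold_cv(table, model_spec("random_forest"), CVProtocol.plain_kfold(k=5, n_repeats=2, seed=0))
        y = table.labels
        n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
        for acc, sens, spec in zip(*[res.per_repeat[k] for k in ("accuracy", "sensitivity", "specificity")]):
            assert acc == pytest.approx((sens * n_pos + spec * n_neg) / y.size)


class TestFoldSafePCA:
    def test_heldout_perturbation_leaves_components_unchanged(self, rng):
        X_train = rng.standard_normal((20, 15))
        X_held = rng.standard_normal((5, 15))
        pca = RankCappedPCA(n_components=4).fit(X_train)
        ref_components = pca.components_.copy()
        tr_a, he_a = fold_safe_pca(X_train, X_held, 4)
        tr_b, he_b = fold_safe_pca(X_train, X_held + 100.0, 4)
        np.testing.assert_array_equal(tr_a, tr_b)
        np.testing.assert_array_equal(pca.components_, ref_components)
        assert not np.allclose(he_a, he_b)

    def test_rank_truncation_on_collinear_data(self, rng):
        t = rng.standard_normal(12)
        direction = rng.standard_normal(5)
        X = np.outer(t, direction)  # 1-D line embedded in 5-D
        with pytest.warns(UserWarning, match="truncating"):
            pca = RankCappedPCA(n_components=3).fit(X)
        assert pca.n_components_ == 1
        assert pca.transform(X).shape == (12, 1)

    def test_full_width_on_wide_training_block(self, rng):
        X_train = rng.standard_normal((79, 5460))
        tr, he = fold_safe_pca(X_train, rng.standard_normal((20, 5460)), 30)
        assert tr.shape == (79, 30) and he.shape == (20, 30)


def constant_space(value):
    return {"C": stats.uniform(loc=value, scale=0)}


class TestInnerTune:
    def test_single_candidate_returned(self, rng):
        spec = ModelSpec("svm_linear", search_space=constant_space(2.5))
        X, y = rng.standard_normal((20, 5)), np.arange(20) % 2
        params = inner_tune(X, y, spec, inner_k=4, n_search=5, pca_components=None, seed=0)
        assert params == {"C": 2.5}

    def test_seed_determinism(self, rng):
        spec = model_spec("svm_radial")
        X, y = rng.standard_normal((24, 8)), np.arange(24) % 2
        a = inner_tune(X, y, spec, 3, 10, None, seed=42)
        b = inner_tune(X, y, spec, 3, 10, None, seed=42)
        assert a == b

    def test_empty_space_skips_inner_cv(self, rng):
        spec = model_spec("random_forest")
        X, y = rng.standard_normal((10, 4)), np.arange(10) % 2
        assert inner_tune(X, y, spec, 3, 10, None, seed=0) == {}


class TestNestedCV:
    def test_oracle_feature_reaches_perfect_accuracy(self):
        table = oracle_table()
        for name in ("svm_linear", "svm_radial"):
            proto = CVProtocol.nested_kfold(n_repeats=2, n_search=4, seed=0)
            res = nested_cv(table, model_spec(name), proto)
            assert res.accuracy == 1.0
            assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_loocv_pools_n_predictions(self):
        table = oracle_table(n=16)
        proto = CVProtocol.nested_loocv(inner_k=3, n_search=3, seed=0)
        with pytest.warns(UserWarning, match="unstratified"):
            res = nested_cv(table, model_spec("svm_linear"), proto)
        assert len(res.chosen_params) == 16  # one outer fit per subject
        assert len(res.per_repeat["accuracy"]) == 1
        assert res.accuracy == 1.0

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            nested_cv(oracle_table(), model_spec("svm_linear"), CVProtocol.plain_kfold())

    def test_determinism_across_runs(self):
        table = pure_noise_dataset(20, 10, seed=3)
        proto = CVProtocol.nested_kfold(n_repeats=2, n_search=4, seed=9)
        r1 = nested_cv(table, model_spec("svm_radial"), proto)
        r2 = nested_cv(table, model_spec("svm_radial"), proto)
        assert r1.per_repeat["accuracy"] == r2.per_repeat["accuracy"]
        assert r1.chosen_params == r2.chosen_params


class TestOptimisticallyBiasedCV:
    def test_single_candidate_reduces_to_plain_kfold(self):
        table = pure_noise_dataset(24, 12, seed=5)
        spec = ModelSpec("svm_linear", search_space=constant_space(1.0))
        biased = optimistically_biased_cv(
            table, spec, CVProtocol.optimistically_biased(k=4, n_search=1, seed=7)
        )
        plain = plain_kfold_cv(
            table,
            ModelSpec("svm_linear"),
            CVProtocol.plain_kfold(k=4, n_repeats=1, seed=7),
            params={"C": 1.0},
        )
        assert biased.accuracy == plain.accuracy

    def test_oracle_feature_reaches_one(self):
        res = optimistically_biased_cv(
            oracle_table(), model_spec("svm_linear"), CVProtocol.optimistically_biased(k=4, n_search=5, seed=0)
        )
        assert res.accuracy == 1.0

    def test_reports_all_candidate_accuracies(self):
        table = pure_noise_dataset(24, 40, seed=2)
        res = optimistically_biased_cv(
            table, model_spec("svm_radial"), CVProtocol.optimistically_biased(k=4, n_search=6, seed=1)
        )
        cand = res.per_repeat["candidate_accuracies"]
        assert len(cand) == 6
        assert res.accuracy == max(cand)


class TestLeakageFreedom:
    @pytest.mark.parametrize("kind", ["nested_kfold", "nested_loocv"])
    def test_fitted_state_ignores_heldout_rows(self, kind, rng):
        X = rng.standard_normal((20, 12))
        y = (np.arange(20) % 2).astype(int)
        table_a = make_table(X, y, measure="dtw_similarity")
        table_a.meta["demean_scope"] = "train_fold"
        X2 = X.copy()
        test_idx = np.arange(16, 20)
        X2[test_idx] += 1e6
        table_b = make_table(X2, y, measure="dtw_similarity")
        table_b.meta["demean_scope"] = "train_fold"
        proto = CVProtocol(kind=kind, outer_k=5, inner_k=3, n_search=3, n_repeats=1,
                           pca_components=4, seed=0)
        train_idx = np.arange(16)
        fit_a = fit_outer_fold(table_a, model_spec("svm_linear"), proto, train_idx, test_idx)
        fit_b = fit_outer_fold(table_b, model_spec("svm_linear"), proto, train_idx, test_idx)
        np.testing.assert_array_equal(fit_a.pca_components, fit_b.pca_components)
        np.testing.assert_array_equal(fit_a.pca_mean, fit_b.pca_mean)
        np.testing.assert_array_equal(fit_a.demean_offset, fit_b.demean_offset)
        assert fit_a.params == fit_b.params


class TestSeedLadder:
    def test_child_seeds_are_stable_and_distinct(self):
        a = derive_seed(1, 2, 3)
        assert a == derive_seed(1, 2, 3)
        assert a != derive_seed(1, 2, 4)
        assert 0 <= a < 2**31

    def test_run_cv_dispatch(self):
        table = oracle_table()
        res = run_cv(table, model_spec("random_forest"), CVProtocol.plain_kfold(k=4, n_repeats=1, seed=0))
        assert res.accuracy == 1.0
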