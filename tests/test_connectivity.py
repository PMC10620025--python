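import numpy as np
import pytest

from dtwfc import (
    DegenerateSignalError,
    DTWConfig,
    FeatureTable,
    SimilarityDemeaner,
    StudySet,
    SubjectRecord,
    build_feature_table,
    distances_to_similarity,
    dtw_fc,
    load_feature_table,
    load_study,
    pearson_fc,
    save_feature_table,
    save_study,
    vectorize_upper,
    zscore_timeseries,
)
from dtwfc.connectivity import pair_names
from dtwfc.dtw import dtw_distance


def record(data, label=0, sid="s0", dt=2.0):
    return SubjectRecord(sid, np.asarray(data, dtype=float), label=label, dt=dt)


class TestZScore:
    def test_population_sd_convention(self):
        rec = zscore_timeseries(record([[1, 2, 3], [4, 4, 8]]))
        np.testing.assert_allclose(rec.data[0], [-1.2247448, 0, 1.2247448], atol=1e-6)
        np.testing.assert_allclose(rec.data.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(rec.data.std(axis=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        rec = zscore_timeseries(record(rng.standard_normal((3, 20))))
        again = zscore_timeseries(rec)
        np.testing.assert_allclose(again.data, rec.data, atol=1e-12)

    def test_constant_row_names_roi(self):
        with pytest.raises(DegenerateSignalError, match="ROI index 1"):
            zscore_timeseries(record([[1, 2, 3], [5, 5, 5]]))


class TestPearsonFC:
    def test_identical_and_negated_rows(self):
        base = np.array([0.3, -1.2, 0.8, 2.0])
        fc = pearson_fc(record(np.vstack([base, base, -base])))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(fc.values), 1.0)

    def test_lagged_spike_correlation(self):
        a = np.array([0, 0, 1, 0, 0, 0], dtype=float)
        fc = pearson_fc(record(np.vstack([a, np.roll(a, 1)])))
        assert fc.values[0, 1] == pytest.approx(-0.2, abs=1e-12)

    def test_constant_row_rejected(self):
        with pytest.raises(DegenerateSignalError):
            pearson_fc(record([[1, 2, 3], [2, 2, 2]]))


class TestDTWFC:
    def test_identical_rows_zero_off_diagonal(self):
        base = np.array([0.5, -0.5, 1.5, 0.0])
        fc = dtw_fc(record(np.vstack([base, base])))
        assert fc.values[0, 1] == 0
        np.testing.assert_allclose(np.diag(fc.values), 0)

    def test_symmetric_three_rois(self, rng):
        fc = dtw_fc(record(rng.standard_normal((3, 10))))
        np.testing.assert_allclose(fc.values, fc.values.T)
        assert fc.measure == "dtw_distance"

    def test_example_pair_rows(self, example_pair):
        a, b = example_pair
        fc = dtw_fc(record(np.vstack([a, b])), DTWConfig(window_seconds=None))
        assert fc.values[0, 1] == 2
        assert fc.values[1, 0] == 2


class TestVectorizeUpper:
    @pytest.mark.parametrize("r,expected", [(2, 1), (3, 3), (10, 45), (105, 5460)])
    def test_feature_count_law(self, r, expected):
        vec = vectorize_upper(np.zeros((r, r)))
        assert vec.size == expected == r * (r - 1) // 2

    def test_row_major_order(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        np.testing.assert_array_equal(vectorize_upper(m), [1, 2, 3])
        assert pair_names(["A", "B", "C"]) == ["A__B", "A__C", "B__C"]

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_upper(np.array([[0, 1], [2, 0.0]]))


def distance_table(X, **meta):
    n, p = X.shape
    return FeatureTable(
        X=X,
        feature_names=[f"p{i}" for i in range(p)],
        labels=np.arange(n) % 2,
        subject_ids=[f"s{i}" for i in range(n)],
        measure="dtw_distance",
        meta=meta,
    )


class TestSimilarityConversion:
    def test_global_demeaning_example(self):
        table = distance_table(np.array([[2.0], [4.0], [6.0]]))
        sim = distances_to_similarity(table, "global")
        np.testing.assert_allclose(sim.X.ravel(), [2, 0, -2])
        assert sim.measure == "dtw_similarity"

    def test_constant_column_maps_to_zero(self):
        table = distance_table(np.full((3, 2), 7.0))
        np.testing.assert_allclose(distances_to_similarity(table, "global").X, 0)

    def test_heldout_uses_training_means(self):
        train = distance_table(np.array([[2.0], [4.0]]))  # negated mean = -3
        demeaner = SimilarityDemeaner().fit(train.X)
        heldout = distance_table(np.array([[5.0]]))
        got = distances_to_similarity(heldout, "train_fold", train_means=demeaner.offset_)
        assert got.X[0, 0] == pytest.approx(-2.0)

    def test_train_fold_without_means_rejected(self):
        with pytest.raises(ValueError, match="train_means"):
            distances_to_similarity(distance_table(np.ones((2, 1))), "train_fold")

    def test_training_columns_centered(self, rng):
        X = rng.uniform(1, 9, size=(12, 5))
        sim = SimilarityDemeaner().fit(X).transform(X)
        np.testing.assert_allclose(sim.mean(axis=0), 0, atol=1e-12)

    def test_negation_reverses_order(self, rng):
        """Before demeaning, similarity is a strictly decreasing transform of
        distance: the most-similar pair has the smallest distance."""
        X = rng.uniform(0, 10, size=(8, 1))
        sim = SimilarityDemeaner().fit(X).transform(X)
        order_by_distance = np.argsort(X.ravel())
        order_by_similarity = np.argsort(-sim.ravel())
        np.testing.assert_array_equal(order_by_distance, order_by_similarity)


class TestBuildFeatureTable:
    def test_shapes_and_names(self, tiny_study):
        table = build_feature_table(tiny_study, "pearson")
        assert table.X.shape == (4, 3)
        assert table.feature_names == ["A__B", "A__C", "B__C"]
        np.testing.assert_array_equal(table.labels, [0, 1, 0, 1])

    def test_identical_subjects_identical_rows(self, rng):
        data = rng.standard_normal((3, 15))
        study = StudySet([record(data, sid=f"s{i}", label=i % 2) for i in range(3)])
        table = build_feature_table(study, "dtw_similarity", demean_scope="global")
        assert np.ptp(table.X, axis=0).max() == 0

    def test_permutation_equivariance(self, tiny_study):
        base = build_feature_table(tiny_study, "pearson")
        permuted = build_feature_table(tiny_study.permute_rois([2, 0, 1]), "pearson")
        for row_a, row_b in zip(base.X, permuted.X):
            np.testing.assert_allclose(sorted(row_a), sorted(row_b), atol=1e-12)
        # the same pair keeps its value under the new naming
        idx_old = base.feature_names.index("A__B")
        idx_new = permuted.feature_names.index("A__B")
        np.testing.assert_allclose(base.X[:, idx_old], permuted.X[:, idx_new], atol=1e-12)

    def test_train_fold_scope_defers_demeaning(self, tiny_study):
        table = build_feature_table(tiny_study, "dtw_similarity")
        assert table.measure == "dtw_similarity"
        assert table.needs_fold_demeaning()
        assert np.all(table.X >= 0)  # still raw distances

    def test_error_carries_subject_id(self):
        bad = StudySet(
            [record([[1, 2, 3], [1, 1, 1]], sid="bad-sub"), ]
        )
        with pytest.raises(DegenerateSignalError, match="bad-sub"):
            build_feature_table(bad, "pearson")

    def test_lag_robustness_of_measures(self, rng):
        """A within-band lagged copy of a zero-padded burst: zero DTW
        distance (warping absorbs the shift through the flat tails) while
        the point-wise correlation drops strictly below 1."""
        burst = rng.standard_normal(10)
        a = np.concatenate([np.zeros(4), burst, np.zeros(4)])
        b = np.roll(a, 2)  # shift stays inside the zero padding
        assert dtw_distance(a, b, DTWConfig(window_seconds=None)).distance == 0
        assert abs(np.corrcoef(a, b)[0, 1]) < 1


class TestIO:
    def test_study_roundtrip(self, tiny_study, tmp_path):
        manifest = save_study(tiny_study, tmp_path / "study")
        loaded = load_study(manifest)
        assert loaded.n_subjects == tiny_study.n_subjects
        assert loaded.roi_names == tiny_study.roi_names
        np.testing.assert_allclose(
            loaded.records[2].data, tiny_study.records[2].data, atol=1e-9
        )
        np.testing.assert_array_equal(loaded.labels, tiny_study.labels)

    def test_feature_table_roundtrip(self, tiny_study, tmp_path):
        table = build_feature_table(tiny_study, "dtw_similarity")
        path = save_feature_table(table, tmp_path / "features.csv")
        assert path.with_suffix(".json").exists()
        loaded = load_feature_table(path)
        assert loaded.measure == "dtw_similarity"
        assert loaded.meta["demean_scope"] == "train_fold"
        assert loaded.feature_order_hash() == table.feature_order_hash()
        np.testing.assert_allclose(loaded.X, table.X, atol=1e-9)
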