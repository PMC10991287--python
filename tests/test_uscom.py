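import numpy as np
import pytest

from mlhdpm import uscom
from mlhdpm.records_io import DomainError
from mlhdpm.synthetic_data import gen_matrix


def blobs(centers, n_per, sd, seed):
    rng = np.random.default_rng(seed)
    parts = [rng.normal(c, sd, size=(n_per, len(c))) for c in centers]
    return np.vstack(parts)


class TestUndersampleMajority:
    def test_two_thirds_of_300_is_200(self):
        rows = uscom.undersample_majority(list(range(300)), 2 / 3, seed=0)
        assert len(rows) == 200
        assert len(set(rows)) == 200

    def test_ratio_one_keeps_all(self):
        rows = uscom.undersample_majority(list(range(17)), 1.0, seed=1)
        assert sorted(rows) == list(range(17))

    def test_same_seed_same_selection(self):
        a = uscom.undersample_majority(list(range(50)), 0.5, seed=9)
        b = uscom.undersample_majority(list(range(50)), 0.5, seed=9)
        assert a == b

    def test_empty_majority_errors(self):
        with pytest.raises(DomainError):
            uscom.undersample_majority([], 0.5, seed=0)


class TestKMeans:
    def test_k_equals_n_zero_sse(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 1.0]])
        model = uscom.kmeans_fit(X, K=3, seed=0)
        assert model.sse == pytest.approx(0.0, abs=1e-12)

    def test_triangle_single_cluster_sse(self):
        # centroid (2/3, 2/3); within-cluster squared error 16/3
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        model = uscom.kmeans_fit(X, K=1, seed=0)
        np.testing.assert_allclose(model.centroids[0], [2 / 3, 2 / 3], atol=1e-12)
        assert model.sse == pytest.approx(16 / 3, abs=1e-9)

    def test_two_blobs_separate(self):
        X = blobs([(0, 0), (100, 100)], n_per=20, sd=0.1, seed=4)
        model = uscom.kmeans_fit(X, K=2, seed=0)
        first, second = model.assignment[:20], model.assignment[20:]
        assert len(set(first.tolist())) == 1
        assert len(set(second.tolist())) == 1
        assert first[0] != second[0]

    def test_k_exceeding_n_errors(self):
        with pytest.raises(DomainError):
            uscom.kmeans_fit(np.zeros((3, 2)), K=4)


class TestChooseK:
    def test_three_blobs_give_three(self):
        X = blobs([(0, 0), (50, 0), (0, 50)], n_per=20, sd=0.5, seed=7)
        assert uscom.choose_k(X, (1, 2, 3, 4, 5, 6), 0.1, seed=0) == 3

    def test_two_blobs_give_two(self):
        X = blobs([(0, 0), (40, 40)], n_per=25, sd=0.5, seed=5)
        assert uscom.choose_k(X, (1, 2, 3, 4, 5), 0.1, seed=0) == 2

    def test_single_blob_flattens_early(self):
        # one Gaussian blob: no added cluster explains a third of the scatter
        # beyond K=2, so the curve flattens well before the range maximum
        X = blobs([(0, 0)], n_per=40, sd=0.5, seed=3)
        assert uscom.choose_k(X, (1, 2, 3, 4, 5, 6), 0.3, seed=0) <= 2

    def test_empty_range_errors(self):
        with pytest.raises(uscom.ConfigError):
            uscom.choose_k(np.zeros((5, 2)), (), 0.1)


class TestSplit811:
    @pytest.mark.parametrize("n,expected", [(100, (80, 10, 10)),
                                            (10, (8, 1, 1)),
                                            (7, (5, 1, 1))])
    def test_sizes(self, n, expected):
        train, val, test = uscom.split_8_1_1(list(range(n)), seed=0)
        assert (len(train), len(val), len(test)) == expected
        assert sorted(train + val + test) == list(range(n))

    def test_too_small_errors(self):
        with pytest.raises(DomainError):
            uscom.split_8_1_1([1, 2], seed=0)


class TestSmote:
    def test_zero_new_is_empty(self):
        out = uscom.smote(np.zeros((5, 3)), 0)
        assert out.shape[0] == 0

    def test_identical_points_degenerate(self):
        minority = np.tile([2.0, 3.0], (4, 1))
        out = uscom.smote(minority, 10, k=2, seed=0)
        np.testing.assert_allclose(out, np.tile([2.0, 3.0], (10, 1)))

    def test_too_few_rows_errors(self):
        with pytest.raises(uscom.ResamplingError):
            uscom.smote(np.zeros((1, 2)), 5)

    def test_synthetics_within_minority_bounding_box(self):
        rng = np.random.default_rng(11)
        minority = rng.normal(size=(30, 4))
        out = uscom.smote(minority, 1000, k=5, seed=2)
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


class TestRunUscom:
    def test_balanced_train_counts(self):
        X, y, _ = gen_matrix(n=90, p=4, n_informative=1, effect_size=1.0,
                             seed=0, class_ratio=(2, 1))
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(undersample_ratio=1.0, seed=0))
        counts = np.bincount(bundle.y_train)
        assert counts[0] == counts[1]

    def test_synthetics_only_in_train(self):
        X, y, _ = gen_matrix(n=120, p=3, n_informative=1, effect_size=1.0,
                             seed=1, class_ratio=(3, 1))
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(seed=3))
        n_orig = sum(p == "original" for p in bundle.train_provenance)
        assert n_orig == len(bundle.train_row_ids)
        assert len(bundle.train_provenance) == len(bundle.y_train)
        # val/test sizes match their row-id lists: all original
        assert len(bundle.y_val) == len(bundle.val_row_ids)
        assert len(bundle.y_test) == len(bundle.test_row_ids)

    def test_original_rows_partition(self):
        X, y, _ = gen_matrix(n=100, p=3, n_informative=1, effect_size=1.0,
                             seed=2, class_ratio=(3, 2))
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(undersample_ratio=1.0, seed=5))
        all_ids = bundle.train_row_ids + bundle.val_row_ids + bundle.test_row_ids
        assert len(all_ids) == len(set(all_ids)) == len(y)

    def test_already_balanced_train_needs_no_synthetics(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 2))
        y = np.array([0, 1] * 20)
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(
            undersample_ratio=1.0, k_range=(1,), seed=0))
        counts = np.bincount(bundle.y_train)
        assert counts[0] == counts[1]

    def test_single_class_errors(self):
        with pytest.raises(uscom.ResamplingError):
            uscom.run_uscom(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_minority_clusters_cover_all_roles(self):
        # two clearly separated minority subgroups, each big enough to split
        rng = np.random.default_rng(21)
        maj = rng.normal(0, 1, size=(60, 2))
        min_a = rng.normal((30, 0), 0.5, size=(15, 2))
        min_b = rng.normal((0, 30), 0.5, size=(15, 2))
        X = np.vstack([maj, min_a, min_b])
        y = np.array([0] * 60 + [1] * 30)
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(
            undersample_ratio=1.0, k_range=(1, 2, 3), seed=0))
        for role_ids in (bundle.val_row_ids, bundle.test_row_ids):
            labels = y[role_ids]
            assert (labels == 1).any(), "minority missing from a role"

    def test_bundle_write(self, tmp_path):
        X, y, _ = gen_matrix(n=60, p=3, n_informative=1, effect_size=1.0,
                             seed=3, class_ratio=(2, 1))
        bundle = uscom.run_uscom(X, y, uscom.USCOMConfig(seed=1))
        bundle.write(tmp_path)
        assert (tmp_path / "train.csv").exists()
        assert (tmp_path / "manifest.json").exists()
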