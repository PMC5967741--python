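"""Hidden-activation clustering, back-projection and activity maps."""

import numpy as np
import pytest
from sklearn.cluster import KMeans

import avalanchekit as ak
from avalanchekit.synthetic import RegionMask


def _blobs(n=60, d=5, sep=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n // 2, d))
    b = rng.normal(sep, 1, (n // 2, d))
    X = np.vstack([a, b])
    truth = np.repeat([0, 1], n // 2)
    return X, truth


class TestClustering:
    def test_separated_blobs_recovered_over_seeds(self):
        for seed in range(10):
            X, truth = _blobs(seed=seed)
            result = ak.cluster_hidden_activations(X, k=2, restarts=10,
                                                   seed=seed)
            # agreement up to relabeling
            agree = (result.assignments == truth).mean()
            assert max(agree, 1 - agree) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        X, _ = _blobs(n=8)
        result = ak.cluster_hidden_activations(X, k=8, restarts=5, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-9)

    def test_duplicated_dataset_keeps_centroids(self):
        X, _ = _blobs(seed=3)
        a = ak.cluster_hidden_activations(X, k=2, restarts=10, seed=1)
        b = ak.cluster_hidden_activations(np.vstack([X, X]), k=2,
                                          restarts=10, seed=1)
        assert np.allclose(np.sort(a.centroids, axis=0),
                           np.sort(b.centroids, axis=0), atol=1e-6)

    def test_k_exceeding_examples_rejected(self):
        X, _ = _blobs(n=6)
        with pytest.raises(ValueError):
            ak.cluster_hidden_activations(X, k=10)

    def test_best_of_restarts_at_least_as_good_as_single_runs(self):
        X, _ = _blobs(n=40, sep=2.0, seed=5)
        best = ak.cluster_hidden_activations(X, k=4, restarts=10, seed=0)
        assert len(best.restart_inertias) == 10
        assert best.inertia == min(best.restart_inertias)


class TestClusterIdentity:
    def test_majority_vote(self):
        result = ak.ClusterResult(k=1, assignments=np.zeros(10, dtype=int),
                                  centroids=np.zeros((1, 2)), inertia=0.0)
        labels = np.array([1] * 9 + [0])
        identity = ak.assign_cluster_identity(result, labels)
        assert identity == {0: 1}
        assert ak.correctly_clustered(result, labels).sum() == 9

    def test_all_quiescence_input(self):
        result = ak.ClusterResult(k=2,
                                  assignments=np.array([0, 0, 1, 1]),
                                  centroids=np.zeros((2, 2)), inertia=0.0)
        identity = ak.assign_cluster_identity(result, np.zeros(4, dtype=int))
        assert identity == {0: 0, 1: 0}

    def test_exact_tie_labeled_quiescence_with_warning(self):
        result = ak.ClusterResult(k=1, assignments=np.zeros(4, dtype=int),
                                  centroids=np.zeros((1, 2)), inertia=0.0)
        with pytest.warns(UserWarning, match="balanced"):
            identity = ak.assign_cluster_identity(result,
                                                  np.array([0, 0, 1, 1]))
        assert identity == {0: 0}


def _region_model(arch_id=1, seed=0):
    """A small 2-region model with random (masked) weights and its layout."""
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[2:12, 2:12] = 1          # "motor": 100 px
    labels[2:12, 13:19] = 2         # second region: 60 px
    mask = RegionMask(labels)
    layout = ak.FeatureLayout.from_mask(mask)
    spec = ak.build_architecture(arch_id, layout.region_sizes,
                                 hidden_per_region=4)
    times = 2 if spec.mode == "dual" else 1
    rbm = ak.train_rbm(
        np.random.default_rng(seed).random((10, layout.n_features * times)),
        spec.masks[0], epochs=10, seed=seed)
    model = ak.init_ffnn_from_rbm(rbm, spec, seed=seed + 1)
    return model, layout, mask


class TestBackProjection:
    def test_zero_centroid_gives_zero_raw_map(self):
        model, layout, mask = _region_model()
        maps = ak.backproject_centroid(np.zeros(8), model, layout,
                                       mask=mask, normalize="raw")
        assert np.all(maps["T1"].values == 0)

    def test_linearity_in_the_centroid(self):
        model, layout, mask = _region_model(seed=2)
        c = np.random.default_rng(0).normal(size=8)
        one = ak.backproject_centroid(c, model, layout, mask=mask,
                                      normalize="raw")["T1"].values
        two = ak.backproject_centroid(2 * c, model, layout, mask=mask,
                                      normalize="raw")["T1"].values
        assert np.allclose(two, 2 * one)

    def test_region_constrained_units_stay_inside_region(self):
        """Mask algebra: motor-only hidden units cannot reach other regions."""
        model, layout, mask = _region_model(seed=3)
        centroid = np.zeros(8)
        centroid[:4] = np.random.default_rng(1).normal(size=4)  # motor group
        raw = ak.backproject_centroid(centroid, model, layout, mask=mask,
                                      normalize="raw")["T1"].values
        outside_motor = mask.labels != 1
        assert np.all(raw[outside_motor] == 0)
        assert np.any(raw[mask.labels == 1] != 0)

    def test_dual_mode_yields_t1_t2_and_mean(self):
        model, layout, mask = _region_model(arch_id=2, seed=4)
        c = np.random.default_rng(2).normal(size=16)
        maps = ak.backproject_centroid(c, model, layout, mask=mask,
                                       normalize="raw")
        assert set(maps) == {"T1", "T2", "mean"}
        assert np.allclose(maps["mean"].values,
                           (maps["T1"].values + maps["T2"].values) / 2)

    def test_dimension_mismatch_rejected(self):
        model, layout, mask = _region_model()
        with pytest.raises(ValueError, match="centroid size"):
            ak.backproject_centroid(np.zeros(5), model, layout, mask=mask)

    def test_per_region_normalization_bounds(self):
        model, layout, mask = _region_model(seed=5)
        c = np.random.default_rng(3).normal(size=8)
        normed = ak.backproject_centroid(c, model, layout, mask=mask,
                                         normalize="per-region")["T1"].values
        for label in (1, 2):
            vals = normed[mask.labels == label]
            assert vals.min() == pytest.approx(0.0)
            assert vals.max() == pytest.approx(1.0)


class TestActivityMaps:
    def test_single_frame_is_minmax_normalized(self):
        rng = np.random.default_rng(0)
        seq = ak.ImageSequence(rng.normal(size=(10, 12, 12)))
        amap = ak.cortical_activity_map(seq, [4])
        expected = (seq.data[4] - seq.data[4].min()) / np.ptp(seq.data[4])
        assert np.allclose(amap.values, expected)

    def test_motor_upstate_frames_peak_in_motor(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:10, 2:10] = 1
        labels[12:18, 12:18] = 2
        rng = np.random.default_rng(1)
        data = rng.normal(0, 0.1, (20, 20, 20))
        data[5:15, 3:9, 3:9] += 4.0     # sustained motor up-state
        seq = ak.ImageSequence(data)
        amap = ak.cortical_activity_map(seq, np.arange(5, 15))
        peak = np.unravel_index(np.argmax(amap.values), amap.values.shape)
        assert labels[peak] == 1

    def test_cancelling_frames_sum_to_zero_before_normalization(self):
        frame = np.random.default_rng(2).normal(size=(12, 12))
        seq = ak.ImageSequence(np.stack([frame, -frame] * 3))
        amap = ak.cortical_activity_map(seq, np.arange(6), normalize="raw")
        assert np.allclose(amap.values, 0.0, atol=1e-12)

    def test_empty_frame_set_rejected(self):
        seq = ak.ImageSequence(np.zeros((10, 12, 12)))
        with pytest.raises(ValueError, match="empty"):
            ak.cortical_activity_map(seq, [])
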