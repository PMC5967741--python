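"""Architecture masks, lesion grid, RBM pretraining and FFNN training."""

import numpy as np
import pytest

import avalanchekit as ak
from avalanchekit import nets


class TestBuildArchitecture:
    @pytest.mark.parametrize("arch_id,mode,layer,expected", [
        (3, "dual", 2, 2),    # one group per time point
        (4, "single", 2, 3),  # C(3,2) unordered region pairs
        (5, "dual", 2, 6),    # region pairs within each time point
        (6, "dual", 3, 2),    # per-time groups above the pair layer
        (7, "dual", 2, 9),    # 3x3 ordered cross-time region pairs
    ])
    def test_three_region_group_counts(self, arch_id, mode, layer, expected):
        spec = ak.build_architecture(arch_id, (5, 5, 5), mode, group_width=1)
        assert spec.layer_sizes[layer] == expected

    def test_four_region_hidden_layer_widths(self):
        single = ak.build_architecture(1, (30, 30, 30, 30))
        dual = ak.build_architecture(2, (30, 30, 30, 30))
        assert single.layer_sizes[1] == 40   # 10 units per region
        assert dual.layer_sizes[1] == 80     # x2 time points

    def test_output_layer_is_single_unit(self):
        for arch_id in range(1, 8):
            spec = ak.build_architecture(arch_id, (8, 8, 8))
            assert spec.layer_sizes[-1] == 1

    def test_region_mask_blocks_cross_region_connections(self):
        spec = ak.build_architecture(1, (4, 6), hidden_per_region=2)
        mask = spec.masks[0]
        assert mask.shape == (4, 10)
        assert np.all(mask[:2, :4] == 1) and np.all(mask[:2, 4:] == 0)
        assert np.all(mask[2:, :4] == 0) and np.all(mask[2:, 4:] == 1)

    def test_group_width_scales_upper_layers(self):
        spec = ak.build_architecture(7, (5, 5, 5), group_width=10)
        assert spec.layer_sizes[2] == 90

    def test_invalid_ids_and_modes_rejected(self):
        with pytest.raises(ValueError):
            ak.build_architecture(8, (5, 5))
        with pytest.raises(ValueError):
            ak.build_architecture(3, (5, 5), mode="single")
        with pytest.raises(ValueError):
            ak.build_architecture(1, (5,))


class TestLesionGrid:
    def test_default_grid_has_43_jobs(self):
        jobs = ak.enumerate_model_grid()
        assert len(jobs) == 43
        assert sum(j.lesion == "none" for j in jobs) == 7
        assert sum(j.lesion == "missing_one" for j in jobs) == 28
        assert sum(j.lesion == "single" for j in jobs) == 8

    def test_restricted_architecture_counting(self):
        assert len(ak.enumerate_model_grid(architectures=(1,))) == 9

    def test_no_lesionable_regions(self):
        assert len(ak.enumerate_model_grid(lesionable_regions=())) == 7


def _separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.clip(0.2 + 0.5 * y[:, None] + 0.1 * rng.standard_normal((n, 12)),
                0, 1)
    return X, y.astype(np.int8)


class TestRBM:
    def _mask(self):
        return ak.build_architecture(1, (6, 6), hidden_per_region=3).masks[0]

    def test_zero_epochs_returns_masked_initialization(self):
        X, _ = _separable_data()
        rbm = ak.train_rbm(X, self._mask(), epochs=0, seed=1)
        assert rbm.epochs_trained == 0
        assert np.all(rbm.weights[rbm.mask == 0] == 0)
        assert np.any(rbm.weights != 0)

    def test_masked_weights_exactly_zero_after_training(self):
        X, _ = _separable_data()
        rbm = ak.train_rbm(X, self._mask(), epochs=50, seed=2)
        assert np.all(rbm.weights[rbm.mask == 0] == 0)

    def test_reconstruction_error_decreases(self):
        """Mean final error < mean initial error across 5 seeds."""
        X, _ = _separable_data(n=60)
        first, last = [], []
        for seed in range(5):
            rbm = ak.train_rbm(X, self._mask(), epochs=150, seed=seed)
            first.append(rbm.recon_errors[0])
            last.append(rbm.recon_errors[-1])
        assert np.mean(last) < np.mean(first)

    def test_unnormalized_input_rejected(self):
        X, _ = _separable_data()
        with pytest.raises(ValueError, match="normalized"):
            ak.train_rbm(X * 5, self._mask(), epochs=1)


class TestSweepMomentum:
    def test_argmin_selection(self):
        values = {0.0: 0.3, 0.1: 0.1, 0.2: 0.2}
        assert ak.sweep_momentum(values.get, values) == 0.1

    def test_ties_break_toward_smaller_momentum(self):
        assert ak.sweep_momentum(lambda m: 1.0, [0.0, 0.5, 1.0]) == 0.0

    def test_single_value_grid(self):
        assert ak.sweep_momentum(lambda m: 0.7, [0.4]) == 0.4

    def test_all_non_finite_raises(self):
        with pytest.raises(ValueError):
            ak.sweep_momentum(lambda m: float("nan"), [0.0, 0.1])

    def test_diverging_grid_points_skipped(self):
        def fn(m):
            if m > 0.05:
                raise nets.TrainingDivergedError(0)
            return 0.5
        assert ak.sweep_momentum(fn, [0.0, 0.1, 0.2]) == 0.0


def _toy_model(seed=0, arch_id=1):
    spec = ak.build_architecture(arch_id, (5, 5), hidden_per_region=3)
    X, y = _separable_data(n=30, seed=seed)
    X = np.repeat(X[:, :10], 1, axis=1)
    rbm = ak.train_rbm(X, spec.masks[0], epochs=20, seed=seed)
    model = ak.init_ffnn_from_rbm(rbm, spec, seed=seed + 1, momentum=0.0)
    return model, X, y


class TestFFNNInit:
    def test_layer1_copied_bitwise_from_rbm(self):
        spec = ak.build_architecture(1, (6, 6), hidden_per_region=3)
        X, _ = _separable_data()
        rbm = ak.train_rbm(X, spec.masks[0], epochs=30, seed=0)
        model = ak.init_ffnn_from_rbm(rbm, spec, seed=5)
        assert np.array_equal(model.weights[0], rbm.weights)
        assert np.array_equal(model.biases[0], rbm.hidden_bias)

    def test_deeper_masked_weights_zero_at_init(self):
        spec = ak.build_architecture(6, (4, 4, 4))
        rbm = ak.train_rbm(np.zeros((4, 24)), spec.masks[0], epochs=0)
        model = ak.init_ffnn_from_rbm(rbm, spec, seed=1)
        assert model.max_masked_weight() == 0.0

    def test_same_seed_gives_identical_models(self):
        a, _, _ = _toy_model(seed=3)
        b, _, _ = _toy_model(seed=3)
        for Wa, Wb in zip(a.weights, b.weights):
            assert np.array_equal(Wa, Wb)

    def test_size_mismatch_rejected(self):
        spec = ak.build_architecture(1, (5, 5), hidden_per_region=3)
        rbm = ak.train_rbm(np.zeros((4, 8)), np.ones((4, 8)), epochs=0)
        with pytest.raises(ValueError, match="does not match"):
            ak.init_ffnn_from_rbm(rbm, spec)


class TestFFNNTraining:
    def test_gradients_match_central_differences(self):
        """Analytic backprop vs finite differences, <= 1e-5 relative error."""
        model, X, y = _toy_model(seed=1)
        _, w_grads, b_grads = model.loss_and_grads(X, y)
        h = 1e-6

        def numeric(array, analytic):
            it = np.nditer(array, flags=["multi_index"])
            worst = 0.0
            for _ in it:
                idx = it.multi_index
                orig = array[idx]
                array[idx] = orig + h
                lp, _, _ = model.loss_and_grads(X, y)
                array[idx] = orig - h
                lm, _, _ = model.loss_and_grads(X, y)
                array[idx] = orig
                num = (lp - lm) / (2 * h)
                denom = max(1e-8, abs(num) + abs(analytic[idx]))
                worst = max(worst, abs(num - analytic[idx]) / denom)
            return worst

        for i in range(len(model.weights)):
            assert numeric(model.weights[i], w_grads[i]) < 1e-5
            assert numeric(model.biases[i], b_grads[i]) < 1e-5

    def test_masked_weights_zero_after_training(self):
        model, X, y = _toy_model(seed=2)
        ak.train_ffnn(model, X, y, epochs=100)
        assert model.max_masked_weight() == 0.0

    def test_learns_separable_toy_data(self):
        model, X, y = _toy_model(seed=4)
        ak.train_ffnn(model, X, y, epochs=500)
        assert ak.evaluate(model, X, y)["accuracy"] > 0.95

    def test_feature_mismatch_rejected(self):
        model, X, y = _toy_model(seed=5)
        with pytest.raises(ValueError, match="feature count"):
            ak.train_ffnn(model, X[:, :5], y, epochs=1)

    def test_divergence_raises_with_epoch(self):
        model, X, y = _toy_model(seed=6)
        model.learning_rate = 1e12
        model.scaling_factor = 10.0
        with pytest.raises(ak.TrainingDivergedError) as err:
            ak.train_ffnn(model, X, y, epochs=500)
        assert err.value.epoch >= 0

    def test_mse_trace_recorded(self):
        model, X, y = _toy_model(seed=7)
        ak.train_ffnn(model, X, y, epochs=50)
        assert len(model.mse_trace) == 50
        assert model.mse_trace[-1] < model.mse_trace[0]
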