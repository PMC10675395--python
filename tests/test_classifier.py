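"""Layer-size formulas, splitting, training and cross-validation."""

import numpy as np
import pytest

import eegfatigue as ef
from eegfatigue.classifier import TrainConfig, _forward
from eegfatigue.errors import ConfigurationError, InputError

from conftest import make_toy_images


@pytest.mark.parametrize("args,expected", [
    ((72, 3, 1, 1, 1), 72),   # 3x3, pad 1: size preserved
    ((72, 1, 1, 0, 1), 72),   # 1x1 kernel identity
    ((72, 5, 1, 0, 1), 68),   # valid 5x5
    ((72, 3, 2, 1, 1), 70),   # dilation 2: effective kernel 5
    ((72, 3, 1, 1, 2), 36),   # stride 2
])
def test_conv_output_size(args, expected):
    assert ef.conv_output_size(*args) == expected


def test_conv_output_size_rejects_oversized_kernel():
    with pytest.raises(ConfigurationError):
        ef.conv_output_size(8, 11, 1, 0, 1)


@pytest.mark.parametrize("args,expected", [
    ((72, 2, 2), 36), ((36, 2, 2), 18), ((10, 10, 1), 1), ((7, 2, 2), 3),
])
def test_pool_output_size(args, expected):
    assert ef.pool_output_size(*args) == expected


def test_pool_window_larger_than_input_rejected():
    with pytest.raises(ConfigurationError):
        ef.pool_output_size(4, 5, 1)


def test_relu_cases():
    assert ef.relu(-3) == 0
    assert ef.relu(5) == 5
    assert ef.relu(0) == 0
    assert np.array_equal(ef.relu(np.array([-1.5, 0.0, 2.5])),
                          [0.0, 0.0, 2.5])


class TestBuildCnn:
    def test_size_chain_and_realized_shapes(self):
        model = ef.build_cnn(seed=0)
        # predicted chain 72 -> 72 -> 36 -> 36 -> 18
        s = ef.conv_output_size(72, 3, 1, 1, 1)
        s = ef.pool_output_size(s, 2, 2)
        s = ef.conv_output_size(s, 3, 1, 1, 1)
        s = ef.pool_output_size(s, 2, 2)
        assert s == 18
        assert model.feature_shape == (18, 18, 32)
        x = np.random.default_rng(0).random((2, 72, 72, 3)).astype(np.float32)
        probs, cache = _forward(model, x)
        assert probs.shape == (2, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert cache[8] == (2, 18, 18, 32)  # realized final feature map

    def test_three_output_classes(self):
        model = ef.build_cnn(seed=0)
        assert model.params["bf2"].size == 3
        assert model.classes == ("normal", "critical", "fatigue")

    def test_parameter_count_cpu_trainable(self):
        assert ef.build_cnn(seed=0).parameter_count < 2_000_000

    def test_inconsistent_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            ef.build_cnn(input_shape=(70, 72, 3))


class TestSplitDataset:
    def table3_labels(self):
        return np.array(["normal"] * 8880 + ["critical"] * 5496
                        + ["fatigue"] * 3924)

    def test_reproduces_published_split_counts(self):
        labels = self.table3_labels()
        tr, te = ef.split_dataset(labels, 0.75, seed=0)
        assert tr.size == 13_725 and te.size == 4575
        for state, n_tr, n_te in [("normal", 6660, 2220),
                                  ("critical", 4122, 1374),
                                  ("fatigue", 2943, 981)]:
            assert (labels[tr] == state).sum() == n_tr
            assert (labels[te] == state).sum() == n_te

    def test_split_is_a_partition(self):
        labels = np.array(["normal"] * 10 + ["fatigue"] * 6)
        tr, te = ef.split_dataset(labels, 0.75, seed=3)
        combined = np.sort(np.concatenate([tr, te]))
        assert np.array_equal(combined, np.arange(16))

    def test_determinism_under_seed(self):
        labels = self.table3_labels()[:500]
        a = ef.split_dataset(labels, 0.75, seed=11)
        b = ef.split_dataset(labels, 0.75, seed=11)
        c = ef.split_dataset(labels, 0.75, seed=12)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], c[0])

    def test_empty_state_warns(self):
        with pytest.warns(UserWarning):
            ef.split_dataset(np.array(["normal"] * 8), 0.5, seed=0)


class TestTraining:
    def test_learns_linearly_separable_toy(self):
        x, y = make_toy_images(20, size=24, seed=1)
        model = ef.build_cnn(input_shape=(24, 24, 3), seed=0)
        model, hist = ef.train(model, x, y,
                               TrainConfig(epochs=30, seed=0))
        assert max(hist["accuracy"]) == 1.0

    def test_training_is_deterministic(self):
        x, y = make_toy_images(8, size=24, seed=2)
        runs = []
        for _ in range(2):
            m = ef.build_cnn(input_shape=(24, 24, 3), seed=5)
            m, _ = ef.train(m, x, y, TrainConfig(epochs=3, seed=5))
            runs.append(m.params)
        for key in runs[0]:
            assert np.array_equal(runs[0][key], runs[1][key])

    def test_empty_training_set_rejected(self):
        model = ef.build_cnn(input_shape=(24, 24, 3), seed=0)
        with pytest.raises(InputError):
            ef.train(model, np.zeros((0, 24, 24, 3)), [],
                     TrainConfig(epochs=1))

    @pytest.mark.parametrize("reg", ["L1", "L2", "dropout", "early_stopping"])
    def test_regularizers_run_and_learn(self, reg):
        x, y = make_toy_images(10, size=24, seed=3)
        model = ef.build_cnn(input_shape=(24, 24, 3), seed=1)
        model, hist = ef.train(model, x, y,
                               TrainConfig(epochs=10, seed=1,
                                           regularization=reg))
        probs = ef.predict_proba(model, x)
        acc = (np.array(model.classes)[probs.argmax(1)] == y).mean()
        assert acc >= 0.9


class TestKfold:
    def test_validation_folds_partition_dataset(self):
        x, y = make_toy_images(10, size=24, seed=4)
        reports = ef.kfold_cv(x, y, k=5, config=TrainConfig(epochs=1, seed=0))
        assert len(reports) == 5
        seen = np.concatenate([r.indices for r in reports])
        assert np.array_equal(np.sort(seen), np.arange(20))
        sizes = sorted(r.n_samples for r in reports)
        assert sizes == [4, 4, 4, 4, 4]

    def test_two_fold_separable_accuracy(self):
        x, y = make_toy_images(16, size=24, seed=5)
        reports = ef.kfold_cv(x, y, k=2,
                              config=TrainConfig(epochs=15, seed=0))
        for r in reports:
            assert r.overall_accuracy >= 0.95

    def test_k_larger_than_dataset_rejected(self):
        x, y = make_toy_images(2, size=24, seed=6)
        with pytest.raises(InputError):
            ef.kfold_cv(x, y, k=50, config=TrainConfig(epochs=1))


def test_checkpoint_round_trip(tmp_path):
    x, y = make_toy_images(4, size=24, seed=7)
    model = ef.build_cnn(input_shape=(24, 24, 3), seed=2)
    model, _ = ef.train(model, x, y, TrainConfig(epochs=1, seed=2))
    path = tmp_path / "model.npz"
    model.save(path)
    back = ef.FatigueCNN.load(path)
    assert back.classes == model.classes
    assert np.array_equal(ef.predict_proba(back, x),
                          ef.predict_proba(model, x))
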