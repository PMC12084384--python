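"""Architecture planning, gradients, the training loop and metrics."""

import numpy as np
import pytest

from nctd.classifier import (
    TrainConfig,
    build_architecture,
    build_network,
    evaluate_metrics,
    load_checkpoint,
    save_checkpoint,
    train,
)
from nctd.errors import ConfigurationError, InputError, TrainingError
from nctd.nn import Sequential, SoftmaxCrossEntropy, softmax
from nctd.preprocess import SplitIndex


def brute_force_metrics(predictions, truth, labels):
    """Independent confusion-matrix metrics via explicit counting loops."""
    k = len(labels)
    pos = {c: i for i, c in enumerate(labels)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predictions):
        confusion[pos[t], pos[p]] += 1
    accuracy = confusion.trace() / confusion.sum()
    precisions, recalls, f1s = [], [], []
    for i in range(k):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return accuracy, np.mean(precisions), np.mean(recalls), np.mean(f1s), confusion


class TestArchitecture:
    def test_printed_progression_for_31(self):
        spec = build_architecture(31, 2)
        assert spec.feature_map_sides == (15, 7, 3, 1)

    @pytest.mark.parametrize("side,expected", [
        (16, (8, 4, 2, 1)),
        (18, (9, 4, 2, 1)),
        (40, (20, 10, 5, 2)),
        (4, (2, 1, 1, 1)),
    ])
    def test_floor_halving(self, side, expected):
        assert build_architecture(side, 2).feature_map_sides == expected

    def test_too_small_input_advises_tiling(self):
        with pytest.raises(ConfigurationError, match="quad"):
            build_architecture(3, 2)

    def test_pooled_vector_length_64(self, rng):
        spec = build_architecture(16, 3)
        net = build_network(spec, seed=0)
        x = rng.uniform(size=(2, 1, 16, 16)).astype(np.float32)
        h = x
        for layer in net.layers:
            h = layer.forward(h, train=False)
            if type(layer).__name__ == "GlobalAvgPool2d":
                assert h.shape == (2, 64)
        assert h.shape == (2, 3)

    def test_softmax_outputs_sum_to_one(self, rng):
        spec = build_architecture(16, 5)
        net = build_network(spec, seed=1)
        probs = net.predict_proba(rng.uniform(size=(7, 1, 16, 16)).astype(np.float32))
        assert probs.shape == (7, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        """Analytic gradients agree with central differences on a tiny net."""
        spec = build_architecture(8, 3, hidden_width=5)
        net = build_network(spec, seed=0)
        loss_fn = SoftmaxCrossEntropy()
        x = rng.normal(size=(6, 1, 8, 8)).astype(np.float32)
        y = np.eye(3, dtype=np.float32)[rng.integers(0, 3, 6)]

        def loss_value():
            return loss_fn.forward(net.forward(x.copy(), train=True), y)

        _, grad = loss_value()
        net.backward(grad)
        checked = 0
        for layer in net.layers:
            params, grads = layer.parameters(), layer.gradients()
            for name, p in params.items():
                flat, gflat = p.reshape(-1), grads[name].reshape(-1)
                for idx in rng.choice(flat.size, min(4, flat.size), replace=False):
                    eps, orig = 1e-3, flat[idx]
                    flat[idx] = orig + eps
                    lp, _ = loss_value()
                    flat[idx] = orig - eps
                    lm, _ = loss_value()
                    flat[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    analytic = gflat[idx]
                    # float32 forward noise dominates near-zero gradients
                    assert abs(numeric - analytic) <= 1e-3 + 0.05 * abs(numeric)
                    checked += 1
        assert checked > 20


def _constant_images(rng, n, side, lo, hi):
    half = n // 2
    imgs = np.concatenate([
        np.full((half, side, side), lo),
        np.full((n - half, side, side), hi),
    ])
    labels = ["0"] * half + ["1"] * (n - half)
    order = rng.permutation(n)
    return imgs[order].astype(np.float32), [labels[i] for i in order]


class TestTraining:
    def test_separable_constant_images_reach_perfect_accuracy(self, rng):
        imgs, labels = _constant_images(rng, 64, 8, 0.1, 0.9)
        split = SplitIndex(np.arange(48), np.arange(48, 64), seed=0)
        spec = build_architecture(8, 2)
        _, report = train(imgs, labels, split, spec, TrainConfig(epochs=10, seed=0))
        assert max(report.per_epoch_val_accuracy) == 1.0
        assert report.accuracy == 1.0

    def test_training_loss_decreases(self, rng):
        imgs, labels = _constant_images(rng, 64, 8, 0.1, 0.9)
        split = SplitIndex(np.arange(48), np.arange(48, 64), seed=0)
        spec = build_architecture(8, 2)
        _, report = train(imgs, labels, split, spec, TrainConfig(epochs=8, seed=0))
        assert report.per_epoch_train_loss[-1] < report.per_epoch_train_loss[0]

    def test_identical_seed_identical_report(self, rng):
        imgs, labels = _constant_images(rng, 40, 8, 0.2, 0.8)
        split = SplitIndex(np.arange(30), np.arange(30, 40), seed=0)
        spec = build_architecture(8, 2)
        reports = [
            train(imgs, labels, split, spec, TrainConfig(epochs=4, seed=11))[1]
            for _ in range(2)
        ]
        assert (
            reports[0].per_epoch_val_accuracy == reports[1].per_epoch_val_accuracy
        )
        assert reports[0].per_epoch_train_loss == reports[1].per_epoch_train_loss
        assert np.array_equal(reports[0].confusion, reports[1].confusion)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0)

    def test_nan_loss_reported_as_training_failure(self, rng):
        imgs, labels = _constant_images(rng, 32, 8, 0.1, 0.9)
        split = SplitIndex(np.arange(24), np.arange(24, 32), seed=0)
        spec = build_architecture(8, 2)
        with np.errstate(all="ignore"), pytest.raises(TrainingError, match="non-finite"):
            train(imgs, labels, split, spec,
                  TrainConfig(learning_rate=1e12, epochs=3, seed=0))

    def test_best_epoch_is_earliest_maximum(self, rng):
        imgs, labels = _constant_images(rng, 48, 8, 0.1, 0.9)
        split = SplitIndex(np.arange(36), np.arange(36, 48), seed=0)
        spec = build_architecture(8, 2)
        _, report = train(imgs, labels, split, spec, TrainConfig(epochs=6, seed=2))
        acc = report.per_epoch_val_accuracy
        assert report.best_epoch == acc.index(max(acc))

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        imgs, labels = _constant_images(rng, 32, 8, 0.1, 0.9)
        split = SplitIndex(np.arange(24), np.arange(24, 32), seed=0)
        spec = build_architecture(8, 2)
        net, _ = train(imgs, labels, split, spec, TrainConfig(epochs=2, seed=0))
        x = imgs[:5][:, None]
        save_checkpoint(tmp_path / "m.npz", net, spec, ["0", "1"])
        net2, spec2, classes = load_checkpoint(tmp_path / "m.npz")
        assert classes == ["0", "1"]
        assert spec2.feature_map_sides == spec.feature_map_sides
        assert np.allclose(net.predict_proba(x), net2.predict_proba(x))


class TestMetrics:
    def test_perfect_prediction(self):
        acc, p, r, f1, _ = evaluate_metrics(["a", "b"], ["a", "b"])
        assert (acc, p, r, f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_binary_case(self):
        acc, p, r, f1, conf = evaluate_metrics(
            ["1", "1", "0", "0"], ["1", "0", "0", "0"]
        )
        assert acc == pytest.approx(0.75)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(5 / 6)
        assert f1 == pytest.approx(11 / 15)
        assert conf.tolist() == [[2, 1], [0, 1]]

    def test_absent_class_zero_division_rule(self):
        acc, p, r, f1, _ = evaluate_metrics(
            ["a", "a"], ["a", "a"], labels=["a", "b"]
        )
        assert acc == 1.0
        assert p == pytest.approx(0.5)  # absent class contributes precision 0

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            evaluate_metrics(["a"], ["a", "b"])

    def test_matches_brute_force_on_random_cases(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 6))
            v = int(rng.integers(1, 30))
            labels = [str(i) for i in range(k)]
            truth = [labels[i] for i in rng.integers(0, k, v)]
            pred = [labels[i] for i in rng.integers(0, k, v)]
            got = evaluate_metrics(pred, truth, labels=labels)
            want = brute_force_metrics(pred, truth, labels)
            for g, w in zip(got[:4], want[:4]):
                assert g == pytest.approx(w)
            assert np.array_equal(got[4], want[4])
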