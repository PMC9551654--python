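import numpy as np
import pytest

from lodgepoint.classify import (
    ImageSample,
    TrainConfig,
    augment_dataset,
    evaluate_model,
    metrics_from_confusion,
    softmax,
    split_by_plot,
    split_dataset,
    train_model,
)
from lodgepoint.classify import _apply_op  # involution checks
from lodgepoint.models import build_model, count_parameters
from lodgepoint.nn import Linear, Network, Sequential


def tiny_samples(n, n_classes=4, size=8, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ImageSample(rng.random((size, size, 3)).astype(np.float32),
                    label=i % n_classes, source_plot=i)
        for i in range(n)
    ]


class TestAugment:
    def test_published_counts_360_to_1000(self):
        out = augment_dataset(tiny_samples(360), 1000, seed=0)
        assert len(out) == 1000
        assert sum(s.augmented for s in out) == 640
        assert sum(not s.augmented for s in out) == 360

    def test_labels_and_plots_inherited(self):
        out = augment_dataset(tiny_samples(8), 30, seed=1)
        by_plot = {s.source_plot: s.label for s in out if not s.augmented}
        for s in out:
            assert s.label == by_plot[s.source_plot]

    def test_horizontal_flip_is_involution(self, rng):
        img = rng.random((6, 6, 3))
        assert np.array_equal(_apply_op(_apply_op(img, "hflip"), "hflip"), img)
        assert np.array_equal(_apply_op(_apply_op(img, "vflip"), "vflip"), img)

    def test_rot90_then_rot270_is_identity(self, rng):
        img = rng.random((6, 6, 3))
        assert np.array_equal(_apply_op(_apply_op(img, "rot90"), "rot270"), img)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset([], 10)


class TestSplit:
    def test_published_sizes_1000_into_640_160_200(self):
        tr, va, te = split_dataset(tiny_samples(1000), seed=0)
        assert (len(tr), len(va), len(te)) == (640, 160, 200)

    def test_exact_ratio_25(self):
        tr, va, te = split_dataset(tiny_samples(25), seed=0)
        assert (len(tr), len(va), len(te)) == (16, 4, 5)

    def test_partition_and_stratification(self):
        samples = tiny_samples(217)
        tr, va, te = split_dataset(samples, seed=3)
        ids = sorted(id(s) for s in tr + va + te)
        assert ids == sorted(id(s) for s in samples)  # disjoint cover
        for label in range(4):
            n_lab = sum(s.label == label for s in samples)
            for part, frac in zip((tr, va, te), (16 / 25, 4 / 25, 5 / 25)):
                got = sum(s.label == label for s in part)
                assert abs(got - n_lab * frac) <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(tiny_samples(24))

    def test_split_by_plot_keeps_augmented_copies_together(self):
        samples = augment_dataset(tiny_samples(40), 120, seed=0)
        tr, va, te = split_by_plot(samples, seed=0)
        assert len(tr) + len(va) + len(te) == 120
        plot_sets = [set(s.source_plot for s in part) for part in (tr, va, te)]
        assert not (plot_sets[0] & plot_sets[1])
        assert not (plot_sets[0] & plot_sets[2])
        assert not (plot_sets[1] & plot_sets[2])


class TestSoftmax:
    def test_equal_logits_uniform(self):
        out = softmax([3.0, 3.0, 3.0, 3.0])
        np.testing.assert_allclose(out.probabilities, 0.25)

    def test_large_logit_no_overflow(self):
        out = softmax([1000.0, 0.0, 0.0, 0.0])
        assert np.isfinite(out.probabilities).all()
        assert out.probabilities[0] == pytest.approx(1.0)
        assert out.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=6)
        a = softmax(z).probabilities
        b = softmax(z + 123.4).probabilities
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])


class TestModels:
    def test_single_linear_layer_parameter_count(self):
        net = Network(Sequential(Linear(3, 4, rng=np.random.default_rng(0))))
        assert count_parameters(net) == 16  # 3*4 weights + 4 biases

    def test_forward_shape_contract(self):
        net = build_model("mobilenetv2", num_classes=4, seed=0, width_mult=0.35)
        x = np.zeros((2, 3, 32, 32), dtype=np.float32)
        assert net.forward(x).shape == (2, 4)

    def test_same_seed_same_initial_weights(self):
        a = build_model("mobilenetv2", num_classes=4, seed=5, width_mult=0.35)
        b = build_model("mobilenetv2", num_classes=4, seed=5, width_mult=0.35)
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_model("resnet50")


class TestMetrics:
    def test_perfect_predictions(self):
        rep = metrics_from_confusion(np.diag([10, 10, 10, 10]))
        assert rep.accuracy == 1.0
        assert rep.macro_precision == 1.0
        assert rep.macro_recall == 1.0
        assert rep.macro_f1 == 1.0

    def test_single_class_collapse_on_balanced_set(self):
        cm = np.zeros((4, 4), dtype=int)
        cm[:, 0] = 25  # everything predicted as class 0
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == 0.25

    def test_two_class_toy_matches_hand_and_sklearn(self):
        from sklearn.metrics import f1_score, precision_score, recall_score

        cm = np.array([[45, 5], [10, 40]])
        rep = metrics_from_confusion(cm)
        c0 = rep.per_class[0]
        assert c0["tp"] == 45 and c0["fp"] == 10 and c0["fn"] == 5 and c0["tn"] == 40
        assert c0["precision"] == pytest.approx(45 / 55)
        assert c0["recall"] == pytest.approx(45 / 50)
        assert c0["accuracy"] == pytest.approx(85 / 100)
        assert c0["f1"] == pytest.approx(2 * (45 / 55) * 0.9 / (45 / 55 + 0.9))
        # independent route: sklearn on the equivalent label vectors
        y_true = np.repeat([0, 1], 50)
        y_pred = np.concatenate([np.repeat([0, 1], [45, 5]), np.repeat([0, 1], [10, 40])])
        assert rep.macro_precision == pytest.approx(
            precision_score(y_true, y_pred, average="macro"))
        assert rep.macro_recall == pytest.approx(
            recall_score(y_true, y_pred, average="macro"))
        assert rep.macro_f1 == pytest.approx(f1_score(y_true, y_pred, average="macro"))

    def test_absent_class_excluded_from_macro(self):
        cm = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 0]])
        rep = metrics_from_confusion(cm)
        assert np.isnan(rep.per_class[2]["f1"])
        assert rep.macro_f1 == pytest.approx(1.0)

    def test_random_guessing_macro_f1_near_quarter(self, rng):
        from sklearn.metrics import confusion_matrix

        f1s = []
        for _ in range(5):
            y_true = np.repeat(np.arange(4), 100)
            y_pred = rng.integers(0, 4, 400)
            rep = metrics_from_confusion(confusion_matrix(y_true, y_pred))
            f1s.append(rep.macro_f1)
        assert abs(np.mean(f1s) - 0.25) < 0.05


class TestTraining:
    def test_frozen_metric_stops_after_patience_plus_one(self):
        samples = tiny_samples(12, n_classes=2, size=16)
        cfg = TrainConfig(model_name="mobilenetv2", num_classes=2, input_size=16,
                          width_mult=0.35, learning_rate=0.0, batch_size=4,
                          max_epochs=50, patience=5, seed=0)
        _, hist = train_model(samples[:8], samples[8:], cfg)
        assert hist["epochs_run"] == cfg.patience + 1
        assert hist["best_epoch"] == 1

    def test_same_seed_identical_history(self):
        samples = tiny_samples(16, n_classes=2, size=16)
        cfg = TrainConfig(model_name="mobilenetv2", num_classes=2, input_size=16,
                          width_mult=0.35, batch_size=4, max_epochs=2,
                          patience=30, seed=9)
        _, h1 = train_model(samples[:12], samples[12:], cfg)
        _, h2 = train_model(samples[:12], samples[12:], cfg)
        assert h1 == h2

    def test_learns_separable_intensity_classes(self):
        # solid dark vs solid bright images are separable by mean intensity
        rng = np.random.default_rng(0)
        samples = []
        for i in range(240):
            lab = i % 2
            img = np.full((32, 32, 3), 0.2 if lab == 0 else 0.8, dtype=np.float32)
            img += rng.normal(0, 0.05, img.shape).astype(np.float32)
            samples.append(ImageSample(np.clip(img, 0, 1), lab, i))
        cfg = TrainConfig(model_name="mobilenetv2", num_classes=2, input_size=32,
                          width_mult=0.35, batch_size=16, learning_rate=0.003,
                          max_epochs=20, patience=30, seed=1)
        model, hist = train_model(samples[:180], samples[180:], cfg)
        assert max(hist["val_accuracy"]) >= 0.95
        rep = evaluate_model(model, samples[180:], input_size=32, num_classes=2)
        assert rep.accuracy >= 0.9

    def test_empty_sets_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            train_model([], tiny_samples(4), cfg)
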