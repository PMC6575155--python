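"""Network construction, shape arithmetic, gradients, and prediction
aggregation."""

from __future__ import annotations

import numpy as np
import pytest

from enteronet.cnn import (
    CLASS_ORDER,
    ClassProbabilities,
    ConfigurationError,
    NetworkConfig,
    TrainingConfig,
    _softmax,
    _to_input,
    build_model,
    layer_activations,
    load_model,
    predict_case,
    predict_image,
    predict_patch,
    save_model,
    train_model,
)
from enteronet.imgprep import RgbImage


TINY = NetworkConfig(
    conv_feature_maps=(2, 3, 3, 3),
    conv_kernels=(3, 3, 3, 3),
    pool_windows=(2, 2, 2, 5),
    fc_width=8,
    dropout_p=0.0,
    input_size=40,
    dtype="float64",
)


class TestArchitecture:
    def test_default_shape_arithmetic(self):
        cfg = NetworkConfig()
        assert cfg.grid_sides() == [500, 125, 25, 5]
        assert cfg.flattened_size == 5 * 5 * 32 == 800
        assert cfg.fc_width == 1024

    def test_conv1_parameter_count(self):
        model = build_model(NetworkConfig())
        w, b = model.convs[0].weight, model.convs[0].bias
        assert w.size + b.size == (5 * 5 * 3 + 1) * 16 == 1216

    def test_indivisible_input_rejected(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            NetworkConfig(input_size=999)

    @pytest.mark.parametrize("side", [200, 400, 1000])
    def test_pool_cascade_for_any_multiple_of_200(self, side):
        cfg = NetworkConfig(input_size=side)
        assert cfg.grid_sides() == [side // 2, side // 8, side // 40, side // 200]

    def test_layer4_grid_is_25x25x32_at_1000(self):
        """Full-width forward at the published input size: the fourth conv
        (pre-pool) grid must be 25 x 25 per map, 5 x 5 after pooling."""
        model = build_model(NetworkConfig(dtype="float32"), init_seed=0)
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (1000, 1000, 3), dtype=np.uint8)
        act = layer_activations(model, img, "conv4")
        assert act.shape == (25, 25, 32)
        pooled = layer_activations(model, img, "pool4")
        assert pooled.shape == (5, 5, 32)
        assert act.min() >= 0.0

    def test_unknown_layer_name_lists_valid(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="conv1"):
            layer_activations(model, np.zeros((40, 40, 3), np.uint8), "conv9")

    def test_zero_input_zero_bias_all_zero(self):
        model = build_model(TINY)
        act = layer_activations(model, np.zeros((40, 40, 3), np.uint8), "conv1")
        # biases are initialized to zero, so a zero input gives zero maps
        assert np.all(act == 0)


class TestGradients:
    def test_analytic_matches_numerical(self):
        """Central-difference check of every parameter group on a tiny
        float64 configuration."""
        model = build_model(TINY, init_seed=1)
        rng = np.random.default_rng(2)
        x = rng.random((3, 40, 40, 3))
        y = np.array([0, 1, 2])

        def loss():
            p = _softmax(model._forward_logits(_to_input(x, TINY), train=False))
            return -np.mean(np.log(p[np.arange(3), y]))

        probs = _softmax(model._forward_logits(_to_input(x, TINY), train=True))
        d = probs.copy()
        d[np.arange(3), y] -= 1
        model._backward(d / 3)
        pick = np.random.default_rng(0)
        for name, layer, attr in model.parameters():
            flat = getattr(layer, attr).reshape(-1)
            grad = np.asarray(getattr(layer, "d" + attr)).reshape(-1)
            for i in pick.choice(flat.size, size=min(6, flat.size), replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                rel = abs(num - grad[i]) / max(1e-8, abs(num) + abs(grad[i]))
                assert rel < 1e-4, f"{name}[{i}]: analytic {grad[i]}, numerical {num}"


def _labeled_batch(rng, n, size):
    x = rng.integers(0, 256, (n, size, size, 3), dtype=np.uint8)
    labels = (["control", "CD", "EE"] * ((n + 2) // 3))[:n]
    return x, labels


class TestTraining:
    def test_default_epochs_is_20(self):
        assert TrainingConfig().epochs == 20

    def test_missing_class_raises(self):
        model = build_model(TINY)
        rng = np.random.default_rng(0)
        x, _ = _labeled_batch(rng, 4, 40)
        with pytest.raises(ValueError, match="EE"):
            train_model(model, x, ["control", "CD", "control", "CD"],
                        TrainingConfig(epochs=1))

    def test_seeded_runs_reproduce_loss(self):
        rng = np.random.default_rng(1)
        x, labels = _labeled_batch(rng, 9, 40)
        tcfg = TrainingConfig(epochs=3, batch_size=4, seed=5)
        losses = []
        for _ in range(2):
            model = build_model(TINY, init_seed=5)
            train_model(model, x, labels, tcfg)
            losses.append(model.loss_history[-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_training_accuracy_on_separable_cohort(self, desk_cohort):
        """A class-separable synthetic cohort is fit to > 0.9 training-set
        patch accuracy within the standard 20 epochs."""
        from enteronet import presets
        from enteronet.imgprep import RgbImage

        px, labels = [], []
        for rec in desk_cohort.records:
            if not rec.case_id.endswith(("000", "001", "002")):
                continue  # 9 cases x 5 images keeps the fit under a minute
            for rel in rec.image_paths:
                px.append(RgbImage.load(desk_cohort.resolve(rel)).pixels)
                labels.append(rec.class_label)
        model = build_model(presets.desk_scale_network(), init_seed=2)
        train_model(model, px, labels, presets.desk_scale_training(seed=2))
        preds = model.predict_proba(np.stack(px))
        acc = np.mean(
            [CLASS_ORDER[i] == l for i, l in zip(preds.argmax(axis=1), labels)]
        )
        assert acc > 0.9

    def test_loss_decreases_on_separable_data(self):
        """Trivially separable patches (class-coded intensity): loss must
        fall from the first epoch to the last."""
        rng = np.random.default_rng(3)
        x = np.zeros((12, 40, 40, 3), dtype=np.uint8)
        labels = []
        for i, level in enumerate([40, 128, 220]):
            x[i * 4 : (i + 1) * 4] = level + rng.integers(-10, 10, (4, 40, 40, 3))
            labels += [["control", "CD", "EE"][i]] * 4
        model = build_model(TINY, init_seed=0)
        train_model(model, x, labels, TrainingConfig(epochs=8, batch_size=4, seed=0))
        assert model.loss_history[-1] < model.loss_history[0]


@pytest.fixture(scope="module")
def pred_model():
    return build_model(
        NetworkConfig(
            conv_feature_maps=(2, 3, 3, 3),
            conv_kernels=(3, 3, 3, 3),
            pool_windows=(2, 2, 2, 5),
            fc_width=8,
            input_size=40,
        ),
        init_seed=4,
    )


class TestPrediction:
    def test_probabilities_sum_to_one(self, pred_model, rng):
        patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        probs = predict_patch(pred_model, patch)
        assert probs.as_array().sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(probs.as_array() >= 0)

    def test_zero_head_weights_give_uniform(self, pred_model, rng):
        patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        pred_model.head.weight[:] = 0
        pred_model.head.bias[:] = 0
        probs = predict_patch(pred_model, patch)
        np.testing.assert_allclose(probs.as_array(), 1 / 3, atol=1e-7)

    def test_inference_deterministic(self, pred_model, rng):
        patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        a = predict_patch(pred_model, patch).as_array()
        b = predict_patch(pred_model, patch).as_array()
        np.testing.assert_array_equal(a, b)

    def test_shape_mismatch_raises(self, pred_model):
        with pytest.raises(ValueError, match="input_size"):
            predict_patch(pred_model, np.zeros((64, 64, 3), np.uint8))

    def test_image_of_patch_size_equals_reflection_mean(self, pred_model, rng):
        """For an image exactly the input size the 15 test patches reduce
        to the three reflections; the image triple is their mean."""
        px = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        image = RgbImage(px, "x")
        expected = np.mean(
            [
                predict_patch(pred_model, px).as_array(),
                predict_patch(pred_model, px[:, ::-1]).as_array(),
                predict_patch(pred_model, px[::-1, :]).as_array(),
            ],
            axis=0,
        )
        np.testing.assert_allclose(
            predict_image(pred_model, image).as_array(), expected, atol=1e-9
        )

    def test_case_mean_and_tie_break(self):
        a = ClassProbabilities(0.6, 0.2, 0.2)
        b = ClassProbabilities(0.2, 0.6, 0.2)
        mean = ClassProbabilities.from_array(
            np.mean([a.as_array(), b.as_array()], axis=0)
        )
        np.testing.assert_allclose(mean.as_array(), [0.4, 0.4, 0.2])
        assert mean.argmax_label() == "control"  # tie broken by class order

    def test_case_label_invariant_to_image_order(self, pred_model, rng):
        images = [
            RgbImage(rng.integers(0, 256, (40, 40, 3), dtype=np.uint8), f"i{k}")
            for k in range(3)
        ]
        p1, l1 = predict_case(pred_model, images)
        p2, l2 = predict_case(pred_model, images[::-1])
        assert l1 == l2
        np.testing.assert_allclose(p1.as_array(), p2.as_array(), atol=1e-12)

    def test_empty_case_rejected(self, pred_model):
        with pytest.raises(ValueError, match="at least one image"):
            predict_case(pred_model, [])

    def test_mean_of_one_image_is_image_prediction(self, pred_model, rng):
        image = RgbImage(rng.integers(0, 256, (40, 40, 3), dtype=np.uint8), "i")
        case_probs, _ = predict_case(pred_model, [image])
        np.testing.assert_allclose(
            case_probs.as_array(), predict_image(pred_model, image).as_array(), atol=1e-12
        )


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_model(TINY, init_seed=9)
        x, labels = _labeled_batch(np.random.default_rng(0), 6, 40)
        train_model(model, x, labels, TrainingConfig(epochs=1, batch_size=3, seed=1))
        path = tmp_path / "model.ckpt"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.class_order == model.class_order
        assert loaded.loss_history == model.loss_history
        patch = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        np.testing.assert_array_equal(
            predict_patch(model, patch).as_array(),
            predict_patch(loaded, patch).as_array(),
        )


class TestProbabilityInvariants:
    def test_simplex_membership_random_models(self):
        for seed in range(3):
            model = build_model(TINY, init_seed=seed)
            rng = np.random.default_rng(seed)
            batch = rng.integers(0, 256, (4, 40, 40, 3), dtype=np.uint8)
            probs = model.predict_proba(batch)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(probs >= 0)
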