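"""Network structure, training mechanics, prediction, and activation maps."""

from __future__ import annotations

import numpy as np
import pytest

from skelact import (
    ActionImage,
    LabeledDataset,
    SkeletonActionCNN,
    TrainingConfig,
    build_model,
    get_ordering,
)
from skelact.nn.layers import softmax


class TestArchitecture:
    def test_layer_census(self):
        net = build_model(9)
        assert net.n_conv_layers == 6
        assert net.n_pool_layers == 2
        assert net.n_fc_layers == 1
        assert net.FILTERS == (64, 64, 128, 128, 256, 256)

    def test_width_chain_32_16_8(self):
        widths = [s[2] for s in build_model(9).feature_shapes()]
        # conv1, conv2, pool, conv3, conv4, pool, conv5, conv6
        assert widths == [32, 32, 16, 16, 16, 8, 8, 8]

    def test_output_width_matches_classes(self):
        for k in (2, 9, 18):
            net = build_model(k)
            out = net.forward(np.zeros((1, 15, 32, 3), dtype=np.float32))
            assert out.shape == (1, k)

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            build_model(1)


class TestTrainingConfig:
    def test_learning_rate_schedule_steps_every_50(self):
        cfg = TrainingConfig()
        assert cfg.learning_rate_at(1) == 0.01
        assert cfg.learning_rate_at(50) == 0.01
        assert cfg.learning_rate_at(51) == pytest.approx(0.001)
        assert cfg.learning_rate_at(101) == pytest.approx(0.0001)

    def test_reference_recipe_defaults(self):
        cfg = TrainingConfig()
        assert (cfg.epochs, cfg.batch_size, cfg.weight_decay, cfg.runs) == (
            200, 64, 1e-4, 20,
        )


class TestPrediction:
    def test_softmax_probabilities_sum_to_one(self):
        logits = np.random.default_rng(0).normal(size=(7, 9)) * 10
        np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_head_gives_uniform_probabilities(self, encoded_b1):
        model = SkeletonActionCNN(encoded_b1, config=TrainingConfig(epochs=1, runs=1))
        results = model.fit(seed=0)
        results.net.fc.weight[:] = 0.0
        results.net.fc.bias[:] = 0.0
        probs, label, score = results.predict(encoded_b1.samples[0])
        np.testing.assert_allclose(probs, 1.0 / 9.0, atol=1e-6)
        assert label == results.classes[0]  # tie broken by lowest index

    def test_ordering_mismatch_rejected(self, overfit_results, small_dataset):
        results, _ = overfit_results
        other = small_dataset.encode(get_ordering("C2")).samples[0]
        with pytest.raises(ValueError, match="ordering"):
            results.predict(other)


class TestTraining:
    def test_overfit_smoke_memorizes_training_set(self, overfit_results):
        """A small net without regularization memorizes 20 images."""
        results, images = overfit_results
        assert results.history["train_acc"].iloc[-1] == 100.0
        for im in images:
            _, label, _ = results.predict(im)
            assert label == im.label

    def test_loss_trend_nonincreasing_10_epoch_average(self, overfit_results):
        results, _ = overfit_results
        smoothed = (
            results.history["train_loss"].rolling(10).mean().dropna().to_numpy()
        )
        assert (np.diff(smoothed) < 1e-3).all()

    def test_same_seed_reproduces_fit(self, encoded_b1):
        sub = LabeledDataset(encoded_b1.samples[:30], encoded_b1.classes)
        cfg = TrainingConfig(epochs=3, runs=1)
        r1 = SkeletonActionCNN(sub, config=cfg).fit(seed=7)
        r2 = SkeletonActionCNN(sub, config=cfg).fit(seed=7)
        assert r1.history["train_loss"].iloc[-1] == pytest.approx(
            r2.history["train_loss"].iloc[-1], abs=1e-6
        )
        np.testing.assert_allclose(
            r1.net.fc.weight, r2.net.fc.weight, atol=1e-6
        )

    def test_mixed_orderings_rejected(self, small_dataset):
        b1 = small_dataset.encode(get_ordering("B1"))
        mixed = LabeledDataset(
            b1.samples[:10] + small_dataset.encode(get_ordering("C2")).samples[:10],
            b1.classes,
        )
        with pytest.raises(ValueError, match="ordering"):
            SkeletonActionCNN(mixed)

    def test_subject_leak_between_train_and_val_rejected(self, encoded_b1):
        with pytest.raises(ValueError, match="leak"):
            SkeletonActionCNN(encoded_b1, val=encoded_b1)

    def test_summary_reports_fit(self, overfit_results):
        text = overfit_results[0].summary()
        assert "train accuracy: 100.0%" in text
        assert "conv layers: 6" in text

    def test_checkpoint_roundtrip(self, overfit_results, tmp_path):
        results, images = overfit_results
        results.save(tmp_path / "ckpt")
        from skelact import ActionCNNResults

        back = ActionCNNResults.load(tmp_path / "ckpt")
        p0 = results.predict_proba([images.samples[0]])
        p1 = back.predict_proba([images.samples[0]])
        np.testing.assert_allclose(p0, p1, atol=1e-6)


class TestClassActivationMaps:
    def test_raw_cam_matches_bruteforce_weighted_sum(self, overfit_results):
        results, images = overfit_results
        image = images.samples[3]
        cls = results.classes[4]
        cam = results.class_activation_map(image, cls, raw=True)
        feats = results.net.features(image.to_float()[None])[0]  # (3, 8, K)
        w = results.net.fc.weight[4]
        expected = np.zeros((3, 8))
        for i in range(3):
            for j in range(8):
                for k in range(feats.shape[2]):
                    expected[i, j] += w[k] * feats[i, j, k]
        np.testing.assert_allclose(cam, expected, rtol=1e-5)

    def test_cam_linear_in_head_weights(self, overfit_results):
        results, images = overfit_results
        image = images.samples[0]
        idx = 2
        cls = results.classes[idx]
        rng = np.random.default_rng(0)
        w_full = results.net.fc.weight[idx].copy()
        w1 = rng.normal(size=w_full.shape).astype(np.float32)
        w2 = w_full - w1
        cam_full = results.class_activation_map(image, cls, raw=True)
        results.net.fc.weight[idx] = w1
        cam1 = results.class_activation_map(image, cls, raw=True)
        results.net.fc.weight[idx] = w2
        cam2 = results.class_activation_map(image, cls, raw=True)
        results.net.fc.weight[idx] = w_full
        np.testing.assert_allclose(cam_full, cam1 + cam2, rtol=1e-3, atol=1e-5)

    def test_zero_weights_give_zero_cam(self, overfit_results):
        results, images = overfit_results
        idx = 1
        keep = results.net.fc.weight[idx].copy()
        results.net.fc.weight[idx] = 0.0
        cam = results.class_activation_map(
            images.samples[0], results.classes[idx], raw=True
        )
        results.net.fc.weight[idx] = keep
        np.testing.assert_array_equal(cam, 0.0)

    def test_display_cam_shape_and_range(self, overfit_results):
        results, images = overfit_results
        cam = results.class_activation_map(images.samples[0], results.classes[0])
        assert cam.shape == (15, 32)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_unknown_class_rejected(self, overfit_results):
        results, images = overfit_results
        with pytest.raises(KeyError):
            results.class_activation_map(images.samples[0], "SPRINTING")
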