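"""Counting network: architecture contracts, autodiff, training loop."""

import numpy as np
import pytest

from edcrowd.nn import (
    MFCNN,
    NetworkConfig,
    TrainingConfig,
    build_model,
    fine_grained_regress,
    splice_strips,
    split_strips,
    train,
)
from edcrowd.nn import autograd as ag
from edcrowd.nn.autograd import Tensor
from edcrowd.scenes import generate_scene


class TestNetworkConfig:
    def test_decreasing_block_schedule_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(blocks_per_stage=(2, 1, 3, 4))

    def test_zero_strip_count_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(strip_count=0)

    def test_odd_base_width_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(base_width=7)


class TestBuildModel:
    def test_same_seed_gives_identical_initial_weights(self, tiny_config):
        a, b = MFCNN(tiny_config), MFCNN(tiny_config)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_different_seed_gives_different_weights(self, tiny_config):
        import dataclasses

        other = dataclasses.replace(tiny_config, seed=99)
        a, b = MFCNN(tiny_config), MFCNN(other)
        assert not np.array_equal(a.params["input.0.w"].data, b.params["input.0.w"].data)

    def test_encoder_stride_bookkeeping_for_128px_input(self, tiny_model):
        assert tiny_model.encoder_feature_sizes(128, 128) == [
            (32, 32), (16, 16), (8, 8), (4, 4), (2, 2),
        ]

    @pytest.mark.parametrize("h,w", [(64, 64), (100, 172), (96, 160)])
    def test_bookkeeping_matches_actual_encoder_shapes(self, tiny_model, h, w):
        # independent oracle: repeated ceil-halving from the input block
        def ceil_half(v):
            return -(-v // 2)

        hh, ww = ceil_half(ceil_half(h)), ceil_half(ceil_half(w))
        expected = [(hh, ww)]
        for _ in range(4):
            hh, ww = ceil_half(hh), ceil_half(ww)
            expected.append((hh, ww))
        assert tiny_model.encoder_feature_sizes(h, w) == expected
        tiny_model.forward(np.zeros((h, w), dtype=np.float32))
        assert tiny_model.last_encoder_shapes == expected


class TestStripOperations:
    def test_split_then_splice_is_identity(self):
        x = np.random.default_rng(0).normal(size=(1, 3, 10, 7)).astype(np.float32)
        for axis in (2, 3):
            strips = split_strips(x, 3, axis=axis)
            back = splice_strips(strips, axis=axis, size=x.shape[axis])
            assert np.array_equal(back, x)

    def test_identity_blocks_fuse_to_twice_the_input(self):
        x = np.random.default_rng(1).normal(size=(4, 9, 11)).astype(np.float32)
        fused = fine_grained_regress(x, strip_count=1)
        assert np.allclose(fused, 2 * x)
        fused4 = fine_grained_regress(x, strip_count=4)
        assert np.allclose(fused4, 2 * x)

    @pytest.mark.parametrize("h,w,s", [(8, 8, 2), (9, 13, 4), (17, 5, 5), (6, 6, 1)])
    def test_output_spatial_size_equals_input(self, h, w, s):
        x = np.zeros((2, 3, h, w), dtype=np.float32)
        assert fine_grained_regress(x, s).shape == x.shape

    def test_oversized_strip_count_rejected(self):
        with pytest.raises(ValueError):
            fine_grained_regress(np.zeros((1, 2, 3, 3)), strip_count=4)


class TestForward:
    @pytest.mark.parametrize("h,w", [(64, 64), (128, 128), (100, 172), (96, 160), (240, 320)])
    def test_density_map_matches_input_size(self, tiny_model, h, w):
        pred = tiny_model.forward(np.zeros((h, w), dtype=np.float32))
        assert pred.density.shape == (h, w)

    def test_predictions_are_non_negative(self, tiny_model):
        scene = generate_scene(10, 64, 96, seed=1)
        pred = tiny_model.forward(scene.image)
        assert (pred.density >= 0).all()

    def test_count_equals_map_total(self, tiny_model):
        pred = tiny_model.forward(generate_scene(5, 64, 64, seed=2).image)
        assert pred.count == pytest.approx(float(pred.density.sum()), rel=1e-5)

    def test_undersized_input_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((48, 64), dtype=np.float32))

    def test_rgb_input_accepted(self, tiny_model):
        pred = tiny_model.forward(np.zeros((64, 64, 3), dtype=np.float32))
        assert pred.density.shape == (64, 64)


class TestAutodiff:
    def test_directional_derivatives_match_numerics(self):
        rng = np.random.default_rng(4)
        x = Tensor(rng.normal(size=(1, 2, 8, 9)).astype(np.float32), requires_grad=True)
        w = Tensor((rng.normal(size=(3, 2, 3, 3)) * 0.4).astype(np.float32), requires_grad=True)

        def f():
            h = ag.conv2d(x, w, stride=2, padding=1)
            h = ag.sigmoid(h)
            h = ag.resize_nearest(h, (8, 9))
            return ag.mul(h, h)

        out = f()
        seed = rng.normal(size=out.data.shape).astype(np.float32)
        out.backward(seed)
        for t in (x, w):
            d = rng.normal(size=t.data.shape).astype(np.float32)
            eps = 1e-3
            orig = t.data.copy()
            t.data = orig + eps * d
            fp = float((f().data * seed).sum())
            t.data = orig - eps * d
            fm = float((f().data * seed).sum())
            t.data = orig
            num = (fp - fm) / (2 * eps)
            ana = float((t.grad * d).sum())
            assert ana == pytest.approx(num, rel=5e-3)

    def test_sse_loss_gradient(self):
        pred = Tensor(np.array([[1.0, 2.0]], dtype=np.float32), requires_grad=True)
        target = np.array([[0.0, 0.0]], dtype=np.float32)
        loss = ag.sse_loss(pred, target)
        loss.backward()
        assert loss.data == pytest.approx(5.0)
        assert np.allclose(pred.grad, [[2.0, 4.0]])


class TestTraining:
    def test_one_epoch_history(self, tiny_config, training_pairs):
        model = MFCNN(tiny_config)
        tcfg = TrainingConfig(batch_size=8, learning_rate=1e-4, epochs=1,
                              val_fraction=0.0, seed=0)
        model, history = train(model, training_pairs, tcfg)
        assert len(history.train_loss) == 1
        assert history.best_epoch == 0
        assert len(history.val_mce) == len(history.val_rmse) == 1

    def test_training_is_seed_reproducible(self, tiny_config, training_pairs):
        tcfg = TrainingConfig(batch_size=4, learning_rate=1e-4, epochs=2,
                              val_fraction=0.25, seed=7)
        _, h1 = train(MFCNN(tiny_config), training_pairs, tcfg)
        _, h2 = train(MFCNN(tiny_config), training_pairs, tcfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_mce == h2.val_mce

    def test_best_epoch_minimizes_validation_mce(self, tiny_config, training_pairs):
        tcfg = TrainingConfig(batch_size=4, learning_rate=1e-4, epochs=4,
                              val_fraction=0.25, seed=1)
        _, history = train(MFCNN(tiny_config), training_pairs, tcfg)
        assert history.best_epoch == int(np.argmin(history.val_mce))

    def test_mismatched_density_shape_rejected(self, tiny_config):
        img = np.zeros((64, 64), dtype=np.float32)
        bad = np.zeros((32, 32), dtype=np.float32)
        with pytest.raises(ValueError):
            train(MFCNN(tiny_config), [(img, bad)], TrainingConfig(epochs=1))

    def test_empty_training_set_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            train(MFCNN(tiny_config), [], TrainingConfig(epochs=1))

    def test_checkpoint_round_trip(self, tiny_config, training_pairs, tmp_path):
        model = MFCNN(tiny_config)
        tcfg = TrainingConfig(batch_size=8, learning_rate=1e-4, epochs=1,
                              val_fraction=0.0, seed=0)
        model, _ = train(model, training_pairs, tcfg)
        model.save(tmp_path / "model.npz")
        loaded = MFCNN.load(tmp_path / "model.npz")
        img = training_pairs[0][0]
        assert loaded.predict_count(img) == pytest.approx(model.predict_count(img))
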