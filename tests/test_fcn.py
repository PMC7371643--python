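"""Network contracts: shapes, gradients, training loop, tiled inference."""

import numpy as np
import pytest

from actinseg import fcn
from actinseg._nn import bce_loss, rmse_loss
from actinseg.datamodel import Crop, CropSet, NormalizationParams
from actinseg.fcn import ModelSpec, TrainedModel, UNet, build_model, predict, train


def tiny_spec(**kw):
    base = dict(name="h_d", encoder_filters=(4, 8), out_channels=2,
                loss="rmse", batch_size=4, seed=0)
    base.update(kw)
    return ModelSpec(**base)


def crop_set(n, window=32, classes=("rings", "fibers"), seed=0,
             labels_from_input=True):
    """Crops whose labels are a threshold of the input (trivially learnable)."""
    rng = np.random.default_rng(seed)
    crops = []
    for i in range(n):
        patch = rng.random((window, window))
        labels = {}
        for j, cls in enumerate(classes):
            if labels_from_input:
                labels[cls] = patch > 0.5 if j == 0 else patch < 0.3
            else:
                labels[cls] = rng.random((window, window)) > 0.5
        crops.append(Crop(patch=patch, labels=labels, source_id=str(i),
                          offset=(0, 0)))
    return CropSet(crops=crops, window=window,
                   normalization=NormalizationParams(m=0.0, M=1.0, factor=1.0))


class TestModelSpec:
    def test_shipped_configurations(self):
        hd = ModelSpec.h_d()
        assert hd.encoder_filters == (16, 32, 64, 128)
        assert hd.out_channels == 2 and hd.loss == "rmse" and hd.batch_size == 72
        ha = ModelSpec.h_a()
        assert ha.encoder_filters == (8, 16, 32, 64)
        assert ha.out_channels == 1 and ha.loss == "cross_entropy"
        assert ha.batch_size == 96

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(encoder_filters=(32, 16))
        with pytest.raises(ValueError):
            ModelSpec(out_channels=3)


class TestForward:
    def test_output_shape_and_range_two_channels(self):
        net = UNet(tiny_spec())
        x = np.random.default_rng(0).random((2, 1, 32, 32)).astype(np.float32)
        y = net.forward(x)
        assert y.shape == (2, 2, 32, 32)
        assert y.min() >= 0 and y.max() <= 1

    def test_single_channel_output(self):
        net = UNet(tiny_spec(out_channels=1, loss="cross_entropy"))
        x = np.random.default_rng(0).random((1, 1, 64, 64)).astype(np.float32)
        assert net.forward(x).shape == (1, 1, 64, 64)

    def test_size_independence(self):
        # the same weights run on any side divisible by the pooling factor
        net = UNet(tiny_spec())
        for side in (16, 32, 48):
            y = net.forward(np.zeros((1, 1, side, side), dtype=np.float32))
            assert y.shape == (1, 2, side, side)

    def test_indivisible_input_raises_naming_padding(self):
        net = UNet(tiny_spec())  # depth 2 -> factor 4
        with pytest.raises(ValueError, match="divisible by 4"):
            net.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))

    def test_eval_mode_deterministic(self):
        net = UNet(tiny_spec())
        x = np.random.default_rng(1).random((1, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(net.forward(x, training=False),
                              net.forward(x, training=False))


class TestGradients:
    @pytest.mark.parametrize("loss_fn", [rmse_loss, bce_loss],
                             ids=["rmse", "bce"])
    def test_backprop_matches_finite_differences(self, loss_fn):
        net = UNet(tiny_spec())
        rng = np.random.default_rng(1)
        x = rng.random((2, 1, 16, 16)).astype(np.float32)
        y = (rng.random((2, 2, 16, 16)) > 0.5).astype(np.float32)
        for p in net.params():
            p.grad[...] = 0
        pred = net.forward(x, training=True)
        _, g = loss_fn(pred, y)
        net.backward(g)
        params = net.params()
        rng2 = np.random.default_rng(2)
        for _ in range(15):
            p = params[int(rng2.integers(len(params)))]
            flat = p.value.ravel()
            ei = int(rng2.integers(flat.size))
            eps = 1e-2
            orig = flat[ei]
            flat[ei] = orig + eps
            l1, _ = loss_fn(net.forward(x, training=True), y)
            flat[ei] = orig - eps
            l2, _ = loss_fn(net.forward(x, training=True), y)
            flat[ei] = orig
            num = (l1 - l2) / (2 * eps)
            ana = p.grad.ravel()[ei]
            assert abs(num - ana) <= 2e-3 + 0.05 * max(abs(num), abs(ana))


class TestTrain:
    def test_learnable_labels_beat_untrained_loss(self):
        tr = crop_set(24, seed=0)
        va = crop_set(8, seed=1)
        spec = tiny_spec(batch_size=8)
        model = build_model(spec)
        x, y = va.stacked(("rings", "fibers"))
        untrained_loss, _ = rmse_loss(model.forward(x), y)
        trained = train(model, tr, va, max_epochs=6, patience=6, seed=0,
                        augment_crops=False)
        assert trained.history["val_loss"].iloc[-1] < untrained_loss
        assert trained.best_epoch <= trained.stopped_epoch

    def test_patience_zero_stops_at_first_non_improvement(self):
        tr = crop_set(8, labels_from_input=False, seed=2)
        va = crop_set(4, labels_from_input=False, seed=3)
        trained = train(build_model(tiny_spec(batch_size=4)), tr, va,
                        max_epochs=50, patience=0, seed=0, augment_crops=False)
        hist = trained.history["val_loss"].to_numpy()
        # stopping epoch is the first whose loss did not improve the best
        assert trained.stopped_epoch < 50 or np.all(np.diff(hist) < 0)

    def test_same_seed_reproduces_history(self):
        tr = crop_set(12, seed=4)
        va = crop_set(4, seed=5)
        h1 = train(build_model(tiny_spec(batch_size=4)), tr, va,
                   max_epochs=3, patience=3, seed=7).history
        h2 = train(build_model(tiny_spec(batch_size=4)), tr, va,
                   max_epochs=3, patience=3, seed=7).history
        assert np.allclose(h1["val_loss"], h2["val_loss"])

    def test_empty_sets_rejected(self):
        tr = crop_set(4)
        with pytest.raises(ValueError):
            train(build_model(tiny_spec()), CropSet([], 32), tr)

    def test_replicates_have_independent_weights(self):
        from actinseg.pipeline import train_replicates
        tr = crop_set(8, seed=6)
        va = crop_set(4, seed=7)
        models = train_replicates(tiny_spec(batch_size=4), tr, va, k=2,
                                  max_epochs=2, patience=2, seed=0)
        assert len(models) == 2
        w0 = models[0].model.params()[0].value
        w1 = models[1].model.params()[0].value
        assert not np.array_equal(w0, w1)
        for m in models:
            assert len(m.history) >= 1


class TestPredict:
    def _trained(self, window=32):
        tr = crop_set(8, window=window)
        va = crop_set(4, window=window, seed=1)
        return train(build_model(tiny_spec(batch_size=4)), tr, va,
                     max_epochs=1, patience=1, seed=0, augment_crops=False)

    def test_prediction_shape_matches_input(self):
        trained = self._trained()
        img = np.random.default_rng(0).random((96, 96))
        preds = predict(trained, img)
        assert set(preds) == {"rings", "fibers"}
        assert all(p.shape == (96, 96) for p in preds.values())
        assert all(0 <= p.min() and p.max() <= 1 for p in preds.values())

    def test_constant_image_periodic_scores_away_from_borders(self):
        # pooling breaks full shift invariance: a constant input maps to a
        # pattern periodic with the pooling factor (2^depth = 4), constant
        # within each phase away from the zero-padded borders
        trained = self._trained()
        preds = predict(trained, np.zeros((64, 64)))
        core = preds["rings"][16:-16, 16:-16]
        # loose tolerance: the receptive field spans most of a 64px image,
        # so faint border leakage remains everywhere
        period4 = np.abs(core[:-4, :-4] - core[4:, 4:]).max()
        period2 = np.abs(core[:-2, :-2] - core[2:, 2:]).max()
        assert period4 < 0.01
        assert period4 < period2  # the structure really is the pooling lattice

    def test_tiled_equals_single_pass_on_interior(self):
        trained = self._trained(window=32)
        img = np.random.default_rng(3).random((160, 160))
        single = predict(trained, img)  # 160 <= 4*window: single pass
        trained_small = self._trained(window=32)
        trained_small.window = 32
        # force tiling by shrinking the single-pass size limit via big image
        big = np.pad(img, ((0, 160), (0, 160)), mode="wrap")
        tiled = predict(trained, big)
        # interior of the original region should roughly agree
        d = np.abs(single["rings"][32:128, 32:128] - tiled["rings"][32:128, 32:128])
        assert np.median(d) < 0.05


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        tr = crop_set(8)
        va = crop_set(4, seed=1)
        trained = train(build_model(tiny_spec(batch_size=4)), tr, va,
                        max_epochs=1, patience=1, seed=0)
        trained.thresholds = {"rings": 0.25, "fibers": 0.4}
        fcn.save_checkpoint(trained, tmp_path / "ckpt")
        back = fcn.load_checkpoint(tmp_path / "ckpt")
        img = np.random.default_rng(5).random((64, 64))
        p1 = predict(trained, img)
        p2 = predict(back, img)
        for cls in p1:
            np.testing.assert_allclose(p1[cls], p2[cls], atol=1e-6)
        assert back.thresholds == trained.thresholds
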