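import numpy as np
import pytest
from scipy import stats

import focusctu as f
from focusctu.segmenter import (
    TrainedEnsemble,
    UNetConfig,
    _one_hot,
    dice_loss,
    foreground_dice,
    predict,
    sample_crop,
    train_cross_validation,
)
from focusctu.segmenter import _layers
from focusctu.segmenter.unet import UNet3D
from focusctu.volio import ImageVolume, LabelVolume


def tiny_dataset(n_cases=2, shape=(16, 16, 8), seed=0):
    """Random paired volumes at the small working spacing, for API tests."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_cases):
        img = ImageVolume(rng.normal(40, 30, shape).astype(np.float32), spacing=(2, 2, 4))
        lab = LabelVolume(rng.integers(0, 4, shape).astype(np.uint8), spacing=(2, 2, 4))
        out.append((img, lab))
    return out


def tiny_config(**overrides):
    base = dict(
        patch_size=(16, 16, 8), working_spacing=(2.0, 2.0, 4.0), folds=2, epochs=2,
        learning_rate=1e-2, depth=2, base_channels=4, crops_per_epoch=1,
    )
    base.update(overrides)
    return UNetConfig(**base)


class TestConfig:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError):
            UNetConfig(patch_size=(30, 32, 16), depth=3)

    def test_minimum_folds_and_epochs(self):
        with pytest.raises(ValueError):
            tiny_config(folds=1)
        with pytest.raises(ValueError):
            tiny_config(epochs=0)

    def test_normalization_window(self):
        cfg = tiny_config()
        hu = np.array([-2000.0, -1024.0, 600.0, 3000.0])
        np.testing.assert_allclose(cfg.normalize(hu), [0.0, 0.0, 1.0, 1.0])


class TestSampleCrop:
    def test_full_volume_crop_is_identity(self):
        (img, lab), = tiny_dataset(1)
        ci, cl = sample_crop(img, lab, img.shape, seed=0)
        np.testing.assert_array_equal(ci.voxels, img.voxels)
        np.testing.assert_array_equal(cl.labels, lab.labels)

    def test_same_seed_same_crop(self):
        (img, lab), = tiny_dataset(1)
        a = sample_crop(img, lab, (8, 8, 4), seed=7)
        b = sample_crop(img, lab, (8, 8, 4), seed=7)
        assert a[0].origin == b[0].origin
        np.testing.assert_array_equal(a[0].voxels, b[0].voxels)

    def test_grid_mismatch_rejected(self):
        (img, _), (_, lab) = tiny_dataset(2)
        lab2 = LabelVolume(lab.labels[:8], spacing=lab.spacing)
        with pytest.raises(ValueError):
            sample_crop(img, lab2, (4, 4, 4), seed=0)

    def test_oversized_patch_pads_with_fill(self):
        (img, lab), = tiny_dataset(1)
        ci, cl = sample_crop(img, lab, (32, 16, 8), seed=0, fill_hu=-1024.0)
        assert ci.shape == (32, 16, 8)
        assert np.all(ci.voxels[16:] == -1024.0)
        assert np.all(cl.labels[16:] == 0)

    def test_origin_distribution_uniform_over_valid_origins(self):
        # 8^3 patch in a 10x10x10 volume: 3 valid origins per axis = 27 cells
        rng = np.random.default_rng(0)
        img = ImageVolume(rng.normal(size=(10, 10, 10)).astype(np.float32))
        lab = LabelVolume(np.zeros((10, 10, 10), dtype=np.uint8))
        valid = {(i, j, k) for i in range(3) for j in range(3) for k in range(3)}
        counts = {v: 0 for v in valid}
        n_draws = 2700
        for s in range(n_draws):
            ci, _ = sample_crop(img, lab, (8, 8, 8), seed=s)
            origin = tuple(int(round(o)) for o in ci.origin)
            assert origin in valid
            counts[origin] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-3


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        lab = np.random.default_rng(0).integers(0, 4, (6, 6, 6))
        onehot = _one_hot(lab, 4)
        assert dice_loss(onehot, onehot) == pytest.approx(0.0, abs=1e-4)

    def test_uniform_prediction_on_background_closed_form(self):
        # uniform p=0.25, all-background truth of N voxels:
        # class 0: (2*0.25N+eps)/(1.25N+eps); classes 1-3: eps/(0.25N+eps)
        N = 4 * 4 * 4
        eps = 1e-5
        onehot = _one_hot(np.zeros((4, 4, 4), dtype=int), 4)
        probs = np.full((4, 4, 4, 4), 0.25, dtype=np.float32)
        d0 = (0.5 * N + eps) / (1.25 * N + eps)
        dk = eps / (0.25 * N + eps)
        expected = 1.0 - (d0 + 3 * dk) / 4.0
        assert dice_loss(probs, onehot, eps) == pytest.approx(expected, rel=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 2, 2, 2)), np.zeros((4, 2, 2, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_loss_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(4), size=(3, 3, 3)).transpose(3, 0, 1, 2)
        lab = rng.integers(0, 4, (3, 3, 3))
        loss = dice_loss(probs.astype(np.float32), _one_hot(lab, 4))
        assert 0.0 <= loss <= 1.0


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Every parameter gradient of the network agrees with float64
        central differences to near machine precision."""
        old = _layers.DTYPE
        _layers.DTYPE = np.float64
        try:
            net = UNet3D(in_channels=1, n_classes=4, depth=2, base_channels=2, seed=1)
            rng = np.random.default_rng(0)
            x = rng.normal(0, 1, (1, 8, 8, 4))
            onehot = _one_hot(rng.integers(0, 4, (8, 8, 4)), 4).astype(float)
            for layer in net.parametric_layers():
                for k, (p, _) in layer.param_items().items():
                    idx = tuple(rng.integers(0, s) for s in p.shape)
                    eps = 1e-6
                    orig = p[idx]
                    p[idx] = orig + eps
                    lp = net.loss_and_grad(x, onehot)
                    p[idx] = orig - eps
                    lm = net.loss_and_grad(x, onehot)
                    p[idx] = orig
                    numeric = (lp - lm) / (2 * eps)
                    net.loss_and_grad(x, onehot)
                    analytic = layer.param_items()[k][1][idx]
                    assert numeric == pytest.approx(analytic, rel=1e-4, abs=1e-8)
        finally:
            _layers.DTYPE = old


class TestEnsemblePrediction:
    def test_single_model_duplicated_changes_nothing(self):
        net = UNet3D(depth=2, base_channels=4, seed=3)
        cfg = tiny_config()
        (img, _), = tiny_dataset(1)
        one = predict(TrainedEnsemble([net], cfg), img)
        two = predict(TrainedEnsemble([net, net], cfg), img)
        np.testing.assert_array_equal(one.labels, two.labels)

    def test_model_order_invariance(self):
        a = UNet3D(depth=2, base_channels=4, seed=1)
        b = UNet3D(depth=2, base_channels=4, seed=2)
        cfg = tiny_config()
        (img, _), = tiny_dataset(1)
        _, p_ab = predict(TrainedEnsemble([a, b], cfg), img, return_probs=True)
        _, p_ba = predict(TrainedEnsemble([b, a], cfg), img, return_probs=True)
        np.testing.assert_allclose(p_ab, p_ba, atol=1e-6)

    def test_empty_ensemble_rejected(self):
        (img, _), = tiny_dataset(1)
        with pytest.raises(RuntimeError):
            predict(TrainedEnsemble([], tiny_config()), img)

    def test_volume_smaller_than_patch_keeps_shape(self):
        net = UNet3D(depth=2, base_channels=4, seed=0)
        cfg = tiny_config(patch_size=(32, 32, 16))
        (img, _), = tiny_dataset(1)  # 16x16x8 < patch
        out = predict(TrainedEnsemble([net], cfg), img)
        assert out.labels.shape == img.shape
        assert set(np.unique(out.labels)) <= {0, 1, 2, 3}

    def test_overlapping_windows_average_in_probability_space(self):
        """Two windows overlapping halfway: the soft prediction in the
        overlap equals the hand-computed mean of the two window outputs."""
        net = UNet3D(depth=2, base_channels=4, seed=5)
        cfg = tiny_config(patch_size=(8, 8, 8))
        rng = np.random.default_rng(6)
        img = ImageVolume(rng.normal(40, 30, (12, 8, 8)).astype(np.float32), spacing=(2, 2, 4))
        _, probs = predict(
            TrainedEnsemble([net], cfg), img, stride=(4, 8, 8), return_probs=True
        )
        arr = cfg.normalize(img.voxels)
        pw0 = net.forward_probs(arr[0:8][None])
        pw1 = net.forward_probs(arr[4:12][None])
        expected = (pw0[:, 4:8] + pw1[:, 0:4]) / 2.0
        np.testing.assert_allclose(probs[:, 4:8], expected, atol=1e-6)


class TestTraining:
    def test_dataset_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError):
            train_cross_validation(tiny_dataset(1), tiny_config(folds=2), seed=0)

    def test_fold_assignment_deterministic(self):
        ds = tiny_dataset(4)
        cfg = tiny_config(epochs=1)
        a = train_cross_validation(ds, cfg, seed=3)
        b = train_cross_validation(ds, cfg, seed=3)
        assert [fr.val_indices for fr in a.fold_results] == [fr.val_indices for fr in b.fold_results]
        assert all(
            sorted(sum((fr.val_indices for fr in a.fold_results), [])) == list(range(4))
            for _ in [0]
        )

    def test_retained_loss_not_worse_than_first_epoch(self):
        ds = tiny_dataset(2)
        ens = train_cross_validation(ds, tiny_config(epochs=4), seed=1)
        for fr in ens.fold_results:
            assert fr.best_val_loss <= fr.val_history[0]
            assert fr.best_val_loss == min(fr.val_history)

    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        ds = tiny_dataset(2)
        ens = train_cross_validation(ds, tiny_config(epochs=1), seed=2)
        before = predict(ens, ds[0][0])
        ens.save(tmp_path / "model")
        loaded = TrainedEnsemble.load(tmp_path / "model")
        after = predict(loaded, ds[0][0])
        np.testing.assert_array_equal(before.labels, after.labels)
        assert loaded.config == ens.config
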