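"""Residual backbone: layer gradients, shapes, determinism, training."""

import numpy as np
import pytest

from beakfusion import _nn
from beakfusion.deep_backbone import (
    BackboneConfig,
    build_backbone,
    extract_deep,
    resize_for_backbone,
    train_backbone,
)
from beakfusion.errors import ConfigError, DataError, SizeError
from beakfusion.synthetic_beaks import SynthConfig, generate_dataset


def numerical_grad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        hi = f()
        x[idx] = orig - eps
        lo = f()
        x[idx] = orig
        g[idx] = (hi - lo) / (2 * eps)
    return g


class TestLayerGradients:
    def test_conv_bn_residual_chain_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        block = _nn.ResidualBlock(
            _nn.Sequential(
                _nn.Conv2d(2, 2, 3, 1, 1, rng), _nn.BatchNorm2d(2), _nn.ReLU(),
                _nn.Conv2d(2, 2, 3, 1, 1, rng), _nn.BatchNorm2d(2),
            ),
            None,
        )
        net = _nn.Sequential(
            _nn.Conv2d(1, 2, 3, 1, 1, rng), _nn.BatchNorm2d(2), _nn.ReLU(),
            _nn.MaxPool2d(2, 2), block, _nn.GlobalAvgPool(),
        )
        head = _nn.Linear(2, 3, rng)
        x = rng.normal(size=(4, 1, 6, 6))
        y = np.array([0, 1, 2, 1])

        def loss_fn():
            logits = head.forward(net.forward(x, train=True), train=True)
            loss, _ = _nn.softmax_cross_entropy(logits, y)
            return loss

        logits = head.forward(net.forward(x, train=True), train=True)
        _, grad = _nn.softmax_cross_entropy(logits, y)
        for p in net.parameters() + head.parameters():
            p.grad[...] = 0.0
        net.backward(head.backward(grad))

        checked = 0
        for p in net.parameters() + head.parameters():
            flat = p.value.ravel()
            sample = np.linspace(0, flat.size - 1, min(4, flat.size)).astype(int)
            for k in sample:
                idx = np.unravel_index(k, p.value.shape)
                num = numerical_grad(loss_fn, p.value)[idx]
                assert p.grad[idx] == pytest.approx(num, abs=2e-4), p
                checked += 1
        assert checked >= 20

    def test_softmax_cross_entropy_of_uniform_logits(self):
        loss, grad = _nn.softmax_cross_entropy(np.zeros((2, 4)), np.array([0, 3]))
        assert loss == pytest.approx(np.log(4))
        assert grad.shape == (2, 4)


@pytest.fixture(scope="module")
def separable_dataset():
    """Fully separated synthetic classes, one view, with the CNN-training
    protocol's augmentation expanding the training images 4-fold."""
    from beakfusion.augmentation import AugmentSpec, sample_augmentations

    cfg = SynthConfig(
        n_per_class=28, views=("upper",), image_side=64,
        shape_separation=1.0, texture_separation=1.0, seed=42,
    )
    images = generate_dataset(cfg)
    by_class = {}
    for im in images:
        by_class.setdefault(im.label, []).append(im)
    train, val = [], []
    for cls in sorted(by_class):
        train += by_class[cls][:20]
        val += by_class[cls][20:]
    augmented = []
    for j, im in enumerate(train):
        spec = AugmentSpec(
            p_flip=0.0, rotation_range_deg=(-12, 12), crop_frac_range=(0.85, 1.0),
            aspect_range=(0.9, 1.1), n_per_image=3, seed=1000 + j,
        )
        augmented += sample_augmentations(im, spec)
    return train + augmented, val


def desk_config(**kw):
    base = dict(profile="desk_small", input_side=32, n_classes=4, feat_dim=64,
                epochs=5, batch_size=16, seed=0)
    base.update(kw)
    return BackboneConfig(**base)


class TestBuild:
    def test_desk_small_pooled_dimension_is_configurable(self):
        bb = build_backbone(desk_config(feat_dim=48))
        assert bb.feature_dim == 48
        f = extract_deep(bb, [np.zeros((32, 32)) + 10.0])
        assert f[0].dim == 48

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_backbone(desk_config(seed=7))
        b = build_backbone(desk_config(seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ConfigError):
            BackboneConfig(profile="vgg")

    def test_zero_epochs_rejected(self):
        with pytest.raises(ConfigError):
            desk_config(epochs=0)


class TestSchedule:
    def test_two_stage_learning_rate_boundary(self):
        cfg = BackboneConfig(profile="desk_small")
        assert cfg.learning_rate(50) == pytest.approx(1e-3)
        assert cfg.learning_rate(51) == pytest.approx(1e-4)
        assert cfg.learning_rate(1) == pytest.approx(1e-3)


class TestTraining:
    def test_validation_loss_improves_on_separable_data(self, separable_dataset):
        train, val = separable_dataset
        bb = build_backbone(desk_config(epochs=5))
        tr32 = resize_for_backbone(train, bb)
        va32 = resize_for_backbone(val, bb)
        trained = train_backbone(bb, tr32, va32)
        h = trained.history
        assert h["val_loss"].iloc[-1] <= h["val_loss"].iloc[0]
        assert list(h["epoch"]) == [1, 2, 3, 4, 5]

    def test_high_separation_reaches_90pct_validation_accuracy(self, separable_dataset):
        train, val = separable_dataset
        bb = build_backbone(desk_config(epochs=20, seed=1))
        trained = train_backbone(
            bb, resize_for_backbone(train, bb), resize_for_backbone(val, bb)
        )
        assert trained.history["val_acc"].max() >= 0.9

    def test_empty_split_rejected(self, separable_dataset):
        train, _ = separable_dataset
        bb = build_backbone(desk_config())
        with pytest.raises(DataError):
            train_backbone(bb, resize_for_backbone(train, bb), [])

    def test_overlapping_train_val_rejected(self, separable_dataset):
        train, _ = separable_dataset
        bb = build_backbone(desk_config())
        imgs = resize_for_backbone(train, bb)
        with pytest.raises(DataError):
            train_backbone(bb, imgs, imgs[:4])


class TestExtract:
    def test_features_independent_of_batch_composition(self, separable_dataset, rng):
        train, _ = separable_dataset
        bb = build_backbone(desk_config())
        imgs = resize_for_backbone(train[:6], bb)
        together = np.vstack([f.values for f in extract_deep(bb, imgs, batch_size=6)])
        alone = np.vstack([extract_deep(bb, [im])[0].values for im in imgs])
        np.testing.assert_allclose(together, alone, atol=1e-5)

    def test_duplicated_input_gives_identical_features(self, separable_dataset):
        train, _ = separable_dataset
        bb = build_backbone(desk_config())
        im = resize_for_backbone(train[:1], bb)[0]
        f = extract_deep(bb, [im, im])
        np.testing.assert_array_equal(f[0].values, f[1].values)

    def test_feature_order_matches_input_order(self, separable_dataset):
        train, _ = separable_dataset
        bb = build_backbone(desk_config())
        imgs = resize_for_backbone(train[:5], bb)
        feats = extract_deep(bb, imgs)
        assert [f.source_id for f in feats] == [im.source_id for im in imgs]

    def test_wrong_input_size_rejected(self):
        bb = build_backbone(desk_config(input_side=32))
        with pytest.raises(SizeError):
            extract_deep(bb, [np.zeros((48, 48))])

    def test_save_load_round_trip_preserves_features(self, separable_dataset, tmp_path):
        train, _ = separable_dataset
        bb = build_backbone(desk_config(seed=3))
        imgs = resize_for_backbone(train[:3], bb)
        before = np.vstack([f.values for f in extract_deep(bb, imgs)])
        bb.save(tmp_path / "bb.npz")
        other = build_backbone(desk_config(seed=99))
        other.load(tmp_path / "bb.npz")
        after = np.vstack([f.values for f in extract_deep(other, imgs)])
        np.testing.assert_allclose(before, after, atol=1e-12)
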