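"""Residual convolutional backbones and deep-feature extraction.

Two profiles are provided:

``reference50``
    The 50-layer bottleneck residual network: a 7x7/2 stem, 3x3/2 max pool,
    bottleneck stages of (3, 4, 6, 3) units with output widths
    (256, 512, 1024, 2048), global average pooling to a 2048-long vector,
    and a final classification layer.  The pooled penultimate vector — the
    input of the fully connected layer — is the deep feature used for
    fusion.

``desk_small``
    A shallow residual network (5 convolutions) with a configurable pooled
    feature width, small enough to train on a laptop CPU in seconds.  It
    exists so the full pipeline can be exercised end to end on synthetic
    data; it is not a stand-in for the reference profile's capacity.

Training follows the two-stage schedule used for the beak experiments:
cross-entropy, SGD with momentum 0.9, learning rate 1e-3 for epochs 1-50
and 1e-4 for epochs 51-100, batch size 16, best-validation-loss weights
retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from beakfusion import _nn
from beakfusion.errors import ConfigError, DataError, SizeError
from beakfusion.io_dataset import LabeledImage

# fixed input standardization constants (intensity scale [0, 1])
INPUT_MEAN = 0.5
INPUT_STD = 0.25

PROFILES = ("reference50", "desk_small")


@dataclass
class BackboneConfig:
    profile: str = "desk_small"
    input_side: int = 224
    n_classes: int = 4
    epochs: int = 100
    batch_size: int = 16
    lr_schedule: list[tuple[tuple[int, int], float]] = field(
        default_factory=lambda: [((1, 50), 1e-3), ((51, 100), 1e-4)]
    )
    feat_dim: int = 64  # pooled width of desk_small; reference50 is fixed at 2048
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ConfigError(f"unknown profile {self.profile!r}; choose from {PROFILES}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ConfigError(f"batch_size must be >= 1, got {self.batch_size}")
        for (lo, hi), rate in self.lr_schedule:
            if rate <= 0:
                raise ConfigError(f"learning rate must be > 0, got {rate}")
            if lo > hi:
                raise ConfigError(f"bad epoch range ({lo}, {hi})")

    def learning_rate(self, epoch: int) -> float:
        """Rate in force at 1-indexed ``epoch``; last range extends onward."""
        for (lo, hi), rate in self.lr_schedule:
            if lo <= epoch <= hi:
                return rate
        return self.lr_schedule[-1][1]


@dataclass
class DeepFeature:
    values: np.ndarray
    source: str
    source_id: str = ""

    @property
    def dim(self) -> int:
        return len(self.values)


class Backbone:
    """A feature trunk plus classification head with a fixed pooled width."""

    def __init__(self, trunk: _nn.Sequential, head: _nn.Linear, config: BackboneConfig, dim: int):
        self.trunk = trunk
        self.head = head
        self.config = config
        self.feature_dim = dim

    def forward(self, x: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        feats = self.trunk.forward(x, train)
        logits = self.head.forward(feats, train)
        return feats, logits

    def backward(self, grad_logits: np.ndarray) -> None:
        self.trunk.backward(self.head.backward(grad_logits))

    def parameters(self) -> list[_nn.Parameter]:
        return self.trunk.parameters() + self.head.parameters()

    def state(self) -> list[np.ndarray]:
        return _nn.get_state(self.trunk) + _nn.get_state(self.head)

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        n_trunk = len(_nn.get_state(self.trunk))
        _nn.set_state(self.trunk, list(state[:n_trunk]))
        _nn.set_state(self.head, list(state[n_trunk:]))

    def save(self, path) -> None:
        np.savez(path, *self.state())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state([data[k] for k in data.files])


def _conv_bn_relu(cin, cout, k, stride, pad, rng) -> list[_nn.Layer]:
    return [_nn.Conv2d(cin, cout, k, stride, pad, rng), _nn.BatchNorm2d(cout), _nn.ReLU()]


def _bottleneck(cin: int, mid: int, cout: int, stride: int, rng) -> _nn.ResidualBlock:
    main = _nn.Sequential(
        *_conv_bn_relu(cin, mid, 1, 1, 0, rng),
        *_conv_bn_relu(mid, mid, 3, stride, 1, rng),
        _nn.Conv2d(mid, cout, 1, 1, 0, rng),
        _nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = _nn.Sequential(_nn.Conv2d(cin, cout, 1, stride, 0, rng), _nn.BatchNorm2d(cout))
    return _nn.ResidualBlock(main, shortcut)


def _basic(cin: int, cout: int, stride: int, rng) -> _nn.ResidualBlock:
    main = _nn.Sequential(
        *_conv_bn_relu(cin, cout, 3, stride, 1, rng),
        _nn.Conv2d(cout, cout, 3, 1, 1, rng),
        _nn.BatchNorm2d(cout),
    )
    shortcut = None
    if stride != 1 or cin != cout:
        shortcut = _nn.Sequential(_nn.Conv2d(cin, cout, 1, stride, 0, rng), _nn.BatchNorm2d(cout))
    return _nn.ResidualBlock(main, shortcut)


def build_backbone(config: BackboneConfig) -> Backbone:
    """Construct a backbone with seed-determined initial weights."""
    rng = np.random.default_rng(config.seed)
    if config.profile == "reference50":
        layers: list[_nn.Layer] = _conv_bn_relu(3, 64, 7, 2, 3, rng)
        layers.append(_nn.MaxPool2d(3, 2, pad=1))
        cin = 64
        for n_blocks, mid, cout, first_stride in (
            (3, 64, 256, 1),
            (4, 128, 512, 2),
            (6, 256, 1024, 2),
            (3, 512, 2048, 2),
        ):
            for b in range(n_blocks):
                layers.append(_bottleneck(cin, mid, cout, first_stride if b == 0 else 1, rng))
                cin = cout
        layers.append(_nn.GlobalAvgPool())
        dim = 2048
    else:  # desk_small: stem conv + two basic residual blocks (5 convs)
        dim = config.feat_dim
        layers = _conv_bn_relu(1, 16, 3, 1, 1, rng)
        layers.append(_nn.MaxPool2d(2, 2))
        layers.append(_basic(16, 32, 2, rng))
        layers.append(_basic(32, dim, 2, rng))
        layers.append(_nn.GlobalAvgPool())
    trunk = _nn.Sequential(*layers)
    head = _nn.Linear(dim, config.n_classes, rng)
    return Backbone(trunk, head, config, dim)


def _expected_channels(backbone: Backbone) -> int:
    return 3 if backbone.config.profile == "reference50" else 1


def images_to_batch(imgs: Sequence[LabeledImage | np.ndarray], backbone: Backbone) -> np.ndarray:
    """Stack images into a standardized NCHW batch of the profile's input size."""
    from beakfusion.io_dataset import to_gray

    side = backbone.config.input_side
    want_c = _expected_channels(backbone)
    batch = []
    for img in imgs:
        px = img.pixels if isinstance(img, LabeledImage) else np.asarray(img)
        px = np.asarray(px, dtype=float)
        if want_c == 1:
            px = to_gray(px)[..., None] if px.ndim == 3 else px[..., None]
        elif px.ndim == 2:
            px = np.repeat(px[..., None], 3, axis=2)
        if px.shape[0] != side or px.shape[1] != side:
            raise SizeError(
                f"expected {side}x{side} input, got {px.shape[0]}x{px.shape[1]}; "
                "resize images to the backbone's input_side first"
            )
        batch.append(px.transpose(2, 0, 1))
    x = np.stack(batch) / 255.0
    return (x - INPUT_MEAN) / INPUT_STD


def resize_for_backbone(imgs: Sequence[LabeledImage], backbone: Backbone) -> list[LabeledImage]:
    """Bilinear-resize labeled images to the backbone's input side."""
    from beakfusion.io_dataset import _resize_bilinear

    side = backbone.config.input_side
    out = []
    for img in imgs:
        px = np.clip(_resize_bilinear(np.asarray(img.pixels, float), side, side), 0, 255)
        out.append(LabeledImage(px, img.label, img.view, img.source_id))
    return out


class TrainedBackbone:
    """A backbone plus its best-validation weights and loss history."""

    def __init__(self, backbone: Backbone, history: pd.DataFrame, classes: list[str]):
        self.backbone = backbone
        self.history = history
        self.classes = classes

    @property
    def config(self) -> BackboneConfig:
        return self.backbone.config


def train_backbone(
    backbone: Backbone,
    train_imgs: Sequence[LabeledImage],
    val_imgs: Sequence[LabeledImage],
    config: BackboneConfig | None = None,
) -> TrainedBackbone:
    """Train with cross-entropy under the two-stage learning-rate schedule.

    Per-epoch train and validation losses are recorded; the weights with the
    lowest validation loss are restored before returning.
    """
    config = config or backbone.config
    if not train_imgs or not val_imgs:
        raise DataError("train and validation sets must both be non-empty")
    train_ids = {im.source_id for im in train_imgs}
    if train_ids & {im.source_id for im in val_imgs}:
        raise DataError("train and validation sets overlap")
    classes = sorted({im.label for im in train_imgs})
    if len(classes) < 2:
        raise DataError("need at least two classes to train")
    cls_index = {c: i for i, c in enumerate(classes)}
    x_train = images_to_batch(train_imgs, backbone)
    y_train = np.array([cls_index[im.label] for im in train_imgs])
    x_val = images_to_batch(val_imgs, backbone)
    y_val = np.array([cls_index[im.label] for im in val_imgs])

    rng = np.random.default_rng(config.seed + 1)
    opt = _nn.SGD(backbone.parameters(), lr=config.learning_rate(1), momentum=config.momentum)
    best_loss = np.inf
    best_state = backbone.state()
    rows = []
    for epoch in range(1, config.epochs + 1):
        opt.lr = config.learning_rate(epoch)
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            opt.zero_grad()
            _, logits = backbone.forward(x_train[idx], train=True)
            loss, grad = _nn.softmax_cross_entropy(logits, y_train[idx])
            backbone.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        train_loss = epoch_loss / len(order)
        _, val_logits = backbone.forward(x_val, train=False)
        val_loss, _ = _nn.softmax_cross_entropy(val_logits, y_val)
        val_acc = float((val_logits.argmax(axis=1) == y_val).mean())
        rows.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "val_acc": val_acc}
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = backbone.state()
    backbone.load_state(best_state)
    return TrainedBackbone(backbone, pd.DataFrame(rows), classes)


def extract_deep(
    trained: TrainedBackbone | Backbone,
    imgs: Sequence[LabeledImage | np.ndarray],
    batch_size: int = 16,
) -> list[DeepFeature]:
    """Pooled penultimate activations in evaluation mode, in input order.

    Batch-norm uses running statistics, so features are independent of how
    the inputs are batched.
    """
    backbone = trained.backbone if isinstance(trained, TrainedBackbone) else trained
    feats: list[np.ndarray] = []
    for start in range(0, len(imgs), batch_size):
        chunk = imgs[start : start + batch_size]
        x = images_to_batch(chunk, backbone)
        f, _ = backbone.forward(x, train=False)
        feats.extend(f)
    out = []
    for img, f in zip(imgs, feats):
        sid = img.source_id if isinstance(img, LabeledImage) else ""
        out.append(DeepFeature(values=np.asarray(f), source=backbone.config.profile, source_id=sid))
    return out
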