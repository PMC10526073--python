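"""Image loading, grayscale conversion/resizing, and dataset partitioning.

Images live in a directory tree ``root/<class>/<view>/*.{png,jpg}`` (the
``<view>`` level — ``upper`` or ``lower`` beak — is optional).  Descriptors
operate on square grayscale grids produced by :func:`to_gray_resized`; the
train/validation/test partition is stratified per class and fully seeded.

Conventions fixed here so that descriptor tests are bit-reproducible:

* grayscale = ITU-R 601 luminance, ``0.299 R + 0.587 G + 0.114 B``;
* resizing = bilinear with half-pixel-center alignment and no antialiasing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

from beakfusion.errors import ImageDecodeError, ImageFormatError, SizeError, SplitSizeError

MIN_SIDE = 3  # descriptors need at least a 3x3 neighborhood
VIEWS = ("upper", "lower")

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class LabeledImage:
    """A labeled beak image.

    ``pixels`` is a 2-D (grayscale) or 3-D (RGB, channels last) array with
    values in [0, 255].  ``label`` is the species identifier, ``view`` is
    ``upper`` or ``lower``, and ``source_id`` is an opaque provenance string
    unique within a dataset.
    """

    pixels: np.ndarray
    label: str
    view: str = "upper"
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] not in (3, 4)):
            raise ImageFormatError(f"expected HxW or HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise SizeError(
                f"image {self.source_id!r} is {px.shape[0]}x{px.shape[1]}; "
                f"minimum is {MIN_SIDE}x{MIN_SIDE}"
            )
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ImageFormatError("pixel values must lie in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test sets of ``source_id`` strings."""

    train_ids: set = field(default_factory=set)
    val_ids: set = field(default_factory=set)
    test_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.train_ids = set(self.train_ids)
        self.val_ids = set(self.val_ids)
        self.test_ids = set(self.test_ids)
        if (
            self.train_ids & self.val_ids
            or self.train_ids & self.test_ids
            or self.val_ids & self.test_ids
        ):
            raise ValueError("train/val/test id sets must be pairwise disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train": sorted(self.train_ids),
            "val": sorted(self.val_ids),
            "test": sorted(self.test_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetSplit":
        payload = json.loads(Path(path).read_text())
        return cls(set(payload["train"]), set(payload["val"]), set(payload["test"]))


def load_image(path: str | Path) -> LabeledImage:
    """Load a PNG/JPEG file into a :class:`LabeledImage`.

    The label is inferred from the parent directory name; when the parent is
    a view directory (``upper``/``lower``) the label comes from the
    grandparent instead.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode in ("1", "L", "I;16", "I", "F"):
                if im.mode != "L":
                    raise ImageFormatError(
                        f"{path}: unsupported bit depth / mode {im.mode!r}; expected 8-bit"
                    )
                px = np.asarray(im)
            elif im.mode in ("RGB", "RGBA", "P", "LA"):
                px = np.asarray(im.convert("RGB"))
            else:
                raise ImageFormatError(f"{path}: unsupported image mode {im.mode!r}")
    except FileNotFoundError:
        raise ImageDecodeError(f"{path}: file not found") from None
    except UnidentifiedImageError as exc:
        raise ImageDecodeError(f"{path}: cannot decode image: {exc}") from None
    except OSError as exc:
        raise ImageDecodeError(f"{path}: cannot read image: {exc}") from None

    parent = path.parent.name
    if parent in VIEWS and path.parent.parent.name:
        label, view = path.parent.parent.name, parent
    else:
        label, view = parent, "upper"
    return LabeledImage(pixels=px, label=label, view=view, source_id=path.stem)


def load_dataset(root: str | Path) -> list[LabeledImage]:
    """Load every PNG/JPEG under ``root/<class>[/<view>]/``, sorted by path."""
    root = Path(root)
    paths = sorted(
        p for p in root.rglob("*") if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    images = []
    for p in paths:
        img = load_image(p)
        # make ids unique across classes/views
        img.source_id = str(p.relative_to(root).with_suffix("")).replace("\\", "/")
        images.append(img)
    return images


def _resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resize with half-pixel-center alignment, no antialiasing.

    Output pixel center (i, j) maps to source coordinates
    ``(i + 0.5) * H/out_h - 0.5`` (clamped to the grid), so an identity
    resize returns the input unchanged.
    """
    h, w = img.shape[:2]
    if (h, w) == (out_h, out_w):
        return img.astype(float, copy=True)
    rows = np.clip((np.arange(out_h) + 0.5) * (h / out_h) - 0.5, 0, h - 1)
    cols = np.clip((np.arange(out_w) + 0.5) * (w / out_w) - 0.5, 0, w - 1)
    r0 = np.minimum(np.floor(rows).astype(int), h - 2) if h > 1 else np.zeros(out_h, int)
    c0 = np.minimum(np.floor(cols).astype(int), w - 2) if w > 1 else np.zeros(out_w, int)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    a = img[np.ix_(r0, c0)]
    b = img[np.ix_(r0, c0 + 1)] if w > 1 else a
    c = img[np.ix_(r0 + 1, c0)] if h > 1 else a
    d = img[np.ix_(r0 + 1, c0 + 1)] if (h > 1 and w > 1) else a
    if img.ndim == 3:
        fr = fr[..., None]
        fc = fc[..., None]
    return (
        a * (1 - fr) * (1 - fc)
        + b * (1 - fr) * fc
        + c * fr * (1 - fc)
        + d * fr * fc
    )


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance conversion; grayscale inputs pass through."""
    px = np.asarray(pixels, dtype=float)
    if px.ndim == 2:
        return px
    return px[..., :3] @ GRAY_WEIGHTS


def to_gray_resized(img: LabeledImage | np.ndarray, side: int) -> np.ndarray:
    """Convert to grayscale and resize to ``side`` x ``side`` (bilinear).

    This is the canonical preprocessing for both shallow descriptors: the
    texture descriptor runs on 512x512 inputs and the gradient descriptor on
    256x256 by default.
    """
    if side < MIN_SIDE:
        raise SizeError(f"side must be >= {MIN_SIDE}, got {side}")
    px = img.pixels if isinstance(img, LabeledImage) else np.asarray(img)
    gray = to_gray(px)
    return _resize_bilinear(gray, side, side)


def split_dataset(
    ids_by_class: Mapping[str, Sequence[str]],
    test_frac: float = 0.2,
    val_frac_of_rest: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified, seeded train/validation/test partition.

    Per class, ``test_frac`` of the ids go to the test set; of the remainder,
    ``val_frac_of_rest`` go to validation and the rest to training (the
    80/20 then 80/20 protocol).  Rounding keeps per-class counts within one
    sample of the exact ratios.
    """
    if not 0 < test_frac < 1 or not 0 < val_frac_of_rest < 1:
        raise ValueError("split fractions must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    val: set[str] = set()
    test: set[str] = set()
    for cls in sorted(ids_by_class):
        ids = list(ids_by_class[cls])
        if len(ids) < 3:
            raise SplitSizeError(
                f"class {cls!r} has only {len(ids)} samples; need at least 3 to split"
            )
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n_test = int(round(len(ids) * test_frac))
        n_test = min(max(n_test, 1), len(ids) - 2)
        rest = shuffled[n_test:]
        n_val = int(round(len(rest) * val_frac_of_rest))
        n_val = min(max(n_val, 1), len(rest) - 1)
        test.update(shuffled[:n_test])
        val.update(rest[:n_val])
        train.update(rest[n_val:])
    return DatasetSplit(train_ids=train, val_ids=val, test_ids=test)
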