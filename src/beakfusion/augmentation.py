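"""Affine training-set augmentation: flip, rotation, random crop, rescale.

Every transform is an affine map ``y = omega @ x + b`` on image coordinates
taken about the image center.  Output pixels are produced by inverse mapping
with bilinear interpolation; coordinates falling outside the source are
filled with 255, the white light board the specimens are photographed on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from beakfusion.errors import ParameterError
from beakfusion.io_dataset import LabeledImage, _resize_bilinear

BACKGROUND = 255.0


@dataclass
class AugmentSpec:
    """Parameters of the stochastic augmentation stage.

    ``n_per_image`` augmented copies are drawn per source image; each copy
    gets an independent random flip (probability ``p_flip``), rotation
    (uniform in ``rotation_range_deg``), crop (area fraction in
    ``crop_frac_range``, random position, resized back) and aspect-ratio
    rescale (width/height factor in ``aspect_range``).
    """

    p_flip: float = 0.5
    rotation_range_deg: tuple[float, float] = (-45.0, 45.0)
    crop_frac_range: tuple[float, float] = (0.7, 1.0)
    aspect_range: tuple[float, float] = (0.8, 1.25)
    n_per_image: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_flip <= 1:
            raise ParameterError(f"p_flip must be in [0,1], got {self.p_flip}")
        if self.crop_frac_range[1] > 1 or self.crop_frac_range[0] <= 0:
            raise ParameterError(f"crop_frac_range must lie in (0,1], got {self.crop_frac_range}")
        if self.n_per_image < 0:
            raise ParameterError(f"n_per_image must be >= 0, got {self.n_per_image}")
        for lo, hi in (self.rotation_range_deg, self.crop_frac_range, self.aspect_range):
            if hi < lo:
                raise ParameterError("range bounds must be ordered (lo <= hi)")


def apply_affine(
    img: np.ndarray, omega: Sequence[Sequence[float]], b: Sequence[float]
) -> np.ndarray:
    """Apply ``y = omega @ x + b`` to a grayscale image about its center.

    ``x``/``y`` are (x, y) coordinates, x rightward and y downward; the
    output grid is sampled by the inverse map with bilinear interpolation
    and background fill.
    """
    omega = np.asarray(omega, dtype=float)
    b = np.asarray(b, dtype=float).reshape(2)
    if omega.shape != (2, 2):
        raise ParameterError(f"omega must be 2x2, got {omega.shape}")
    if abs(np.linalg.det(omega)) < 1e-12:
        raise ParameterError("omega is singular; affine transform must be invertible")
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    inv = np.linalg.inv(omega)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    out_xy = np.stack([xx.ravel(), yy.ravel()])  # (2, H*W), rows (x, y)
    src_xy = inv @ (out_xy - b[:, None])
    src_rows = src_xy[1].reshape(h, w) + cy
    src_cols = src_xy[0].reshape(h, w) + cx
    return ndimage.map_coordinates(
        img, [src_rows, src_cols], order=1, mode="constant", cval=BACKGROUND
    )


def _rotation(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def _crop_resize(px: np.ndarray, frac: float, aspect: float, pos: tuple[float, float]) -> np.ndarray:
    """Crop a box of relative area ``frac``² and aspect ratio ``aspect``
    (width/height) at relative position ``pos``, then resize back."""
    h, w = px.shape[:2]
    cw = int(round(np.clip(w * frac * np.sqrt(aspect), 3, w)))
    ch = int(round(np.clip(h * frac / np.sqrt(aspect), 3, h)))
    top = int(round(pos[0] * (h - ch)))
    left = int(round(pos[1] * (w - cw)))
    crop = px[top : top + ch, left : left + cw]
    return _resize_bilinear(crop, h, w)


def sample_augmentations(img: LabeledImage, spec: AugmentSpec) -> list[LabeledImage]:
    """Draw ``spec.n_per_image`` augmented copies of ``img``.

    Deterministic given ``spec.seed``; labels and views are preserved, and
    each copy's ``source_id`` is suffixed ``#augN``.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[LabeledImage] = []
    px = np.asarray(img.pixels, dtype=float)
    channels = [px] if px.ndim == 2 else [px[..., c] for c in range(px.shape[2])]
    for i in range(spec.n_per_image):
        omega = np.eye(2)
        if rng.random() < spec.p_flip:
            omega = omega @ np.diag([-1.0, 1.0])
        angle = rng.uniform(*spec.rotation_range_deg)
        omega = _rotation(angle) @ omega
        frac = rng.uniform(*spec.crop_frac_range)
        aspect = rng.uniform(*spec.aspect_range)
        pos = (rng.random(), rng.random())
        new_channels = []
        for ch in channels:
            t = apply_affine(ch, omega, np.zeros(2))
            t = _crop_resize(t, frac, aspect, pos)
            new_channels.append(t)
        new_px = new_channels[0] if px.ndim == 2 else np.stack(new_channels, axis=-1)
        new_px = np.clip(np.round(new_px), 0, 255).astype(np.uint8)
        out.append(
            LabeledImage(
                pixels=new_px,
                label=img.label,
                view=img.view,
                source_id=f"{img.source_id}#aug{i}",
            )
        )
    return out
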