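"""Synthetic beak-like image generator.

Each image is a dark, hooked silhouette on a light board (intensity ~255),
emulating a cephalopod beak photographed for species identification.  The
silhouette is an area-preserving elongated ellipse with a circular "bite"
removed, which produces a rostrum-and-hood hook; its elongation
(hood/crest-length ratio) and the position of the bite (hook curvature) are
the class-specific *shape* signal.  Inside the silhouette, a fine sinusoidal
pigmentation stripe pattern is drawn whose *period in pixels* is the
class-specific *texture* signal; stripe orientation and phase are randomized
per image, and stripe amplitude is scaled proportionally to the period so
the local gradient energy is the same for every class — texture classes are
therefore separable by local texture statistics but carry almost no
orientation/edge signal.  The two signals are scaled independently by
``shape_separation`` and ``texture_separation`` in [0, 1]; at 0 the
class-conditional image distributions coincide and no classifier can beat
chance in expectation.

Intra-class variability comes from per-image jitter of every silhouette
parameter, a random similarity transform (rotation, scale, translation) and
clipped Gaussian pixel noise.  The lower-beak view is a mirrored variant
with a shifted hood/crest ratio.  Generation is fully deterministic given
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from beakfusion.errors import ParameterError
from beakfusion.io_dataset import LabeledImage

DEFAULT_CLASSES = ("D_gigas", "I_argentinus", "E_luminosa", "O_bartramii")

# base silhouette geometry (normalized body coordinates)
_A0 = 0.58  # ellipse semi-axis along the body (hood-crest) axis
_B0 = 0.32  # ellipse semi-axis across the body
_ROT0 = -20.0  # body orientation, degrees
_BITE = (0.10, -0.30)  # bite-disc center (body frame)
_Q0 = 0.34  # bite-disc radius
_T0 = 5.0  # base stripe period, pixels
_AMP0 = 16.0  # base stripe amplitude at period _T0
_PHI0 = 45.0  # mean stripe orientation, degrees

# per-class offsets, scaled by the separation knobs
_D_ELONG = np.array([-0.30, -0.10, 0.10, 0.30])  # hood/crest elongation
_D_BITE = np.array([0.20, -0.20, -0.20, 0.20])  # hook (bite) position
_D_PERIOD = np.array([-0.40, -0.15, 0.15, 0.45])  # stripe period


@dataclass
class SynthConfig:
    n_per_class: int = 50
    classes: tuple[str, ...] = DEFAULT_CLASSES
    views: tuple[str, ...] = ("upper", "lower")
    image_side: int = 512
    shape_separation: float = 1.0
    texture_separation: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if len(self.classes) != 4:
            raise ParameterError(f"exactly 4 classes are modeled, got {len(self.classes)}")
        if not 0 <= self.shape_separation <= 1 or not 0 <= self.texture_separation <= 1:
            raise ParameterError("separations must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.image_side < 16:
            raise ParameterError(f"image_side must be >= 16, got {self.image_side}")


def _class_params(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for k, cls in enumerate(config.classes):
        elong = 1.0 + config.shape_separation * _D_ELONG[k]
        a, b = _A0 * elong, _B0 / elong  # area-preserving elongation
        bite_x = _BITE[0] + config.shape_separation * _D_BITE[k] * 0.25
        period = _T0 * (1.0 + config.texture_separation * _D_PERIOD[k])
        rows.append(
            {
                "class": cls,
                "hood_crest_ratio": a / b,
                "curvature": bite_x,
                "stripe_period_px": period,
                "stripe_orientation_deg": _PHI0,
            }
        )
    return pd.DataFrame(rows)


def describe_ground_truth(config: SynthConfig) -> pd.DataFrame:
    """Per-class contour and texture parameters, for recovery tests."""
    return _class_params(config)


def _render(
    side: int,
    a: float,
    b: float,
    rot_deg: float,
    bite_xy: tuple[float, float],
    q: float,
    center: tuple[float, float],
    scale: float,
    mirror: bool,
    period_px: float,
    amp: float,
    phi_deg: float,
    phase: float,
) -> np.ndarray:
    """Render one silhouette+stripes image as float in [0, 255] (no noise)."""
    half = side / 2.0
    yy, xx = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    u = (xx - half - center[0] * half) / (half * scale)
    v = (yy - half - center[1] * half) / (half * scale)
    if mirror:
        u = -u
    t = np.deg2rad(rot_deg)
    ub = np.cos(t) * u + np.sin(t) * v
    vb = -np.sin(t) * u + np.cos(t) * v
    body = (ub / a) ** 2 + (vb / b) ** 2 <= 1.0
    bite = (ub - bite_xy[0]) ** 2 + (vb - bite_xy[1]) ** 2 <= q**2
    mask = body & ~bite
    img = np.full((side, side), 255.0)
    phi = np.deg2rad(phi_deg)
    d = xx * np.cos(phi) + yy * np.sin(phi)
    stripes = amp * np.sin(2.0 * np.pi * d / period_px + phase)
    pigment = 60.0 + 50.0 * (ub / a + 1.0) / 2.0 + stripes
    img[mask] = pigment[mask]
    return img


def generate_dataset(config: SynthConfig) -> list[LabeledImage]:
    """Generate ``n_per_class * |classes| * |views|`` labeled images.

    Iteration order (class, view, index) and a single generator seeded with
    ``config.seed`` make the output bitwise reproducible.
    """
    rng = np.random.default_rng(config.seed)
    params = _class_params(config).set_index("class")
    out: list[LabeledImage] = []
    for cls in config.classes:
        row = params.loc[cls]
        for view in config.views:
            for i in range(config.n_per_class):
                elong_j = 1.0 + rng.normal(0.0, 0.03)
                # recover (a, b) from the stored area-preserving ratio, jittered
                a = np.sqrt(row["hood_crest_ratio"] * _A0 * _B0) * elong_j
                b = np.sqrt(_A0 * _B0 / row["hood_crest_ratio"]) / elong_j
                if view == "lower":
                    b = b * 1.10  # hood/crest ratio shift between the views
                rot = _ROT0 + rng.normal(0.0, 3.0)
                bite_xy = (
                    row["curvature"] + rng.normal(0.0, 0.03),
                    _BITE[1] + rng.normal(0.0, 0.03),
                )
                q = _Q0 * (1.0 + rng.normal(0.0, 0.05))
                center = (rng.normal(0.0, 0.04), rng.normal(0.0, 0.04))
                scale = 1.0 + rng.normal(0.0, 0.04)
                period = row["stripe_period_px"] * (1.0 + rng.normal(0.0, 0.05))
                # amplitude tracks the period so gradient energy is class-free
                amp = _AMP0 * (period / _T0) * (1.0 + rng.normal(0.0, 0.10))
                phi = _PHI0 + rng.normal(0.0, 10.0)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                img = _render(
                    config.image_side,
                    a,
                    b,
                    rot,
                    bite_xy,
                    q,
                    center,
                    scale,
                    view == "lower",
                    period,
                    amp,
                    phi,
                    phase,
                )
                if config.noise_sd > 0:
                    img = img + rng.normal(0.0, config.noise_sd, img.shape)
                px = np.clip(np.round(img), 0, 255).astype(np.uint8)
                out.append(
                    LabeledImage(
                        pixels=px,
                        label=cls,
                        view=view,
                        source_id=f"{cls}/{view}/{cls}_{view}_{i:04d}",
                    )
                )
    return out


def write_dataset(images: Sequence[LabeledImage], root: str | Path) -> None:
    """Write images in the ``root/<class>/<view>/*.png`` layout."""
    root = Path(root)
    for img in images:
        name = img.source_id.split("/")[-1]
        d = root / img.label / img.view
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img.pixels).save(d / f"{name}.png")
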