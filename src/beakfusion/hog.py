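"""Histogram of oriented gradients.

Gradients are central differences, ``G_x(x,y) = I(x+1,y) - I(x-1,y)`` and
``G_y(x,y) = I(x,y+1) - I(x,y-1)`` (x = column, y = row, edge-replicated
borders), with magnitude ``sqrt(G_x**2 + G_y**2)`` and orientation from the
two-argument arctangent, folded to [0, 180) when unsigned.  Magnitude-
weighted orientation votes are accumulated per ``C x C``-pixel cell with
linear interpolation between the two nearest bin centers; blocks of
``block_cells x block_cells`` cells slide with a stride of
``block_stride_cells`` cells, each block is L2-normalized, and all block
vectors are concatenated row-major.

Descriptor length is ``((side/C - block_cells)/stride + 1)**2 *
block_cells**2 * n_bins``: with the default 9 unsigned bins, 2x2-cell blocks
and 1-cell stride on a 256x256 input this gives 8100 (C=16), 1764 (C=32) and
324 (C=64) dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from beakfusion.errors import ParameterError, SizeError


@dataclass(frozen=True)
class HOGConfig:
    cell_px: int = 16
    block_cells: int = 2
    block_stride_cells: int = 1
    n_bins: int = 9
    signed: bool = False
    block_norm_eps: float = 1e-10

    def __post_init__(self) -> None:
        if self.cell_px < 2:
            raise ParameterError(f"cell_px must be >= 2, got {self.cell_px}")
        if self.n_bins < 2:
            raise ParameterError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.block_cells < 1 or self.block_stride_cells < 1:
            raise ParameterError("block geometry must be positive")
        if self.block_norm_eps <= 0:
            raise ParameterError("block_norm_eps must be > 0")

    @property
    def angle_span(self) -> float:
        return 360.0 if self.signed else 180.0

    def descriptor_length(self, side: int) -> int:
        cells = side // self.cell_px
        blocks = (cells - self.block_cells) // self.block_stride_cells + 1
        return blocks**2 * self.block_cells**2 * self.n_bins


def gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and orientation (degrees, (-180, 180]).

    Central differences with edge replication at the borders.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise SizeError(f"need a 2-D grayscale image of side >= 3, got shape {img.shape}")
    padded = np.pad(img, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]  # I(x+1,y) - I(x-1,y)
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]  # I(x,y+1) - I(x,y-1)
    mag = np.hypot(gx, gy)
    angle = np.degrees(np.arctan2(gy, gx))
    return mag, angle


def cell_histograms(mag: np.ndarray, angle: np.ndarray, config: HOGConfig) -> np.ndarray:
    """Per-cell orientation histograms, shape (cells_y, cells_x, n_bins).

    Votes are weighted by magnitude and split linearly between the two
    nearest bin centers (centers at ``(k + 0.5) * span/n_bins``, circular).
    """
    mag = np.asarray(mag, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if mag.shape != angle.shape:
        raise SizeError("magnitude and angle grids must share a shape")
    h, w = mag.shape
    c = config.cell_px
    if h % c or w % c:
        raise SizeError(f"image shape {h}x{w} not divisible by cell size {c}")
    span = config.angle_span
    nb = config.n_bins
    bin_w = span / nb
    a = np.mod(angle, span)
    # fractional bin position relative to bin centers
    pos = a / bin_w - 0.5
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    lo_bin = np.mod(lo, nb)
    hi_bin = np.mod(lo + 1, nb)
    cells_y, cells_x = h // c, w // c
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cell_idx = (rows // c) * cells_x + (cols // c)
    hist = np.zeros(cells_y * cells_x * nb)
    np.add.at(hist, cell_idx.ravel() * nb + lo_bin.ravel(), (mag * (1 - frac)).ravel())
    np.add.at(hist, cell_idx.ravel() * nb + hi_bin.ravel(), (mag * frac).ravel())
    return hist.reshape(cells_y, cells_x, nb)


def hog_descriptor(img: np.ndarray, config: HOGConfig = HOGConfig()) -> np.ndarray:
    """Full block-normalized HOG feature vector of a square grayscale image.

    Intensities are scaled to [0, 1] first (gradient orientations are scale
    invariant; this fixes the magnitude scale the ``block_norm_eps`` guard
    sees).  A constant image yields the zero vector.
    """
    img = np.asarray(img, dtype=float) / 255.0
    mag, angle = gradients(img)
    hist = cell_histograms(mag, angle, config)
    cells_y, cells_x, nb = hist.shape
    bc, st = config.block_cells, config.block_stride_cells
    if cells_y < bc or cells_x < bc:
        raise SizeError(
            f"{cells_y}x{cells_x} cells cannot form a {bc}x{bc}-cell block"
        )
    blocks = []
    for by in range(0, cells_y - bc + 1, st):
        for bx in range(0, cells_x - bc + 1, st):
            v = hist[by : by + bc, bx : bx + bc].ravel()
            norm = np.linalg.norm(v)
            blocks.append(v / max(norm, config.block_norm_eps))
    return np.concatenate(blocks)
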