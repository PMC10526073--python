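"""Circular, interpolated, uniform local binary patterns.

Each pixel is assigned a ``P``-bit code by thresholding the intensities at
``P`` points sampled on a circle of radius ``R`` against the center pixel:

    LBP(x_c, y_c) = sum_p 2^p * S(i_p - i_c),    S(x) = 1 iff x >= 0,

with sampling point ``p`` at ``(x_c + R cos(2*pi*p/P), y_c - R sin(2*pi*p/P))``
(x rightward, y = image row downward; the minus sign fixes the bit order).
Fractional sample coordinates are resolved by bilinear interpolation.

Codes are binned with the uniform-pattern mapping: the ``P*(P-1) + 2`` codes
with at most two circular 0/1 transitions each get their own bin and all
remaining codes share one catch-all bin, giving ``P*(P-1) + 3`` bins — 59 for
``P = 8``, the dimensionality used for fusion.  The image is divided into
``grid_n x grid_n`` cells; per-cell histograms are normalized to sum 1 and
concatenated in row-major order (``grid_n = 1`` gives a single global
histogram).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from beakfusion.errors import ParameterError, SizeError

_MAX_P = 20  # lookup-table mapping; 2^P entries

# Bilinear interpolation of equal neighbors must compare as "equal" to the
# center so that S(0) = 1 holds exactly; this absorbs ~1e-13 rounding noise
# on the 0-255 intensity scale.
_THRESH_EPS = 1e-9


@dataclass(frozen=True)
class LBPConfig:
    """Geometry of the circular neighborhood and the histogram grid."""

    R: float = 1.0
    P: int = 8
    grid_n: int = 1
    uniform: bool = True

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ParameterError(f"radius R must be > 0, got {self.R}")
        if not 4 <= self.P <= _MAX_P:
            raise ParameterError(f"P must be in [4, {_MAX_P}], got {self.P}")
        if self.grid_n < 1:
            raise ParameterError(f"grid_n must be >= 1, got {self.grid_n}")

    @property
    def n_bins(self) -> int:
        """Histogram bins per cell: P(P-1)+3 uniform, else 2^P raw codes."""
        return self.P * (self.P - 1) + 3 if self.uniform else 2**self.P

    @property
    def descriptor_length(self) -> int:
        return self.grid_n**2 * self.n_bins


def sample_positions(center: tuple[float, float], config: LBPConfig) -> list[tuple[float, float]]:
    """Circle sampling coordinates (x_p, y_p) for p = 0 .. P-1.

    ``center`` is (x_c, y_c); y points down, so y_p = y_c - R sin(2*pi*p/P).
    """
    xc, yc = center
    out = []
    for p in range(config.P):
        theta = 2.0 * np.pi * p / config.P
        out.append((xc + config.R * np.cos(theta), yc - config.R * np.sin(theta)))
    return out


def _bilinear_sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional (row, col) coordinates.

    Coordinates must lie within the grid; exact hits on the last row/column
    are handled by shifting the base cell inward.
    """
    h, w = img.shape
    r0 = np.clip(np.floor(rows).astype(int), 0, h - 2)
    c0 = np.clip(np.floor(cols).astype(int), 0, w - 2)
    fr = rows - r0
    fc = cols - c0
    return (
        img[r0, c0] * (1 - fr) * (1 - fc)
        + img[r0, c0 + 1] * (1 - fr) * fc
        + img[r0 + 1, c0] * fr * (1 - fc)
        + img[r0 + 1, c0 + 1] * fr * fc
    )


def _circular_transitions(code: int, P: int) -> int:
    bits = [(code >> p) & 1 for p in range(P)]
    return sum(bits[p] != bits[(p + 1) % P] for p in range(P))


@lru_cache(maxsize=8)
def _uniform_table(P: int) -> np.ndarray:
    """Lookup table code -> bin index.

    Uniform codes (<= 2 circular transitions) get bins 0..P(P-1)+1 in
    increasing code order; all other codes map to the final catch-all bin.
    """
    n_codes = 2**P
    table = np.empty(n_codes, dtype=np.int64)
    catch_all = P * (P - 1) + 2
    next_bin = 0
    for code in range(n_codes):
        if _circular_transitions(code, P) <= 2:
            table[code] = next_bin
            next_bin += 1
        else:
            table[code] = catch_all
    assert next_bin == catch_all
    return table


def uniform_bin(code: int, P: int) -> int:
    """Map a raw LBP code to its uniform-pattern histogram bin."""
    if not 0 <= code < 2**P:
        raise ParameterError(f"code {code} outside [0, 2^{P})")
    return int(_uniform_table(P)[code])


def _codes_grid(img: np.ndarray, config: LBPConfig) -> tuple[np.ndarray, int]:
    """LBP codes for all valid centers; returns (codes, margin).

    Centers closer than ceil(R) to a border are skipped (no padding), so
    every bilinear sample uses only real pixels.
    """
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    margin = int(np.ceil(config.R))
    if h < 2 * margin + 1 or w < 2 * margin + 1:
        raise SizeError(
            f"image {h}x{w} smaller than the {2 * margin + 1} pixel neighborhood"
        )
    rows, cols = np.meshgrid(
        np.arange(margin, h - margin), np.arange(margin, w - margin), indexing="ij"
    )
    center = img[rows, cols]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p in range(config.P):
        theta = 2.0 * np.pi * p / config.P
        sample = _bilinear_sample(
            img,
            rows - config.R * np.sin(theta),
            cols + config.R * np.cos(theta),
        )
        codes |= (sample - center >= -_THRESH_EPS).astype(np.int64) << p
    return codes, margin


def lbp_code(img: np.ndarray, center: tuple[int, int], config: LBPConfig) -> int:
    """Raw LBP code at one center pixel, given as (row, col)."""
    img = np.asarray(img, dtype=float)
    r, c = center
    ic = img[r, c]
    code = 0
    for p, (x, y) in enumerate(sample_positions((c, r), config)):
        ip = _bilinear_sample(img, np.array([y]), np.array([x]))[0]
        if ip - ic >= -_THRESH_EPS:
            code |= 1 << p
    return code


def lbp_descriptor(img: np.ndarray, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Concatenated per-cell normalized LBP histogram of the whole image.

    Length is ``grid_n**2 * (P*(P-1)+3)`` with the uniform mapping; each
    cell's histogram sums to 1 provided the cell contains a valid center.
    """
    img = np.asarray(img, dtype=float)
    codes, margin = _codes_grid(img, config)
    if config.uniform:
        bins = _uniform_table(config.P)[codes]
    else:
        bins = codes
    h, w = img.shape
    n = config.grid_n
    # cell index of each center, from its position in the full image
    rows = np.arange(margin, h - margin)
    cols = np.arange(margin, w - margin)
    cell_r = np.minimum((rows * n) // h, n - 1)
    cell_c = np.minimum((cols * n) // w, n - 1)
    cell_of = cell_r[:, None] * n + cell_c[None, :]
    nb = config.n_bins
    flat = cell_of.ravel() * nb + bins.ravel()
    hist = np.bincount(flat, minlength=n * n * nb).astype(float).reshape(n * n, nb)
    sums = hist.sum(axis=1, keepdims=True)
    np.divide(hist, sums, out=hist, where=sums > 0)
    return hist.ravel()
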