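"""HOG: gradients, cell voting, block normalization, descriptor length."""

import numpy as np
import pytest

from beakfusion.errors import SizeError
from beakfusion.hog import HOGConfig, cell_histograms, gradients, hog_descriptor


def naive_hog(img, cell_px, n_bins=9, block_cells=2, stride=1, eps=1e-10):
    """Literal per-pixel reimplementation of the descriptor."""
    img = np.asarray(img, dtype=float) / 255.0
    h, w = img.shape
    span, bw = 180.0, 180.0 / n_bins
    cells_y, cells_x = h // cell_px, w // cell_px
    hist = np.zeros((cells_y, cells_x, n_bins))
    for r in range(h):
        for c in range(w):
            cp = min(c + 1, w - 1)
            cm = max(c - 1, 0)
            rp = min(r + 1, h - 1)
            rm = max(r - 1, 0)
            gx = img[r, cp] - img[r, cm]
            gy = img[rp, c] - img[rm, c]
            mag = np.hypot(gx, gy)
            ang = np.degrees(np.arctan2(gy, gx)) % span
            pos = ang / bw - 0.5
            lo = int(np.floor(pos))
            frac = pos - lo
            hist[r // cell_px, c // cell_px, lo % n_bins] += mag * (1 - frac)
            hist[r // cell_px, c // cell_px, (lo + 1) % n_bins] += mag * frac
    blocks = []
    for by in range(0, cells_y - block_cells + 1, stride):
        for bx in range(0, cells_x - block_cells + 1, stride):
            v = hist[by : by + block_cells, bx : bx + block_cells].ravel()
            blocks.append(v / max(np.linalg.norm(v), eps))
    return np.concatenate(blocks)


class TestGradients:
    def test_constant_image_has_zero_magnitude(self):
        mag, _ = gradients(np.full((8, 8), 40.0))
        np.testing.assert_array_equal(mag, 0.0)

    def test_horizontal_ramp(self):
        # I(x, y) = x: central difference 2, pointing along +x
        img = np.tile(np.arange(8.0), (8, 1))
        mag, ang = gradients(img)
        np.testing.assert_allclose(mag[1:-1, 1:-1], 2.0)
        np.testing.assert_allclose(ang[1:-1, 1:-1], 0.0)

    def test_transpose_swaps_gradient_roles(self, random_gray):
        mag, ang = gradients(random_gray)
        mag_t, _ = gradients(random_gray.T)
        np.testing.assert_allclose(mag_t, mag.T, atol=1e-12)


class TestCellHistograms:
    def test_zero_magnitude_gives_zero_histograms(self):
        cfg = HOGConfig(cell_px=4)
        h = cell_histograms(np.zeros((8, 8)), np.zeros((8, 8)), cfg)
        np.testing.assert_array_equal(h, 0.0)

    def test_vote_at_bin_center_goes_to_single_bin(self):
        cfg = HOGConfig(cell_px=4, n_bins=9)
        mag = np.zeros((4, 4))
        ang = np.zeros((4, 4))
        mag[1, 2] = 7.0
        ang[1, 2] = 30.0  # exactly the center of bin 1 (bins 20 deg wide)
        h = cell_histograms(mag, ang, cfg)[0, 0]
        expected = np.zeros(9)
        expected[1] = 7.0
        np.testing.assert_allclose(h, expected, atol=1e-12)

    def test_indivisible_shape_rejected(self):
        with pytest.raises(SizeError):
            cell_histograms(np.zeros((10, 10)), np.zeros((10, 10)), HOGConfig(cell_px=4))


class TestDescriptor:
    @pytest.mark.parametrize("cell,length", [(16, 8100), (32, 1764), (64, 324)])
    def test_length_on_256_input(self, rng, cell, length):
        img = rng.uniform(0, 255, (256, 256))
        assert len(hog_descriptor(img, HOGConfig(cell_px=cell))) == length

    def test_constant_image_gives_zero_vector(self):
        d = hog_descriptor(np.full((64, 64), 200.0), HOGConfig(cell_px=16))
        np.testing.assert_array_equal(d, 0.0)

    def test_matches_naive_per_pixel_oracle(self, rng):
        img = rng.uniform(0, 255, (48, 48))
        got = hog_descriptor(img, HOGConfig(cell_px=8))
        want = naive_hog(img, cell_px=8)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_oracle_equivalence_at_64(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        got = hog_descriptor(img, HOGConfig(cell_px=16))
        want = naive_hog(img, cell_px=16)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_block_norms_at_most_one(self, rng):
        img = rng.uniform(0, 255, (64, 64))
        cfg = HOGConfig(cell_px=16)
        d = hog_descriptor(img, cfg).reshape(-1, cfg.block_cells**2 * cfg.n_bins)
        norms = np.linalg.norm(d, axis=1)
        assert np.all(norms <= 1.0 + 1e-12)
        assert np.all((np.abs(norms - 1.0) < 1e-9) | (norms < 1e-9))

    def test_intensity_rescaling_invariance(self, rng):
        img = rng.uniform(10, 200, (64, 64))
        a = hog_descriptor(img, HOGConfig(cell_px=16))
        b = hog_descriptor(img * 1.2, HOGConfig(cell_px=16))
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_too_few_cells_for_block_rejected(self):
        with pytest.raises(SizeError):
            hog_descriptor(np.zeros((16, 16)), HOGConfig(cell_px=16))
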