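"""Circular uniform LBP: sampling geometry, codes, binning, descriptor."""

import numpy as np
import pytest

from beakfusion.errors import SizeError
from beakfusion.lbp import LBPConfig, lbp_code, lbp_descriptor, sample_positions, uniform_bin


def naive_bilinear(img, y, x):
    """Independent bilinear interpolation at (row=y, col=x)."""
    h, w = img.shape
    y0 = min(int(np.floor(y)), h - 2)
    x0 = min(int(np.floor(x)), w - 2)
    fy, fx = y - y0, x - x0
    return (
        img[y0, x0] * (1 - fy) * (1 - fx)
        + img[y0, x0 + 1] * (1 - fy) * fx
        + img[y0 + 1, x0] * fy * (1 - fx)
        + img[y0 + 1, x0 + 1] * fy * fx
    )


def naive_transitions(code, P):
    bits = [(code >> p) & 1 for p in range(P)]
    return sum(bits[p] != bits[(p + 1) % P] for p in range(P))


def naive_descriptor(img, R, P):
    """Literal per-pixel translation of the code/histogram definition."""
    h, w = img.shape
    m = int(np.ceil(R))
    # same bin-assignment rule: uniform codes in increasing code order
    table, nxt = {}, 0
    for code in range(2**P):
        if naive_transitions(code, P) <= 2:
            table[code] = nxt
            nxt += 1
    catch_all = nxt
    hist = np.zeros(P * (P - 1) + 3)
    for r in range(m, h - m):
        for c in range(m, w - m):
            ic = img[r, c]
            code = 0
            for p in range(P):
                theta = 2 * np.pi * p / P
                xs = c + R * np.cos(theta)
                ys = r - R * np.sin(theta)
                if naive_bilinear(img, ys, xs) - ic >= -1e-9:
                    code |= 1 << p
            hist[table.get(code, catch_all)] += 1
    return hist / hist.sum()


class TestSamplingGeometry:
    def test_first_point_lies_east_of_center(self):
        pts = sample_positions((10, 10), LBPConfig(R=1, P=8))
        assert pts[0] == pytest.approx((11, 10))

    def test_quarter_turn_point_lies_north(self):
        # y axis points down, so p = P/4 is one radius *up* from the center
        pts = sample_positions((10, 10), LBPConfig(R=1, P=8))
        assert pts[2] == pytest.approx((10, 9))

    def test_matches_direct_trigonometric_evaluation(self):
        cfg = LBPConfig(R=2, P=16)
        pts = sample_positions((10, 10), cfg)
        p = 3
        expected = (
            10 + 2 * np.cos(2 * np.pi * p / 16),
            10 - 2 * np.sin(2 * np.pi * p / 16),
        )
        assert pts[p] == pytest.approx(expected, abs=1e-12)


class TestCodes:
    def test_constant_image_gives_all_ones_code(self):
        img = np.full((7, 7), 9.0)
        assert lbp_code(img, (3, 3), LBPConfig(R=1, P=8)) == 255

    def test_dark_center_sees_every_neighbor_above(self):
        img = np.full((3, 3), 5.0)
        img[1, 1] = 4.0
        assert lbp_code(img, (1, 1), LBPConfig(R=1, P=8)) == 255

    def test_intensity_shift_invariance(self, random_gray):
        cfg = LBPConfig(R=1, P=8)
        shifted = np.clip(random_gray, 0, 200) + 50.0
        base = np.clip(random_gray, 0, 200)
        for center in [(5, 5), (10, 20), (16, 16)]:
            assert lbp_code(base, center, cfg) == lbp_code(shifted, center, cfg)


class TestUniformBinning:
    def test_flat_codes_get_distinct_dedicated_bins(self):
        assert uniform_bin(0, 8) != uniform_bin(255, 8)
        assert uniform_bin(255, 8) < 58  # both are uniform, not catch-all
        assert uniform_bin(0, 8) < 58

    def test_uniform_code_count_by_enumeration(self):
        # brute force: codes with <= 2 circular transitions
        uniform = [c for c in range(256) if naive_transitions(c, 8) <= 2]
        assert len(uniform) == 58
        assert LBPConfig(R=1, P=8).n_bins == 59
        bins = {uniform_bin(c, 8) for c in uniform}
        assert bins == set(range(58))
        non_uniform_bins = {uniform_bin(c, 8) for c in range(256) if c not in uniform}
        assert non_uniform_bins == {58}


class TestDescriptor:
    def test_length_59_on_512_image(self, rng):
        img = rng.uniform(0, 255, (512, 512))
        assert len(lbp_descriptor(img, LBPConfig(R=1, P=8, grid_n=1))) == 59

    def test_constant_image_concentrates_on_all_ones_bin(self):
        img = np.full((64, 64), 128.0)
        d = lbp_descriptor(img, LBPConfig(R=1, P=8))
        assert d[uniform_bin(255, 8)] == pytest.approx(1.0)
        assert d.sum() == pytest.approx(1.0)

    def test_matches_naive_double_loop_oracle(self, random_gray):
        got = lbp_descriptor(random_gray, LBPConfig(R=1, P=8))
        want = naive_descriptor(random_gray, R=1, P=8)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_oracle_equivalence_at_larger_radius(self, rng):
        img = rng.uniform(0, 255, (24, 24))
        got = lbp_descriptor(img, LBPConfig(R=2, P=12))
        want = naive_descriptor(img, R=2, P=12)
        np.testing.assert_allclose(got, want, atol=1e-9)

    @pytest.mark.parametrize("P,grid_n", [(4, 1), (8, 2), (10, 1), (16, 1), (8, 3)])
    def test_length_formula_across_configs(self, rng, P, grid_n):
        img = rng.uniform(0, 255, (48, 48))
        cfg = LBPConfig(R=1, P=P, grid_n=grid_n)
        d = lbp_descriptor(img, cfg)
        assert len(d) == grid_n**2 * (P * (P - 1) + 3)

    def test_cell_histograms_each_sum_to_one(self, rng):
        img = rng.uniform(0, 255, (60, 60))
        cfg = LBPConfig(R=1, P=8, grid_n=3)
        d = lbp_descriptor(img, cfg).reshape(9, 59)
        np.testing.assert_allclose(d.sum(axis=1), 1.0, atol=1e-9)

    def test_descriptor_shift_invariance(self, random_gray):
        img = np.clip(random_gray, 0, 200)
        a = lbp_descriptor(img, LBPConfig(R=1, P=8))
        b = lbp_descriptor(img + 30.0, LBPConfig(R=1, P=8))
        np.testing.assert_array_equal(a, b)

    def test_image_smaller_than_neighborhood_rejected(self):
        with pytest.raises(SizeError):
            lbp_descriptor(np.zeros((4, 4)), LBPConfig(R=2, P=8))
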