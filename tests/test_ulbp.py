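"""ULBP histogram oracle equivalence, curve behaviour, line fits and similarity."""

import numpy as np
import pytest

from her2feat import (
    LineFit,
    ULBPCurveSet,
    default_grid,
    generate_tile,
    linear_parameterize,
    pairwise_curve_similarity,
    reduce_ulbp,
    ulbp_curves,
    ulbp_histogram,
)

GRID = default_grid()


def brute_force_ulbp(values, roi):
    """Independent per-pixel enumeration of the ULBP histogram."""
    h, w = values.shape
    counts = np.zeros(10)
    n = 0
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            if not roi[y, x]:
                continue
            n += 1
            bits = [1 if values[y + dy, x + dx] >= values[y, x] else 0
                    for dy, dx in ring]
            transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
            if transitions <= 2:
                counts[sum(bits)] += 1
            else:
                counts[9] += 1
    if n == 0:
        return np.zeros(10), 0
    return counts / n, n


class TestHistogram:
    def test_constant_regions_fall_into_u8(self):
        """All-ones and all-zeros masks: every neighbour ties the centre."""
        roi = np.ones((8, 8), bool)
        for mask in (np.ones((8, 8)), np.zeros((8, 8))):
            hist = ulbp_histogram(mask, roi)
            assert hist.u[8] == pytest.approx(1.0)
            assert hist.u[:8].sum() == pytest.approx(0.0)
            assert hist.nonuniform == pytest.approx(0.0)

    def test_single_centre_pixel_pattern(self):
        """A lone stained pixel on a 5x5 zero mask, checked against the oracle.

        Under the tie rule (neighbour >= centre counts as 1) the stained
        centre sees eight losing neighbours (pattern 00000000, U0) while
        each zero-valued interior pixel ties or loses to none (all bits
        set, U8), so the histogram is U0 = 1/9, U8 = 8/9.
        """
        mask = np.zeros((5, 5))
        mask[2, 2] = 1.0
        roi = np.ones((5, 5), bool)
        hist = ulbp_histogram(mask, roi)
        expected, n = brute_force_ulbp(mask, roi)
        assert n == 9
        assert np.allclose(np.append(hist.u, hist.nonuniform), expected)
        assert hist.u[0] == pytest.approx(1 / 9)
        assert hist.u[8] == pytest.approx(8 / 9)

    def test_oracle_equivalence_on_random_masks(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            mask = (rng.uniform(size=(16, 16)) < rng.uniform(0.2, 0.8)).astype(float)
            roi = rng.uniform(size=(16, 16)) < 0.9
            hist = ulbp_histogram(mask, roi)
            expected, n = brute_force_ulbp(mask, roi)
            assert hist.n_evaluated == n
            assert np.allclose(np.append(hist.u, hist.nonuniform), expected)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        mask = (rng.uniform(size=(12, 12)) < 0.5).astype(float)
        roi = np.ones((12, 12), bool)
        base = ulbp_histogram(mask, roi)
        for k in (1, 2, 3):
            rot = ulbp_histogram(np.rot90(mask, k), roi)
            assert np.array_equal(rot.u, base.u)
            assert rot.nonuniform == base.nonuniform

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            mask = (rng.uniform(size=(10, 10)) < 0.5).astype(float)
            hist = ulbp_histogram(mask, np.ones((10, 10), bool))
            assert hist.u.sum() + hist.nonuniform == pytest.approx(1.0, abs=1e-9)

    def test_empty_roi_flagged(self):
        hist = ulbp_histogram(np.ones((6, 6)), np.zeros((6, 6), bool))
        assert hist.empty
        assert hist.n_evaluated == 0
        assert np.allclose(hist.u, 0.0)


class TestCurves:
    def test_full_curve_set_dimensions(self):
        tile, _ = generate_tile("2+", seed=0, size=96)
        cset = ulbp_curves(tile)
        assert cset.curves.shape == (8, 21)  # 168 values before reduction

    def test_curves_vanish_beyond_maximum_saturation(self):
        """Past the strongest staining the mask empties and U0..U7 -> 0."""
        for label in ("0", "1+"):  # sat_mean 0.20/0.25: nothing survives t=0.5
            tile, _ = generate_tile(label, seed=2, size=96)
            cset = ulbp_curves(tile)
            assert np.allclose(cset.curves[:, -1], 0.0, atol=1e-9)

    def test_texture_components_separate_staining_morphology(self):
        """Component curves discriminate staining morphology between classes.

        Under the mask substrate, U_m is the fraction of stained pixels
        with exactly m stained neighbours: fragmented 1+ staining carries
        more isolated-strand mass (U1) than a contiguous 3+ blob, whose
        smooth rim dominates the many-neighbour components (U4..U7).
        """
        for seed in (1, 2):
            weak = ulbp_curves(generate_tile("1+", seed=seed, size=128)[0]).curves
            strong = ulbp_curves(generate_tile("3+", seed=seed, size=128)[0]).curves
            assert weak[1].mean() > strong[1].mean()
            assert strong[4:8].mean() > weak[4:8].mean()


class TestLineFit:
    def test_constant_curve(self):
        fit = linear_parameterize(np.full(21, 0.4), GRID)
        assert fit.slope == pytest.approx(0.0, abs=1e-9)
        assert fit.intercept == pytest.approx(0.4)

    def test_exact_line_recovered(self):
        fit = linear_parameterize(2 * GRID + 1, GRID)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)

    def test_three_point_ols_closed_form(self):
        t = np.array([0.1, 0.3, 0.5])
        v = np.array([0.30, 0.20, 0.10])
        fit = linear_parameterize(v, t)
        assert fit.slope == pytest.approx(-0.5)
        assert fit.intercept == pytest.approx(0.35)


def _curveset(curves, tile_id="t"):
    return ULBPCurveSet(t=GRID, curves=np.asarray(curves, dtype=float),
                        tile_id=tile_id)


class TestSimilarity:
    def _random_sets(self, n, rng):
        return [_curveset(np.clip(rng.uniform(0, 1, (8, 21)), 0, 1))
                for _ in range(n)]

    def test_identical_curves_reported_redundant(self):
        rng = np.random.default_rng(0)
        sets = []
        for _ in range(10):
            c = np.clip(rng.uniform(0, 1, (8, 21)), 0, 1)
            c[6] = c[2]  # U2 == U6 in every sample
            sets.append(_curveset(c))
        matrix, redundant = pairwise_curve_similarity(sets)
        assert matrix[2, 6] == pytest.approx(1.0)
        assert (2, 6) in redundant

    def test_independent_curves_not_reported(self):
        rng = np.random.default_rng(1)
        matrix, redundant = pairwise_curve_similarity(self._random_sets(500, rng))
        off = matrix[~np.eye(8, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.5
        assert redundant == []

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(2)
        matrix, _ = pairwise_curve_similarity(self._random_sets(20, rng))
        assert np.allclose(matrix, matrix.T, equal_nan=True)
        assert np.allclose(np.diag(matrix), 1.0)

    def test_all_constant_pair_is_nan_not_zero(self):
        sets = [_curveset(np.vstack([np.full((2, 21), 0.3),
                                     np.random.default_rng(3).uniform(0, 1, (6, 21))]))
                for _ in range(5)]
        matrix, _ = pairwise_curve_similarity(sets)
        assert np.isnan(matrix[0, 1])


class TestReduce:
    def test_zero_set_reduces_to_25_zeros(self):
        out = reduce_ulbp(_curveset(np.zeros((8, 21))))
        assert out.shape == (25,)
        assert np.allclose(out, 0.0)

    def test_curve_major_order(self):
        c = np.zeros((8, 21))
        c[0] = 1.0  # U0 constant one
        out = reduce_ulbp(_curveset(c))
        assert np.allclose(out[:5], 1.0)
        assert np.allclose(out[5:], 0.0)

    def test_selected_points_are_every_fifth_threshold(self):
        c = np.tile(np.arange(21) / 21.0, (8, 1))
        out = reduce_ulbp(_curveset(c))
        assert np.allclose(out[:5], np.array([0, 5, 10, 15, 20]) / 21.0)
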