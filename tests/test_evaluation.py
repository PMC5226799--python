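import numpy as np
import pytest

import stainwave as sw
from stainwave.estimation import DensityMaps, StainMatrix
from stainwave.evaluation import (
    AnnotatedPixelSet,
    bland_altman,
    density_correlation,
    ground_truth_stain_matrix,
    stain_vector_angle,
    stain_vector_distance,
)
from stainwave.od_io import OdImage


def _od_from_pixels(vals, shape=(2, 3)):
    """Build an OdImage whose columns are the given per-pixel OD triples."""
    return OdImage(d=np.array(vals, dtype=float).T, shape=shape)


class TestGroundTruthStainMatrix:
    def test_median_of_three_pixels(self):
        od = _od_from_pixels(
            [[0.2, 0.5, 0.5], [0.5, 0.5, 0.5], [0.9, 0.5, 0.5]]
            + [[0.1, 0.9, 0.1]] * 3
        )
        annots = AnnotatedPixelSet(
            coords={
                "haematoxylin": [(0, 0), (0, 1), (0, 2)],
                "eosin": [(1, 0), (1, 1), (1, 2)],
            }
        )
        m = ground_truth_stain_matrix(od, annots)
        expected = np.array([0.5, 0.5, 0.5])
        assert np.allclose(m.vector("haematoxylin"), expected / np.linalg.norm(expected))

    def test_even_count_uses_mean_of_middle_two(self):
        # median convention checked against an independent sort-based oracle
        reds = [0.2, 0.4]
        od = _od_from_pixels([[r, 0.5, 0.5] for r in reds] + [[0.1, 0.9, 0.1]] * 4)
        annots = AnnotatedPixelSet(
            coords={"haematoxylin": [(0, 0), (0, 1)], "eosin": [(1, 0), (1, 1)]}
        )
        m = ground_truth_stain_matrix(od, annots)
        srt = sorted(reds)
        oracle = np.array([(srt[0] + srt[1]) / 2, 0.5, 0.5])
        assert np.allclose(m.vector("haematoxylin"), oracle / np.linalg.norm(oracle))

    def test_single_pixel_gives_its_direction(self):
        od = _od_from_pixels([[0.3, 0.6, 0.2]] + [[0.1, 0.9, 0.1]] * 5)
        annots = AnnotatedPixelSet(
            coords={"haematoxylin": [(0, 0)], "eosin": [(1, 0)]}
        )
        m = ground_truth_stain_matrix(od, annots)
        v = np.array([0.3, 0.6, 0.2])
        assert np.allclose(m.vector("haematoxylin"), v / np.linalg.norm(v))

    def test_residual_is_canonical_cross_product(self):
        od = _od_from_pixels([[0.65, 0.70, 0.29]] * 3 + [[0.07, 0.99, 0.11]] * 3)
        annots = AnnotatedPixelSet(
            coords={"haematoxylin": [(0, 0)], "eosin": [(1, 0)]}
        )
        m = ground_truth_stain_matrix(od, annots)
        r = m.vector("residual")
        assert np.isclose(np.linalg.norm(r), 1.0)
        assert np.all(r >= 0)

    def test_empty_stain_set_names_the_stain(self):
        od = _od_from_pixels([[0.5, 0.5, 0.5]] * 6)
        annots = AnnotatedPixelSet(coords={"haematoxylin": [(0, 0)]})
        with pytest.raises(ValueError, match="eosin"):
            ground_truth_stain_matrix(od, annots)

    def test_out_of_bounds_annotation(self):
        od = _od_from_pixels([[0.5, 0.5, 0.5]] * 6)
        annots = AnnotatedPixelSet(
            coords={"haematoxylin": [(9, 9)], "eosin": [(1, 0)]}
        )
        with pytest.raises(ValueError, match="out of bounds"):
            ground_truth_stain_matrix(od, annots)

    def test_csv_round_trip(self, tmp_path):
        annots = AnnotatedPixelSet(
            coords={"haematoxylin": [(1, 2), (3, 4)], "eosin": [(5, 6)]}
        )
        annots.to_csv(tmp_path / "a.csv", tile="t1")
        back = AnnotatedPixelSet.from_csv(tmp_path / "a.csv", tile="t1")
        assert back.coords == annots.coords


def _matrix_with_h(v):
    v = np.asarray(v, float)
    v = v / np.linalg.norm(v)
    e = np.array([0.0, 1.0, 0.0])
    r = np.cross(v, e)
    r = np.abs(r) / np.linalg.norm(r)
    return StainMatrix(m=np.column_stack([v, e, r]))


class TestStainVectorDistance:
    def test_identical_vectors(self):
        m = sw.synthetic.default_stain_matrix()
        d = stain_vector_distance(m, m)
        assert all(v == 0.0 for v in d.values())

    def test_orthogonal_unit_vectors(self):
        m1 = _matrix_with_h([1, 0, 0])
        m2 = _matrix_with_h([0, 0, 1])
        assert np.isclose(stain_vector_distance(m1, m2)["haematoxylin"], np.sqrt(2))

    def test_sixty_degree_chord_is_one(self):
        m1 = _matrix_with_h([1, 0, 0])
        m2 = _matrix_with_h([np.cos(np.pi / 3), 0, np.sin(np.pi / 3)])
        assert np.isclose(stain_vector_distance(m1, m2)["haematoxylin"], 1.0)
        assert np.isclose(stain_vector_angle(m1, m2)["haematoxylin"], 60.0)

    def test_symmetric_nonneg_bounded(self, rng):
        for _ in range(10):
            m1 = _matrix_with_h(np.abs(rng.normal(size=3)) + 1e-3)
            m2 = _matrix_with_h(np.abs(rng.normal(size=3)) + 1e-3)
            d12 = stain_vector_distance(m1, m2)["haematoxylin"]
            d21 = stain_vector_distance(m2, m1)["haematoxylin"]
            assert d12 == d21 and 0.0 <= d12 <= 2.0


class TestDensityCorrelation:
    def test_perfect_and_inverted(self, rng):
        n = DensityMaps(n=np.abs(rng.normal(size=(3, 100))), shape=(10, 10))
        same = density_correlation(n, n)
        assert all(np.isclose(r, 1.0) for r, _ in same.values())
        flipped = DensityMaps(n=-n.n + 2.0, shape=(10, 10))
        inv = density_correlation(flipped, n)
        assert all(np.isclose(r, -1.0) for r, _ in inv.values())

    def test_affine_invariance(self, rng):
        n = DensityMaps(n=np.abs(rng.normal(size=(3, 200))), shape=(10, 20))
        scaled = DensityMaps(n=3.5 * n.n + 1.2, shape=(10, 20))
        r = density_correlation(scaled, n)
        assert all(np.isclose(v, 1.0) for v, _ in r.values())

    def test_noise_attenuation_matches_closed_form(self):
        # analytic oracle: corr(x, x + e) = s / sqrt(s^2 + sigma^2)
        rng = np.random.default_rng(11)
        s, sigma, p = 1.0, 0.5, 200_000
        x = rng.normal(0, s, size=(3, p))
        noisy = x + rng.normal(0, sigma, size=(3, p))
        shape = (400, 500)
        r = density_correlation(
            DensityMaps(n=noisy, shape=shape), DensityMaps(n=x, shape=shape)
        )
        expected = s / np.sqrt(s**2 + sigma**2)
        for val, _ in r.values():
            assert abs(val - expected) < 0.01

    def test_zero_variance_reported_as_nan(self, rng):
        n = DensityMaps(n=np.abs(rng.normal(size=(3, 100))), shape=(10, 10))
        flat = DensityMaps(n=np.zeros((3, 100)), shape=(10, 10))
        r = density_correlation(flat, n)
        assert all(np.isnan(v) for v, _ in r.values())


class TestBlandAltman:
    def test_identical_maps(self, rng):
        n = DensityMaps(n=np.abs(rng.normal(size=(3, 100))), shape=(10, 10))
        out = bland_altman(n, n)
        for ba in out.values():
            assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self, rng):
        n = DensityMaps(n=np.abs(rng.normal(size=(3, 100))), shape=(10, 10))
        shifted = DensityMaps(n=n.n + 0.7, shape=(10, 10))
        out = bland_altman(shifted, n)
        for ba in out.values():
            assert np.isclose(ba.bias, 0.7)
            assert np.isclose(ba.loa_low, 0.7) and np.isclose(ba.loa_high, 0.7)

    def test_standard_normal_limits(self):
        rng = np.random.default_rng(5)
        diffs = rng.standard_normal(10**5)
        ba = bland_altman(diffs, np.zeros_like(diffs), subsample=None)
        assert abs(ba.loa_high - 1.96) < 0.02
        assert abs(ba.loa_low + 1.96) < 0.02
        # ~95% of differences inside the limits
        inside = np.mean((diffs > ba.loa_low) & (diffs < ba.loa_high))
        assert abs(inside - 0.95) < 0.005

    def test_limits_bracket_bias(self, rng):
        a = rng.normal(size=1000)
        b = rng.normal(size=1000)
        ba = bland_altman(a, b)
        assert ba.loa_low <= ba.bias <= ba.loa_high

    def test_subsample_is_seeded(self, rng):
        a = rng.normal(size=50_000)
        b = rng.normal(size=50_000)
        ba1 = bland_altman(a, b, subsample=5000, seed=9)
        ba2 = bland_altman(a, b, subsample=5000, seed=9)
        assert np.array_equal(ba1.differences, ba2.differences)
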