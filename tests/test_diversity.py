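import io

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from gmeb.datasets import OtuTable, ValidationError
from gmeb.diversity import (
    alpha_diversity,
    beta_dissimilarity,
    distance_decay,
    faith_pd,
    geographic_distance,
    latitude_gradient_fit,
    shannon,
)

from conftest import make_metadata


def brute_shannon(counts):
    total = sum(counts)
    return -sum((c / total) * np.log(c / total) for c in counts if c > 0)


def brute_bray_curtis(x, y):
    return 1 - 2 * sum(min(a, b) for a, b in zip(x, y)) / (sum(x) + sum(y))


class TestAlpha:
    def test_uniform_counts(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(np.log(4), abs=1e-12)

    def test_hand_value(self):
        assert shannon([5, 3, 2]) == pytest.approx(1.0297, abs=5e-5)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(0, 50, size=12)
            counts[rng.integers(12)] += 1  # never empty
            assert shannon(counts) == pytest.approx(brute_shannon(counts), abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestFaithPD:
    tree = "((A:1,B:1):1,(C:2,D:2):3):0.0;"

    def _tree(self):
        return TreeNode.read(io.StringIO(self.tree))

    def test_root_path_included(self):
        t = TreeNode.read(io.StringIO("((A:1,B:1):1):0.0;"))
        assert faith_pd([1, 1], ["A", "B"], t) == pytest.approx(3.0)

    def test_monotone_in_added_taxa(self):
        t = self._tree()
        otus = ["A", "B", "C", "D"]
        pd_vals = [faith_pd([1] * k + [0] * (4 - k), otus, t) for k in range(1, 5)]
        assert all(b >= a for a, b in zip(pd_vals, pd_vals[1:]))

    def test_missing_tip_named(self):
        with pytest.raises(ValidationError, match="Z"):
            faith_pd([1, 1], ["A", "Z"], self._tree())


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        t = OtuTable([[3, 1, 0], [3, 1, 0], [0, 0, 9]],
                     ["a", "b", "c"], ["x", "y", "z"])
        dm = beta_dissimilarity(t)
        assert dm["a", "b"] == pytest.approx(0.0)
        assert dm["a", "c"] == pytest.approx(1.0)

    def test_hand_value(self):
        t = OtuTable([[2, 0, 1], [1, 1, 0]], ["a", "b"], ["x", "y", "z"])
        assert beta_dissimilarity(t)["a", "b"] == pytest.approx(0.6, abs=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x, y = rng.integers(0, 30, 10) + 1, rng.integers(0, 30, 10)
            t = OtuTable(np.vstack([x, y]), ["a", "b"], [f"o{i}" for i in range(10)])
            assert t.data.sum(axis=1).min() > 0 or True
            dm = beta_dissimilarity(t)
            assert dm["a", "b"] == pytest.approx(brute_bray_curtis(x, y), abs=1e-12)


class TestGeographicDistance:
    def test_same_point_and_antipode(self):
        meta = make_metadata(["p", "q", "r"], latitude=[0.0, 0.0, 0.0],
                             longitude=[10.0, 10.0, -170.0])
        dm = geographic_distance(meta)
        assert dm["p", "q"] == 0.0
        assert dm["p", "r"] == pytest.approx(np.pi * 6371.0, rel=1e-4)

    def test_symmetry_random_fixture(self):
        rng = np.random.default_rng(2)
        n = 15
        meta = make_metadata([f"s{i}" for i in range(n)],
                             latitude=rng.uniform(-60, 60, n),
                             longitude=rng.uniform(-170, 170, n))
        dm = geographic_distance(meta)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)


def _exact_line_matrices(n=20, slope=-0.2, intercept=1.0, seed=3):
    """Distances + dissimilarities lying exactly on ln S = slope*ln d + intercept."""
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n)]
    d = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    d[iu] = rng.uniform(10, 5000, size=len(iu[0]))
    d = d + d.T
    sim = np.exp(intercept + slope * np.log(np.where(d > 0, d, 1.0)))
    sim = np.minimum(sim, 1.0)
    dis = 1 - sim
    np.fill_diagonal(dis, 0)
    return DistanceMatrix(d, ids), DistanceMatrix(dis, ids)


class TestDistanceDecay:
    def test_exact_line_recovers_slope(self):
        geo, dis = _exact_line_matrices(slope=-0.2, intercept=-1.0)
        res = distance_decay(geo, dis, mantel_permutations=99, seed=0)
        assert res.fit.slope == pytest.approx(-0.2, abs=1e-9)

    def test_slope_invariant_to_distance_rescaling(self):
        geo, dis = _exact_line_matrices(slope=-0.15, intercept=-1.0)
        geo_m = DistanceMatrix(geo.data * 1000.0, geo.ids)  # km -> m
        a = distance_decay(geo, dis, mantel_permutations=49, seed=0)
        b = distance_decay(geo_m, dis, mantel_permutations=49, seed=0)
        assert a.fit.slope == pytest.approx(b.fit.slope, abs=1e-9)

    def test_identical_matrices_give_mantel_r_one(self):
        geo, _ = _exact_line_matrices()
        res = distance_decay(geo, DistanceMatrix(geo.data / geo.data.max(), geo.ids),
                             mantel_permutations=99, seed=1)
        assert res.mantel.r == pytest.approx(1.0)
        assert res.mantel.p_value < 0.05

    def test_mantel_null_calibration(self):
        """Independent random matrices should rarely reach p < 0.05."""
        rng = np.random.default_rng(8)
        n = 30
        rejections = 0
        reps = 100
        for k in range(reps):
            a, b = np.zeros((n, n)), np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            a[iu], b[iu] = rng.random(len(iu[0])), rng.random(len(iu[0]))
            a, b = a + a.T, b + b.T
            dis = 1 - (1 - b) * 0.5
            np.fill_diagonal(dis, 0)
            da = DistanceMatrix(a, [str(i) for i in range(n)])
            res = distance_decay(da, DistanceMatrix(dis, da.ids),
                                 mantel_permutations=199, seed=k)
            rejections += res.mantel.p_value < 0.05
        assert rejections <= 5  # >= 95% of replicates stay non-significant

    def test_too_few_pairs_errors(self):
        ids = ["a", "b"]
        geo = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids)
        dis = DistanceMatrix(np.array([[0, 0.5], [0.5, 0]]), ids)
        with pytest.raises(ValidationError):
            distance_decay(geo, dis, mantel_permutations=9, seed=0)


class TestLatitudeGradient:
    def test_exact_parabola_peak(self):
        lat = np.linspace(20, 60, 30)
        y = -0.02 * (lat - 40) ** 2 + 3.0
        fit = latitude_gradient_fit(lat, y)
        assert fit.quadratic.peak == pytest.approx(40.0, abs=1e-8)

    def test_linear_data_has_no_curvature(self):
        lat = np.linspace(20, 60, 30)
        fit = latitude_gradient_fit(lat, 0.05 * lat + 1.0)
        assert abs(fit.quadratic.quadratic_coefficient) < 1e-8
        assert fit.linear.pearson_r == pytest.approx(1.0)

    def test_noisy_unimodal_recovery(self):
        rng = np.random.default_rng(12)
        lat = rng.uniform(20, 60, 300)
        y = -0.005 * (lat - 40) ** 2 + 3.0 + rng.normal(0, 0.2, 300)
        fit = latitude_gradient_fit(lat, y)
        assert fit.quadratic.peak == pytest.approx(40.0, abs=2.0)

    def test_constant_latitude_errors(self):
        with pytest.raises(ValidationError):
            latitude_gradient_fit([30] * 10, np.arange(10))


def test_alpha_diversity_series_has_sample_index(tiny_dataset):
    h = alpha_diversity(tiny_dataset.table)
    assert list(h.index) == ["s1", "s2", "s3"]
    pd_vals = alpha_diversity(tiny_dataset.table, "faith_pd", tree=tiny_dataset.tree)
    assert (pd_vals > 0).all()
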