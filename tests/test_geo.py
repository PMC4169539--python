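import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import procrustes as scipy_procrustes

from eurostruct.geo import (
    PopCentroids,
    best_alignment_angle,
    geo_distance_matrix,
    haversine_km,
    mantel_test,
    population_centroids,
    procrustes_test,
    spearman_axis,
)
from eurostruct.io import GeoPanel
from eurostruct.pca import PCAResult


def make_pca_result(scores):
    scores = np.asarray(scores, float)
    n, k = scores.shape
    return PCAResult(
        scores=scores,
        eigenvalues=np.ones(k),
        variance_fraction=np.full(k, 1.0 / k),
        loadings=np.zeros((1, k)),
        eigenvalues_all=np.ones(k),
        n_samples=n,
        n_snps=1,
    )


def centroids_from(pc, geo_xy, pops=None):
    pc = np.atleast_2d(np.asarray(pc, float).T).T
    pops = pops or [f"P{i}" for i in range(pc.shape[0])]
    return PopCentroids(pops, pc, np.asarray(geo_xy, float))


GEO4 = GeoPanel.from_dict({"A": (40, 0), "B": (45, 5), "C": (50, 10), "D": (55, 15)})


class TestCentroids:
    def test_mean_of_identical_samples_is_the_sample(self):
        res = make_pca_result([[1.5, -2.0]] * 4)
        c = population_centroids(res, ["X"] * 4, GeoPanel.from_dict({"X": (50, 5)}), m=2)
        assert np.allclose(c.pc_coords, [[1.5, -2.0]])

    def test_symmetric_pair_averages_to_zero(self):
        res = make_pca_result([[1.0, 0.0], [-1.0, 0.0]])
        c = population_centroids(res, ["X", "X"], GeoPanel.from_dict({"X": (50, 5)}), m=1)
        assert c.pc_coords[0, 0] == pytest.approx(0.0)

    def test_equirectangular_degree_of_longitude_at_equator(self):
        geo = GeoPanel.from_dict({"A": (0.0, 0.0), "B": (0.0, 1.0)})
        res = make_pca_result([[0.0], [1.0]])
        c = population_centroids(res, ["A", "B"], geo, m=1)
        dx = c.geo_xy[1, 0] - c.geo_xy[0, 0]
        assert dx == pytest.approx(6371.0 * math.pi / 180.0, abs=0.01)  # 111.19 km

    def test_population_without_coordinates_dropped_with_warning(self):
        res = make_pca_result([[0.0], [1.0], [2.0]])
        with pytest.warns(UserWarning):
            c = population_centroids(
                res, ["A", "B", "USA"], GeoPanel.from_dict({"A": (40, 0), "B": (50, 5)}), m=1
            )
        assert c.populations == ["A", "B"]

    def test_no_overlap_raises(self):
        res = make_pca_result([[0.0]])
        with pytest.raises(ValueError):
            population_centroids(res, ["Z"], GeoPanel.from_dict({"A": (40, 0)}), m=1)


class TestSpearmanAxis:
    def _centroids(self, pc):
        xy = np.array([[0, 0], [100, 200], [200, 400], [300, 600], [400, 800]], float)
        return centroids_from(np.array(pc, float).reshape(-1, 1), xy)

    def test_monotone_gives_rho_one(self):
        c = self._centroids([0.1, 0.5, 0.7, 1.2, 3.0])
        rho, _ = spearman_axis(c, 0, "latitude")
        assert rho == pytest.approx(1.0)

    def test_matches_exact_enumeration_at_n4(self):
        """scipy's small-n Spearman p equals brute-force over all 4! rankings."""
        pc = np.array([0.3, 0.1, 0.9, 0.5])
        lat = np.array([1.0, 2.0, 3.0, 4.0])
        c = centroids_from(pc.reshape(-1, 1), np.column_stack([np.zeros(4), lat]))
        rho, p = spearman_axis(c, 0, "latitude")
        obs = abs(stats.spearmanr(pc, lat)[0])
        count = sum(
            abs(stats.spearmanr(perm, lat)[0]) >= obs - 1e-12
            for perm in itertools.permutations(pc)
        )
        assert p == pytest.approx(count / math.factorial(4))

    def test_constant_pc_rejected(self):
        c = self._centroids([1.0] * 5)
        with pytest.raises(ValueError):
            spearman_axis(c, 0, "latitude")

    def test_too_few_populations_rejected(self):
        c = centroids_from(np.array([[0.0], [1.0]]), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            spearman_axis(c, 0, "latitude")


class TestBestAlignmentAngle:
    def _grid_centroids(self, values):
        rng = np.random.default_rng(0)
        xy = np.column_stack([rng.uniform(-500, 500, len(values)), rng.uniform(-800, 800, len(values))])
        return centroids_from(np.asarray(values).reshape(-1, 1), xy), xy

    def test_pure_latitude_gradient_gives_zero_bearing(self):
        c, xy = self._grid_centroids(np.zeros(8))
        c.pc_coords[:, 0] = xy[:, 1]  # PC equals northing
        angle, rho = best_alignment_angle(c, 0)
        assert angle == pytest.approx(0.0)
        assert rho == pytest.approx(1.0)

    def test_pure_longitude_gradient_resolved_near_the_grid_boundary(self):
        """An east-west PC reaches |rho| = 1 near +/-90 deg; rank correlation
        plateaus at 1 over nearby bearings, and ties resolve toward the
        smallest |angle| on the plateau."""
        c, xy = self._grid_centroids(np.zeros(8))
        c.pc_coords[:, 0] = xy[:, 0]  # PC equals easting
        angle, rho = best_alignment_angle(c, 0)
        assert abs(angle) > 60.0
        assert abs(rho) == pytest.approx(1.0)

    def test_planted_bearing_recovered(self):
        theta = math.radians(-35.0)
        c, xy = self._grid_centroids(np.zeros(10))
        c.pc_coords[:, 0] = xy[:, 1] * math.cos(theta) + xy[:, 0] * math.sin(theta)
        angle, rho = best_alignment_angle(c, 0)
        assert angle == pytest.approx(-35.0, abs=0.5)


class TestMantel:
    def _dist(self, pts):
        pts = np.asarray(pts, float)
        return np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)

    def test_self_comparison(self):
        d = self._dist(np.random.default_rng(1).standard_normal((6, 2)))
        r, p = mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(2)
        d1 = self._dist(rng.standard_normal((4, 2)))
        d2 = self._dist(rng.standard_normal((4, 2)))
        r_obs, p = mantel_test(d1, d2, exact=True)
        iu = np.triu_indices(4, 1)
        count = 0
        for perm in itertools.permutations(range(4)):
            pm = np.asarray(perm)
            r = stats.pearsonr(d1[iu], d2[np.ix_(pm, pm)][iu])[0]
            count += r >= r_obs - 1e-12
        assert p == pytest.approx(count / 24)

    def test_constant_matrix_rejected(self):
        d1 = self._dist(np.random.default_rng(3).standard_normal((5, 2)))
        d2 = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError):
            mantel_test(d1, d2)

    def test_asymmetric_rejected(self):
        d = self._dist(np.random.default_rng(4).standard_normal((4, 2)))
        bad = d.copy()
        bad[0, 1] += 1.0
        with pytest.raises(ValueError):
            mantel_test(d, bad)

    def test_invariant_to_joint_relabeling(self):
        rng = np.random.default_rng(5)
        d1 = self._dist(rng.standard_normal((7, 2)))
        d2 = self._dist(rng.standard_normal((7, 2)))
        perm = rng.permutation(7)
        r1, p1 = mantel_test(d1, d2, n_perm=199, seed=9)
        r2, p2 = mantel_test(d1[np.ix_(perm, perm)], d2[np.ix_(perm, perm)], n_perm=199, seed=9)
        assert r1 == pytest.approx(r2)


class TestProcrustes:
    def test_congruent_configurations(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((8, 2))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        y = 3.0 * x @ rot.T + np.array([10.0, -5.0])
        t, p = procrustes_test(x, y, n_perm=99, seed=0)
        assert t == pytest.approx(1.0, abs=1e-10)
        assert p == pytest.approx(1 / 100)

    def test_reflection_flag(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((6, 2))
        y = x.copy()
        y[:, 0] *= -1  # mirror image
        t_rot, _ = procrustes_test(x, y, n_perm=9, seed=0, allow_reflection=False)
        t_ref, _ = procrustes_test(x, y, n_perm=9, seed=0, allow_reflection=True)
        assert t_ref == pytest.approx(1.0, abs=1e-10)
        assert t_rot < 1.0 - 1e-6

    def test_matches_scipy_disparity_when_reflections_allowed(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((9, 2))
        y = rng.standard_normal((9, 2))
        t, _ = procrustes_test(x, y, n_perm=9, seed=0, allow_reflection=True)
        _, _, disparity = scipy_procrustes(x, y)
        assert t == pytest.approx(math.sqrt(1.0 - disparity), abs=1e-8)

    def test_exact_enumeration_matches_brute_force(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((4, 2))
        y = rng.standard_normal((4, 2))
        t_obs, p = procrustes_test(x, y, exact=True)
        xc = x - x.mean(0)
        xc /= np.linalg.norm(xc)
        yc = y - y.mean(0)
        yc /= np.linalg.norm(yc)

        def t_of(perm):
            m = yc[list(perm)].T @ xc
            u, s, vt = np.linalg.svd(m)
            if np.linalg.det(u @ vt) < 0:
                s = s.copy()
                s[-1] *= -1
            return s.sum()

        count = sum(t_of(perm) >= t_obs - 1e-12 for perm in itertools.permutations(range(4)))
        assert p == pytest.approx(count / 24)

    def test_invariance_to_similarity_transform(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((7, 2))
        y = rng.standard_normal((7, 2))
        theta = -1.2
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        t1, _ = procrustes_test(x, y, n_perm=9, seed=1)
        t2, _ = procrustes_test(0.1 * x @ rot.T + 7.0, y, n_perm=9, seed=1)
        assert t1 == pytest.approx(t2, abs=1e-10)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            procrustes_test(np.ones((4, 2)), np.random.default_rng(0).standard_normal((4, 2)))


class TestDistances:
    def test_haversine_antipodal(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(math.pi * 6371.0, abs=0.1)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        d = geo_distance_matrix(GEO4)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert d[0, 3] > d[0, 1] > 0
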