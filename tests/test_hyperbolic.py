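"""Information distance, MDS/HMDS, and geodesic readouts."""

import math

import numpy as np
import pytest

import chromage as c
from chromage import hyperbolic as hy


def _random_hyperboloid_cloud(rng, n, dim, scale=0.8):
    return hy.lift(rng.standard_normal((n, dim)) * scale)


def _pairwise(points, kappa=1.0):
    n = len(points)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = hy.lorentz_distance(points[i], points, kappa)
    np.fill_diagonal(d, 0.0)
    return d


class TestInformationDistance:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        assert c.information_distance(x, x.copy()) == 0.0

    def test_hand_computed_two_bin_case(self):
        """x alternates between two bins, y constant: H(X)=1 bit, H(Y)=0,
        H(X,Y)=1 bit, so D = (2-1-0)/1 = 1."""
        x = np.tile([0.05, 0.95], 50)
        y = np.full(100, 0.05)
        cfg = c.InfoDistanceConfig(normalization="given")
        assert c.information_distance(x, y, cfg) == pytest.approx(1.0)

    def test_base_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(300), rng.random(300)
        d2 = c.information_distance(x, y, c.InfoDistanceConfig(base=2))
        de = c.information_distance(x, y, c.InfoDistanceConfig(base=math.e))
        d10 = c.information_distance(x, y, c.InfoDistanceConfig(base=10))
        assert d2 == pytest.approx(de, abs=1e-12)
        assert d2 == pytest.approx(d10, abs=1e-12)

    def test_independence_limit(self):
        """Independent uniform samples approach D = 1 as length grows."""
        rng = np.random.default_rng(2)
        big = c.information_distance(rng.random(20000), rng.random(20000))
        assert big > 0.9

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = rng.random(100), rng.random(100)
            d = c.information_distance(x, y)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(c.information_distance(y, x))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            c.information_distance(np.zeros(3), np.zeros(4))

    def test_matrix_properties(self):
        rng = np.random.default_rng(4)
        rows = rng.random((5, 80))
        rows[3] = rows[0]           # duplicated row
        d = c.distance_matrix(rows, "information")
        np.testing.assert_allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert d[0, 3] == 0.0

    def test_euclidean_matrix_triangle(self):
        rng = np.random.default_rng(5)
        d = c.distance_matrix(rng.standard_normal((6, 4)), "euclidean")
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestEMDS:
    def test_planar_points_exact(self):
        rng = np.random.default_rng(6)
        pts = rng.standard_normal((10, 2))
        d = c.distance_matrix(pts, "euclidean")
        _, stress = c.emds(d, 2)
        assert stress < 1e-9

    def test_tree_metric_not_flat(self):
        # star tree: 4 leaves at distance 2 via the center; not planar-embeddable
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        _, stress = c.emds(d, 2)
        assert stress > 1e-3

    def test_stress_monotone_in_dim(self):
        rng = np.random.default_rng(7)
        d = c.distance_matrix(rng.standard_normal((12, 6)), "euclidean")
        stresses = [c.emds(d, k)[1] for k in range(1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(stresses, stresses[1:]))

    def test_nonfinite_raises(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError):
            c.emds(d, 2)


class TestShepherd:
    def test_identical_matrices(self):
        rng = np.random.default_rng(8)
        d = c.distance_matrix(rng.standard_normal((6, 3)), "euclidean")
        assert c.shepherd_r2(d, d) == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        rng = np.random.default_rng(9)
        a = c.distance_matrix(rng.standard_normal((30, 3)), "euclidean")
        b = c.distance_matrix(rng.standard_normal((30, 3)), "euclidean")
        assert c.shepherd_r2(a, b) < 0.1

    def test_hand_computed_4x4(self):
        target = np.zeros((4, 4))
        achieved = np.zeros((4, 4))
        tv = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        av = [1.1, 1.9, 3.2, 3.8, 5.1, 6.0]
        iu = np.triu_indices(4, 1)
        target[iu] = tv
        achieved[iu] = av
        target += target.T
        achieved += achieved.T
        r = np.corrcoef(tv, av)[0, 1]
        assert c.shepherd_r2(target, achieved) == pytest.approx(r**2)

    def test_constant_distances_raise(self):
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0)
        with pytest.raises(ValueError):
            c.shepherd_r2(d, np.zeros((3, 3)))


class TestHMDS:
    def test_two_points_exact(self):
        d = np.array([[0.0, 1.3], [1.3, 0.0]])
        emb = c.hmds(d, c.HyperbolicSpace(2, 1.0), seed=0)
        assert emb.stress < 1e-6
        assert abs(emb.achieved[0, 1] - 1.3) < 1e-6

    def test_recovery_from_known_hyperboloid_points(self):
        rng = np.random.default_rng(10)
        pts = _random_hyperboloid_cloud(rng, 15, 3)
        d = _pairwise(pts)
        emb = c.hmds(d, c.HyperbolicSpace(3, 1.0), seed=1)
        assert emb.shepherd_r2 > 0.99
        np.testing.assert_allclose(emb.achieved, d, atol=1e-3)

    def test_kappa_scaling_consistency(self):
        """Distances from a kappa=4 space embed exactly when kappa=4 is given."""
        rng = np.random.default_rng(11)
        pts = _random_hyperboloid_cloud(rng, 8, 2, scale=0.5)
        d = _pairwise(pts, kappa=4.0)
        emb = c.hmds(d, c.HyperbolicSpace(2, 4.0), seed=2)
        assert emb.stress < 1e-5

    def test_hyperboloid_constraint_held(self):
        rng = np.random.default_rng(12)
        d = c.distance_matrix(rng.standard_normal((8, 4)), "euclidean")
        emb = c.hmds(d, c.HyperbolicSpace(3, 1.0), seed=3)
        mk = hy.minkowski_dot(emb.points, emb.points)
        np.testing.assert_allclose(mk, -1.0, atol=1e-9)

    def test_seeded_bit_reproducibility(self):
        rng = np.random.default_rng(13)
        d = c.distance_matrix(rng.standard_normal((7, 3)), "euclidean")
        e1 = c.hmds(d, c.HyperbolicSpace(2, 1.0), seed=4)
        e2 = c.hmds(d, c.HyperbolicSpace(2, 1.0), seed=4)
        np.testing.assert_array_equal(e1.points, e2.points)

    def test_hyperbolic_beats_euclidean_on_tree_distances(self):
        """Tree-like (hierarchical) metrics embed better hyperbolically at
        equal parameter count."""
        # balanced binary tree with 8 leaves, unit edges; leaf-leaf path lengths
        import itertools
        leaves = list(itertools.product([0, 1], repeat=3))
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    depth = 3
                    common = 0
                    for a, b in zip(leaves[i], leaves[j]):
                        if a == b:
                            common += 1
                        else:
                            break
                    d[i, j] = 2 * (depth - common)
        emb_h = c.hmds(d, c.HyperbolicSpace(2, 1.0), seed=5)
        _, coords_stress = c.emds(d, 2)
        coords, _ = c.emds(d, 2)
        from scipy.spatial.distance import pdist, squareform
        r2_e = c.shepherd_r2(d, squareform(pdist(coords)))
        assert emb_h.shepherd_r2 >= r2_e - 1e-9


class TestSelectGeometry:
    def test_single_cell_grid(self):
        rng = np.random.default_rng(14)
        d = c.distance_matrix(rng.standard_normal((6, 3)), "euclidean")
        space, table = c.select_geometry(d, [2], [1.0])
        assert (space.dim, space.kappa) == (2, 1.0)
        assert len(table) == 1

    def test_recovers_planted_geometry_and_table_size(self):
        rng = np.random.default_rng(15)
        pts = _random_hyperboloid_cloud(rng, 12, 3, scale=1.2)
        d = _pairwise(pts)
        dims, kappas = [2, 3], [0.5, 1.0, 2.0]
        space, table = c.select_geometry(d, dims, kappas, seed=6)
        assert len(table) == len(dims) * len(kappas)
        assert space.dim == 3   # true dimension within one grid step


class TestGeodesicOps:
    def test_karcher_single_and_midpoint(self):
        a = hy.lift(np.array([0.0, 0.0]))
        b = hy.lift(np.array([1.0, 0.5]))
        np.testing.assert_allclose(hy.hyperbolic_centroid(a[None]), a)
        mid = hy.hyperbolic_centroid(np.stack([a, b]))
        da = float(hy.lorentz_distance(mid, a, 1.0))
        db = float(hy.lorentz_distance(mid, b, 1.0))
        assert abs(da - db) <= 1e-6

    def test_centroid_of_reflective_cloud(self):
        rng = np.random.default_rng(16)
        sp = rng.standard_normal((40, 2)) * 0.5
        pts = hy.lift(np.vstack([sp, -sp]))    # symmetric about the apex
        cen = hy.hyperbolic_centroid(pts)
        np.testing.assert_allclose(cen, hy.lift(np.zeros(2)), atol=1e-6)

    def test_endpoints_project_to_themselves(self):
        a = hy.lift(np.array([0.0, 0.0]))
        b = hy.lift(np.array([1.5, 0.0]))
        d_ab = float(hy.lorentz_distance(a, b, 1.0))
        p, do = c.hyperbolic_image(a, a, b)
        assert abs(p) < 1e-6 and do < 1e-6
        p, do = c.hyperbolic_image(b, a, b)
        assert abs(p - d_ab) < 1e-6 and do < 1e-6

    def test_degenerate_geodesic_raises(self):
        a = hy.lift(np.array([0.3, 0.3]))
        with pytest.raises(ValueError):
            c.hyperbolic_image(a, a, a)

    def test_flat_limit_matches_euclidean_projection(self):
        """Near the apex at small scale, the geodesic readout converges to
        the Euclidean projection of the chart coordinates."""
        from chromage import axis as ax
        rng = np.random.default_rng(17)
        eps = 1e-3
        sp = rng.standard_normal((20, 3)) * eps
        a_sp, b_sp = np.zeros(3), np.array([2 * eps, 0.0, 0.0])
        a, b = hy.lift(a_sp), hy.lift(b_sp)
        eu_axis = ax.ImAgeAxis(a_sp, np.array([1.0, 0, 0]), "centroid")
        eu = ax.project(sp, eu_axis)
        for i in range(len(sp)):
            p, do = c.hyperbolic_image(hy.lift(sp[i]), a, b)
            assert abs(p - eu["p"].iloc[i]) <= 1e-3
            assert abs(do - eu["d_o"].iloc[i]) <= 1e-3

    def test_variance_fraction_limits(self):
        a = hy.lift(np.array([0.0, 0.0, 0.0]))
        b = hy.lift(np.array([1.0, 0.0, 0.0]))
        # all points on the geodesic
        ts = np.linspace(-0.5, 1.5, 9)
        u = hy.log_map(a, b) / float(hy.lorentz_distance(a, b, 1.0))
        on_geo = np.stack([hy.exp_map(a, t * u) for t in ts])
        assert c.geodesic_variance_fraction(on_geo, a, b) == pytest.approx(1.0, abs=1e-9)
        # isotropic tangent cloud in 3 dims -> ~1/3
        rng = np.random.default_rng(18)
        cloud = hy.lift(rng.standard_normal((3000, 3)) * 0.01)
        frac = c.geodesic_variance_fraction(cloud, a, b)
        assert abs(frac - 1 / 3) < 0.05

    def test_variance_fraction_monotone_in_drift(self):
        rng = np.random.default_rng(19)
        a = hy.lift(np.array([0.0, 0.0]))
        b = hy.lift(np.array([1.0, 0.0]))
        fracs = []
        for drift in (0.0, 0.5, 2.0):
            sp = rng.standard_normal((200, 2)) * 0.05
            sp[:, 0] += np.linspace(0, drift, 200)
            fracs.append(c.geodesic_variance_fraction(hy.lift(sp), a, b))
        assert fracs[0] < fracs[1] < fracs[2]
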