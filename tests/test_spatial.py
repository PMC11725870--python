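"""Point-pattern analytics: linkage, NND/CSR, pair distances, thinning."""

import numpy as np
import pytest
from scipy import stats

from hots.spatial import (
    Histogram,
    NoPeakError,
    PointPattern,
    csr_null,
    fit_gaussian_peak,
    link_clusters,
    nnd_centroids,
    pairwise_distance_histogram,
    rectangle_region,
    size_distribution,
    subtract_background,
    thin_labels,
)
from hots.theory import SizeDistribution


def square_pattern(points, side=10_000.0, **kw):
    return PointPattern(points=np.asarray(points, float),
                        region=rectangle_region(side, side), **kw)


class TestLinkClusters:
    def test_chain_linkage(self):
        pts = [[100, 100], [109, 100], [118, 100]]  # spacing 9 < cutoff 10
        cs = link_clusters(square_pattern(pts), cutoff=10.0)
        assert cs.sizes.tolist() == [3]

    def test_beyond_cutoff_stays_separate(self):
        pts = [[100, 100], [111, 100]]
        cs = link_clusters(square_pattern(pts), cutoff=10.0)
        assert sorted(cs.sizes.tolist()) == [1, 1]

    def test_tie_at_exact_cutoff_links(self):
        pts = [[100.0, 100.0], [110.0, 100.0]]
        cs = link_clusters(square_pattern(pts), cutoff=10.0)
        assert cs.sizes.tolist() == [2]

    def test_matches_brute_force_transitive_closure(self, rng):
        pts = rng.uniform(0, 2000, size=(200, 2))
        cutoff = 60.0
        cs = link_clusters(square_pattern(pts), cutoff=cutoff)
        parent = list(range(200))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(200):
            for j in range(i + 1, 200):
                if np.hypot(*(pts[i] - pts[j])) <= cutoff:
                    parent[find(i)] = find(j)
        brute = np.sort(np.unique([find(i) for i in range(200)], return_counts=True)[1])
        assert np.array_equal(np.sort(cs.sizes), brute)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.uniform(2000, 6000, size=(80, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ rot.T + np.array([6000.0, 800.0])
        a = link_clusters(square_pattern(pts), cutoff=50.0)
        b = link_clusters(square_pattern(moved, side=20_000.0), cutoff=50.0)
        assert np.array_equal(np.sort(a.sizes), np.sort(b.sizes))

    def test_empty_pattern(self):
        cs = link_clusters(square_pattern(np.zeros((0, 2))), cutoff=10.0)
        assert cs.n_clusters == 0

    def test_singleton_centroid_is_the_point(self):
        cs = link_clusters(square_pattern([[5.0, 7.0]]), cutoff=10.0)
        np.testing.assert_allclose(cs.centroids[0], [5.0, 7.0])

    def test_points_outside_region_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            square_pattern([[20_000.0, 50.0]], side=10_000.0)


class TestSizeDistribution:
    def test_singletons_density(self):
        pts = np.column_stack([np.linspace(100, 2000, 10), np.full(10, 50.0)])
        # 10 singletons over a 5 μm² region
        pattern = PointPattern(points=pts, region=rectangle_region(2500.0, 2000.0))
        cs = link_clusters(pattern, cutoff=10.0)
        dist = size_distribution(cs, pattern.area_um2)
        assert dist.density[0] == pytest.approx(2.0)

    def test_total_density_conserved(self, rng):
        pts = rng.uniform(0, 10_000, size=(300, 2))
        pattern = square_pattern(pts)
        cs = link_clusters(pattern, cutoff=120.0)
        dist = size_distribution(cs, pattern.area_um2)
        assert dist.total() == pytest.approx(300 / pattern.area_um2, rel=1e-9)


class TestSubtractBackground:
    def test_zero_background_identity(self):
        d = SizeDistribution(n=np.arange(1, 4), density=np.array([2.0, 1.0, 0.5]))
        bg = SizeDistribution(n=np.array([1]), density=np.array([0.0]))
        out = subtract_background(d, bg)
        np.testing.assert_allclose(out.density, d.density)

    def test_clamped_bin_recorded(self):
        d = SizeDistribution(n=np.arange(1, 3), density=np.array([2.0, 0.1]))
        bg = SizeDistribution(n=np.arange(1, 3), density=np.array([0.5, 0.4]))
        with pytest.warns(UserWarning):
            out = subtract_background(d, bg)
        np.testing.assert_allclose(out.density, [1.5, 0.0])
        assert out.meta["clamped_n"] == [2]

    def test_mismatched_nmax_padded(self):
        d = SizeDistribution(n=np.arange(1, 5), density=np.array([2.0, 1.0, 0.5, 0.2]))
        bg = SizeDistribution(n=np.arange(1, 3), density=np.array([0.5, 0.2]))
        out = subtract_background(d, bg)
        np.testing.assert_allclose(out.density, [1.5, 0.8, 0.5, 0.2])

    def test_signal_recovered_from_mixture(self, rng):
        """Subtracting an independently sampled background estimate recovers
        the planted signal within Poisson sampling error."""
        area = 4000.0
        signal = np.array([3.0, 1.0, 0.4])
        background = np.array([0.6, 0.05, 0.0])
        mix_counts = rng.poisson((signal + background) * area)
        bg_counts = rng.poisson(background * area)
        mix = SizeDistribution(n=np.arange(1, 4), density=mix_counts / area)
        bg = SizeDistribution(n=np.arange(1, 4), density=bg_counts / area)
        out = subtract_background(mix, bg)
        err = np.abs(out.density - signal)
        tol = 4 * np.sqrt((signal + 2 * background) / area)
        assert np.all(err < tol + 1e-9)


class TestNND:
    def test_two_clusters_symmetric_distance(self):
        pts = [[0, 0], [6, 0], [3, 5], [1000, 0], [1006, 0], [1003, 5]]
        pattern = square_pattern(np.asarray(pts) + 2000.0)
        cs = link_clusters(pattern, cutoff=10.0)
        d = nnd_centroids(cs, min_size=3)
        assert len(d) == 2
        assert d[0] == pytest.approx(d[1])
        assert d[0] == pytest.approx(1000.0)

    def test_min_size_one_hand_spacing(self):
        pts = [[100, 100], [200, 100], [450, 100]]
        cs = link_clusters(square_pattern(pts), cutoff=10.0)
        d = nnd_centroids(cs, min_size=1)
        np.testing.assert_allclose(np.sort(d), [100.0, 100.0, 250.0])

    def test_matches_brute_force_minimum(self, rng):
        pts = rng.uniform(0, 9000, size=(120, 2))
        cs = link_clusters(square_pattern(pts), cutoff=5.0)
        d = nnd_centroids(cs, min_size=1)
        cents = cs.centroids
        for i in range(len(cents)):
            dd = np.hypot(*(cents - cents[i]).T)
            dd[i] = np.inf
            assert d[i] == pytest.approx(dd.min())

    def test_too_few_qualifying_warns(self):
        cs = link_clusters(square_pattern([[100, 100], [500, 500]]), cutoff=10.0)
        with pytest.warns(UserWarning):
            out = nnd_centroids(cs, min_size=3)
        assert out.size == 0


class TestCSRNull:
    def test_matches_poisson_nnd_closed_form(self):
        """NND of uniform points in a large square follows the 2D Poisson
        law F(r) = 1 - exp(-pi λ r²) (KS test)."""
        rng = np.random.default_rng(3)
        region = rectangle_region(10_000.0, 10_000.0)
        samples = csr_null(region, 400, 1, rng)
        lam = 400 / 10_000.0**2
        ks = stats.kstest(samples, lambda r: 1 - np.exp(-np.pi * lam * r**2))
        assert ks.pvalue > 0.01

    def test_seed_reproducibility(self):
        region = rectangle_region(5000.0, 5000.0)
        a = csr_null(region, 50, 3, np.random.default_rng(9))
        b = csr_null(region, 50, 3, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_mean_nnd_two_points_unit_square(self):
        """For 2 uniform points the mean NND equals the mean inter-point
        distance of a unit square, ≈0.5214 (quadrature value)."""
        rng = np.random.default_rng(12)
        region = rectangle_region(1.0, 1.0)
        samples = csr_null(region, 2, 20000, rng)
        assert samples.mean() == pytest.approx(0.52140543, abs=0.01)

    def test_degenerate_polygon_rejected(self):
        from shapely.geometry import Polygon

        line = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError):
            csr_null(line, 10, 1, np.random.default_rng(0))


class TestPairwiseDistances:
    def test_equilateral_triangle(self):
        s = 5.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]]) + 100.0
        hist = pairwise_distance_histogram(square_pattern(pts), max_distance=10.0)
        np.testing.assert_allclose(hist.distances, [5.0, 5.0, 5.0])

    def test_matches_brute_force_enumeration(self, rng):
        pts = rng.uniform(0, 300, size=(60, 2))
        hist = pairwise_distance_histogram(square_pattern(pts), max_distance=100.0)
        brute = []
        for i in range(60):
            for j in range(i + 1, 60):
                d = np.hypot(*(pts[i] - pts[j]))
                if d <= 100.0:
                    brute.append(d)
        np.testing.assert_allclose(np.sort(hist.distances), np.sort(brute))

    def test_precision_filter(self):
        pts = np.array([[100, 100], [105, 100], [110, 100]], float)
        pattern = square_pattern(pts, precision=np.array([0.5, 0.5, 3.0]))
        hist = pairwise_distance_histogram(pattern, 20.0, precision_filter=1.0)
        np.testing.assert_allclose(hist.distances, [5.0])


class TestGaussianPeak:
    def test_exact_gaussian_recovered(self):
        centers = np.arange(0.25, 20.0, 0.5)
        counts = 100 * np.exp(-0.5 * ((centers - 5.2) / 1.1) ** 2)
        hist = Histogram(edges=np.arange(0, 20.5, 0.5), counts=counts,
                         distances=np.array([]))
        fit = fit_gaussian_peak(hist)
        assert fit.mean == pytest.approx(5.2, abs=0.01)
        assert fit.sd == pytest.approx(1.1, abs=0.05)

    def test_monotone_histogram_raises(self):
        counts = np.array([50, 30, 20, 10, 5, 2], float)
        hist = Histogram(edges=np.arange(0, 3.5, 0.5), counts=counts,
                         distances=np.array([]))
        with pytest.raises(NoPeakError):
            fit_gaussian_peak(hist)

    def test_bimodal_fits_taller_peak_and_flags(self):
        centers = np.arange(0.25, 30.0, 0.5)
        counts = (100 * np.exp(-0.5 * ((centers - 5.0) / 1.0) ** 2)
                  + 70 * np.exp(-0.5 * ((centers - 20.0) / 1.0) ** 2))
        hist = Histogram(edges=np.arange(0, 30.5, 0.5), counts=counts,
                         distances=np.array([]))
        fit = fit_gaussian_peak(hist)
        assert fit.mean == pytest.approx(5.0, abs=0.2)
        assert fit.secondary_peak


class TestThinning:
    def test_efficiency_one_identity(self, rng):
        pts = rng.uniform(0, 10_000, size=(100, 2))
        pattern = square_pattern(pts)
        out = thin_labels(pattern, 1.0, rng)
        np.testing.assert_array_equal(out.points, pts)

    def test_binomial_count(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10_000, size=(10_000, 2))
        out = thin_labels(square_pattern(pts), 0.5, rng)
        # 99% binomial interval around 5000
        assert abs(out.n_points - 5000) < 2.58 * np.sqrt(10_000 * 0.25)

    def test_invalid_efficiency(self, rng):
        with pytest.raises(ValueError):
            thin_labels(square_pattern([[1.0, 1.0]]), 0.0, rng)
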