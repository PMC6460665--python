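"""Spatial ACF estimation, null-field synthesis, cluster-extent inference."""

import numpy as np
import pytest
from scipy import ndimage, stats

from cerefc.clusters import (ACFParams, Cluster, ClusterReport,
                             NullFieldSimulator, cluster_threshold,
                             estimate_acf, label_clusters, peak_to_seed,
                             simulate_null_field)
from cerefc.glm import StatMap
from cerefc.grids import BinaryMask, VolumeGrid


@pytest.fixture(scope="module")
def box():
    grid = VolumeGrid((20, 24, 20), (3.0, 3.0, 3.0))
    mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
    return grid, mask


class TestACFParams:
    def test_unity_at_zero_and_monotone(self):
        acf = ACFParams(0.6, 5.0, 4.0)
        r = np.linspace(0, 30, 100)
        vals = acf(r)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ACFParams(1.2, 3.0, 3.0)
        with pytest.raises(ValueError):
            ACFParams(0.5, -1.0, 3.0)


class TestEstimateACF:
    def test_white_noise_has_no_spatial_correlation(self, rng):
        grid = VolumeGrid((24, 24, 24), (3.0, 3.0, 3.0))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        fields = [rng.standard_normal(grid.dims) for _ in range(5)]
        acf = estimate_acf(fields, mask)
        assert float(acf(3.0)) < 0.1

    def test_gaussian_smoothed_noise_matches_theory(self, rng):
        """Noise smoothed at FWHM f has ACF(r) = exp(-r^2 / (4 sigma^2));
        the fitted mixture is Gaussian-dominated and tracks it at 3 lags."""
        fwhm = 6.0
        grid = VolumeGrid((32, 32, 32), (3.0, 3.0, 3.0))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        sigma_mm = fwhm / (2 * np.sqrt(2 * np.log(2)))
        fields = [ndimage.gaussian_filter(rng.standard_normal(grid.dims),
                                          sigma_mm / 3.0) for _ in range(8)]
        acf = estimate_acf(fields, mask)
        assert acf.a > 0.8
        for r in (3.0, 6.0, 9.0):
            theory = np.exp(-r ** 2 / (4 * sigma_mm ** 2))
            assert float(acf(r)) == pytest.approx(theory, abs=0.05)

    def test_round_trip_recovery(self, rng):
        """Fields synthesised from known (a, b, c) give the parameters back
        within 20% (and the fitted curve matches at the first lags)."""
        grid = VolumeGrid((48, 48, 48), (3.0, 3.0, 3.0))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        true = ACFParams(0.8, 4.0, 3.0)
        sim = NullFieldSimulator(grid, mask, true)
        fields = [sim.simulate(rng) for _ in range(30)]
        est = estimate_acf(fields, mask)
        assert est.a == pytest.approx(true.a, rel=0.2)
        assert est.b == pytest.approx(true.b, rel=0.2)
        for r in (3.0, 6.0, 9.0):
            assert float(est(r)) == pytest.approx(float(true(r)), abs=0.05)


class TestNullFields:
    def test_white_limit_uncorrelated_neighbours(self, box, rng):
        grid, mask = box
        f = simulate_null_field(grid, mask, ACFParams(1.0, 0.1, 0.1), rng)
        c = np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]
        assert abs(c) < 0.05

    def test_target_neighbour_correlation(self, box, rng):
        """Construction check: sample neighbour-lag correlation within 0.05
        of the target over 50 fields."""
        grid, mask = box
        acf = ACFParams(0.8, 4.0, 3.0)
        sim = NullFieldSimulator(grid, mask, acf)
        cs = [np.corrcoef(f[:-1].ravel(), f[1:].ravel())[0, 1]
              for f in (sim.simulate(rng) for _ in range(50))]
        assert np.mean(cs) == pytest.approx(float(acf(3.0)), abs=0.05)

    def test_fixed_seed_reproduces_field(self, box):
        grid, mask = box
        acf = ACFParams(0.7, 4.0, 3.0)
        a = simulate_null_field(grid, mask, acf, np.random.default_rng(42))
        b = simulate_null_field(grid, mask, acf, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_standardised_inside_mask(self, box, rng):
        grid, mask = box
        f = simulate_null_field(grid, mask, ACFParams(0.7, 4.0, 3.0), rng)
        vals = f[mask.membership]
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0, abs=1e-12)


class TestClusterThreshold:
    def test_white_noise_threshold_small(self, rng):
        """Nearly-white fields at p<0.005 on a large mask: the minimum
        cluster size is tiny, matching a direct Monte-Carlo oracle."""
        grid = VolumeGrid((40, 40, 40), (3.0, 3.0, 3.0))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        acf = ACFParams(1.0, 0.1, 0.1)
        thr = cluster_threshold(acf, mask, 0.005, 0.05, 200,
                                rng=np.random.default_rng(0))
        assert thr <= 4
        # direct MC oracle on freshly thresholded white noise
        zthr = stats.norm.isf(0.0025)
        maxes = []
        for _ in range(200):
            sup = np.abs(rng.standard_normal(grid.dims)) >= zthr
            lab, n = ndimage.label(sup,
                                   ndimage.generate_binary_structure(3, 1))
            maxes.append(np.bincount(lab.ravel())[1:].max() if n else 0)
        oracle = next(k for k in range(1, max(maxes) + 2)
                      if np.mean(np.asarray(maxes) >= k) <= 0.05)
        assert abs(thr - oracle) <= 1

    def test_submask_threshold_not_larger(self, box):
        grid, mask = box
        acf = ACFParams(0.8, 4.0, 3.0)
        sub = np.zeros(grid.dims, bool)
        sub[:, :, :5] = True
        small = BinaryMask(grid, sub, "cerebellum")
        t_small = cluster_threshold(acf, small, 0.005, 0.05, 300,
                                    rng=np.random.default_rng(1))
        t_big = cluster_threshold(acf, mask, 0.005, 0.05, 300,
                                  rng=np.random.default_rng(1))
        assert t_small <= t_big

    def test_monotone_in_alpha(self, box):
        grid, mask = box
        acf = ACFParams(0.8, 4.0, 3.0)
        t_strict = cluster_threshold(acf, mask, 0.005, 0.01, 300,
                                     rng=np.random.default_rng(2))
        t_loose = cluster_threshold(acf, mask, 0.005, 0.05, 300,
                                    rng=np.random.default_rng(2))
        assert t_strict >= t_loose

    def test_monotone_in_voxel_p(self, box):
        """A stricter voxel threshold needs no larger a cluster size."""
        grid, mask = box
        acf = ACFParams(0.8, 4.0, 3.0)
        t1 = cluster_threshold(acf, mask, 0.001, 0.05, 300,
                               rng=np.random.default_rng(3))
        t2 = cluster_threshold(acf, mask, 0.01, 0.05, 300,
                               rng=np.random.default_rng(3))
        assert t1 <= t2


def _stat_map_from_t(grid, mask, tvals, df=100):
    p = 2 * stats.t.sf(np.abs(tvals), df)
    return StatMap(tvals.copy(), tvals, p, df, grid=grid, mask=mask)


class TestLabelClusters:
    def test_single_suprathreshold_voxel(self, box):
        grid, mask = box
        t = np.zeros(mask.n_voxels)
        t[100] = 10.0
        rep = label_clusters(_stat_map_from_t(grid, mask, t), 0.005)
        assert len(rep.clusters) == 1
        assert rep.clusters[0].size == 1

    def test_corner_touching_voxels_split_under_faces(self):
        grid = VolumeGrid((4, 4, 4))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        t = np.zeros(grid.dims)
        t[1, 1, 1] = 10.0
        t[2, 2, 2] = 10.0  # corner neighbour only
        sm = _stat_map_from_t(grid, mask, t[mask.membership])
        assert len(label_clusters(sm, 0.005, "faces").clusters) == 2
        assert len(label_clusters(sm, 0.005,
                                  "faces+edges+corners").clusters) == 1

    def test_matches_bfs_flood_fill_oracle(self, rng):
        """Random map: component labels identical to an independent BFS."""
        grid = VolumeGrid((10, 10, 10))
        mask = BinaryMask(grid, np.ones(grid.dims, bool), "gray")
        t = rng.standard_normal(grid.dims) * 3
        sm = _stat_map_from_t(grid, mask, t[mask.membership])
        rep = label_clusters(sm, 0.005)

        zthr = stats.t.isf(0.0025, 100)
        sup = np.abs(t) >= zthr
        seen = np.zeros(grid.dims, bool)
        comps = []
        for start in map(tuple, np.argwhere(sup)):
            if seen[start]:
                continue
            comp, queue = [], [start]
            seen[start] = True
            while queue:
                cur = queue.pop()
                comp.append(cur)
                for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                          (0, 0, 1), (0, 0, -1)):
                    nb = tuple(np.add(cur, d))
                    if all(0 <= nb[i] < 10 for i in range(3)) and \
                            sup[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
            comps.append(frozenset(comp))
        got = {frozenset(map(tuple, c.voxels)) for c in rep.clusters}
        assert got == set(comps)

    def test_peak_is_max_abs_t(self, rng, box):
        grid, mask = box
        t = np.zeros(mask.n_voxels)
        t[:50] = -np.linspace(4, 8, 50)  # negative cluster
        sm = _stat_map_from_t(grid, mask, t)
        rep = label_clusters(sm, 0.005)
        peaks = [c.peak_stat for c in rep.clusters]
        assert min(peaks) == pytest.approx(-8.0)

    def test_empty_report_allowed(self, box):
        grid, mask = box
        rep = label_clusters(_stat_map_from_t(grid, mask,
                                              np.zeros(mask.n_voxels)), 0.005)
        assert rep.clusters == []


class TestPeakToSeed:
    def test_sphere_count_and_size(self):
        grid = VolumeGrid((11, 11, 11), (3.0, 3.0, 3.0))
        rep = ClusterReport(
            [Cluster(1, 40, np.array([[5, 5, 5]]), (5, 5, 5), 6.0),
             Cluster(2, 10, np.array([[1, 8, 8]]), (1, 8, 8), -5.0)],
            0.005, size_threshold=5, alpha=0.05,
        )
        seeds = peak_to_seed(rep, grid, 6.0)
        assert len(seeds) == 2
        assert seeds[0].n_voxels == 33
        assert 0 < seeds[1].n_voxels < 33  # clipped at the grid edge

    def test_only_surviving_clusters_seeded(self):
        grid = VolumeGrid((11, 11, 11), (3.0, 3.0, 3.0))
        rep = ClusterReport(
            [Cluster(1, 40, np.array([[5, 5, 5]]), (5, 5, 5), 6.0),
             Cluster(2, 2, np.array([[8, 8, 8]]), (8, 8, 8), 5.0)],
            0.005, size_threshold=5, alpha=0.05,
        )
        assert len(peak_to_seed(rep, grid, 6.0)) == 1
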