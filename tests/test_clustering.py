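"""Ripley statistics, DBSCAN/OPTICS and cluster morphology."""

import numpy as np
import pytest

from lama import (ClusterResult, SimulationConfig, cluster_morphology, dbscan,
                  extract_dbscan, optics, ripley, simulate_points)

from conftest import dbscan_oracle, hull_oracle, table_from_xy


class TestRipley:
    def test_two_point_hand_computation(self):
        # region area A, one pair at distance d: K jumps from 0 to A at r = d
        t = table_from_xy([(0, 0), (300, 400)], region=(0, 0, 1000, 1000))
        curve = ripley(t, [100, 499, 500, 800], edge_correction="none")
        area = 1000.0 * 1000.0
        np.testing.assert_allclose(curve.K, [0.0, 0.0, area, area])

    def test_l_and_h_derived_from_k(self):
        rng = np.random.default_rng(0)
        t = table_from_xy(rng.uniform(0, 1000, (200, 2)), region=(0, 0, 1000, 1000))
        curve = ripley(t, np.arange(10, 300, 10))
        np.testing.assert_allclose(curve.L, np.sqrt(curve.K / np.pi))
        np.testing.assert_allclose(curve.H, curve.L - curve.radii)

    def test_k_monotone_nondecreasing(self):
        rng = np.random.default_rng(1)
        for ec in ("none", "translation"):
            t = table_from_xy(rng.uniform(0, 2000, (500, 2)), region=(0, 0, 2000, 2000))
            curve = ripley(t, np.arange(10, 510, 10), edge_correction=ec)
            assert (np.diff(curve.K) >= -1e-9).all()

    def test_csr_mean_k_close_to_pi_r_squared(self):
        """Translation-corrected K under CSR tracks pi*r^2 (50 replicates)."""
        radii = np.arange(25, 525, 25)
        ks = []
        for seed in range(50):
            cfg = SimulationConfig(seed=seed, n_molecules=1000)
            t = table_from_xy(simulate_points(cfg).positions, region=cfg.region)
            ks.append(ripley(t, radii).K)
        mean_k = np.mean(ks, axis=0)
        np.testing.assert_allclose(mean_k, np.pi * radii ** 2, rtol=0.05)

    def test_clustered_pattern_h_peak_tracks_cluster_scale(self):
        """The H-function peak sits a small multiple (~2-3x) of sigma_c above
        the cluster radius and shifts proportionally when sigma_c doubles."""
        medians = {}
        for sigma_c in (25.0, 50.0):
            peaks = []
            for seed in range(20):
                cfg = SimulationConfig(seed=seed, pattern="gaussian_clusters",
                                       n_molecules=600, n_clusters=5, sigma_c=sigma_c)
                t = table_from_xy(simulate_points(cfg).positions, region=cfg.region)
                curve = ripley(t, np.arange(10, 410, 10))
                peaks.append(curve.radii[np.argmax(curve.H)])
            medians[sigma_c] = np.median(peaks)
            assert sigma_c <= medians[sigma_c] <= 4 * sigma_c
        assert medians[50.0] > medians[25.0]

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            ripley(table_from_xy([(0, 0)]), [10.0])


class TestDbscan:
    def test_chain_merges_into_one_cluster(self):
        t = table_from_xy([(0, 0), (1, 0), (2, 0)])
        r = dbscan(t, eps=1.5, min_pts=2)
        assert r.n_clusters == 1
        assert list(r.labels) == [0, 0, 0]

    def test_isolated_points_are_noise(self):
        t = table_from_xy([(0, 0), (10, 0)])
        r = dbscan(t, eps=1.0, min_pts=2)
        assert r.n_clusters == 0
        assert list(r.labels) == [-1, -1]

    def test_cluster_sizes_respect_min_pts_and_total(self):
        rng = np.random.default_rng(2)
        t = table_from_xy(rng.uniform(0, 500, (300, 2)))
        r = dbscan(t, eps=30.0, min_pts=5)
        total = 0
        for cid in range(r.n_clusters):
            members = r.members(cid)
            assert len(members) >= 1
            total += len(members)
        assert total + int(np.sum(r.labels == -1)) == 300

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(5, 200))
            pts = rng.uniform(0, 100, (n, 2))
            eps = float(rng.uniform(2, 15))
            min_pts = int(rng.integers(2, 8))
            got = dbscan(table_from_xy(pts), eps, min_pts)
            np.testing.assert_array_equal(got.labels, dbscan_oracle(pts, eps, min_pts))

    def test_agrees_with_sklearn_on_core_and_components(self):
        """Independent library cross-check: identical core/noise sets and
        core-point partition (border attachment conventions may differ)."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(4)
        for _ in range(20):
            pts = rng.uniform(0, 100, (int(rng.integers(20, 150)), 2))
            eps, min_pts = float(rng.uniform(3, 12)), int(rng.integers(2, 6))
            ours = dbscan(table_from_xy(pts), eps, min_pts)
            sk = SkDBSCAN(eps=eps, min_samples=min_pts).fit(pts)
            core = np.zeros(len(pts), bool)
            core[sk.core_sample_indices_] = True
            # every sklearn core cluster maps onto exactly one of our clusters
            for cid in set(sk.labels_[core]):
                members = np.flatnonzero(core & (sk.labels_ == cid))
                assert len(set(ours.labels[members])) == 1
                assert (ours.labels[members] >= 0).all()


class TestOptics:
    def test_eps_cut_reproduces_dbscan(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            n = int(rng.integers(5, 200))
            pts = rng.uniform(0, 100, (n, 2))
            eps = float(rng.uniform(2, 15))
            min_pts = int(rng.integers(2, 8))
            t = table_from_xy(pts)
            direct = dbscan(t, eps, min_pts)
            via_optics = extract_dbscan(optics(t, min_pts, max_eps=2 * eps), eps)
            np.testing.assert_array_equal(direct.labels, via_optics.labels)

    def test_two_blobs_show_two_reachability_valleys(self):
        rng = np.random.default_rng(6)
        blob1 = rng.normal([100, 100], 5, (60, 2))
        blob2 = rng.normal([500, 500], 5, (60, 2))
        t = table_from_xy(np.vstack([blob1, blob2]))
        res = optics(t, min_pts=5)
        reach = res.reachability[res.ordering]
        # a valley = a maximal run of ordered points below a threshold
        below = np.isfinite(reach) & (reach < 20.0)
        below[0] = True  # the first point has undefined reachability
        starts = np.sum(below[1:] & ~below[:-1]) + int(below[0])
        assert starts == 2

    def test_single_point_ordering(self):
        res = optics(table_from_xy([(0, 0)]), min_pts=2)
        assert list(res.ordering) == [0]
        assert np.isinf(res.reachability[0])


class TestMorphology:
    def test_unit_square_closed_forms(self):
        t = table_from_xy([(0, 0), (1, 0), (1, 1), (0, 1)])
        shapes = cluster_morphology(t, ClusterResult(np.zeros(4, int), 1, {}))
        s = shapes[0]
        assert s.area == pytest.approx(1.0)
        assert s.perimeter == pytest.approx(4.0)
        assert s.circularity == pytest.approx(np.pi / 4.0)
        np.testing.assert_allclose(s.centroid, [0.5, 0.5])
        assert s.max_diameter == pytest.approx(np.sqrt(2.0))
        assert s.n_localizations == 4

    def test_regular_64gon_circularity_near_one(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = 100.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        shapes = cluster_morphology(table_from_xy(pts),
                                    ClusterResult(np.zeros(64, int), 1, {}))
        assert shapes[0].circularity == pytest.approx(1.0, abs=1e-3)
        assert shapes[0].circularity <= 1.0 + 1e-9

    def test_matches_qhull_oracle_on_random_clusters(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            pts = rng.uniform(0, 100, (int(rng.integers(4, 50)), 2))
            shapes = cluster_morphology(table_from_xy(pts),
                                        ClusterResult(np.zeros(len(pts), int), 1, {}))
            area, perim = hull_oracle(pts)
            assert shapes[0].area == pytest.approx(area, rel=1e-9)
            assert shapes[0].perimeter == pytest.approx(perim, rel=1e-9)

    def test_collinear_cluster_flagged_degenerate(self):
        t = table_from_xy([(0, 0), (1, 1), (2, 2)])
        s = cluster_morphology(t, ClusterResult(np.zeros(3, int), 1, {}))[0]
        assert s.degenerate
        assert s.area == 0.0
        assert np.isnan(s.circularity)

    def test_noise_excluded_and_counts_conserved(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 300, (200, 2))
        t = table_from_xy(pts)
        r = dbscan(t, eps=25.0, min_pts=4)
        shapes = cluster_morphology(t, r)
        assert len(shapes) == r.n_clusters
        total = sum(s.n_localizations for s in shapes)
        assert total + int(np.sum(r.labels == -1)) == len(t)
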