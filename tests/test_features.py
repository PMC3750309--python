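import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import surfhist as sh
from surfhist.features import _pair_features_vec

from naive_reference import naive_histograms


class TestDarbouxPairFeatures:
    def test_coplanar_pair_all_angles_zero(self):
        pf = sh.darboux_pair_features([0, 0, 0], [0, 0, 1], [1, 0, 0], [0, 0, 1])
        assert (pf.alpha, pf.phi, pf.theta, pf.d) == (0.0, 0.0, 0.0, 1.0)

    def test_cylinder_cross_pair(self):
        pf = sh.darboux_pair_features([1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0])
        assert pf.alpha == pytest.approx(0.0, abs=1e-12)
        assert pf.phi == pytest.approx(-np.sqrt(0.5), abs=1e-12)
        assert pf.theta == pytest.approx(-np.pi / 2, abs=1e-12)
        assert pf.d == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_symmetric_in_argument_order(self):
        # The swap rule makes the feature set independent of which point
        # is passed first.
        rng = np.random.default_rng(0)
        for _ in range(100):
            ps, pt = rng.normal(size=(2, 3))
            ns, nt = rng.normal(size=(2, 3))
            ns /= np.linalg.norm(ns)
            nt /= np.linalg.norm(nt)
            a = sh.darboux_pair_features(ps, ns, pt, nt)
            b = sh.darboux_pair_features(pt, nt, ps, ns)
            assert a == b

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        ps = rng.normal(size=(1000, 3))
        pt = ps + rng.normal(size=(1000, 3))
        ns = rng.normal(size=(1000, 3))
        nt = rng.normal(size=(1000, 3))
        ns /= np.linalg.norm(ns, axis=1)[:, None]
        nt /= np.linalg.norm(nt, axis=1)[:, None]
        base = _pair_features_vec(ps, ns, pt, nt)
        rot = Rotation.random(1000, random_state=2).as_matrix()
        shift = rng.normal(scale=10, size=(1000, 3))
        moved = _pair_features_vec(
            np.einsum("nij,nj->ni", rot, ps) + shift,
            np.einsum("nij,nj->ni", rot, ns),
            np.einsum("nij,nj->ni", rot, pt) + shift,
            np.einsum("nij,nj->ni", rot, nt))
        for b, m in zip(base, moved):
            dev = np.abs(m - b)
            # theta is circular: -pi and pi are the same angle
            if b is base[2]:
                dev = np.minimum(dev, 2 * np.pi - dev)
            assert dev.max() < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            sh.darboux_pair_features([0, 0, 0], [0, 0, 1], [0, 0, 0], [0, 0, 1])

    def test_degenerate_frame_is_deterministic(self):
        # connecting line parallel to the source normal
        a = sh.darboux_pair_features([0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        b = sh.darboux_pair_features([0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 1])
        assert a == b and np.isfinite([a.alpha, a.phi, a.theta]).all()

    def test_feature_ranges(self):
        rng = np.random.default_rng(3)
        ps = rng.normal(size=(500, 3))
        pt = ps + rng.normal(size=(500, 3))
        ns = rng.normal(size=(500, 3))
        nt = rng.normal(size=(500, 3))
        ns /= np.linalg.norm(ns, axis=1)[:, None]
        nt /= np.linalg.norm(nt, axis=1)[:, None]
        a, p, t, d = _pair_features_vec(ps, ns, pt, nt)
        assert np.all((a >= -1 - 1e-12) & (a <= 1 + 1e-12))
        assert np.all((p >= -1 - 1e-12) & (p <= 1 + 1e-12))
        assert np.all((t > -np.pi - 1e-12) & (t <= np.pi + 1e-12))
        assert np.all(d > 0)


class TestDistanceWeight:
    def test_closed_form_values(self):
        assert sh.distance_weight(0.0, 12.0) == 0.5
        assert sh.distance_weight(6.0, 12.0) == 0.25
        assert sh.distance_weight(12.0, 12.0) == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sh.distance_weight(-0.1, 12.0)
        with pytest.raises(ValueError):
            sh.distance_weight(12.1, 12.0)

    def test_strictly_decreasing_and_bounded(self):
        d = np.linspace(0, 12, 200)
        w = sh.distance_weight(d, 12.0)
        assert np.all(np.diff(w) < 0)
        assert w.min() >= 0.0 and w.max() <= 0.5


class TestRawHistogram:
    def test_plane_mass_in_central_bin(self, plane_grid):
        idx = sh.build_index(plane_grid)
        nf = sh.estimate_normals(plane_grid, idx, r_n=2.5)
        cfg = sh.FeatureConfig(r_n=2.5, r_h=4.0)
        h = sh.raw_point_histogram(plane_grid, nf, idx, 60, cfg)
        assert h.valid
        # alpha = phi = theta = 0 for every coplanar pair: the joint bin
        # of (0,0,0) is the middle bin along each of the three axes.
        center = (2 * 5 + 2) * 5 + 2
        assert h.values[center] == 1.0

    def test_single_neighbor_is_one_hot(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [50, 50, 50]], dtype=float)
        cloud = sh.PointCloud(points=pts)
        idx = sh.build_index(cloud)
        nf = sh.NormalField(normals=np.tile([0.0, 0.0, 1.0], (3, 1)),
                            valid=np.ones(3, dtype=bool))
        h = sh.raw_point_histogram(cloud, nf, idx, 0, sh.FeatureConfig(r_h=5.0))
        assert h.valid and h.values.max() == 1.0 and h.values.sum() == 1.0

    def test_invalid_normal_gives_invalid_histogram(self, plane_grid):
        idx = sh.build_index(plane_grid)
        nf = sh.estimate_normals(plane_grid, idx, r_n=2.5)
        nf.valid[0] = False
        h = sh.raw_point_histogram(plane_grid, nf, idx, 0,
                                   sh.FeatureConfig(r_h=4.0))
        assert not h.valid and not h.values.any()


class TestAggregate:
    def _one_hot(self, bin_id, n_bins=125):
        v = np.zeros(n_bins)
        v[bin_id] = 1.0
        return sh.FeatureHistogram(values=v, valid=True)

    def test_isolated_point_identity(self):
        pts = np.array([[0, 0, 0], [100, 0, 0]], dtype=float)
        cloud = sh.PointCloud(points=pts)
        idx = sh.build_index(cloud)
        raw = [self._one_hot(3), self._one_hot(7)]
        cfg = sh.FeatureConfig(r_h=12.0)
        out = sh.aggregate_histogram(raw, cloud, idx, 0, cfg)
        np.testing.assert_array_equal(out.values, raw[0].values)

    def test_neighbor_at_rim_contributes_nothing(self):
        cfg = sh.FeatureConfig(r_h=12.0)
        pts = np.array([[0, 0, 0], [12.0, 0, 0]], dtype=float)
        cloud = sh.PointCloud(points=pts)
        idx = sh.build_index(cloud)
        raw = [self._one_hot(3), self._one_hot(7)]
        out = sh.aggregate_histogram(raw, cloud, idx, 0, cfg)
        np.testing.assert_array_equal(out.values, raw[0].values)

    def test_three_point_hand_computation(self):
        # coincident neighbor (weight exactly 0.5) + neighbor at r_h/2
        # (weight 0.25): final = normalize(h0 + 0.5 h1 + 0.25 h2)
        cfg = sh.FeatureConfig(r_h=12.0)
        pts = np.array([[0, 0, 0], [0, 0, 0], [6.0, 0, 0]], dtype=float)
        cloud = sh.PointCloud(points=pts)
        idx = sh.build_index(cloud)
        raw = [self._one_hot(0), self._one_hot(1), self._one_hot(2)]
        out = sh.aggregate_histogram(raw, cloud, idx, 0, cfg)
        expected = np.zeros(125)
        expected[[0, 1, 2]] = np.array([1.0, 0.5, 0.25]) / 1.75
        np.testing.assert_allclose(out.values, expected, atol=1e-15)


class TestComputeFeatures:
    def test_rows_sum_to_one(self, sphere_patch_300):
        fm = sh.compute_features(sphere_patch_300, sh.FeatureConfig(r_h=6.0))
        sums = fm.histograms.sum(axis=1)
        np.testing.assert_allclose(sums[fm.valid], 1.0, atol=1e-12)
        assert not fm.histograms[~fm.valid].any()

    def test_invalid_radius_order_rejected(self, sphere_patch_300):
        with pytest.raises(ValueError, match="r_n < r_h"):
            sh.FeatureConfig(r_n=12.0, r_h=2.5)

    def test_resolution_constraint_enforced(self, sphere_patch_300):
        sphere_patch_300.resolution_hint = 3.0
        with pytest.raises(ValueError, match="resolution"):
            sh.compute_features(sphere_patch_300, sh.FeatureConfig(r_n=2.5))

    def test_matches_per_point_operations(self, sphere_patch_300):
        cfg = sh.FeatureConfig(r_n=2.5, r_h=6.0)
        idx = sh.build_index(sphere_patch_300)
        nf = sh.estimate_normals(sphere_patch_300, idx, r_n=cfg.r_n)
        fm = sh.compute_features(sphere_patch_300, cfg, normals=nf, index=idx)
        raw = [sh.raw_point_histogram(sphere_patch_300, nf, idx, i, cfg)
               for i in range(len(sphere_patch_300))]
        for i in range(len(sphere_patch_300)):
            agg = sh.aggregate_histogram(raw, sphere_patch_300, idx, i, cfg)
            assert agg.valid == fm.valid[i]
            np.testing.assert_allclose(fm.histograms[i], agg.values, atol=1e-12)

    def test_matches_naive_reference(self, sphere_patch_300):
        cfg = sh.FeatureConfig(r_n=2.5, r_h=6.0)
        idx = sh.build_index(sphere_patch_300)
        nf = sh.estimate_normals(sphere_patch_300, idx, r_n=cfg.r_n)
        fm = sh.compute_features(sphere_patch_300, cfg, normals=nf, index=idx)
        ref, ref_valid = naive_histograms(sphere_patch_300.points, nf.normals,
                                          nf.valid, cfg.r_h,
                                          cfg.bins_per_feature)
        np.testing.assert_array_equal(fm.valid, ref_valid)
        np.testing.assert_allclose(fm.histograms, ref, atol=1e-12)

    def test_density_invariance_on_plane(self):
        cfgs = {}
        for res in (1.0, 2.0):
            plane = sh.sample_primitive("plane", {"size_x": 40.0, "size_y": 40.0},
                                        resolution=res, noise_sd=0.0, seed=2)
            fm = sh.compute_features(plane, sh.FeatureConfig(r_n=2.5 * res,
                                                             r_h=8.0 * res))
            mid = np.argmin(np.linalg.norm(plane.points - [20, 20, 0], axis=1))
            cfgs[res] = fm.histograms[mid]
        assert np.abs(cfgs[1.0] - cfgs[2.0]).sum() < 0.05

    def test_pair_radius_switch(self, sphere_patch_300):
        cfg = sh.FeatureConfig(r_n=2.5, r_h=6.0, pair_radius="r_n")
        fm = sh.compute_features(sphere_patch_300, cfg)
        assert fm.valid.any()
        np.testing.assert_allclose(fm.histograms[fm.valid].sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_csv_export(self, sphere_patch_300, tmp_path):
        fm = sh.compute_features(sphere_patch_300, sh.FeatureConfig(r_h=6.0))
        path = fm.to_csv(str(tmp_path / "f.csv"))
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == len(sphere_patch_300)
        assert df.shape[1] == 2 + fm.config.n_bins
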