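import numpy as np
import pytest

import surfhist as sh


@pytest.fixture
def plane_grid():
    """11x11 planar grid at z=0, 1 mm spacing."""
    xx, yy = np.meshgrid(np.arange(11.0), np.arange(11.0), indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(121)])
    return sh.PointCloud(points=pts)


@pytest.fixture
def sphere_patch_300():
    """~300 noisy points from a sphere cap: a generic small test cloud."""
    cloud = sh.sample_primitive("sphere", {"radius": 10.0}, resolution=1.0,
                                noise_sd=0.05, seed=42)
    keep = np.flatnonzero(cloud.points[:, 2] > 4.0)[:300]
    return cloud.subset(keep)


@pytest.fixture(scope="session")
def two_organ_scene():
    """Small labeled plane+cylinder scene with computed features (shared)."""
    plane = sh.sample_primitive("plane", {"size_x": 30.0, "size_y": 30.0},
                                resolution=1.0, noise_sd=0.088, seed=5)
    cyl = sh.sample_primitive("cylinder", {"radius": 2.5, "length": 60.0},
                              resolution=1.0, noise_sd=0.088, seed=6,
                              origin=[45.0, 15.0, 0.0])
    pts = np.vstack([plane.points, cyl.points])
    labels = np.concatenate([np.full(len(plane), sh.LEAF),
                             np.full(len(cyl), sh.STEM)])
    cloud = sh.PointCloud(points=pts, labels=labels, resolution_hint=0.5)
    cfg = sh.FeatureConfig(r_n=2.5, r_h=8.0)
    return cloud, sh.compute_features(cloud, cfg)


def make_onehot_features(n_per_class=10, bins=5, seed=0):
    """Linearly separable toy FeatureMatrix: one-hot bin 0 vs bin 1."""
    n_bins = bins ** 3
    hists = np.zeros((2 * n_per_class, n_bins))
    hists[:n_per_class, 0] = 1.0
    hists[n_per_class:, 1] = 1.0
    labels = np.concatenate([np.zeros(n_per_class, dtype=int),
                             np.ones(n_per_class, dtype=int)])
    fm = sh.FeatureMatrix(histograms=hists,
                          valid=np.ones(2 * n_per_class, dtype=bool),
                          config=sh.FeatureConfig(bins_per_feature=bins))
    return fm, labels


@pytest.fixture
def onehot_features():
    return make_onehot_features()
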