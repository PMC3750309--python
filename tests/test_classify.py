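import numpy as np
import pytest

import surfhist as sh
from conftest import make_onehot_features


class TestTrainPredict:
    def test_separable_toy_perfect_training_accuracy(self, onehot_features):
        fm, labels = onehot_features
        model = sh.train_svm(fm, labels, np.arange(len(labels)))
        pred = sh.predict(model, fm)
        np.testing.assert_array_equal(pred, labels)

    def test_invalid_rows_skipped_with_warning(self, onehot_features):
        fm, labels = onehot_features
        fm.valid[0] = False
        with pytest.warns(UserWarning, match="skipping"):
            model = sh.train_svm(fm, labels, np.arange(len(labels)))
        assert sh.predict(model, fm)[0] == -1

    def test_single_class_training_rejected(self, onehot_features):
        fm, labels = onehot_features
        with pytest.raises(ValueError, match="2 classes"):
            sh.train_svm(fm, labels, np.arange(10))

    def test_contradictory_labels_stay_near_chance(self):
        fm, _ = make_onehot_features(n_per_class=20)
        fm.histograms[:] = fm.histograms[0]  # identical features
        labels = np.tile([0, 1], 20)
        model = sh.train_svm(fm, labels, np.arange(40))
        acc = (sh.predict(model, fm) == labels).mean()
        assert 0.4 <= acc <= 0.6

    def test_config_fingerprint_mismatch_rejected(self, onehot_features):
        fm, labels = onehot_features
        model = sh.train_svm(fm, labels, np.arange(len(labels)))
        other = sh.FeatureMatrix(histograms=np.zeros((2, 3 ** 3)),
                                 valid=np.ones(2, dtype=bool),
                                 config=sh.FeatureConfig(bins_per_feature=3))
        with pytest.raises(ValueError, match="mismatch"):
            sh.predict(model, other)

    def test_model_round_trip(self, onehot_features, tmp_path):
        fm, labels = onehot_features
        model = sh.train_svm(fm, labels, np.arange(len(labels)))
        path = model.save(str(tmp_path / "m.joblib"))
        back = sh.ClassifierModel.load(path)
        np.testing.assert_array_equal(sh.predict(back, fm), labels)


class TestSubsampleCV:
    def test_separable_toy_mean_one_sd_zero(self):
        fm, labels = make_onehot_features(n_per_class=50)
        rep = sh.subsample_cv(fm, labels, train_fraction=0.1, iterations=5,
                              seed=1)
        assert rep.mean_accuracy == 1.0 and rep.sd_accuracy == 0.0

    def test_same_seed_reproducible(self, two_organ_scene):
        cloud, fm = two_organ_scene
        a = sh.subsample_cv(fm, cloud.labels, iterations=3, seed=11)
        b = sh.subsample_cv(fm, cloud.labels, iterations=3, seed=11)
        assert a.iteration_accuracies == b.iteration_accuracies
        assert a.confusion == b.confusion

    def test_fraction_out_of_range(self, onehot_features):
        fm, labels = onehot_features
        with pytest.raises(ValueError, match="train_fraction"):
            sh.subsample_cv(fm, labels, train_fraction=1.5)

    def test_tiny_class_without_training_point_rejected(self):
        fm, labels = make_onehot_features(n_per_class=5)
        with pytest.raises(ValueError, match="training point"):
            sh.subsample_cv(fm, labels, train_fraction=0.04)

    def test_permuted_labels_fall_to_class_prior(self, two_organ_scene):
        cloud, fm = two_organ_scene
        rng = np.random.default_rng(2)
        permuted = rng.permutation(cloud.labels)
        rep = sh.subsample_cv(fm, permuted, train_fraction=0.1, iterations=5,
                              seed=3)
        prior = max(np.mean(permuted == c) for c in np.unique(permuted))
        assert abs(rep.mean_accuracy - prior) < 0.1

    def test_point_order_invariance(self, two_organ_scene):
        cloud, fm = two_organ_scene
        rep = sh.subsample_cv(fm, cloud.labels, iterations=3, seed=5)
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(fm))
        fm_p = sh.FeatureMatrix(histograms=fm.histograms[perm],
                                valid=fm.valid[perm], config=fm.config)
        rep_p = sh.subsample_cv(fm_p, cloud.labels[perm], iterations=3, seed=5)
        assert abs(rep.mean_accuracy - rep_p.mean_accuracy) < 0.02

    def test_confusion_counts_sum_to_evaluated(self, two_organ_scene):
        cloud, fm = two_organ_scene
        rep = sh.subsample_cv(fm, cloud.labels, iterations=2, seed=1)
        n_labeled = int(((cloud.labels != -1) & fm.valid).sum())
        classes, counts = np.unique(cloud.labels[(cloud.labels != -1) & fm.valid],
                                    return_counts=True)
        n_train = int(np.round(counts * 0.04).sum())
        expected = 2 * (n_labeled - n_train) - rep.n_excluded_invalid
        assert sum(rep.confusion.values()) == expected


class TestLeaveOneOut:
    def test_identical_separable_plants(self):
        fm, labels = make_onehot_features(n_per_class=20)
        rep = sh.leave_one_out_cv([(fm, labels)] * 3)
        assert rep.mean_accuracy == 1.0
        assert len(rep.iteration_accuracies) == 3

    def test_swapped_label_conventions_detected(self):
        fm, labels = make_onehot_features(n_per_class=20)
        rep = sh.leave_one_out_cv([(fm, labels), (fm, 1 - labels)])
        assert rep.mean_accuracy == 0.0

    def test_single_class_fold_skipped(self):
        fm, labels = make_onehot_features(n_per_class=20)
        with pytest.warns(UserWarning, match="single class"):
            rep = sh.leave_one_out_cv([(fm, labels), (fm, labels),
                                       (fm, np.zeros_like(labels))])
        assert len(rep.iteration_accuracies) == 2

    def test_fewer_than_two_plants_rejected(self):
        fm, labels = make_onehot_features()
        with pytest.raises(ValueError, match="2 plants"):
            sh.leave_one_out_cv([(fm, labels)])


class TestSweeps:
    def test_single_cell_matches_direct_call(self, two_organ_scene):
        cloud, fm = two_organ_scene
        cv = {"train_fraction": 0.1, "iterations": 2, "seed": 4}
        sweep = sh.radius_sweep(cloud, cloud.labels, [2.5], [8.0],
                                cv_settings=cv)
        direct = sh.subsample_cv(fm, cloud.labels, **cv)
        assert sweep.accuracy[0, 0] == pytest.approx(direct.mean_accuracy)

    def test_infeasible_cells_flagged(self, two_organ_scene):
        cloud, _ = two_organ_scene
        sweep = sh.radius_sweep(cloud, cloud.labels, [2.5, 9.0], [8.0],
                                cv_settings={"train_fraction": 0.1,
                                             "iterations": 1, "seed": 0})
        assert sweep.feasible[0, 0] and not sweep.feasible[1, 0]
        assert np.isnan(sweep.accuracy[1, 0])

    def test_resolution_sweep_single_value_matches_direct(self, two_organ_scene):
        cloud, _ = two_organ_scene
        cv = {"train_fraction": 0.1, "iterations": 2, "seed": 4}
        sweep = sh.resolution_sweep(cloud, cloud.labels, [1.0],
                                    radius_policy=lambda r: (2.5, 8.0),
                                    cv_settings=cv)
        thinned = sh.rasterize(cloud.with_labels(cloud.labels), 1.0)
        fm = sh.compute_features(thinned, sh.FeatureConfig(r_n=2.5, r_h=8.0))
        direct = sh.subsample_cv(fm, thinned.labels, **cv)
        assert sweep.accuracy[0] == pytest.approx(direct.mean_accuracy)

    def test_resolution_sweep_counts_non_increasing(self, two_organ_scene):
        cloud, _ = two_organ_scene
        sweep = sh.resolution_sweep(cloud, cloud.labels, [1.0, 2.0],
                                    radius_policy=lambda r: (2.5 * r, 8.0 * r),
                                    cv_settings={"train_fraction": 0.1,
                                                 "iterations": 1, "seed": 0})
        assert sweep.point_counts["total"][0] >= sweep.point_counts["total"][1]

    def test_descending_resolutions_rejected(self, two_organ_scene):
        cloud, _ = two_organ_scene
        with pytest.raises(ValueError, match="ascending"):
            sh.resolution_sweep(cloud, cloud.labels, [2.0, 1.0])
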