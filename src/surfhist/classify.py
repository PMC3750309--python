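"""SVM classification of feature histograms and validation harnesses.

Histograms are already normalized, so rows are fed to an RBF-kernel SVM
unscaled (defaults: C = 1, gamma = 1 / n_bins).  Two validation protocols
are provided: repeated random sub-sample cross-validation with stratified
per-class 4% training draws, and per-plant leave-one-out (train on one
labeled plant, evaluate on all others).  Sweep harnesses map accuracy over
the (r_n, r_h) grid and over point-cloud resolutions.

Accuracy is correctly labeled evaluated points / evaluated points; points
without a valid descriptor (label -1 after prediction) are excluded from
both numerator and denominator and reported separately.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

from .features import FeatureConfig, FeatureMatrix, compute_features
from .io import PointCloud, UNLABELED, rasterize

__all__ = [
    "SVMConfig",
    "ClassifierModel",
    "ValidationReport",
    "SweepResult",
    "train_svm",
    "predict",
    "subsample_cv",
    "leave_one_out_cv",
    "radius_sweep",
    "resolution_sweep",
]


@dataclass(frozen=True)
class SVMConfig:
    """Kernel settings.

    ``gamma=None`` selects the median heuristic: 1 / median pairwise
    squared distance of (up to 512 evenly spaced) training rows.
    Histogram rows live on the probability simplex, where squared
    distances are far below 1, so a fixed gamma tied only to the feature
    count makes the RBF kernel nearly constant and the classifier
    collapses to the majority class; the median heuristic adapts the
    kernel width to the actual spread of the descriptors.  A float or a
    scikit-learn string ("scale"/"auto") is passed through unchanged.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: object = None


@dataclass
class ClassifierModel:
    svc: SVC
    classes: np.ndarray
    fingerprint: tuple
    n_bins: int
    svm_config: SVMConfig

    def save(self, path: str) -> str:
        import joblib

        joblib.dump(self, path)
        return path

    @staticmethod
    def load(path: str) -> "ClassifierModel":
        import joblib

        return joblib.load(path)


@dataclass
class ValidationReport:
    """Per-iteration (or per-fold) accuracies plus pooled confusion counts."""

    iteration_accuracies: List[float]
    confusion: Dict[Tuple[int, int], int]
    misclassified_ids: List[np.ndarray]
    n_excluded_invalid: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.iteration_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.iteration_accuracies, ddof=0))

    def to_dict(self) -> dict:
        return {
            "iteration_accuracies": list(map(float, self.iteration_accuracies)),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "confusion": {f"{t}->{p}": c for (t, p), c in self.confusion.items()},
            "n_excluded_invalid": self.n_excluded_invalid,
        }


@dataclass
class SweepResult:
    """Accuracy grid over radii or resolutions.

    ``feasible`` marks grid cells that satisfy resolution < r_n < r_h;
    infeasible cells carry NaN accuracy, not zero.
    """

    axis_names: Tuple[str, ...]
    axes: Tuple[np.ndarray, ...]
    accuracy: np.ndarray
    feasible: np.ndarray
    timing: np.ndarray
    point_counts: Optional[dict] = None

    def to_dataframe(self):
        import pandas as pd

        rows = []
        it = np.ndindex(*self.accuracy.shape)
        for idx in it:
            row = {n: self.axes[k][idx[k]] for k, n in enumerate(self.axis_names)}
            row["feasible"] = bool(self.feasible[idx])
            row["accuracy"] = self.accuracy[idx]
            row["seconds"] = self.timing[idx]
            rows.append(row)
        return pd.DataFrame(rows)


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """1 / median pairwise squared distance, on <= 512 evenly spaced rows."""
    from scipy.spatial.distance import pdist

    rows = X[np.linspace(0, len(X) - 1, min(len(X), 512)).astype(int)]
    d2 = pdist(rows, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        return 1.0
    return float(1.0 / np.median(d2))


def _resolve_gamma(cfg: SVMConfig, X: np.ndarray):
    return _median_heuristic_gamma(X) if cfg.gamma is None else cfg.gamma


def train_svm(features: FeatureMatrix, labels: np.ndarray,
              train_ids: np.ndarray, svm_config: Optional[SVMConfig] = None,
              seed: int = 0) -> ClassifierModel:
    """Train an SVM on the histogram rows listed in ``train_ids``.

    Rows without a valid descriptor are skipped with a warning; at least
    two classes must remain.
    """
    svm_config = svm_config or SVMConfig()
    labels = np.asarray(labels)
    train_ids = np.asarray(train_ids, dtype=np.int64)
    ok = features.valid[train_ids]
    if not ok.all():
        warnings.warn(f"skipping {int((~ok).sum())} training points without a "
                      f"valid descriptor")
        train_ids = train_ids[ok]
    classes = np.unique(labels[train_ids])
    if classes.size < 2:
        raise ValueError("training set contains fewer than 2 classes")
    X = features.histograms[train_ids]
    svc = SVC(kernel=svm_config.kernel, C=svm_config.C,
              gamma=_resolve_gamma(svm_config, X), random_state=seed)
    svc.fit(X, labels[train_ids])
    return ClassifierModel(svc=svc, classes=classes,
                           fingerprint=features.config.fingerprint(),
                           n_bins=features.config.n_bins,
                           svm_config=svm_config)


def predict(model: ClassifierModel, features: FeatureMatrix) -> np.ndarray:
    """One label per point; rows without a valid descriptor get -1."""
    if features.config.fingerprint() != model.fingerprint:
        raise ValueError(
            "feature config mismatch: features were built with "
            f"{features.config.fingerprint()} but the model expects "
            f"{model.fingerprint}")
    out = np.full(len(features), UNLABELED, dtype=np.int64)
    if features.valid.any():
        out[features.valid] = model.svc.predict(
            features.histograms[features.valid])
    return out


def _evaluate(true_labels: np.ndarray, pred: np.ndarray,
              eval_ids: np.ndarray):
    """Returns (n_correct, n_evaluated, confusion, wrong_ids, n_invalid)."""
    evaluated = eval_ids[pred[eval_ids] != UNLABELED]
    n_invalid = len(eval_ids) - len(evaluated)
    t, p = true_labels[evaluated], pred[evaluated]
    confusion: Dict[Tuple[int, int], int] = {}
    for ti, pi in zip(t, p):
        confusion[(int(ti), int(pi))] = confusion.get((int(ti), int(pi)), 0) + 1
    return int((t == p).sum()), len(evaluated), confusion, evaluated[t != p], n_invalid


def subsample_cv(features: FeatureMatrix, labels: np.ndarray,
                 train_fraction: float = 0.04, iterations: int = 10,
                 seed: int = 0,
                 svm_config: Optional[SVMConfig] = None) -> ValidationReport:
    """Repeated random sub-sample cross-validation.

    Each iteration draws ``train_fraction`` of every class uniformly
    without replacement (stratified), trains, and evaluates on all
    remaining labeled points.  Reproducible under ``seed``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    labeled = np.flatnonzero((labels != UNLABELED) & features.valid)
    classes, counts = np.unique(labels[labeled], return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 labeled classes")
    n_train = np.round(counts * train_fraction).astype(int)
    if np.any(n_train < 1):
        bad = classes[n_train < 1]
        raise ValueError(f"classes {bad} have no training point at "
                         f"fraction {train_fraction}")

    accs, confusion, missed = [], {}, []
    n_invalid_total = 0
    for _ in range(iterations):
        train_ids = np.concatenate([
            rng.choice(labeled[labels[labeled] == c], size=k, replace=False)
            for c, k in zip(classes, n_train)])
        model = train_svm(features, labels, train_ids, svm_config, seed=seed)
        pred = predict(model, features)
        eval_ids = np.setdiff1d(labeled, train_ids)
        n_ok, n_eval, conf, wrong, n_inv = _evaluate(labels, pred, eval_ids)
        accs.append(n_ok / n_eval if n_eval else float("nan"))
        missed.append(wrong)
        n_invalid_total += n_inv
        for k, v in conf.items():
            confusion[k] = confusion.get(k, 0) + v
    return ValidationReport(iteration_accuracies=accs, confusion=confusion,
                            misclassified_ids=missed,
                            n_excluded_invalid=n_invalid_total)


def leave_one_out_cv(plants: Sequence[Tuple[FeatureMatrix, np.ndarray]],
                     svm_config: Optional[SVMConfig] = None,
                     seed: int = 0) -> ValidationReport:
    """Per-plant leave-one-out: train on one plant, evaluate on the rest.

    One fold per plant; folds whose training plant carries a single class
    are skipped with a warning.  This mirrors the practical use case where
    a single manually labeled plant classifies all remaining plants.
    """
    if len(plants) < 2:
        raise ValueError("need at least 2 plants")
    accs, confusion, missed = [], {}, []
    n_invalid_total = 0
    for k, (feat_k, lab_k) in enumerate(plants):
        lab_k = np.asarray(lab_k)
        train_ids = np.flatnonzero((lab_k != UNLABELED) & feat_k.valid)
        if np.unique(lab_k[train_ids]).size < 2:
            warnings.warn(f"plant {k} has a single class; fold skipped")
            continue
        model = train_svm(feat_k, lab_k, train_ids, svm_config, seed=seed)
        fold_correct = fold_total = 0
        for m, (feat_m, lab_m) in enumerate(plants):
            if m == k:
                continue
            lab_m = np.asarray(lab_m)
            pred = predict(model, feat_m)
            eval_ids = np.flatnonzero(lab_m != UNLABELED)
            n_ok, n_eval, conf, wrong, n_inv = _evaluate(lab_m, pred, eval_ids)
            fold_correct += n_ok
            fold_total += n_eval
            missed.append(wrong)
            n_invalid_total += n_inv
            for kk, v in conf.items():
                confusion[kk] = confusion.get(kk, 0) + v
        accs.append(fold_correct / fold_total if fold_total else float("nan"))
    return ValidationReport(iteration_accuracies=accs, confusion=confusion,
                            misclassified_ids=missed,
                            n_excluded_invalid=n_invalid_total)


def radius_sweep(cloud: PointCloud, labels: np.ndarray,
                 r_n_values: Sequence[float], r_h_values: Sequence[float],
                 cv_settings: Optional[dict] = None,
                 base_config: Optional[FeatureConfig] = None) -> SweepResult:
    """Accuracy over the (r_n, r_h) grid via :func:`subsample_cv`.

    Cells with ``r_n >= r_h`` or ``r_n <= resolution`` are marked
    infeasible (NaN accuracy).
    """
    r_n_values = np.asarray(list(r_n_values), dtype=float)
    r_h_values = np.asarray(list(r_h_values), dtype=float)
    if r_n_values.size == 0 or r_h_values.size == 0:
        raise ValueError("radius lists must be non-empty")
    cv = {"train_fraction": 0.04, "iterations": 10, "seed": 0}
    cv.update(cv_settings or {})
    base = base_config or FeatureConfig()
    res = cloud.resolution_hint
    acc = np.full((r_n_values.size, r_h_values.size), np.nan)
    feas = np.zeros_like(acc, dtype=bool)
    timing = np.full_like(acc, np.nan)
    for i, rn in enumerate(r_n_values):
        for j, rh in enumerate(r_h_values):
            if rn >= rh or (res is not None and rn <= res):
                continue
            feas[i, j] = True
            cfg = FeatureConfig(r_n=rn, r_h=rh,
                                bins_per_feature=base.bins_per_feature,
                                features_used=base.features_used,
                                pair_radius=base.pair_radius)
            t0 = time.perf_counter()
            feats = compute_features(cloud, cfg)
            report = subsample_cv(feats, labels, **cv)
            timing[i, j] = time.perf_counter() - t0
            acc[i, j] = report.mean_accuracy
    return SweepResult(axis_names=("r_n", "r_h"),
                       axes=(r_n_values, r_h_values),
                       accuracy=acc, feasible=feas, timing=timing)


def resolution_sweep(cloud: PointCloud, labels: np.ndarray,
                     resolutions: Sequence[float],
                     radius_policy=None,
                     cv_settings: Optional[dict] = None,
                     base_config: Optional[FeatureConfig] = None,
                     min_points: int = 50) -> SweepResult:
    """Rasterize to each resolution, recompute features, cross-validate.

    ``radius_policy`` maps a resolution to ``(r_n, r_h)``; the default
    keeps the standard radii but grows ``r_n`` just above coarse
    resolutions.  Per-resolution point counts per class are recorded.
    """
    resolutions = np.asarray(list(resolutions), dtype=float)
    if np.any(np.diff(resolutions) <= 0):
        raise ValueError("resolutions must be strictly ascending")
    base = base_config or FeatureConfig()
    if radius_policy is None:
        def radius_policy(res):
            return (max(base.r_n, 1.3 * res), base.r_h)
    cv = {"train_fraction": 0.04, "iterations": 10, "seed": 0}
    cv.update(cv_settings or {})
    labels = np.asarray(labels)
    acc = np.full(resolutions.size, np.nan)
    feas = np.zeros(resolutions.size, dtype=bool)
    timing = np.full(resolutions.size, np.nan)
    counts: dict = {"total": [], "per_class": []}
    labeled_cloud = cloud.with_labels(labels)
    for i, res in enumerate(resolutions):
        thinned = rasterize(labeled_cloud, res)
        cls, cnt = np.unique(
            thinned.labels[thinned.labels != UNLABELED], return_counts=True)
        counts["total"].append(len(thinned))
        counts["per_class"].append({int(c): int(k) for c, k in zip(cls, cnt)})
        if len(thinned) < min_points:
            warnings.warn(f"resolution {res} leaves {len(thinned)} < "
                          f"{min_points} points; skipped")
            continue
        rn, rh = radius_policy(res)
        cfg = FeatureConfig(r_n=rn, r_h=rh,
                            bins_per_feature=base.bins_per_feature,
                            features_used=base.features_used,
                            pair_radius=base.pair_radius)
        feas[i] = True
        t0 = time.perf_counter()
        feats = compute_features(thinned, cfg)
        report = subsample_cv(feats, thinned.labels, **cv)
        timing[i] = time.perf_counter() - t0
        acc[i] = report.mean_accuracy
    return SweepResult(axis_names=("resolution",), axes=(resolutions,),
                       accuracy=acc, feasible=feas, timing=timing,
                       point_counts=counts)
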