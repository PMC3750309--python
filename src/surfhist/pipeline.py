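"""End-to-end workflow: preprocessing through organ volumes.

Mirrors the seven-step dataflow of an automated yield-estimation run
(scan acquisition itself is out of scope): crop, rasterize, estimate
normals, compute surface feature histograms, classify with an SVM trained
on a separately labeled plant, grow regions, and extract alpha-shape
volumes of the target organ.  Every stage writes its artifact to the
output directory and the whole run is reproducible under the config seed.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Union

import numpy as np

from . import classify as _classify
from .features import FeatureConfig, compute_features
from .io import PointCloud, crop_by_height, rasterize, read_cloud, write_cloud
from .regions import build_adjacency, extract_regions, merge_small_regions
from .volume import region_volumes

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Defaults are the operating point used for wheat yield runs: 1 mm
    resolution, r_n = 2.5 mm, r_h = 12 mm.  The adjacency radius for
    region growing defaults to twice the resolution; ``alpha`` must exceed
    the target organ's cross-section circumradius (8 mm covers a wheat ear
    of radius ~5.6 mm with bumps).
    """

    z_min: Optional[float] = None
    resolution: float = 1.0
    r_n: float = 2.5
    r_h: float = 12.0
    bins_per_feature: int = 5
    svm: _classify.SVMConfig = field(default_factory=_classify.SVMConfig)
    adjacency_radius: Optional[float] = None
    alpha: float = 8.0
    target_label: int = 3
    seed: int = 0
    output_dir: Optional[str] = None

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(r_n=self.r_n, r_h=self.r_h,
                             bins_per_feature=self.bins_per_feature)

    def validate(self) -> None:
        if not self.resolution < self.r_n < self.r_h:
            raise ValueError(
                f"config requires resolution < r_n < r_h, got "
                f"{self.resolution}, {self.r_n}, {self.r_h}")


def _preprocess(cloud: PointCloud, config: PipelineConfig) -> PointCloud:
    if config.z_min is not None:
        cloud = crop_by_height(cloud, config.z_min)
    return rasterize(cloud, config.resolution)


def run_pipeline(config: PipelineConfig,
                 cloud: Union[str, PointCloud],
                 training: Union[str, PointCloud, _classify.ClassifierModel,
                                 None] = None) -> dict:
    """Execute preprocessing through parameter extraction.

    ``cloud`` is the unlabeled scan (path or in-memory).  ``training`` is
    either a trained :class:`ClassifierModel` or a labeled cloud (path or
    in-memory) that is pushed through the same preprocessing and feature
    stages and then used to train the SVM — the one-labeled-plant-
    classifies-the-rest usage.  Returns the run report dict; artifacts and
    ``report.json`` are written to ``config.output_dir`` when set.
    """
    config.validate()
    report: dict = {"config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__")
                                   else v)
                               for k, v in asdict(config).items()},
                    "stages": {}}
    out = config.output_dir
    if out:
        os.makedirs(out, exist_ok=True)

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 4),
                                      **counts}
        return done

    try:
        done = stage("preprocess")
        if isinstance(cloud, str):
            cloud = read_cloud(cloud)
        target = _preprocess(cloud, config)
        done(n_points=len(target))

        done = stage("features")
        fcfg = config.feature_config()
        feats = compute_features(target, fcfg)
        done(n_valid=int(feats.valid.sum()))

        done = stage("classify")
        if training is None:
            raise ValueError("a trained model or a labeled training cloud "
                             "is required")
        if isinstance(training, str):
            training = read_cloud(training)
        if isinstance(training, PointCloud):
            if training.labels is None:
                raise ValueError("training cloud carries no labels")
            train_cloud = _preprocess(training, config)
            train_feats = compute_features(train_cloud, fcfg)
            train_ids = np.flatnonzero(train_cloud.labels != -1)
            model = _classify.train_svm(train_feats, train_cloud.labels,
                                        train_ids, config.svm,
                                        seed=config.seed)
        else:
            model = training
        pred = _classify.predict(model, feats)
        labeled = target.with_labels(pred)
        done(n_classified=int((pred != -1).sum()),
             classes={int(c): int((pred == c).sum()) for c in np.unique(pred)})

        done = stage("regions")
        adj_r = config.adjacency_radius or 2.0 * config.resolution
        graph = build_adjacency(labeled, adj_r)
        regions = extract_regions(labeled, pred, graph, adjacency_radius=adj_r)
        n_before = len(regions)
        regions = merge_small_regions(regions, labeled)
        repaired = regions.point_labels(len(labeled))
        labeled = labeled.with_labels(repaired)
        done(n_regions_before_merge=n_before, n_regions=len(regions))

        done = stage("volumes")
        reports = region_volumes(regions, labeled, config.target_label,
                                 config.alpha)
        done(n_target_regions=len(reports),
             volumes=[r.to_dict() for r in reports])
    except Exception as exc:
        failed = [s for s in ("preprocess", "features", "classify", "regions",
                              "volumes") if s not in report["stages"]]
        if out:
            with open(os.path.join(out, "report.json"), "w") as fh:
                json.dump(report, fh, indent=2)
        raise RuntimeError(
            f"pipeline failed at stage {failed[0] if failed else '?'}: {exc}"
        ) from exc

    if out:
        write_cloud(labeled, os.path.join(out, "labeled.ply"))
        regions.to_csv(os.path.join(out, "regions.csv"))
        import pandas as pd

        pd.DataFrame([r.to_dict() for r in reports]).to_csv(
            os.path.join(out, "volumes.csv"), index=False)
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
    report["labels"] = labeled.labels
    report["regions"] = regions
    report["volumes"] = reports
    return report
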