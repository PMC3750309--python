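# surfhist

Pointwise classification of plant organs from 3D laser-scanned point
clouds, for plant phenotyping: separate grapevine leaves from stems, or
wheat ears from stems, directly on the points — no mesh, no color, no
smoothness assumptions — and turn the resulting organ regions into
quantitative traits such as ear volume, a proxy for grain yield.

## Method

Every point `p_i` gets a **surface feature histogram**. For each neighbor
`p_j` within the histogram radius `r_H`, a Darboux frame is erected from
the source normal `n_s` and the connecting line `t̂ = (p_t − p_s)/d`
(source = the point whose normal makes the smaller angle with the line):

    u = n_s,  v = u × t̂ / ‖u × t̂‖,  w = u × v
    α = v · n_t,   φ = u · t̂,   θ = atan2(w · n_t, u · n_t)

The triplets (α, φ, θ) of all neighbor pairs are binned into a joint
histogram (5³ = 125 bins). The final descriptor adds each neighbor's own
histogram with the linear distance weight

    w_b(d) = 1 − (0.5 + d/r_H · 0.5)

so a touching neighbor counts 50:50 against the source and a neighbor at
the rim contributes nothing; the result is normalized and fed to an
RBF-kernel SVM. Normals come from radius-`r_N` PCA neighborhoods
(`resolution < r_N < r_H` is enforced). After classification, connected
same-label regions are extracted and implausibly small regions are
absorbed into their nearest large neighbor; alpha-shape volumes of the
target organ regions give the yield parameters.

No scan data ships with the package: the `synthetic` module generates
labeled grapevine- and wheat-like scenes (curved leaf sheets, 5 mm stems,
bump-modulated ear capsules with closed-form volumes) at controllable
resolution and sensor noise, and all validation runs on those scenes.
See `docs/methods.md` for the modelling details and their limits.

## Worked example

```python
import surfhist as sh

# a labeled synthetic grapevine at 1 mm resolution with 0.088 mm noise
scene = sh.synth_grapevine(sh.SceneSpec(resolution=1.0, seed=1))
print(len(scene), (scene.labels == sh.LEAF).mean())
# 47333 0.7378  -> ~47k points, ~74% of them leaf

feats = sh.compute_features(scene, sh.FeatureConfig(r_n=2.5, r_h=12.0))
report = sh.subsample_cv(feats, scene.labels, train_fraction=0.04,
                         iterations=10, seed=7)
print(round(report.mean_accuracy, 4), round(report.sd_accuracy, 5))
# 0.9946 0.00076  -> 99.5% of held-out points get the right organ label
```

Training on 4% of each class and evaluating on the rest, repeated ten
times, classifies 99.5% of the points correctly (sd 0.08 percentage
points across iterations). The same workflow runs from the shell:

```bash
surfhist synth grapevine scene.ply --resolution 1.0 --seed 1
surfhist pipeline wheat_plant.ply out/ --training-cloud labeled_plant.ply
```

The `pipeline` command chains cropping, rasterization, normal and
histogram computation, SVM classification, region repair and ear volume
extraction, and writes `labeled.ply`, `regions.csv`, `volumes.csv` and a
`report.json` with per-stage counts and timings.

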