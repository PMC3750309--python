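# Methods

## The descriptor

The package classifies single points of a plant point cloud by the local
geometry of the surface around them. For an ordered pair of oriented
points (p_s, n_s), (p_t, n_t) the Darboux frame u = n_s,
v = normalize(u × t̂), w = u × v (t̂ the unit vector from source to
target) yields three pose-invariant features: α = v·n_t ∈ [−1, 1],
φ = u·t̂ ∈ [−1, 1], θ = atan2(w·n_t, u·n_t) ∈ (−π, π]. The source of a
pair is the point whose normal makes the smaller acute angle with the
connecting line; ties keep input order. When the line is parallel to the
source normal the frame is completed deterministically from the
coordinate axis least aligned with it. The pair distance d is used only
for weighting, never binned — binning it would tie the descriptor to the
sampling density.

Per point, the features of all pairs with neighbors inside the histogram
radius r_H are clamped to their invariant ranges and binned into a joint
histogram with 5 uniform divisions per feature (125 bins; left-closed
bins, last bin right-closed). The final descriptor is
normalize(raw_i + Σ_j w_b(d_ij)·raw_j) with the linear weight
w_b(d) = 0.5·(1 − d/r_H): a coincident neighbor reaches a 50:50 ratio
against the source's own term, a neighbor at the rim contributes nothing.
All histograms are normalized to sum 1; points whose normal cannot be
estimated, or that have no valid neighbor, carry an all-zero histogram
flagged invalid and receive label −1 downstream.

Whole-cloud computation is vectorized (k-d-tree pair lists, chunked pair
features, a sparse weighted adjacency product for the aggregation); the
per-point operations `raw_point_histogram` / `aggregate_histogram` are
the readable reference path and the test suite pins the two together and
against an independent brute-force reimplementation at 1e−12.

## Parameters

| parameter | default | meaning |
|---|---|---|
| resolution r | 1.0 mm | minimal point-to-point distance, enforced by greedy thinning |
| r_N | 2.5 mm | PCA normal neighborhood radius; must exceed r |
| r_H | 12 mm | histogram/aggregation radius; must exceed r_N |
| bins per feature | 5 | 125 joint bins over (α, φ, θ) |
| SVM | RBF, C = 1 | gamma defaults to the median heuristic (below) |
| adjacency radius | 2 r | region-growing connectivity |
| alpha | 8 mm | alpha-shape radius for organ volumes |
| noise sd | 0.088 mm | synthetic sensor noise (scanner reproducibility) |

Rasterization is deterministic greedy thinning in input order: a point is
kept iff no already-kept point lies strictly within the resolution, so
kept points are a subset of measured points (no synthetic centroids) and
the output's minimal spacing is ≥ the resolution. Normal signs are
disambiguated toward a viewpoint, by default far above the plant; the
angular features are computed from whatever orientation the viewpoint
induces, and train/test data share that convention.

### SVM kernel width

Histogram rows live on the probability simplex; typical pairwise squared
distances are far below 1. A gamma tied only to the feature count
(1/125) makes the RBF kernel nearly constant, and the classifier then
collapses to the majority class — on the wheat scenes this produced
leave-one-out accuracy equal to the ear prior (~0.73). The default is
therefore the median heuristic: gamma = 1/median pairwise squared
distance over up to 512 evenly spaced training rows. It is deterministic,
adapts to the descriptor spread, and needs no tuning; explicit floats and
scikit-learn's "scale"/"auto" remain available.

## Validation protocols

*Sub-sample cross-validation*: per iteration, 4% of each class is drawn
uniformly without replacement (stratified), the SVM is trained on the
draw and evaluated on all remaining labeled points; ten iterations by
default, reproducible under an explicit seed. *Leave-one-out per plant*:
train on one labeled plant, evaluate on all others, average over all
choices of training plant — the practical scenario where one manually
labeled plant classifies a whole batch. Accuracy counts only points with
a valid descriptor; invalid points are reported separately, never as
errors.

## Region repair

Misclassification concentrates in small islands (flat stem patches that
look like leaf, leaf borders that look like stem). Connected components
of the per-label adjacency subgraph (edge iff distance ≤ 2 r) are
extracted, and a component merges into the surviving region with the
nearest centroid when its size is *significantly* small: strictly below
the mean region size **and** below half the smallest at-or-above-mean
region. The mean alone cannot serve as the criterion — of any two unequal
regions one is always below their mean, so a bare below-mean rule erodes
legitimate organs on repeated application; the factor-two guard makes the
repair a fixed point on its own output while leaving the island-sized
targets unchanged. Thresholds and absorbers are fixed at entry (single
pass); ties in centroid distance break toward the lowest region index.
Merging is label-agnostic: a stem-labeled island inside a leaf becomes
leaf.

## Volumes

The alpha complex keeps the Delaunay tetrahedra with circumradius ≤
alpha; the volume is the sum of their volumes, always ≤ the convex hull
volume and non-decreasing in alpha. Because scans sample only the organ
*surface*, the tetrahedra spanning the interior of a closed organ have
circumradii near the organ's cross-section circumradius — for a tube of
radius R, about R; for a sphere, the sphere radius itself. Alpha must
exceed that, not merely the sampling spacing, or the interior is not
filled and the volume collapses to ~0. Conversely an alpha much larger
than the concavity scale bridges surface detail: for the bumpy ear
capsule (cross-section up to 5.6 mm, bump wavelength 8.75 mm) alpha ≈
6.5 mm recovers the closed-form volume to within ~8%, while alpha = 8 mm
overestimates by ~12% by bridging the valleys between bumps. The
pipeline default (8 mm) favours robustness to ear size variation; pass a
tighter alpha when absolute volume accuracy matters. Yield parameters
are related to volume by ordinary least squares; R² is reported per
parameter, undefined (with a warning) for zero-variance columns.

## Synthetic scenes

The generators emulate the study conditions: grapevine = curved leaf
sheets (paraboloid bending, ~70–90 × 55–75 mm) on branched 5.0 mm
diameter stem tubes, ~75–80% leaf points; wheat = the region above the
highest leaf, 1–4 thin stems (radius 1.5 mm) per plant each topped by an
ear capsule (radius 5 mm, length 60–85 mm) with an axisymmetric
sinusoidal spikelet profile of amplitude 0.6 mm and integer period count,
whose enclosed volume has the closed form π L (R² + A²/2) + 4/3 π R³ and
is stored as ground truth. Surfaces are sampled quasi-uniformly at the
target spacing with deterministic jitter; sensor noise is Gaussian along
the true surface normal, truncated at ±3 sd (the scanner's
reproducibility is a bound, not a tail), sd 0.088 mm by default. Scene
assembly thins organ seams so the minimal spacing stays above half the
target resolution; labels are exact by construction and every generator
is deterministic under its seed.

What passing on these scenes shows — and what it does not: the scenes
reproduce the *local differential geometry* that the descriptor measures
(curvature contrast between sheets, thin tubes and bumpy capsules) under
realistic sampling and noise, so they validate the descriptor, the
learning setup, the repair and the volume extraction. They do not model
occlusion, scan-line artifacts, leaf venation, self-contact, or the
gradual leaf-to-stem transitions of real plants, so absolute accuracies
on real scans will differ; trends (radius dependence, resolution
robustness) are the transferable result.

## Problem sizes and numerical choices

Validation runs use a ~47k-point grapevine scene at 1 mm (the published
operating point r_N = 2.5 mm, r_H = 12 mm), a ~30k-point scene spanning
resolutions 0.5–4.0 mm with r_H = 5 mm (the best-performing histogram
radius of the original resolution study), twelve wheat plants of ~3–15k
points each, and a ~20k-point sphere sample for volumes. Degenerate
covariances (fewer than 3 support points, or second eigenvalue ≤ 1e−12 of
the largest) invalidate a normal; near-flat tetrahedra (determinant below
1e−12 relative to edge scale) get infinite circumradius and are never
kept; feature values are clamped to their ranges before binning, and θ's
periodicity means −π and π land in the first and last bin respectively
(a measure-zero boundary on real data). Pair features are evaluated in
2M-pair chunks to bound memory.

## Known limitations

Binary organ classification per run (multi-organ separation requires one
pass per organ pair); no normal-sign propagation (a viewpoint must
roughly face the scanned side); alpha is global per run, so organs of
very different girth need separate runs; the region repair assumes
organs are at least twice the size of misclassification islands.
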