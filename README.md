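# mgmorph — quantitative microglia morphometry

Microglia (MG) shift morphology with activation state: homeostatic cells are
ramified, with a small soma and long branched processes; during
neuroinflammation they retract processes and round up into amoeboid forms.
`mgmorph` is a reusable, tested implementation of a brightfield-IHC
morphometry workflow for Iba1-stained tissue sections, aimed at labs
quantifying MG activation in models of CNS inflammation (e.g. EAE), plus the
genotype-stratified bootstrap analyses used to compare single-cell
composition between experimental groups.

## What it computes

**Object detection.** Each RGB slide image is reduced to its blue channel
(DAB reaction product is weak in blue), rescaled by `1.55 · m / 0.43137`
where `m` is the mean blue intensity, inverted, and thresholded at
intensity > 0.72 in the negative image, so stained structures become
foreground. Holes are filled, connected components are labeled, and a
10-measurement shape panel is recorded per object: area `A`, perimeter `P`
(boundary-pixel count), radius min/max/mean/SD (centroid-to-boundary
distances), centroid `(y, x)`, eccentricity `e = √(1 − λ₂/λ₁)` and
orientation `θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂)` from central second moments.
Only objects with `50 < A < 3000` pixels are kept.

**Cell screening.** A balanced random forest (1,500 trees, 3 candidate
features per split; by default 277 cells + 277 non-cellular objects sampled
from a manually labeled pool, remainder held out for validation) removes
debris.

**Morphological states.** Features are rank-scaled across all objects (ties
averaged) and clustered by complete-linkage agglomeration; the dendrogram is
cut at k = 3 and clusters are mapped to *activated* (round) / *activating*
(bushy) / *homeostatic* (ramified) by a ramification score,
`mean[rank(P²/A) + rank(radius SD)]/2`, lowest to highest. Counts per state
are summarized per image and per genotype (mean ± SD).

**Histomorphometry.** Quadrant-based scoring (percent of grid quadrants
positive for inflammatory pockets, CD3⁺ counts) and the myelin ratio
(myelinated plaque area / total white-matter area), with per-genotype
mean ± SD.

**Composition bootstrap.** For unbalanced single-cell genotype groups:
2,000 cells resampled with replacement per genotype, cell types tallied,
500 replicates; plus the mean 800 × 800 binned 2-D embedding density over
the same resampling, on a shared extent.

A fully ground-truthed synthetic data generator (three planted MG
archetypes, sub-/super-threshold and gate-passing debris, labeled feature
tables, genotype-stratified label tables, quadrant annotations) exercises
every stage without slide scans or sequencing data.

## Worked example

Generate a synthetic slide and detect objects:

```sh
$ mgmorph synth --out-dir demo_images --seed 4 --n-images 1
wrote 1 image(s) to demo_images
$ mgmorph detect --image demo_images/synthetic00.tif --out-dir demo_det
mgmorph.segmentation: scale_intensity: m=0.432208 factor=1.553012
mgmorph.segmentation: size_filter: kept 27, removed 18 objects
synthetic00: 27 gated objects
```

The image carries 45 planted objects (15 cells of three archetypes, 30
debris). The intensity factor is `1.55 · 0.432208 / 0.43137 = 1.553`; the
area gate removes the 18 debris objects outside (50, 3000) px, leaving the
15 cells and 12 gate-passing debris fibers for the classifier.

The end-to-end demo generates images, trains the screen on ground-truth
labels, runs the full analysis, and verifies recovery:

```sh
$ mgmorph demo --seed 1 --out-dir demo_out
all recovery checks passed
```

From `demo_out/demo_report.json` (seed 1): cell retention 1.0, retained
non-cell fraction 0.0, and cluster ramification scores
`{1: 126.9, 2: 77.1, 3: 25.5}`, so cluster 3 is labeled *activated*,
cluster 2 *activating*, and cluster 1 *homeostatic*; the adjusted Rand index
between the three states and the planted archetypes is 0.93 on this run.
All tables (gated objects, classified objects, per-image and per-genotype
state counts, bootstrap summaries, histology scores) are written under
`demo_out/results/`.

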