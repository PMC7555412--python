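# Methods

## Detection model

The detection chain assumes brightfield RGB images in which the chromogen
(DAB) darkens the blue channel against a brighter counterstained background.
All rasters are normalized to [0, 1] by the dtype maximum on read (8- or
16-bit integer input; float input is assumed pre-normalized), because the
fixed thresholds below are defined on that scale. Grayscale images are
replicated to three channels and alpha planes dropped so "blue channel" is
always defined.

Stages, in order, on the blue plane `I`:

1. **Scaling** — `I ← clip(I · 1.55 · m / 0.43137, 0, 1)` with `m = mean(I)`.
   The multiplier normalizes overall staining intensity relative to a fixed
   reference mean (0.43137); at `m = 0.43137` the factor is exactly 1.55.
   Clipping preserves the [0, 1] invariant; an all-zero image yields factor
   0 and a logged warning rather than an error.
2. **Negative threshold** — foreground = `{1 − I > 0.72}` with a strict
   inequality. The stained (dark) pixels are bright in the negative, so they
   are the pixels *kept*; the opposite reading would segment background.
3. **Hole filling** — every background region not connected to the raster
   border becomes foreground (monotone and idempotent).
4. **Labeling** — connected components under 8-connectivity by default
   (thin diagonal MG processes stay connected; 4-connectivity is available
   via `connectivity: 4`), labels assigned in raster-scan order.

### Shape panel conventions

Coordinates are 0-based `(row, col)`, origin top-left. Perimeter is the
count of object pixels with at least one background 4-neighbor, the raster
border counting as background. Radii are Euclidean distances from the
centroid (mean of all object pixels) to each perimeter pixel; the radius SD
uses the population (n) denominator. Eccentricity and angle come from the
central second moments of the pixel set (x = column, y = row): eigenvalues
λ₁ ≥ λ₂ of the covariance give `e = √(1 − λ₂/λ₁)` (defined as 0 for a
single pixel), and `θ = ½·atan2(2μ₁₁, μ₂₀ − μ₀₂)` is measured from the
column axis, mapped into (−π/2, π/2]. These are boundary-pixel conventions
(testable exactly), not Crofton estimators; they agree with the R/EBImage
`computeFeatures` values on shared fixtures except for a sub-pixel offset in
the radius statistics, which EBImage measures to traced contour points
(≤ ~6% relative on small objects).

The area gate keeps `50 < A < 3000` (both strict), applied after feature
extraction so the removed-object count is auditable.

## Cell screening

The random forest uses the classical algorithm: 1,500 trees, bootstrap row
resampling, 3 candidate features per split, unlimited depth, majority vote,
over the full 10-feature panel. Training follows the balanced protocol:
`train_per_class` objects per class (default 277) sampled without
replacement from the labeled pool; all remaining labeled objects form the
validation set on which overall accuracy is stored with the model. Tie
votes resolve to *non-cell* — screening is conservative and deterministic.
When the labeled pool is smaller than the protocol size (synthetic runs),
the per-class count is clamped to 80% of the smallest class so a validation
remainder always exists; the clamp is logged.

## Morphological states

Each feature column is replaced by its rank across all pooled objects in
the run (ties averaged), making the clustering invariant to any strictly
increasing per-feature transform. Clustering is agglomerative with complete
linkage (inter-cluster distance = maximum member pair distance, Euclidean on
ranks), cut at k = 3. The merge loop is written out explicitly with ties
broken toward the smallest cluster-index pair and cluster numbering by
smallest member row, so dendrograms are bit-reproducible across platforms;
on tie-free data it agrees with SciPy's complete-linkage implementation
(cross-checked in the tests).

**Feature subset.** Centroid coordinates and the orientation angle are
excluded from clustering by default (7 of the 10 measurements enter).
Position and rotation are extrinsic: two identical cells at different
places or orientations must receive the same state. Practically, the angle
rank column is uniform noise of the same magnitude as informative columns
and can flip complete-linkage merge orders at some sample sizes. The subset
is configurable (`cluster_states(columns=...)`).

**State mapping.** The three clusters are ordered by ramification score —
the member mean of `(rank(P²/A) + rank(radius SD))/2` over pooled objects.
`P²/A` is minimal for a disk and grows with boundary complexity; radius SD
grows with process length heterogeneity; both are computed from raw (not
rank-scaled) features and re-ranked. Lowest score → *activated* (round),
middle → *activating* (bushy), highest → *homeostatic* (ramified). Exact
score ties abort with an instruction to supply `state_override`
(cluster → state) in the config, which also supports expert relabeling.

## Histomorphometry

Quadrant positivity, CD3 counts, and the myelin/white-matter masks are
expert annotations — inputs, not detections. The module implements only the
arithmetic: percent positive quadrants, CD3 totals, plaque/white-matter
area ratio (with containment enforced), and per-genotype mean ± SD using
the sample (n−1) denominator, reported as absent at n = 1.

## Composition and density bootstrap

For each genotype independently, `boot_n` = 2,000 cells are drawn uniformly
with replacement and their type labels tallied; `boot_reps` = 500
replicates. Replicate-level count arrays are retained so percentile
intervals and replicate-paired genotype differences (mean difference,
2.5–97.5% interval, fraction positive) can be reported. The density variant
bins each replicate's sampled embedding coordinates into an 800 × 800
histogram over the *pooled* coordinate range of all genotypes (so grids are
comparable across genotypes), with the top edge right-closed so each
replicate's mass is exactly `boot_n`; the per-bin mean over replicates is
returned. Each genotype draws from its own namespaced RNG stream derived
from the single config seed, so replicates are reproducible and
genotype-wise independent.

## Synthetic data

The generator emulates the statistical structure each stage assumes, not
histology appearance:

* **Images.** Objects are stamped onto a uniform background with i.i.d.
  Gaussian noise (default SD 0.02) clipped to [0, 1]; blue-channel levels
  are 0.10 (stain) vs 0.45 (background), chosen so that after mean-based
  scaling the stained pixels fall below the 0.72 negative threshold and the
  background stays above it across realistic object densities. Red/green
  channels carry DAB-brown-like fixed levels and the same noise. Placement
  is rejection-sampled with ≥ 3 px clearance so planted pixel sets are
  disjoint and objects never merge; a frame that cannot host the request
  raises a capacity error rather than degrading.
* **Archetypes.** *round*: disk, radius 9–12 px; *bushy*: soma 7.5–8.5 px
  plus 3–4 thick (≈3 px) processes of 9–13 px; *dendritic*: soma 3.5–5 px
  plus 4–6 thin branched processes of 18–30 px. Geometry was chosen so the
  archetypes differ systematically along `P²/A` and radius SD — the axes
  the shape panel and ramification score can see — making three-state
  recovery achievable by construction. Debris comes in three flavors:
  specks (≤ 50 px), blobs (≥ 3000 px), and gate-passing thin gently curved
  fibers (no soma, near-unit eccentricity) that only the classifier can
  remove.
* **Tables.** The feature-space training generator draws the two classes
  from unit-variance Gaussians separated by `separation` standard
  deviations along one axis (0 = exchangeable); the label-table generator
  draws genotype-stratified categorical types with stated proportions and
  isotropic Gaussian embedding clouds; quadrant annotations use Bernoulli
  positivity and Poisson CD3 counts.

**What passing tests show — and don't.** Synthetic scenes have no
overlapping or touching cells, no texture, no uneven illumination, no
color-deconvolution ambiguity, and debris families with stable geometry.
Perfect retention/ARI on them validates the implementation of the
algorithms, not the biological accuracy of any threshold on real slides;
on real data the classifier needs its own manually labeled training pool,
and cluster→state mapping should be reviewed (the override map exists for
that purpose).

## Problem sizes and numerical choices

The push-button demo uses 12 images of 768² px (4 for classifier training,
8 for analysis) with 5+5+5 planted cells and 18 debris each; the recovery
experiment in the acceptance script uses 5 training + 20 analysis images
with 30 debris each, repeated over five seeds. Bootstraps always run at the
full 2,000 × 500 / 800 × 800 design. All randomness flows from one seed
through per-stage namespaced streams (`seed × stage-name × substream`),
keeping every derived seed below 2³¹; repeated runs are byte-identical,
which the test suite asserts by hashing entire output trees.

Degenerate inputs are handled explicitly: all-zero images scale to zero
with a warning; empty masks yield empty (but fully typed) feature tables;
K < k objects, empty genotypes, zero coordinate ranges, empty white matter,
and score ties raise typed errors naming the offending field.

## Known limitations

* No splitting of touching cells (watershed is out of scope); crowded
  fields undercount cells.
* The 0.72/1.55/0.43137 constants are treated as given; their provenance
  (presumably a calibration slide) is not modeled, and no µm/px calibration
  is applied to the 50/3000 px gates.
* The two-category collapse (ramified vs amoeboid) sometimes reported for
  MG counts is not automated; the package reports all three states.
* Bootstrap sampling is stratified by genotype only, not blocked by animal
  or batch; between-animal variance is not propagated.
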