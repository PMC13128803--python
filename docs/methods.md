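# Methods

## Cell maps and compartments

The analysis unit is a *cell map*: one row per nucleus centroid with a
phenotype in {LYMPHOCYTE, TUMOR, OTHER} and a compartment in
{TUMOR_REGION, STROMA}. Coordinates are micrometers in image convention
(origin top-left, y downward); `microns_per_pixel` is applied once at
ingest and never again. Compartments derive from geometry: a tissue
polygon and zero or more tumor-region polygons (GeoJSON, planar μm
coordinates), with tumor polygons clipped to the tissue and the stroma
defined as the remainder, so the three areas (mm²) satisfy
`stroma = tissue − tumor` exactly.

Phenotype integration follows the rule used by H&E TIL pipelines: a
nucleus classified as lymphocyte keeps that identity irrespective of
compartment (lymphocytes inside tumor nests are still lymphocytes); any
other nucleus is a tumor cell inside the tumor region and an "other"
cell in the stroma.

Numerical conventions worth stating:

* A point exactly on a tumor-polygon edge is TUMOR_REGION (closed
  polygons). This is deterministic and mirrors how rasterized masks
  resolve boundary pixels. Cells straddling the boundary in the original
  mask-based pipelines have no published resolution rule;
  centroid-in-polygon is our stand-in.
* A provided compartment column that disagrees with the geometry is an
  error, never silently overridden — it almost always indicates a
  front-end inconsistency.
* CSV round trips are bit-exact: floats are written at shortest
  round-trip precision and parsed with the round-trip converter.

## Spatial features

**Proximity.** All neighbor queries run on a k-d tree and are verified in
the test suite against exhaustive O(n²) scans for exact equality.
`avg_min_distance_r` is a *censored* mean: only reference cells whose
nearest target lies within r contribute. The alternative — truncating
all nearest distances at r — was rejected because it makes the
per-radius values nearly affine in one another, destroying the distinct
per-radius correlation structure the censored version exhibits.
Distances are centroid Euclidean with no boundary edge-correction.

**Aggregates.** The default linkage is single-linkage connected
components of the graph joining same-phenotype cells at distance
strictly < 20 μm: chained adjacencies form one cluster, which is the
standard reading of cell aggregates drawn as nodes joined by adjacency
vectors, and is what density-reachable clustering does in spatial
pathology generally. The literal all-pairs reading (every pairwise
distance < 20 μm) is kept as `LinkageMode.CLIQUE`, which returns all
maximal cliques (a cell may then belong to several). The threshold is
strict `<` in both modes. Aggregate densities are normalized by
whole-tissue area; quantification densities use their own compartment's
area. The denominators are configurable because either convention is
defensible; tissue area is the default.

**Missingness.** A feature undefined on a sample (no lymphocytes, no
qualifying reference cell, zero-area compartment) is recorded as NaN,
never zero-filled at extraction time — imputation belongs to the model,
where it can be fitted per training fold. A count over an empty target
set is a true 0, not missing.

**Determinism.** `extract_features` canonically orders cells by
`cell_id` before computing, so features are bit-identical under
permutation of input rows despite order-dependent float summation.

## Synthetic cohorts

The generator emulates a pre-treatment biopsy: a rectangular tissue
(default 2 × 2 mm) with 2–6 disk-shaped tumor nests (radius 150–400 μm,
overlaps unioned), tumor cells as a homogeneous Poisson process at 4 000
cells/mm² inside the nest union, "other" stromal cells at 1 500
cells/mm² in the stroma, and lymphocytes as an inhomogeneous Poisson
process with intensity

```
λ(x) = β · exp(γ·(g − 3)) · [1 + α · exp(−d(x) · g / (s·5/g))]
```

where g is the latent MP grade, d(x) the distance to the nearest
tumor-cell centroid, β = 300 cells/mm² the stromal baseline, γ = 0.35
the per-grade log-density slope, α = 3 the peritumoral attraction
strength and s = 30 μm its base length scale. Sampling is by thinning
(candidates from Poisson(λ_max·A), accepted with probability λ/λ_max),
which is exact and fully seedable; cohort generation spawns per-sample
seeds from one master seed. Default grade probabilities
(0.16, 0.22, 0.28, 0.22, 0.12) put 34% of samples at MP4–5, matching the
responder fraction typical of neoadjuvant chemo-immunotherapy TNBC
cohorts; the within-band split is our choice, as per-grade counts are
rarely reported.

Two consequences of this functional form deserve emphasis. First, the
attraction length scale `s·5/g²` *tightens* as grade rises, so high-grade
samples concentrate lymphocytes hard against tumor cells — this produces
the intended negative grade correlation of the censored mean distances
at 10–30 μm together with the positive correlation of stromal density.
Second, at grade 1 the halo is broadest (~150 μm decay) and partly
offsets the lower baseline, so the expected stromal lymphocyte density
is not strictly monotone between grades 1 and 2 (Monte-Carlo at 100
samples/grade: ≈245, 243, 314, 434, 608 cells/mm²); it is strictly
increasing from grade 2 on, and the rank correlation over realistic
cohorts is strongly positive (ρ ≈ +0.95 at n = 60).

What the generator does **not** emulate: nuclear morphology, segmentation
error, irregular nest shapes, tertiary lymphoid structures as organized
follicles, tissue-processing artifacts, or inter-patient variation in
cellularity beyond Poisson noise. Passing tests on these cohorts
therefore demonstrates that the pipeline recovers a planted spatial
signal of the stated *direction*; effect magnitudes (correlation sizes,
AUC) are properties of the generator, not estimates for real cohorts —
on real data all of these will be attenuated.

## Screening statistics

Spearman correlations use average ranks with a two-sided p from the t
approximation on n−2 df (adequate at the n ≥ 10 cohort sizes this
package targets). Mann-Whitney U compares MP4–5 against MP1–3, exact for
combined n ≤ 20 without ties, otherwise the tie- and continuity-corrected
normal approximation; U is oriented so that values above the null mean
indicate the feature is larger in high responders. Each screen's full
tested feature family is adjusted by Benjamini–Hochberg step-up
(q(i) = min over j≥i of m·p(j)/j, capped at 1); the two screens are
adjusted separately because they answer different questions and are
reported separately. Missing values are handled pairwise-complete with
`n_used` reported; features with fewer than 3 complete pairs, constant
values, or an empty comparison group are skipped with a logged reason
rather than contributing meaningless tests to the family.

## Response model

Binary target: MP4–5 (high response) vs MP1–3. Forest hyperparameters:
500 trees, minimum terminal-node size 5, √p candidate features per split,
bootstrap sampling. Evaluation: stratified 5-fold CV repeated 3 times,
fold assignment and every forest seeded deterministically from one
config seed. Median imputation is fitted on each training fold alone
(verified in tests by planting sentinels in held-out rows). Per-fold AUC
is the tie-adjusted Mann-Whitney probability; a fold whose test split
degenerates to one class yields a missing AUC, excluded from the mean
with a warning. Reported alongside the mean ± sd: the across-fold
2.5–97.5 percentile interval (labelled as such — it is not a bootstrap
CI), the best fold's ROC and 0.5-threshold confusion matrix (best-fold
reporting is optimistic on its own, hence never reported without the
mean), out-of-bag error from a full-data fit, and Gini importances both
raw (mean impurity decrease) and normalized to sum to 1. The DeLong test
uses placement-value variance on the pooled out-of-fold scores against
AUC = 0.5; under perfect separation the variance is zero and the p-value
is floored at the smallest positive double with a flag.

## Problem sizes

Defaults were chosen so that a full cohort study is interactive on a
laptop: 60 samples × ~10⁴ cells generate and featurize in well under a
minute; the repeated-CV forest fits in a few seconds at p = 61 features.
The acceptance script uses 60-sample signal/null cohorts, 20 replicate
32-sample null cohorts for the FDR check, and 500 chance-level score
vectors (n = 200) for DeLong calibration.

## Known limitations

* Compartment assignment is centroid-based; densely packed boundary
  regions where a nucleus overlaps both compartments are resolved by the
  centroid alone.
* No edge correction: reference cells near the tissue boundary see
  truncated disks, biasing `avg_count_r` slightly downward at large r.
* The Spearman p approximation is poor below n ≈ 10; an exact permutation
  option would be needed for very small cohorts.
* The clique aggregate mode enumerates maximal cliques, which is
  exponential in the worst case; it is intended for the ≤ 20 μm scales
  where cliques are tiny.
* The forest's AUC on synthetic cohorts reflects the planted effect size
  and should not be read as an expected real-data performance.
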