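# tilspatial

Spatial analysis of tumor-infiltrating lymphocyte (TIL) organization in
H&E-derived cell maps, and prediction of Miller-Payne (MP) pathological
response from those spatial features.

## Who this is for

Computational pathology groups that already have per-nucleus output from a
segmentation/classification front-end (e.g. QuPath-style detections: centroid
coordinates, a lymphocyte / tumor-cell / other label, and tumor-vs-stroma
compartment polygons) and want to quantify how lymphocytes are arranged
around tumor cells — and whether that arrangement predicts response to
neoadjuvant chemo-immunotherapy, graded on the five-tier Miller-Payne scale
(MP1 = no reduction in tumor cellularity … MP5 = no residual invasive
carcinoma).

The package consumes cell tables (CSV) plus compartment geometry (GeoJSON);
it performs no image processing. Because public per-cell data for such
cohorts are scarce, it ships a seeded synthetic-cohort generator that
emulates biopsy-scale cell maps (10³–10⁴ cells) in which higher MP grade
brings denser stromal lymphocytes and tighter peritumoral infiltration, so
the entire pipeline is testable end to end without any download.

## The features and the model

For each sample three spatial feature families are computed (61 features
with default settings):

1. **Bidirectional proximity.** With reference cells ℛ of one phenotype and
   targets 𝒯 of the other (lymphocyte→tumor and tumor→lymphocyte), and radii
   r ∈ {10, 20, 30, 50, 100, 200} μm:
   - `avg_count_r` = mean over i∈ℛ of #{ j∈𝒯 : d(i,j) ≤ r },
   - `avg_density_r` = `avg_count_r` / (πr²), per mm²,
   - `avg_min_distance_r` = mean of dᵢ = min_j d(i,j) over the reference
     cells with dᵢ ≤ r (a censored mean, so each radius carries distinct
     information).
2. **Lymphocyte aggregates.** Clusters of lymphocytes linked at pairwise
   distances < 20 μm (single-linkage components by default; an all-pairs
   maximal-clique mode is available). For each size threshold n ∈ {2..5}:
   number of clusters with ≥ n cells (`aggregate_n_count`), that count per
   mm² of tissue, and the mean qualifying cluster size.
3. **Compartment quantification.** Counts and densities (per mm²) of
   lymphocytes and tumor cells in the tumor region, the stroma, and overall,
   plus the stromal lymphocyte percentage.

Cohort-level screening uses Spearman rank correlation against the ordinal MP
grade and Mann-Whitney U between MP1–3 and MP4–5, each family adjusted by
Benjamini–Hochberg FDR. Response prediction (MP4–5 vs MP1–3) uses a random
forest — 500 trees, terminal node size 5, √p candidate variables per split —
evaluated by stratified 5-fold cross-validation repeated 3 times with
fold-wise median imputation, out-of-bag error, Gini importances, and a
DeLong placement-value test of the pooled out-of-fold AUC against chance.

## Worked example

```sh
tilspatial all --output-dir demo --seed 7
```

simulates a 32-sample cohort, extracts features, runs both screens, fits the
cross-validated forest and writes `demo/summary.md` plus CSV/JSON artifacts
and a checksum manifest (72 files). From an actual run:

```
## Spearman correlation with MP grade (top 10 by |R|)
                      feature  statistic            p            q  n_used
     lym_density_tumor_region   0.960263 3.539566e-18 2.088344e-16      32
     tumor_lym.avg_density_30   0.952246 5.281886e-17 6.232626e-16      32
...
tumor_lym.avg_min_distance_30  -0.936213 3.645623e-15 2.150917e-14      32

## Cross-validated prediction (high vs low/intermediate response)
- mean AUC: 1.000 ± 0.000 (across-fold interval 1.000-1.000)
- best fold AUC: 1.000
- out-of-bag error: 0.062
- DeLong test vs chance: p = 0
```

Read: lymphocyte density near and inside tumor regions rises with MP grade
(R > 0), the mean lymphocyte–tumor nearest distance within 30 μm falls with
grade (R < 0), and the forest separates high responders essentially
perfectly on this synthetic cohort — the generator's grade effect is strong
relative to its sampling noise, so treat the AUC as a pipeline check, not a
clinical estimate. The same subcommands run stage by stage
(`simulate`, `extract`, `stats`, `train`, `report`), and the library API
(`tilspatial.extract_features`, `spearman_screen`, `repeated_stratified_cv`,
…) accepts your own cell tables via `tilspatial.read_cell_table`.

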