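# Methods note

This note records the statistical formulation, default parameters, the
synthetic study conditions, numerical choices and deliberate design
decisions behind `lrscape`.

## 1. Pair scoring

For a ligand–receptor pair (L, R) and sample i with non-negative expression
values `l_i`, `r_i`, the activity score is the geometric mean
`s_i = sqrt(l_i * r_i)`. It is zero whenever either partner is silent,
symmetric in the two genes, and covariant under joint rescaling
(`score(a·l, a·r) = a·score(l, r)`). Pairs whose ligand or receptor is
absent from the expression matrix are dropped and reported in
`PairScoreMatrix.dropped_pairs` rather than silently imputed.

**Design decision.** The original workflow scores pairs with a regularized
product-correlation model over a curated LR database. At desk scale, with
synthetic expression and no database, the geometric mean preserves the
essential semantics (joint-expression proxy, zero-dominance) without the
inference machinery; everything downstream treats the score matrix as an
opaque input, so a different scorer can be substituted.

## 2. Maximally selected rank statistics

For a continuous marker `s` and right-censored survival data, each candidate
cutpoint c splits samples into low (`s ≤ c`) and high groups. We use the
linear-rank formulation with log-rank scores: with the Nelson–Aalen estimate
`Λ̂` of cumulative hazard, sample i gets the martingale-residual score
`a_i = δ_i − Λ̂(t_i)` (δ = event indicator), which sums to zero. For a low
group of size m the standardized statistic is

    Z(c) = |Σ_{i low} a_i| / sqrt( m(N−m)/(N−1) · σ²_a ),   σ²_a = Σ(a_i−ā)²/N.

The search is restricted to splits with `minprop = 0.3 ≤ m/N ≤ maxprop = 0.7`;
the best cutpoint maximizes Z. Its significance is assessed by a permutation
test (default B = 1000): the scores `a` are permuted against the marker
ordering and the maximum of the cumulative-sum statistics recomputed, giving
an exact-level Monte-Carlo p-value in O(B·n) per marker. Ties in the marker
are handled by enumerating only distinct values; the reported cutoff is the
largest score of the low group. An independent brute-force implementation
(per-split python loop on lifelines' Nelson–Aalen estimate) serves as the
test oracle.

## 3. Screening cascade

A pair passes the screen iff its maxstat permutation p-value is ≤ α (default
0.05) for **both** OS and PFI **and** the direction of effect agrees between
endpoints ("unfavorable" iff the low group's score sum is negative).
Screening is order-invariant: samples are canonically sorted and each pair's
permutation stream is seeded by `(seed XOR crc32(pair_name)) mod (2³¹−1)`.

Screened pairs are filtered by random survival forest permutation importance
(default `ntree = 1000`, `seed = 666`, 3 permutation repeats,
`min_samples_leaf = 15`). Raw importances are clipped at zero and scaled by
the maximum; pairs with scaled importance > 0.3 are retained.

**Deliberate deviation.** The reference procedure min–max scales the
importances, which forces the weakest screened pair to exactly 0 and
therefore always discards at least one pair — including a true pair when
only true pairs survive the screen (as in the two-planted-pair validation
condition). We scale by the maximum only, preserving the threshold's
intent (drop pairs far less important than the best) without the forced
casualty. This was decided from the mathematical analysis of the estimator,
before running the recovery experiment.

Retained pairs enter an L1-penalized Cox model (coordinate-descent elastic
net with `l1_ratio = 1`). The penalty is chosen on a 5-fold split by the
cross-validated partial-likelihood deviance of Verweij–van Houwelingen,
`−2(ll_full − ll_train)`, with our own Breslow partial log-likelihood;
because the path solver may truncate the requested penalty grid per fold,
deviances are keyed by the actually fitted penalties and only penalties
complete in all folds compete.

## 4. Frozen risk signature

`lrscape/data/published_lr_cox_model.json` ships a 14-pair L1-Cox OS
signature (HPV-negative head-and-neck squamous carcinoma). The risk score is
the linear predictor `η_i = Σ_k β_k s_ki`; no intercept, no standardization
at scoring time. Patients are dichotomized at the optimal cutpoint (maxstat,
Section 2) on a training cohort, or at an explicitly supplied cutoff for
held-out data (high iff `η > cutoff`), and groups are compared with
Kaplan–Meier estimates and the two-sample log-rank test (lifelines).

## 5. Spatial colocalization

Per slide, the ligand-high (receptor-high) set is the top 20% of spots by
expression — the `ceil(0.2·n)` largest values extended to all ties with the
smallest included value — giving categories BothHigh > ligand_high >
receptor_high > none. Each spot's interaction score uses its k = 6 nearest
neighbors (Euclidean, self excluded, distance ties broken by spot index):

    g_i = max( L_i · max_{j∈N(i)} R_j ,  R_i · max_{j∈N(i)} L_j ),
    c_i = min( log1p(g_i), Q95(log1p(g)) ).

The 95th-percentile cap bounds hotspot outliers. `coloc_summary` aggregates
mean/max capped scores and category counts per declared region.

## 6. Histology preprocessing

- **Tiling**: non-overlapping `tile_px = 512` tiles, row-major; partial edge
  tiles discarded. A tile is background when the fraction of pixels with
  mean-RGB brightness > 216 exceeds `1 − min_tissue_fraction` (default 0.5).
  The manifest records every grid position with a retained/background status.
- **Stain normalization**: sparse non-negative two-stain separation in
  optical-density space (`OD = −log(RGB/255)`), via dictionary learning with
  positive codes and dictionary on ≤ 5000 subsampled tissue pixels; the basis
  rows are unit-norm, deterministically ordered by the red/blue OD ratio, and
  each stain's concentration scale is its 99th percentile. Normalization maps
  a patch's concentrations onto a reference profile and recomposes; patches
  with degenerate color content pass through unchanged with a warning flag.
- **Embedding**: a deterministic 56-dimensional handcrafted descriptor
  (3×8-bin channel histograms, HSV means/stds, 16 gray-level co-occurrence
  texture properties, Sobel edge histogram and moments). Any callable with a
  declared `dim` (e.g. CNN global-average-pool features) satisfies the
  contract.
- **Reduction**: columns are z-scored with training statistics, then PCA to
  32 components (full SVD, seeded). Standardization is essential — the
  descriptor mixes scales (histogram fractions in [0, 1] vs co-occurrence
  contrast up to ~10²), and unscaled PCA is dominated by the large-magnitude
  channels. Rank-deficient inputs reduce the component count with a warning.
- **Clustering**: seeded K-means, default k = 6, 10 initializations; cluster
  maps are rendered with a fixed palette consistent across slides.

## 7. Silicon region selection and MIL fusion

Cases (not slides) are split 8:2, stratified by label, with a fixed seed
(default 666); all slides of a case stay on one side. An inner 75/25 case
split of the training cohort screens clusters: per cluster, a patch
classifier (standardized logistic regression by default; the trainer is
pluggable) is trained on slide-inherited labels and scored on validation
slides by strict-majority voting (positive iff **strictly more** than 50% of
patches are positive). Clusters are then dropped by a threshold, bottom-k
(default k = 2) or explicit rule; the selection never empties.

Each slide's selected-cluster patch likelihoods are summarized as a
10-bin patch-likelihood histogram (equal-width bins on [0, 1], likelihood
1.0 in the last bin, normalized to sum 1) concatenated with a 16-word TF-IDF
bag of words over discretized likelihoods (`idf = ln((1+N)/(1+n_w)) + 1`,
document frequencies from training bags only, so a ubiquitous word has idf
exactly 1). Features are redundancy-filtered greedily by decreasing variance
(keep iff |Pearson r| < 0.8 with everything kept, at most 32 features,
zero-variance features never kept). The slide classifier is an SVM-RBF
(C = 1, gamma = 1/d, Platt probabilities), KNN (k = 5, distance weights) or
random forest (500 trees), all seeded. Evaluation reports accuracy at 0.5,
ROC AUC, the confusion matrix, and decision-curve net benefit
`NB(p_t) = TP/N − FP/N · p_t/(1−p_t)` against treat-all/treat-none.
`run_silicon_pipeline` runs the identical chain with and without cluster
selection on the same split and seeds, so an all-cluster selection rule
yields bit-identical arms.

## 8. Synthetic generators: what they emulate — and don't

- **Bulk cohort** (`gen_bulk_cohort`): log-normal pair scores; exponential
  proportional-hazards survival with hazard `h_0 · exp(Σ β_k z_ki)` on
  standardized scores; independent exponential censoring whose rate is
  solved by bisection to hit the target censoring fraction; PFI is the
  minimum of a progression process and OS, so PFI ≤ OS always. Planted
  prognostic pairs have known log hazard ratios. *Not emulated*: gene-gene
  correlation structure, batch effects, non-PH effects.
- **Spatial slide** (`gen_spatial_slide`): Poisson counts on a grid with
  circular hotspots where both genes' rates are multiplied by a gain;
  per-spot region labels (hotspot/background) are returned as ground truth.
  *Not emulated*: platform spot geometry, segmentation noise, cell-type
  deconvolution.
- **Synthetic WSIs** (`gen_synthetic_wsis`): procedural texture tiles —
  per-class base colors plus Gaussian-smoothed noise blobs thresholded at a
  coverage fraction. For informative classes the coverage depends on the
  slide label (0.30 vs 0.60); non-informative classes are label-independent
  by construction. Tiles are rendered lazily and deterministically
  (`SeedSequence([seed, slide, row, col])`); every slide is guaranteed at
  least one informative tile; ~15% of cases contribute two slides, so the
  case-level split guard is exercised. *Not emulated*: actual tissue
  morphology, scanner artifacts, magnification pyramids.

## 9. Problem sizes and numerical choices

Validation experiments are sized for a single CPU:

- cascade recovery: n = 300 samples, 32 pairs (2 planted at log-HR 1.0),
  censoring 0.4, RSF `ntree = 300` (the config default stays 1000; 300 trees
  give stable importance rankings at 30 pairs), 20 replicates, ~3–5 s each;
- Silicon benefit: 60 slides × 16 tiles, 4 texture classes (2 informative),
  tiles rendered at 96 px — the texture statistics that drive the embedding
  are resolution-free, and 512 px rendering would only multiply pixel work
  ~28-fold (the `SyntheticWsiSpec` default remains 512 px); 10 replicates,
  ~5 s each.

Other numerical choices: permutation p-values use B = 1000 by default (the
acceptance cutoff-oracle check, which only compares the maximizer, uses
B = 20); all seeds are < 2³¹; per-stage pipeline seeds are
`(seed + 1000003·(stage_index+1)) mod (2³¹−1)`; all file outputs are written
with fixed float formatting so reruns are checksum-identical.

## 10. Limitations

- The geometric-mean pair score ignores expression-level normalization
  subtleties (library size, gene length); inputs are assumed comparably
  normalized.
- The permutation maxstat p-value is Monte-Carlo (resolution 1/B) and is not
  corrected for multiple testing across pairs; the dual-endpoint requirement
  is the multiplicity control, as in the reference workflow.
- The handcrafted embedding is a stand-in; real deployments should plug in a
  pretrained CNN via the `embed_patches` / trainer contracts.
- Decision-curve analysis is reported descriptively; no confidence bands.
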