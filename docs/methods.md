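# Methods

This note documents the model behind `snfs`, the choices made where the
procedure is genuinely underdetermined, and what the synthetic benchmark
does and does not establish.

## The selection model

The pipeline treats biomarker discovery as three filters applied in
sequence, each discarding genes by a different notion of redundancy:

1. **Univariate/embedded evidence.** Stage 1 keeps genes that look
   class-informative to at least some of several heterogeneous scorers.
   Merging by mean rank (Borda count) rather than by score makes the
   combination scale-free: chi-square statistics, bits of information gain,
   Gini importances and elimination orders are not commensurable, their
   ranks are. Mean rank is symmetric in its arguments and invariant to gene
   relabelling up to tie handling.
2. **Co-expression geometry.** Stage 2 asks which candidates behave as a
   group. Each gene is reduced to its per-class training means — for two
   classes a point in the plane — and repeated k-means (one run per
   k ∈ {3, 4, 5}) votes on co-membership. The co-occurrence count is a
   consensus-clustering similarity: genes that land together under every
   granularity are interchangeable signals.
3. **Network centrality.** Stage 3 partitions the co-occurrence graph into
   communities and keeps, per community, the genes most exclusively tied to
   it: the corrected degree of domesticity
   z_d = (z_in + ε)/(z_out + ε). Selecting *per community* rather than
   globally forces the panel to cover all co-expression groups instead of
   oversampling one.

The final classifier is deliberately generic (RBF-kernel SVM, grid-tuned by
stratified cross-validation on the training partition only); the pipeline's
claim is about the panel, not the classifier.

### Assumptions

- Exactly two classes; every stage (scoring, class-mean profiles, SVM
  tuning) uses the training partition only, so the test partition stays
  untouched until the final evaluation.
- Expression values are numeric with no missing entries; no normalisation
  is applied internally — the caller normalises as appropriate for their
  platform.
- Genes with zero variance are legal everywhere (they score 0 in the
  filters and are eliminated early by RFE).

## Tunable parameters

| Parameter | Default | Meaning and rationale |
| --- | --- | --- |
| `candidate_percent` | 0.05 | fraction of genes kept after rank merging; ceiling rounding so a nonzero percent never selects zero genes |
| `n_bins` | 10 | equal-frequency bins for CS/IG discretization |
| `rf_trees` | 500 | forest size for Gini importances; seeded |
| `svm_cost` | 1.0 | fixed linear-SVM cost during SQRT-RFE elimination |
| `k_values` | (3, 4, 5) | one k-means run per entry; longer or repeated lists raise the consensus resolution R |
| `kmeans_restarts` | 10 | k-means++ restarts per run |
| `edge_threshold` | 1 | minimum co-occurrence count for a graph edge; 1 keeps every observed co-membership (dense graph, documented below) |
| `cd_method` | louvain | louvain / walktrap (4 steps, modularity cut) / infomap, all weight-aware and seeded |
| `epsilon` | 1e-6 | z_d correction; any ε < 1/max_degree² ranks all z_out = 0 genes above all genes with an outside edge while ordering the former by z_in |
| `biomarker_percent` | 0.10 | per-community retention, ceiling rounding |
| cost grid | 2⁻²…2⁸ | SVM tuning, 10-fold stratified CV |
| gamma grid | 2⁻⁶…2⁶ / p | feature-scaled: centred on 1/p, the natural RBF scale for p unit-variance features. A fixed absolute grid stops being informative once p reaches thousands (exp(−γ·2p) underflows the kernel to the identity), which would cripple the whole-feature baseline this package must support |

Ties in CV accuracy resolve to the smallest cost, then the smallest gamma.

## Tie handling in biomarker selection

In dense co-occurrence graphs whole communities are often mutually tied on
z_d (cliques with z_out = 0, identical z_in). How those ties break decides
which genes are reported, so it is a first-class design choice, not a
detail. `select_biomarkers` uses a *stable* sort on z_d and the pipeline
passes the metric table in combined-rank order, so ties fall back on the
stage-1 evidence. The alternative — breaking ties by gene identifier —
selects runs of adjacent genes, which in blocked-correlation data means
highly redundant panels; on the simulated benchmark that choice costs
roughly 10 accuracy points. Rank fallback keeps the panel anchored to
measured evidence and is reproducible.

## The simulator

`snfs.simulate` generates the two-group blocked-dependency design: p genes
in independent blocks of equal size, within-block covariance
Σᵢⱼ = ρ^|i−j| with +ρ in the first half of the blocks and −ρ in the rest,
and a constant shift (default +0.5) added to the first `n_shifted_genes`
genes of class-2 samples. Samples are drawn via the symmetric (spectral)
square root of each block covariance — the spectral root rather than a
Cholesky factor, so the documented stream order (block by block, training
partition before test) pins down every draw given the seed. Both
partitions use the same block sign pattern. Defaults encode the benchmark
design used throughout the tests: 10,000 genes in 100 blocks of 100, 200
shifted genes (the first two blocks), 200 training and 600 test samples,
balanced classes, ρ ∈ {0.60, 0.90}.

What it emulates: realistic feature dimensionality, heavy within-block
correlation (redundant probes), weak per-gene effects (t ≈ 3.5 at the
default shift), and a known ground truth. What it does not emulate:
platform noise (probe effects, background, saturation), heavy-tailed or
skewed expression, batch structure, or label noise. Passing the benchmark
therefore shows the pipeline recovers structured Gaussian signal at
realistic dimensions — not that it is robust to microarray artefacts.

## Numerical choices

- **SQRT-RFE Gram downdating.** The linear-SVM eliminations precompute the
  sample Gram matrix once and subtract each eliminated batch's outer
  product (K ← K − X_elim·X_elimᵀ). This is algebraically identical to
  refitting on the raw surviving features and reduces the elimination cost
  at p = 10⁴ from minutes to seconds. Weight recovery uses the dual
  coefficients on the support vectors.
- **Kernel-grid tuning.** SVM tuning precomputes the pairwise squared
  distances once; each gamma is a single elementwise exponentiation and
  each (fold, cost) fit runs on the precomputed kernel. The full
  143-point grid at 10 folds costs seconds even on 10,000 features.
- **Discretization.** Equal-frequency binning with quantile edges; tied
  values never split across an edge, making codes invariant to sample
  permutation, and constant genes map to a single category.
- **Degenerate inputs.** Zero-variance genes score 0; empty classes,
  percents outside (0, 1], ε ≤ 0, k exceeding the candidate count, and
  non-positive-definite covariances raise immediately with the offending
  quantity named.
- **Seeding.** A master seed fans out through blake2b hashes of
  (stage, combination) tags, all below 2³¹. Sweep combinations are
  therefore independent: adding or removing one never changes another's
  results. igraph's RNG is re-seeded before each community-detection call.

## Benchmark problem sizes

The acceptance-style tests run the full benchmark design (10,000 genes,
200/600 samples) over five seeds per correlation level — about two minutes
of compute — and the structural property suites use thousands of small
randomized fixtures. The worked example in the README uses a 2,000-gene
reduction of the same design purely for brevity.

## Known limitations

- Two classes only; the multiclass generalisation would need multiclass
  scorers and a revised class-mean geometry.
- With two classes the clustering operates on 2-D profiles; communities
  mirror the plane's geometry, and the selection outcome is sensitive to
  tie handling (see above) — a different tie policy changes the panel, and
  published variants of this pipeline are frequently silent on it.
- The per-community quota means pure-noise communities still contribute
  their share of the panel; the method trades some precision for coverage
  by construction.
- `edge_threshold = 1` yields dense graphs on consensus-heavy data;
  raising it sparsifies the graph but changes community counts and hence
  panel sizes (ceiling per community).
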