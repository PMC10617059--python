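# snfs — social network feature selection for expression biomarkers

`snfs` selects small, interpretable biomarker panels from high-dimensional
two-class gene-expression data (bulk microarray or RNA-seq style matrices,
typically thousands of genes and tens to hundreds of samples) and evaluates
them with a tuned support-vector machine. It is aimed at researchers who
want a reproducible hybrid feature-selection pipeline — filters, an embedded
SVM ranker, consensus clustering and network community analysis in one
place — plus a matching synthetic-data generator, so every stage can be
exercised and benchmarked without any external download.

## The method

The pipeline has three stages followed by hold-out evaluation:

1. **Rank aggregation.** Genes are scored by two or more of: chi-square
   (CS) and information-gain (IG) filters on equal-frequency-discretized
   expression, random-forest Gini importance (RF), and linear-SVM recursive
   feature elimination with square-root batch sizes (SVM SQRT-RFE, removing
   ⌊√remaining⌋ genes per refit). Rankings are merged by mean rank and the
   top percentage (e.g. 5%) becomes the candidate set.
2. **Co-occurrence network.** Each candidate is reduced to its class-mean
   profile (mean expression per class on the training samples) and k-means
   is run once for each k ∈ {3, 4, 5}. A weighted adjacency matrix counts,
   for every gene pair, in how many runs the two genes shared a cluster
   (entries 0…R, R = number of runs).
3. **Community selection.** The weighted graph is partitioned by Louvain,
   Walktrap or Infomap, and each gene *i* is scored by the **corrected
   degree of domesticity**

   z_d(i) = (z_in(i) + ε) / (z_out(i) + ε),

   where z_in and z_out count the gene's edges inside and outside its own
   community. The plain ratio z_in/z_out is undefined for genes with no
   outside edge; the ε correction (default 10⁻⁶) keeps it finite and makes
   those fully "domestic" genes comparable with each other. The top
   percentage (e.g. 10%) of each community by z_d is the biomarker panel.

An RBF-kernel SVM is then grid-tuned by cross-validation on the training
samples only and scored on the held-out test set (accuracy, sensitivity,
specificity, AUC).

The package also ships the blocked-covariance simulator used for
benchmarking: p genes in independent blocks with within-block covariance
Σᵢⱼ = ρ^|i−j| (sign alternating between block halves) and an additive mean
shift on the first genes of class 2 — so the truly informative genes are
known by construction.

## Worked example

```python
from snfs import SNFS
from snfs.simulate import SimulationConfig, generate_dataset

cfg = SimulationConfig(n_genes=2000, n_blocks=20, block_size=100,
                       n_positive_blocks=10, rho=0.6,
                       n_train=120, n_test=300, seed=42)
train, test = generate_dataset(cfg)
result = SNFS(train, test, fs_methods=("svm_sqrt_rfe", "rf"),
              cd_method="louvain", candidate_percent=0.05).fit(seed=42)
print(result.summary())
```

prints

```
Social network feature selection - results
==============================================
Feature selection : SVM SQRT-RFE+RF
Community method  : Louvain
Candidates        : 100 (5% of 2000 genes)
Communities       : 4 (sizes [26, 41, 16, 17])
Biomarkers        : 12 (10% per community by z_d, eps=1e-06)
SVM (RBF)         : cost=64, gamma=0.00521, CV acc=0.917
----------------------------------------------
Test accuracy     : 0.700
Test sensitivity  : 0.627
Test specificity  : 0.773
Test AUC          : 0.781
Train accuracy    : 0.967
Positive label    : 2
```

Reading it: of 2,000 simulated genes the rank-merge stage kept 100
candidates, the network stage grouped them into four communities, and the
top 10% of each community by corrected degree of domesticity gives a
12-gene panel. The SVM tuned on those 12 genes classifies 70% of the 300
held-out samples correctly with AUC 0.78 — using 0.6% of the genes.
`result` also carries every intermediate artifact (rankings, candidate set,
adjacency, graph, partition, per-gene metric table) for inspection, and
`snfs.sweep(...)` runs the full grid of six scorer pairs × three community
methods, returning the study-shaped results table.

From the shell, the same pipeline is available as:

```bash
snfs simulate --rho 0.6 --seed 1 --out-prefix sim/
snfs run --config cfg.yaml        # full combination sweep
snfs baseline --config cfg.yaml   # tuned SVM on all genes, no selection
```

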