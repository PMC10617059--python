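"""Stage 1: per-gene feature scoring, rank aggregation, candidate selection.

Four scorers are provided — chi-square (CS) and information gain (IG) filters
on equal-frequency-discretized expression, random-forest impurity importance
(RF), and linear SVM recursive feature elimination with square-root batch
sizes (SVM SQRT-RFE).  Any two or more rankings are merged by mean rank
(Borda-style) and the top percentage of the combined list becomes the
candidate set handed to the network stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from ._util import derive_seed
from .dataset import ExpressionDataset

__all__ = [
    "RankedFeatureList",
    "CandidateSet",
    "discretize",
    "chi_square_scores",
    "info_gain_scores",
    "rf_importance_scores",
    "svm_sqrt_rfe_ranking",
    "merge_ranks",
    "select_candidates",
]

METHODS = ("cs", "ig", "rf", "svm_sqrt_rfe")


@dataclass
class RankedFeatureList:
    """Genes ordered best to worst by one scoring method.

    ``scores`` align with ``gene_ids``; when ``higher_is_better`` is False
    (RFE elimination ranks, merged mean ranks) smaller scores are better and
    the stored scores are non-decreasing instead of non-increasing.
    """

    method: str
    gene_ids: np.ndarray
    scores: np.ndarray
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.gene_ids.size != self.scores.size:
            raise ValueError("gene_ids and scores must align")

    def __len__(self) -> int:
        return self.gene_ids.size

    def ranks(self) -> pd.Series:
        """Rank position per gene, 1 = best."""
        return pd.Series(np.arange(1, len(self) + 1), index=self.gene_ids, name=self.method)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.gene_ids, "score": self.scores, "rank": np.arange(1, len(self) + 1)}
        )


@dataclass
class CandidateSet:
    """Top fraction of the combined ranking, in combined-rank order."""

    gene_ids: np.ndarray
    percent: float
    source_methods: tuple = ()

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)

    def __len__(self) -> int:
        return self.gene_ids.size


def _ordered(method: str, gene_ids: np.ndarray, scores: np.ndarray,
             higher_is_better: bool = True) -> RankedFeatureList:
    """Sort by score (best first), ties broken by gene id (stable)."""
    key = -scores if higher_is_better else scores
    order = np.lexsort((gene_ids, key))
    return RankedFeatureList(method, gene_ids[order], scores[order], higher_is_better)


# -- discretization -------------------------------------------------------

def discretize(values, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency bin codes for one gene (or a genes x samples matrix).

    Bin edges are the interior quantiles, and tied values never split across
    an edge, so the coding is invariant to sample permutation and a constant
    gene maps to a single category.  The number of occupied bins may be below
    ``n_bins`` when ties dominate.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = np.asarray(values, dtype=float)
    single = v.ndim == 1
    mat = v[None, :] if single else v
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(mat, qs, axis=1)  # (n_bins-1, p)
    codes = (mat[:, :, None] >= edges.T[:, None, :]).sum(axis=2)
    return codes[0] if single else codes


def _contingency_counts(data: ExpressionDataset, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    classes = data.classes
    if classes.size != 2:
        raise ValueError(f"two-class labels required, found {classes.tolist()}")
    y = (data.labels == classes[1]).astype(np.int64)
    codes = discretize(data.values, n_bins).astype(np.int64)
    p = data.n_genes
    flat = (np.arange(p)[:, None] * (n_bins * 2) + codes * 2 + y[None, :]).ravel()
    counts = np.bincount(flat, minlength=p * n_bins * 2).reshape(p, n_bins, 2)
    return counts.astype(float), classes


def chi_square_scores(data: ExpressionDataset, n_bins: int = 10) -> RankedFeatureList:
    """Pearson chi-square of the discretized-gene x class table, per gene.

    A constant gene yields a one-row table and a statistic of 0.
    """
    counts, _ = _contingency_counts(data, n_bins)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    n = data.n_samples
    expected = row * col / n
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return _ordered("cs", data.gene_ids, cells.sum(axis=(1, 2)))


def info_gain_scores(data: ExpressionDataset, n_bins: int = 10) -> RankedFeatureList:
    """Mutual information H(class) - H(class | discretized gene), in bits."""
    counts, _ = _contingency_counts(data, n_bins)
    n = data.n_samples
    pc = counts[0].sum(axis=0) / n  # class marginals — identical across genes
    pc = pc[pc > 0]
    h_class = -(pc * np.log2(pc)).sum()
    row = counts.sum(axis=2)[:, :, None]  # (p, n_bins, 1)
    safe_counts = np.where(counts > 0, counts, 1.0)
    safe_row = np.where(row > 0, row, 1.0)
    h_cond = -(counts * (np.log2(safe_counts) - np.log2(safe_row))).sum(axis=(1, 2)) / n
    ig = np.maximum(h_class - h_cond, 0.0)
    return _ordered("ig", data.gene_ids, ig)


def rf_importance_scores(data: ExpressionDataset, n_trees: int = 500,
                         seed: int = 0) -> RankedFeatureList:
    """Random-forest Gini importance per gene, deterministic given the seed."""
    classes, counts = np.unique(data.labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least 2 samples each")
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(data.X, data.labels)
    return _ordered("rf", data.gene_ids, rf.feature_importances_)


def svm_sqrt_rfe_ranking(data: ExpressionDataset, svm_cost: float = 1.0) -> RankedFeatureList:
    """SVM recursive feature elimination with square-root batch sizes.

    A linear SVM is refit on the surviving genes; genes with the smallest
    squared weights are eliminated in batches of floor(sqrt(remaining))
    (minimum 1) until none remain.  The final ranking is the reverse
    elimination order, with within-batch order by weight.  The linear Gram
    matrix is precomputed once and downdated as columns are eliminated, which
    reproduces the refit-on-raw-features ranking at a fraction of the cost.
    """
    if data.n_genes < 2:
        raise ValueError("need at least 2 genes")
    if data.classes.size != 2:
        raise ValueError("two-class labels required")
    X = np.ascontiguousarray(data.X)
    y = data.labels
    surviving = np.arange(data.n_genes)
    K = X @ X.T
    eliminated: list[int] = []
    iteration = 0
    while surviving.size > 0:
        iteration += 1
        if surviving.size == 1:
            eliminated.append(int(surviving[0]))
            break
        try:
            clf = SVC(C=svm_cost, kernel="precomputed")
            clf.fit(K, y)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"SVM fit failed at RFE iteration {iteration}: {exc}") from exc
        w = clf.dual_coef_[0] @ X[clf.support_][:, surviving]
        w2 = w**2
        n_elim = max(1, math.floor(math.sqrt(surviving.size)))
        # worst first within the batch; ties broken by gene id for stability
        order = np.lexsort((data.gene_ids[surviving], w2))
        batch = surviving[order[:n_elim]]
        eliminated.extend(int(g) for g in batch)
        cols = X[:, batch]
        K -= cols @ cols.T
        keep = np.ones(surviving.size, dtype=bool)
        keep[order[:n_elim]] = False
        surviving = surviving[keep]
    ranking = np.array(eliminated[::-1], dtype=int)
    return RankedFeatureList(
        "svm_sqrt_rfe",
        data.gene_ids[ranking],
        np.arange(1, data.n_genes + 1, dtype=float),
        higher_is_better=False,
    )


# -- aggregation ----------------------------------------------------------

def merge_ranks(lists) -> RankedFeatureList:
    """Combine rankings by arithmetic mean of rank positions (1 = best).

    All lists must cover the same gene set; the output is sorted ascending by
    mean rank with ties broken lexicographically by gene id.
    """
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("need at least two rankings to merge")
    base = set(lists[0].gene_ids)
    for rl in lists[1:]:
        other = set(rl.gene_ids)
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ValueError(f"rankings cover different gene sets; difference: {diff[:10]}")
    ranks = pd.concat([rl.ranks() for rl in lists], axis=1)
    mean_rank = ranks.mean(axis=1)
    method = "+".join(rl.method for rl in lists)
    return _ordered(method, mean_rank.index.to_numpy().astype(str),
                    mean_rank.to_numpy(), higher_is_better=False)


def select_candidates(combined: RankedFeatureList, percent: float) -> CandidateSet:
    """Keep the top ceil(percent x p) genes of the combined list."""
    if not 0 < percent <= 1:
        raise ValueError(f"percent must lie in (0, 1], got {percent}")
    k = math.ceil(percent * len(combined))
    return CandidateSet(combined.gene_ids[:k], percent,
                        tuple(combined.method.split("+")))
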