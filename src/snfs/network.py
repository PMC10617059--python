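"""Stage 2: class-mean reduction and the k-means co-occurrence network.

Each candidate gene is reduced to its mean expression per class on the
training samples (a 2-vector for two-class data).  k-means is then run once
for every k in ``k_values`` (default 3, 4, 5) on these profiles, and a
symmetric integer adjacency matrix counts, for every gene pair, in how many
of the runs the two genes landed in the same cluster.  Entries therefore
range from 0 to the number of repetitions R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ._util import derive_seed
from .dataset import ExpressionDataset
from .ranking import CandidateSet

__all__ = ["WeightedAdjacency", "class_mean_profile", "cooccurrence_adjacency"]


@dataclass
class WeightedAdjacency:
    """Symmetric co-occurrence count matrix over candidate genes."""

    matrix: np.ndarray
    gene_ids: np.ndarray
    k_values: tuple

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.k_values = tuple(self.k_values)
        n = self.gene_ids.size
        if self.matrix.shape != (n, n):
            raise ValueError("adjacency must be square over the gene ids")

    @property
    def repetitions(self) -> int:
        return len(self.k_values)

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.gene_ids.size, k=1)
        w = self.matrix[iu]
        keep = w > 0
        return pd.DataFrame(
            {
                "gene_i": self.gene_ids[iu[0][keep]],
                "gene_j": self.gene_ids[iu[1][keep]],
                "weight": w[keep],
            }
        )

    def write_tsv(self, edge_path, dense_path=None) -> None:
        self.to_edge_list().to_csv(edge_path, sep="\t", index=False)
        if dense_path is not None:
            pd.DataFrame(self.matrix, index=self.gene_ids, columns=self.gene_ids).to_csv(
                dense_path, sep="\t", index_label="gene_id"
            )


def class_mean_profile(train: ExpressionDataset, candidates: CandidateSet) -> pd.DataFrame:
    """Mean expression of each candidate gene per class, training data only.

    Returns a DataFrame indexed by candidate gene (in candidate order) with
    one column per class label.
    """
    classes = train.classes
    if classes.size != 2:
        raise ValueError("two classes required")
    sub = train.subset(candidates.gene_ids)
    cols = {}
    for c in classes:
        mask = sub.labels == c
        if not mask.any():
            raise ValueError(f"class {c!r} has no training samples")
        cols[c] = sub.values[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=sub.gene_ids)


def cooccurrence_adjacency(profile: pd.DataFrame, k_values=(3, 4, 5),
                           seed: int = 0, n_init: int = 10) -> WeightedAdjacency:
    """Count gene co-clusterings over one seeded k-means run per k.

    Each run uses k-means++ initialization with ``n_init`` restarts on the
    raw class-mean profile rows (Euclidean distance, no rescaling); runs are
    seeded per (position, k) from ``seed``.
    """
    X = profile.to_numpy(dtype=float)
    n = X.shape[0]
    for k in k_values:
        if not 2 <= k <= n:
            raise ValueError(f"each k must lie in [2, {n}], got {k}")
    A = np.zeros((n, n), dtype=int)
    for i, k in enumerate(k_values):
        km = KMeans(n_clusters=int(k), n_init=n_init,
                    random_state=derive_seed(seed, "kmeans", i, k))
        labels = km.fit_predict(X)
        A += labels[:, None] == labels[None, :]
    np.fill_diagonal(A, 0)
    return WeightedAdjacency(A, profile.index.to_numpy().astype(str), tuple(k_values))
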