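"""Stage 3: community detection and the corrected degree of domesticity.

The weighted co-occurrence matrix becomes an undirected graph; a community
detection algorithm (Louvain, Walktrap or Infomap, all weight-aware)
partitions the genes, and each gene i is scored by the corrected degree of
domesticity

    z_d(i) = (z_in(i) + eps) / (z_out(i) + eps)

where z_in counts the gene's edges inside its own community and z_out the
edges leaving it.  The plain ratio z_in/z_out is undefined for nodes with no
outside edge; the eps correction keeps it finite and — for any
eps < 1/max_degree^2 — ranks all zero-z_out nodes above every node with an
outside edge while still ordering the zero-z_out nodes among themselves by
z_in.  The top percentage of each community by z_d is returned as the
biomarker set.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd

from .network import WeightedAdjacency

__all__ = [
    "CommunityPartition",
    "BiomarkerSet",
    "build_graph",
    "detect_communities",
    "corrected_degree_of_domesticity",
    "select_biomarkers",
    "write_graphml",
]

CD_METHODS = ("louvain", "walktrap", "infomap")


@dataclass
class CommunityPartition:
    """Community id (dense, 1-based) per candidate gene."""

    gene_ids: np.ndarray
    membership: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.membership = np.asarray(self.membership, dtype=int)
        if self.gene_ids.size != self.membership.size:
            raise ValueError("one community per gene required")
        ids = np.unique(self.membership)
        if ids.size and not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("community ids must be dense from 1")

    @property
    def n_communities(self) -> int:
        return int(self.membership.max(initial=0))

    def sizes(self) -> pd.Series:
        return pd.Series(self.membership).value_counts().sort_index()


@dataclass
class BiomarkerSet:
    """Final selected genes with per-community provenance."""

    gene_ids: np.ndarray
    per_community: dict
    percent: float
    metric: str = "z_d"

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)

    def __len__(self) -> int:
        return self.gene_ids.size


def build_graph(adj: WeightedAdjacency, edge_threshold: int = 1) -> ig.Graph:
    """Undirected weighted graph with an edge wherever the count >= threshold."""
    if edge_threshold < 1:
        raise ValueError("edge_threshold must be >= 1")
    n = adj.gene_ids.size
    iu = np.triu_indices(n, k=1)
    w = adj.matrix[iu]
    keep = w >= edge_threshold
    edges = list(zip(iu[0][keep].tolist(), iu[1][keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = w[keep].tolist()
    g.vs["name"] = adj.gene_ids.tolist()
    return g


def detect_communities(graph: ig.Graph, method: str = "louvain",
                       seed: int = 0) -> CommunityPartition:
    """Weight-aware community detection; isolated nodes become singletons.

    ``louvain`` is multilevel modularity optimization, ``walktrap`` random-walk
    agglomeration (step length 4) cut at maximum modularity, ``infomap`` the
    map equation.  The igraph RNG is seeded before each call, so stochastic
    methods are reproducible.
    """
    if method not in CD_METHODS:
        raise ValueError(f"unknown community detection method {method!r}; "
                         f"choose from {CD_METHODS}")
    ig.set_random_number_generator(random.Random(seed))
    weights = graph.es["weight"] if graph.ecount() else None
    if method == "louvain":
        clustering = graph.community_multilevel(weights=weights)
    elif method == "walktrap":
        clustering = graph.community_walktrap(weights=weights, steps=4).as_clustering()
    else:
        clustering = graph.community_infomap(edge_weights=weights)
    membership = np.asarray(clustering.membership, dtype=int)
    # densify ids (igraph ids are already dense 0-based; keep defensive remap)
    _, dense = np.unique(membership, return_inverse=True)
    return CommunityPartition(np.asarray(graph.vs["name"], dtype=str), dense + 1, method)


def corrected_degree_of_domesticity(graph: ig.Graph, partition: CommunityPartition,
                                    epsilon: float = 1e-6) -> pd.DataFrame:
    """Per-gene network metrics with respect to the community partition.

    Returns a DataFrame indexed by gene with columns: community, z_in, z_out,
    z_d, degree, weighted_degree, intra_centrality, out_centrality, coverage.
    z_in/z_out count unweighted edges; weights enter community detection only.
    Companion centralities normalize z_in by (community size - 1) and z_out by
    (n - community size); coverage is z_in / degree with 0/0 -> 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    names = np.asarray(graph.vs["name"], dtype=str)
    if not np.array_equal(names, partition.gene_ids):
        raise ValueError("partition does not match graph vertex order")
    n = graph.vcount()
    member = partition.membership
    z_in = np.zeros(n, dtype=int)
    z_out = np.zeros(n, dtype=int)
    wdeg = np.zeros(n, dtype=float)
    if graph.ecount():
        e = np.asarray(graph.get_edgelist(), dtype=int)
        w = np.asarray(graph.es["weight"], dtype=float)
        same = member[e[:, 0]] == member[e[:, 1]]
        for col in (0, 1):
            np.add.at(z_in, e[same, col], 1)
            np.add.at(z_out, e[~same, col], 1)
            np.add.at(wdeg, e[:, col], w)
    z_d = (z_in + epsilon) / (z_out + epsilon)
    sizes = partition.sizes().reindex(member).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        intra = np.where(sizes > 1, z_in / np.maximum(sizes - 1, 1), 0.0)
        out_c = np.where(n > sizes, z_out / np.maximum(n - sizes, 1), 0.0)
        deg = z_in + z_out
        coverage = np.where(deg > 0, z_in / np.maximum(deg, 1), 0.0)
    return pd.DataFrame(
        {
            "community": member,
            "z_in": z_in,
            "z_out": z_out,
            "z_d": z_d,
            "degree": deg,
            "weighted_degree": wdeg,
            "intra_centrality": intra,
            "out_centrality": out_c,
            "coverage": coverage,
        },
        index=pd.Index(names, name="gene_id"),
    )


def select_biomarkers(metrics: pd.DataFrame, percent: float) -> BiomarkerSet:
    """Top ceil(percent x size) genes of each community by z_d.

    The sort is stable, so genes tied on z_d keep the row order of
    ``metrics``.  The pipeline passes the table in combined-rank order, which
    makes the stage-1 ranking the tie-breaker: dense communities are full of
    mutually tied nodes (identical z_in, z_out = 0), and falling back to the
    feature-selection evidence there picks informative genes instead of an
    arbitrary-by-identifier subset.
    """
    if not 0 < percent <= 1:
        raise ValueError(f"percent must lie in (0, 1], got {percent}")
    selected: list[str] = []
    per_community: dict[int, int] = {}
    for comm, grp in metrics.groupby("community", sort=True):
        k = math.ceil(percent * len(grp))
        top = (
            grp.reset_index()
            .sort_values("z_d", ascending=False, kind="mergesort")
            .head(k)
        )
        selected.extend(top["gene_id"].tolist())
        per_community[int(comm)] = k
    return BiomarkerSet(np.array(selected, dtype=str), per_community, percent)


def write_graphml(graph: ig.Graph, partition: CommunityPartition, path) -> None:
    """Export the weighted gene graph with a per-node community attribute."""
    g = graph.copy()
    g.vs["community"] = partition.membership.tolist()
    g.write_graphml(str(path))
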