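"""The SNFS model object: configure once, ``fit()`` to run the pipeline.

``SNFS`` bundles the three pipeline stages plus hold-out evaluation behind a
statsmodels-style interface: the constructor takes the data and the method
configuration, ``fit(seed)`` runs ranking -> co-occurrence network ->
communities -> biomarker selection -> tuned RBF-SVM evaluation, and the
returned :class:`SNFSResults` carries every intermediate artifact plus a
``summary()`` table.  :func:`sweep` runs the study's full combination grid
(six feature-selection pairs x three community-detection methods), reusing
each base ranking across combinations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import derive_seed
from .communities import (
    CD_METHODS,
    build_graph,
    corrected_degree_of_domesticity,
    detect_communities,
    select_biomarkers,
)
from .dataset import ExpressionDataset
from .evaluate import (
    EvaluationReport,
    SplitSpec,
    evaluate_classifier,
    stratified_holdout_split,
    tune_rbf_svm,
)
from .network import class_mean_profile, cooccurrence_adjacency
from .ranking import (
    METHODS,
    chi_square_scores,
    info_gain_scores,
    merge_ranks,
    rf_importance_scores,
    select_candidates,
    svm_sqrt_rfe_ranking,
)

__all__ = ["SNFS", "SNFSResults", "sweep", "whole_feature_baseline",
           "DEFAULT_FS_PAIRS", "FS_LABELS", "CD_LABELS"]

DEFAULT_FS_PAIRS = (
    ("svm_sqrt_rfe", "ig"),
    ("svm_sqrt_rfe", "cs"),
    ("svm_sqrt_rfe", "rf"),
    ("ig", "cs"),
    ("ig", "rf"),
    ("cs", "rf"),
)

FS_LABELS = {"svm_sqrt_rfe": "SVM SQRT-RFE", "cs": "CS", "ig": "IG", "rf": "RF"}
CD_LABELS = {"louvain": "Louvain", "walktrap": "Walktrap", "infomap": "Infomap"}

RESULT_COLUMNS = ["FS", "CD", "CN", "Acc", "Sens", "Spe", "AUC", "FN"]


class SNFS:
    """Social network feature selection on a two-class expression dataset.

    Parameters
    ----------
    train, test : ExpressionDataset
        If ``test`` is None, ``train`` is split according to ``split``.
    fs_methods : feature scorers merged in stage 1 (two or more of
        ``cs``, ``ig``, ``rf``, ``svm_sqrt_rfe``).
    candidate_percent : fraction of genes kept after rank merging.
    k_values : cluster counts for the repeated k-means co-occurrence runs.
    cd_method : ``louvain`` | ``walktrap`` | ``infomap``.
    biomarker_percent : fraction of each community kept by z_d.
    epsilon : correction constant of the corrected degree of domesticity.
    """

    def __init__(self, train: ExpressionDataset, test: ExpressionDataset | None = None, *,
                 fs_methods=("svm_sqrt_rfe", "rf"), candidate_percent: float = 0.05,
                 n_bins: int = 10, rf_trees: int = 500, svm_cost: float = 1.0,
                 k_values=(3, 4, 5), kmeans_restarts: int = 10, edge_threshold: int = 1,
                 cd_method: str = "louvain", epsilon: float = 1e-6,
                 biomarker_percent: float = 0.10, cost_grid=None, gamma_grid=None,
                 n_folds: int = 10, positive_label: str | None = None,
                 split: SplitSpec | None = None):
        if test is None:
            split = split or SplitSpec()
            train, test = stratified_holdout_split(train, split)
        for m in fs_methods:
            if m not in METHODS:
                raise ValueError(f"unknown feature selection method {m!r}")
        if cd_method not in CD_METHODS:
            raise ValueError(f"unknown community detection method {cd_method!r}")
        if train.classes.size != 2:
            raise ValueError("SNFS requires exactly two classes")
        self.train = train
        self.test = test
        self.fs_methods = tuple(fs_methods)
        self.candidate_percent = candidate_percent
        self.n_bins = n_bins
        self.rf_trees = rf_trees
        self.svm_cost = svm_cost
        self.k_values = tuple(k_values)
        self.kmeans_restarts = kmeans_restarts
        self.edge_threshold = edge_threshold
        self.cd_method = cd_method
        self.epsilon = epsilon
        self.biomarker_percent = biomarker_percent
        self.cost_grid = cost_grid
        self.gamma_grid = gamma_grid
        self.n_folds = n_folds
        self.positive_label = positive_label

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels, test_df: pd.DataFrame | None = None,
                       test_labels=None, **kwargs) -> "SNFS":
        """Build from genes x samples DataFrames (and labels per column)."""
        train = ExpressionDataset.from_dataframe(df, labels)
        test = None
        if test_df is not None:
            test = ExpressionDataset.from_dataframe(test_df, test_labels)
        return cls(train, test, **kwargs)

    # -- stage runners ----------------------------------------------------

    def compute_ranking(self, method: str, seed: int = 0):
        """Run one base feature scorer; seeds depend on the method only, so
        rankings can be shared across sweep combinations."""
        if method == "cs":
            return chi_square_scores(self.train, self.n_bins)
        if method == "ig":
            return info_gain_scores(self.train, self.n_bins)
        if method == "rf":
            return rf_importance_scores(self.train, self.rf_trees,
                                        seed=derive_seed(seed, "rank", "rf"))
        if method == "svm_sqrt_rfe":
            return svm_sqrt_rfe_ranking(self.train, self.svm_cost)
        raise ValueError(f"unknown feature selection method {method!r}")

    def fit(self, seed: int = 0, rankings: dict | None = None) -> "SNFSResults":
        """Run the full pipeline and evaluate on the held-out test set."""
        rankings = dict(rankings or {})
        ranked = [rankings.get(m) or self.compute_ranking(m, seed) for m in self.fs_methods]
        combined = merge_ranks(ranked)
        candidates = select_candidates(combined, self.candidate_percent)
        profile = class_mean_profile(self.train, candidates)
        fs_tag = "+".join(self.fs_methods)
        adjacency = cooccurrence_adjacency(
            profile, self.k_values,
            seed=derive_seed(seed, "net", fs_tag), n_init=self.kmeans_restarts,
        )
        graph = build_graph(adjacency, self.edge_threshold)
        partition = detect_communities(
            graph, self.cd_method, seed=derive_seed(seed, "cd", fs_tag, self.cd_method)
        )
        metrics = corrected_degree_of_domesticity(graph, partition, self.epsilon)
        biomarkers = select_biomarkers(metrics, self.biomarker_percent)
        params = tune_rbf_svm(
            self.train, biomarkers.gene_ids, self.cost_grid, self.gamma_grid,
            self.n_folds, seed=derive_seed(seed, "tune", fs_tag, self.cd_method),
        )
        metadata = {
            "FS": "+".join(FS_LABELS[m] for m in self.fs_methods),
            "CD": CD_LABELS[self.cd_method],
            "CN": partition.n_communities,
            "seed": seed,
        }
        report = evaluate_classifier(self.train, self.test, biomarkers.gene_ids,
                                     params, self.positive_label, metadata)
        return SNFSResults(model=self, seed=seed, rankings={m: r for m, r in zip(self.fs_methods, ranked)},
                           combined_ranking=combined, candidates=candidates,
                           profile=profile, adjacency=adjacency, graph=graph,
                           partition=partition, node_metrics=metrics,
                           biomarkers=biomarkers, params=params, report=report)


@dataclass
class SNFSResults:
    """Everything one SNFS run produced, stage by stage."""

    model: SNFS
    seed: int
    rankings: dict
    combined_ranking: object
    candidates: object
    profile: pd.DataFrame
    adjacency: object
    graph: object
    partition: object
    node_metrics: pd.DataFrame
    biomarkers: object
    params: dict
    report: EvaluationReport

    @property
    def selected_genes(self) -> np.ndarray:
        return self.biomarkers.gene_ids

    def metrics_table(self) -> pd.DataFrame:
        table = self.node_metrics.copy()
        table["selected"] = table.index.isin(self.biomarkers.gene_ids)
        return table

    def summary(self) -> str:
        r = self.report
        m = self.model
        lines = [
            "Social network feature selection - results",
            "=" * 46,
            f"Feature selection : {'+'.join(FS_LABELS[x] for x in m.fs_methods)}",
            f"Community method  : {CD_LABELS[m.cd_method]}",
            f"Candidates        : {len(self.candidates)} "
            f"({m.candidate_percent:.0%} of {m.train.n_genes} genes)",
            f"Communities       : {self.partition.n_communities} "
            f"(sizes {self.partition.sizes().tolist()})",
            f"Biomarkers        : {len(self.biomarkers)} "
            f"({m.biomarker_percent:.0%} per community by z_d, eps={m.epsilon:g})",
            f"SVM (RBF)         : cost={self.params['cost']:g}, "
            f"gamma={self.params['gamma']:.3g}, CV acc={self.params['cv_accuracy']:.3f}",
            "-" * 46,
            f"Test accuracy     : {r.accuracy:.3f}",
            f"Test sensitivity  : {r.sensitivity:.3f}",
            f"Test specificity  : {r.specificity:.3f}",
            f"Test AUC          : {r.auc:.3f}",
            f"Train accuracy    : {r.train_accuracy:.3f}",
            f"Positive label    : {r.positive_label}",
        ]
        return "\n".join(lines)


def whole_feature_baseline(train: ExpressionDataset, test: ExpressionDataset,
                           seed: int = 0, cost_grid=None, gamma_grid=None,
                           n_folds: int = 10,
                           positive_label: str | None = None) -> EvaluationReport:
    """Tuned RBF SVM on the entire feature set (no selection)."""
    params = tune_rbf_svm(train, None, cost_grid, gamma_grid, n_folds,
                          seed=derive_seed(seed, "tune", "baseline"))
    metadata = {"FS": "None (all genes)", "CD": "-", "CN": "-", "seed": seed}
    return evaluate_classifier(train, test, train.gene_ids, params,
                               positive_label, metadata)


def sweep(train: ExpressionDataset, test: ExpressionDataset | None = None, *,
          fs_pairs=DEFAULT_FS_PAIRS, cd_methods=CD_METHODS, seed: int = 0,
          on_error: str = "continue", **model_kwargs):
    """Run every (feature-selection pair) x (community method) combination.

    Base rankings are computed once per scorer and reused.  Errors in one
    combination are recorded and the sweep continues (``on_error='raise'``
    to propagate).  Returns ``(table, results, errors)`` where ``table`` is
    the study-shaped DataFrame with columns FS, CD, CN, Acc, Sens, Spe, AUC,
    FN.
    """
    base_model = SNFS(train, test, **model_kwargs)
    train, test = base_model.train, base_model.test
    needed = sorted({m for pair in fs_pairs for m in pair})
    rankings = {m: base_model.compute_ranking(m, seed) for m in needed}
    rows, results, errors = [], {}, {}
    for pair in fs_pairs:
        for cd in cd_methods:
            key = ("+".join(pair), cd)
            model = SNFS(train, test, fs_methods=pair, cd_method=cd, **{
                k: v for k, v in model_kwargs.items() if k not in ("fs_methods", "cd_method")
            })
            try:
                res = model.fit(seed, rankings=rankings)
            except Exception as exc:
                if on_error == "raise":
                    raise
                errors[key] = str(exc)
                continue
            results[key] = res
            rows.append(res.report.to_row())
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table, results, errors
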