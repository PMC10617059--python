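"""Expression-matrix container and delimited-text I/O.

The matrix is stored genes x samples (the common orientation of microarray
text exports); ``.X`` exposes the samples x genes view scikit-learn expects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionDataset:
    """A numeric expression matrix with per-sample class labels.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_samples)
    gene_ids, sample_ids : unique string identifiers matching the two axes
    labels : one class label per sample (two distinct values for a run)
    """

    values: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (self.gene_ids.size, self.sample_ids.size):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.gene_ids.size} gene ids x {self.sample_ids.size} sample ids"
            )
        if self.labels.size != self.sample_ids.size:
            raise ValueError("one label per sample required")
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if np.unique(ids).size != ids.size:
                raise ValueError(f"{name} ids are not unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    # -- views ------------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def X(self) -> np.ndarray:
        """Samples x genes view (scikit-learn orientation)."""
        return self.values.T

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, gene_ids) -> "ExpressionDataset":
        """Restrict to ``gene_ids``, preserving the requested order."""
        gene_ids = np.asarray(gene_ids, dtype=str)
        idx = pd.Index(self.gene_ids).get_indexer(gene_ids)
        if (idx < 0).any():
            missing = gene_ids[idx < 0]
            raise KeyError(f"genes not in dataset: {missing[:10].tolist()}")
        return ExpressionDataset(
            self.values[idx], gene_ids, self.sample_ids.copy(), self.labels.copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, labels) -> "ExpressionDataset":
        """Build from a genes x samples DataFrame plus a label per column."""
        labels = pd.Series(labels)
        if labels.index.dtype == object and set(labels.index) == set(df.columns):
            labels = labels.reindex(df.columns)
        return cls(df.to_numpy(dtype=float), df.index.to_numpy(), df.columns.to_numpy(), labels.to_numpy())

    @classmethod
    def read_tsv(cls, matrix_path, labels_path, samples_as_rows: bool = False,
                 sep: str = "\t") -> "ExpressionDataset":
        """Read a delimited matrix (first column = row id, header = column ids)
        and a two-column (sample id, class) label file."""
        df = pd.read_csv(matrix_path, sep=sep, index_col=0)
        if samples_as_rows:
            df = df.T
        lab = pd.read_csv(labels_path, sep=sep, index_col=0).iloc[:, 0]
        missing = set(map(str, df.columns)) - set(map(str, lab.index.astype(str)))
        if missing:
            raise ValueError(f"labels missing for samples: {sorted(missing)[:10]}")
        lab.index = lab.index.astype(str)
        lab = lab.reindex(df.columns.astype(str))
        return cls(df.to_numpy(dtype=float), df.index.to_numpy().astype(str),
                   df.columns.to_numpy().astype(str), lab.to_numpy().astype(str))

    def write_tsv(self, matrix_path, labels_path, sep: str = "\t") -> None:
        self.to_frame().to_csv(matrix_path, sep=sep, index_label="gene_id")
        pd.DataFrame({"sample_id": self.sample_ids, "class": self.labels}).to_csv(
            labels_path, sep=sep, index=False
        )
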