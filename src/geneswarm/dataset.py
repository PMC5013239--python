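"""The two-class expression container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledExpressionDataset"]


@dataclass
class LabeledExpressionDataset:
    """A genes x samples expression matrix with gene ids and binary labels.

    Rows are genes (microarray convention), columns are samples.  Labels are
    arbitrary hashable class tags, but exactly two distinct classes must be
    present.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    labels: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x samples)")
        if self.matrix.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"{self.matrix.shape[0]} matrix rows but {len(self.gene_ids)} gene ids"
            )
        if self.matrix.shape[1] != self.labels.shape[0]:
            raise ValueError(
                f"{self.matrix.shape[1]} matrix columns but {self.labels.shape[0]} labels"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        classes = sorted(set(self.labels.tolist()), key=str)
        if len(classes) != 2:
            raise ValueError(
                f"expected exactly two classes, found {len(classes)}: {classes}"
            )
        if self.sample_ids is None:
            self.sample_ids = [f"S{i+1}" for i in range(self.matrix.shape[1])]
        elif len(self.sample_ids) != self.matrix.shape[1]:
            raise ValueError("sample_ids length does not match matrix columns")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> tuple:
        return tuple(sorted(set(self.labels.tolist()), key=str))

    def restrict_genes(self, gene_ids: list[str]) -> "LabeledExpressionDataset":
        """Dataset restricted to the given genes, in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return LabeledExpressionDataset(
            matrix=self.matrix[rows],
            gene_ids=list(gene_ids),
            labels=self.labels.copy(),
            sample_ids=list(self.sample_ids),
        )
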