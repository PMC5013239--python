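"""Preprocessing: per-gene z-scoring and two-sample t-test gene ranking.

The wrapper search space is far too large at genome scale (2^n_genes
subsets), so genes are first ranked by a classical pooled-variance
two-sample t-test between the two classes and only the ``k`` genes with the
smallest p-values (k = 50 by default) are kept; these k genes define the
particle length of the downstream optimizers.

Note the filter is applied once, to all samples, before leave-one-out cross
validation — the protocol this package reproduces does the same, and the
resulting gene ranking therefore sees the test sample of every fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import LabeledExpressionDataset

__all__ = ["GeneRanking", "normalize", "t_test_rank", "select_top_k"]


@dataclass
class GeneRanking:
    """Genes ordered by ascending t-test p-value (ties by input position)."""

    gene_ids: list[str]
    t_statistics: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        self.t_statistics = np.asarray(self.t_statistics, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not (len(self.gene_ids) == self.t_statistics.size == self.p_values.size):
            raise ValueError("ranking fields must have equal lengths")
        if np.any(np.diff(self.p_values) < 0):
            raise ValueError("ranking must be sorted by ascending p-value")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "t_statistic": self.t_statistics,
                "p_value": self.p_values,
                "rank": np.arange(1, len(self.gene_ids) + 1),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def normalize(data: LabeledExpressionDataset) -> LabeledExpressionDataset:
    """Z-score each gene across samples (mean 0, sd 1, population sd).

    Zero-variance genes carry no class information on any scale and are
    mapped to all-zero rows rather than dividing by zero.
    """
    m = data.matrix
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0.0
    sd[flat] = 1.0
    out = (m - mean) / sd
    out[flat] = 0.0
    return LabeledExpressionDataset(
        matrix=out,
        gene_ids=list(data.gene_ids),
        labels=data.labels.copy(),
        sample_ids=list(data.sample_ids),
    )


def t_test_rank(data: LabeledExpressionDataset, welch: bool = False) -> GeneRanking:
    """Rank genes by a two-sided two-sample t-test between the classes.

    Pooled-variance (Student) test by default, Welch on request.  Genes with
    zero pooled variance (identical constant values in both classes) are
    assigned t = 0, p = 1 and fall to the bottom of the ranking.
    """
    a_class, b_class = data.classes
    ga = data.matrix[:, data.labels == a_class]
    gb = data.matrix[:, data.labels == b_class]
    if ga.shape[1] < 2 or gb.shape[1] < 2:
        raise ValueError("each class needs at least two samples for a t-test")
    t, p = stats.ttest_ind(ga, gb, axis=1, equal_var=not welch)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    p = np.where(np.isnan(p), 1.0, np.asarray(p))
    order = np.lexsort((np.arange(len(p)), p))  # ascending p, ties by index
    return GeneRanking(
        gene_ids=[data.gene_ids[i] for i in order],
        t_statistics=t[order],
        p_values=p[order],
    )


def select_top_k(ranking: GeneRanking, k: int = 50) -> list[str]:
    """The ``min(k, n_genes)`` top-ranked gene identifiers, in rank order."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return list(ranking.gene_ids[:k])
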