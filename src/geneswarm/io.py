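"""Readers and writers for the expression TSV/CSV pair.

Matrix file: first column gene identifiers, header row sample identifiers,
numeric body.  Labels file: two columns (sample id, class tag) with a header
row; samples are aligned to matrix columns by id, not by order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import LabeledExpressionDataset

__all__ = ["read_expression", "write_expression"]


def _sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(matrix_path: str | Path, labels_path: str | Path) -> LabeledExpressionDataset:
    """Load a dataset from a matrix file and a labels file.

    Raises ``ValueError`` with a specific message on duplicate gene ids,
    non-numeric cells, samples missing from the labels file, or a class
    count other than two.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    mat = pd.read_csv(matrix_path, sep=_sep(matrix_path), index_col=0)
    if mat.index.has_duplicates:
        dupes = sorted(mat.index[mat.index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate gene ids in {matrix_path.name}: {dupes[:5]}")
    try:
        values = mat.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {matrix_path.name}: {exc}") from exc
    if np.isnan(values).any():
        raise ValueError(f"missing/non-numeric expression values in {matrix_path.name}")

    lab = pd.read_csv(labels_path, sep=_sep(labels_path), dtype=str)
    if lab.shape[1] < 2:
        raise ValueError(f"labels file {labels_path.name} needs (sample id, class) columns")
    lab_map = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    samples = [str(s) for s in mat.columns]
    missing = [s for s in samples if s not in lab_map]
    if missing:
        raise ValueError(f"samples missing from labels file: {missing[:5]}")
    labels = np.array([lab_map[s] for s in samples])
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(
            f"expected exactly two classes, found {len(classes)}: {classes}"
        )
    return LabeledExpressionDataset(
        matrix=values,
        gene_ids=[str(g) for g in mat.index],
        labels=labels,
        sample_ids=samples,
    )


def write_expression(
    data: LabeledExpressionDataset, matrix_path: str | Path, labels_path: str | Path
) -> None:
    """Write the matrix + labels pair consumed by :func:`read_expression`."""
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    pd.DataFrame(
        data.matrix, index=pd.Index(data.gene_ids, name="gene_id"), columns=data.sample_ids
    ).to_csv(matrix_path, sep=_sep(matrix_path))
    pd.DataFrame({"sample_id": data.sample_ids, "label": data.labels}).to_csv(
        labels_path, sep=_sep(labels_path), index=False
    )
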