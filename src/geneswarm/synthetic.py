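"""Synthetic two-class expression matrices with planted informative genes.

The generator emulates the statistical structure the wrapper assumes: a
handful of informative genes whose class means differ by ``effect_size``
noise standard deviations, embedded among independent Gaussian noise genes.
Defaults produce a 500-gene, 40-sample (20 + 20) matrix with 5 planted genes
at effect size 2 — large enough for a t-filter and a maximal-margin
classifier to succeed, small enough to run the full search protocol on a
single CPU.  It makes no attempt to mimic probe-level microarray artifacts,
batch effects or gene-gene correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledExpressionDataset

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    ``effect_size`` is the class-mean difference of each planted gene in
    units of the noise standard deviation; classes sit at ±effect/2 so the
    overall gene mean stays near zero.
    """

    n_per_class: tuple[int, int] = (20, 20)
    n_genes: int = 500
    n_informative: int = 5
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_class) < 1 or self.n_genes < 1:
            raise ValueError("sample and gene counts must be positive")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ValueError("n_informative must lie in [0, n_genes]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def generate(spec: SyntheticSpec) -> tuple[LabeledExpressionDataset, list[str]]:
    """Draw one dataset; returns it with the planted gene ids (ground truth).

    Noise genes are i.i.d. Normal(0, noise_sd^2) for every sample; planted
    genes are Normal(-effect/2 * sd, sd^2) in class A and Normal(+effect/2
    * sd, sd^2) in class B.  Planted genes are scattered at seeded-random
    row positions.  Bit-identical for a given spec (same seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_class
    n = n1 + n2
    matrix = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    planted_rows = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    shift = spec.effect_size * spec.noise_sd / 2.0
    matrix[np.ix_(planted_rows, np.arange(n1))] -= shift
    matrix[np.ix_(planted_rows, np.arange(n1, n))] += shift
    gene_ids = [f"G{i:04d}" for i in range(spec.n_genes)]
    labels = np.array(["A"] * n1 + ["B"] * n2)
    data = LabeledExpressionDataset(matrix=matrix, gene_ids=gene_ids, labels=labels)
    return data, [gene_ids[i] for i in planted_rows]
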