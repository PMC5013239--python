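"""End-to-end selection pipeline and the repeated-run benchmark harness.

``run_pipeline`` chains the published protocol: z-score normalisation,
t-test ranking, top-k prefilter (k = 50 fixes the particle length), then one
run of the configured optimizer with the SVM/LOOCV composite objective.

``run_benchmark`` repeats each configured algorithm ``repeats`` times
(25 by default) with consecutive seeds and aggregates best / mean /
population-standard-deviation of the best LOOCV accuracy, the mean subset
size over all runs, and per-gene selection frequencies over the runs that
attained the maximum accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binary_core import ParticleLayout
from .dataset import LabeledExpressionDataset
from .fitness import FitnessWeights, SVMConfig, make_evaluator
from .optimizers import (
    BPSOParams,
    BQPSOParams,
    GAParams,
    RunResult,
    run_bpso,
    run_bqpso,
    run_ga,
)
from .prefilter import normalize, select_top_k, t_test_rank

__all__ = [
    "PipelineConfig",
    "AlgorithmSummary",
    "BenchmarkReport",
    "run_pipeline",
    "run_benchmark",
    "selection_frequency_table",
]

_RUNNERS: dict[str, tuple[Callable, type]] = {
    "bqpso": (run_bqpso, BQPSOParams),
    "bpso": (run_bpso, BPSOParams),
    "ga": (run_ga, GAParams),
}


@dataclass
class PipelineConfig:
    """Everything one selection run (or benchmark arm) needs."""

    algorithm: str = "bqpso"
    prefilter_k: int = 50
    params: BQPSOParams | BPSOParams | GAParams | None = None
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    svm: SVMConfig = field(default_factory=SVMConfig)
    repeats: int = 25
    base_seed: int = 0
    apply_normalize: bool = True

    def __post_init__(self) -> None:
        if self.algorithm not in _RUNNERS:
            raise ValueError(f"unknown algorithm: {self.algorithm!r}")
        if self.params is None:
            self.params = _RUNNERS[self.algorithm][1](seed=self.base_seed)

    def with_seed(self, seed: int) -> "PipelineConfig":
        from dataclasses import replace

        return PipelineConfig(
            algorithm=self.algorithm,
            prefilter_k=self.prefilter_k,
            params=replace(self.params, seed=seed),
            weights=self.weights,
            svm=self.svm,
            repeats=self.repeats,
            base_seed=self.base_seed,
            apply_normalize=self.apply_normalize,
        )


def run_pipeline(data: LabeledExpressionDataset, config: PipelineConfig) -> RunResult:
    """Normalize, rank, prefilter, then optimize a gene subset.

    The returned result's ``selected_indices`` are row indices into the
    original dataset and ``selected_genes`` the corresponding identifiers.
    """
    work = normalize(data) if config.apply_normalize else data
    ranking = t_test_rank(work)
    top_genes = select_top_k(ranking, config.prefilter_k)
    reduced = work.restrict_genes(top_genes)
    evaluator = make_evaluator(reduced, config.weights, config.svm)
    runner, _ = _RUNNERS[config.algorithm]
    layout = ParticleLayout.single(reduced.n_genes)
    result = runner(evaluator, layout, config.params)
    # remap from the reduced search space back to original gene identity
    result.selected_genes = [top_genes[i] for i in result.selected_indices]
    gene_index = {g: i for i, g in enumerate(data.gene_ids)}
    result.selected_indices = [gene_index[g] for g in result.selected_genes]
    return result


@dataclass
class AlgorithmSummary:
    """Cross-run aggregate for one algorithm (one benchmark arm)."""

    algorithm: str
    best_accuracy: float
    mean_accuracy: float
    std_accuracy: float  # population standard deviation (divide by n)
    mean_subset_size: float
    selection_frequencies: dict[str, int]
    runs: list[RunResult]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_accuracy": self.best_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_subset_size": self.mean_subset_size,
            "selection_frequencies": dict(self.selection_frequencies),
            "runs": [r.to_dict() for r in self.runs],
        }


@dataclass
class BenchmarkReport:
    """Per-algorithm summaries plus the per-run results behind them."""

    summaries: dict[str, AlgorithmSummary]
    repeats: int
    base_seed: int

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "base_seed": self.base_seed,
            "algorithms": {k: s.to_dict() for k, s in self.summaries.items()},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        summaries = {}
        for name, s in d["algorithms"].items():
            runs = [RunResult(**r) for r in s["runs"]]
            summaries[name] = AlgorithmSummary(
                algorithm=s["algorithm"],
                best_accuracy=s["best_accuracy"],
                mean_accuracy=s["mean_accuracy"],
                std_accuracy=s["std_accuracy"],
                mean_subset_size=s["mean_subset_size"],
                selection_frequencies={
                    k: int(v) for k, v in s["selection_frequencies"].items()
                },
                runs=runs,
            )
        return cls(summaries=summaries, repeats=d["repeats"], base_seed=d["base_seed"])

    @classmethod
    def from_json(cls, path: str | Path) -> "BenchmarkReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": s.algorithm,
                "best_accuracy": s.best_accuracy,
                "mean_accuracy": s.mean_accuracy,
                "std_accuracy": s.std_accuracy,
                "mean_subset_size": s.mean_subset_size,
            }
            for s in self.summaries.values()
        ]
        return pd.DataFrame(rows)


def _summarize(algorithm: str, runs: list[RunResult]) -> AlgorithmSummary:
    accs = np.array([r.best_accuracy for r in runs], dtype=float)
    best = float(accs.max())
    freqs: dict[str, int] = {}
    for r in runs:
        if r.best_accuracy == best:  # only runs attaining the maximum accuracy
            for g in r.selected_genes or []:
                freqs[g] = freqs.get(g, 0) + 1
    return AlgorithmSummary(
        algorithm=algorithm,
        best_accuracy=best,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std()),  # ddof=0: population convention
        mean_subset_size=float(np.mean([len(r.selected_genes or []) for r in runs])),
        selection_frequencies=freqs,
        runs=runs,
    )


def run_benchmark(
    data: LabeledExpressionDataset,
    configs: Sequence[PipelineConfig] | Mapping[str, PipelineConfig],
    repeats: int | None = None,
    base_seed: int | None = None,
) -> BenchmarkReport:
    """Run each configured algorithm ``repeats`` times and aggregate.

    Run r of an arm uses seed ``base_seed + r`` (r = 0..repeats-1), so the
    whole report is a pure function of (data, configs, repeats, base_seed).
    """
    if isinstance(configs, Mapping):
        config_items = list(configs.items())
    else:
        config_items = [(c.algorithm, c) for c in configs]
    if not config_items:
        raise ValueError("at least one pipeline configuration is required")
    first = config_items[0][1]
    n_rep = repeats if repeats is not None else first.repeats
    seed0 = base_seed if base_seed is not None else first.base_seed
    if n_rep < 1:
        raise ValueError("repeats must be at least 1")
    summaries: dict[str, AlgorithmSummary] = {}
    for name, config in config_items:
        runs = [run_pipeline(data, config.with_seed(seed0 + r)) for r in range(n_rep)]
        summaries[name] = _summarize(name, runs)
    return BenchmarkReport(summaries=summaries, repeats=n_rep, base_seed=seed0)


def selection_frequency_table(
    report: BenchmarkReport, algorithm: str | None = None, top_n: int = 5
) -> pd.DataFrame:
    """Top genes by selection frequency among an arm's best-accuracy runs.

    Sorted by descending count, ties by gene id; at most ``top_n`` rows.
    """
    if top_n < 1:
        raise ValueError("top_n must be positive")
    if algorithm is None:
        algorithm = next(iter(report.summaries))
    freqs = report.summaries[algorithm].selection_frequencies
    ordered = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return pd.DataFrame(ordered, columns=["gene_id", "count"])
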