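"""End-to-end convenience: dataset -> ensemble -> scores -> regions.

Chains the individual stages with their defaults so the whole
discriminative-region discovery procedure is a single call; every stage
remains available separately for finer control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .brain_mapping import RegionFrequencyTable, region_frequencies
from .ensemble import (
    Dataset,
    DatasetSplit,
    EvaluationResult,
    SvmConfig,
    WrsvmcEnsemble,
    evaluate,
    split_dataset,
    train_ensemble,
)
from .feature_selection import (
    FeatureScoreTable,
    SelectionResult,
    filter_effective,
    score_features,
    sweep_top_p,
    top_k,
)


@dataclass
class PipelineResult:
    split: DatasetSplit
    ensemble: WrsvmcEnsemble
    evaluation: EvaluationResult
    effective: WrsvmcEnsemble
    score_table: FeatureScoreTable
    selection: SelectionResult
    regions: RegionFrequencyTable


def discover_regions(
    dataset: Dataset,
    n_train_val: int,
    config: SvmConfig,
    n_classifiers: int = 500,
    n_important: int = 400,
    p_grid: Sequence[int] | None = None,
    sweep_classifiers: int | None = None,
    repeats: int = 5,
    score_variant: str = "literal",
    eval_set: str = "test",
    seed: int = 0,
) -> PipelineResult:
    """Run the full procedure on a labelled feature dataset.

    ``eval_set`` chooses where classifier effectiveness and feature
    scores are measured: ``"test"`` reuses the unseen test samples
    (reference behaviour, leaks test data into selection) while
    ``"validation"`` uses the train-validation samples only
    (``holdout-clean``).
    """
    if eval_set not in ("test", "validation"):
        raise ValueError(f"unknown eval_set {eval_set!r}")
    split = split_dataset(dataset, n_train_val=n_train_val, seed=seed)
    ensemble = train_ensemble(
        dataset, split, config, n_classifiers=n_classifiers, mode="weighted", seed=seed
    )
    X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
    evaluation = evaluate(ensemble, X_te, y_te)

    idx = split.test_indices if eval_set == "test" else split.train_val_indices
    eval_X, eval_y = dataset.X[idx], dataset.y[idx]
    effective = filter_effective(ensemble, eval_X, eval_y)
    score_table = score_features(effective, eval_X, variant=score_variant, eval_set=eval_set)

    important = top_k(score_table, k=min(n_important, dataset.n_features))
    if p_grid is None:
        hi = important.size
        p_grid = tuple(range(max(70, config.n_features), hi + 1, 2))
    selection = sweep_top_p(
        dataset, split, config,
        important_features=important,
        p_grid=p_grid,
        n_classifiers=n_classifiers if sweep_classifiers is None else sweep_classifiers,
        repeats=repeats,
        seed=seed + 1,
    )
    if dataset.index_map is None:
        raise ValueError("dataset has no feature index map; cannot map regions")
    regions = region_frequencies(selection.optimal_subset, dataset.index_map)
    return PipelineResult(
        split=split,
        ensemble=ensemble,
        evaluation=evaluation,
        effective=effective,
        score_table=score_table,
        selection=selection,
        regions=regions,
    )
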