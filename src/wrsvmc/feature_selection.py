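"""Feature importance scoring and optimal-subset search.

Base classifiers whose accuracy on an evaluation set is strictly above
50% are "effective". For an effective classifier ``i`` holding feature
``j``, the feature's per-classifier score is

    Score_{i,j} = (sum_k H_{k,j}) * W_i,

where ``H_{k,j}`` is the raw value of feature ``j`` in the ``k``-th
evaluation sample and ``W_i`` the classifier's voting weight; totals
``Score_j`` sum over the effective classifiers containing ``j``. The
top 400 features by total score are the "important features"; the
ensemble is then retrained with its feature draws restricted to the top
``p`` of those for ``p`` on a grid ({70, 72, ..., 400} at reference
scale), and the ``p`` maximizing test accuracy defines the optimal
feature subset.

The literal score depends on feature scale and sign; an
``absolute-values`` variant (summing |H|) is available since
large-magnitude features such as shortest-path sentinels otherwise
dominate. The evaluation set is, by default, the test set itself —
mirroring the reference procedure's reuse of the unseen samples; pass
the validation remainder instead for a leakage-free variant
(``holdout-clean``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    Dataset,
    DatasetSplit,
    SvmConfig,
    WrsvmcEnsemble,
    evaluate,
    train_ensemble,
)

#: reference number of "important features"
DEFAULT_TOP_K = 400

#: reference top-p grid {70, 72, ..., 400}
DEFAULT_P_GRID = tuple(range(70, 401, 2))

ScoreVariant = Literal["literal", "absolute-values"]


def default_p_grid(start: int = 70, stop: int = 400, step: int = 2) -> tuple[int, ...]:
    return tuple(range(start, stop + 1, step))


def classifier_accuracies(ensemble: WrsvmcEnsemble, eval_X: np.ndarray, eval_y: np.ndarray) -> np.ndarray:
    """Per-base-classifier accuracy on an evaluation set."""
    eval_y = np.asarray(eval_y, dtype=int)
    votes = ensemble.votes(eval_X)
    return (votes == eval_y[None, :]).mean(axis=1)


def filter_effective(
    ensemble: WrsvmcEnsemble,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    threshold: float = 0.5,
) -> WrsvmcEnsemble:
    """Retain base classifiers with evaluation accuracy strictly > threshold."""
    if np.asarray(eval_y).size == 0:
        raise ValueError("evaluation set is empty")
    acc = classifier_accuracies(ensemble, eval_X, eval_y)
    keep = [c for c, a in zip(ensemble.classifiers, acc) if a > threshold]
    if not keep:
        raise ValueError(
            f"no classifier exceeds accuracy {threshold}; lower the threshold "
            "or enlarge the ensemble"
        )
    return WrsvmcEnsemble(
        classifiers=keep,
        mode=ensemble.mode,
        config=ensemble.config,
        rng_seed=ensemble.rng_seed,
        majority_label=ensemble.majority_label,
    )


@dataclass
class FeatureScoreTable:
    """Total score and contributing-classifier count per feature."""

    scores: np.ndarray
    n_contributing: np.ndarray
    variant: str = "literal"
    eval_set: str = "test"

    def to_frame(self, feature_names: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature_index": np.arange(self.scores.size),
            "score": self.scores,
            "n_contributing_classifiers": self.n_contributing,
        })
        if feature_names is not None:
            df.insert(1, "feature", list(feature_names))
        return df


def score_features(
    effective: WrsvmcEnsemble,
    eval_X: np.ndarray,
    variant: ScoreVariant = "literal",
    eval_set: str = "test",
) -> FeatureScoreTable:
    """Accumulate per-feature scores over the effective classifiers.

    Features held by no effective classifier score 0.
    """
    eval_X = np.atleast_2d(np.asarray(eval_X, dtype=float))
    if variant == "absolute-values":
        col_sums = np.abs(eval_X).sum(axis=0)
    elif variant == "literal":
        col_sums = eval_X.sum(axis=0)
    else:
        raise ValueError(f"unknown score variant {variant!r}")
    scores = np.zeros(eval_X.shape[1])
    counts = np.zeros(eval_X.shape[1], dtype=int)
    for clf in effective.classifiers:
        scores[clf.feature_indices] += col_sums[clf.feature_indices] * clf.weight
        counts[clf.feature_indices] += 1
    return FeatureScoreTable(scores=scores, n_contributing=counts, variant=variant, eval_set=eval_set)


def top_k(scores: np.ndarray | FeatureScoreTable, k: int = DEFAULT_TOP_K) -> np.ndarray:
    """Indices of the ``k`` highest-scoring features.

    Ordered by score descending; ties break toward the smaller feature
    index, so the result is deterministic.
    """
    if isinstance(scores, FeatureScoreTable):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds number of features {scores.size}")
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


@dataclass
class SelectionResult:
    """Outcome of the top-p accuracy sweep."""

    important_features: np.ndarray
    p_grid: tuple[int, ...]
    accuracy_by_p: pd.DataFrame  # columns: p, accuracy (mean over repeats)
    optimal_p: int
    optimal_subset: np.ndarray

    def to_dict(self) -> dict:
        return {
            "important_features": self.important_features.tolist(),
            "p_grid": list(self.p_grid),
            "accuracy_by_p": self.accuracy_by_p.to_dict(orient="records"),
            "optimal_p": int(self.optimal_p),
            "optimal_subset": self.optimal_subset.tolist(),
        }


def sweep_top_p(
    dataset: Dataset,
    split: DatasetSplit,
    config: SvmConfig,
    important_features: np.ndarray,
    p_grid: Sequence[int] = DEFAULT_P_GRID,
    n_classifiers: int = 500,
    repeats: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Accuracy of fresh ensembles restricted to the top-p important features.

    For each ``p`` a new ensemble is trained whose feature draws come
    only from ``important_features[:p]``; test accuracy is averaged over
    ``repeats`` seeds. The optimal ``p`` is the accuracy argmax, smallest
    on ties, and the optimal subset is its top-p feature list.
    """
    important_features = np.asarray(important_features, dtype=int)
    p_grid = tuple(sorted(set(int(p) for p in p_grid)))
    if not p_grid:
        raise ValueError("p_grid is empty")
    if p_grid[0] < config.n_features:
        raise ValueError(
            f"smallest p ({p_grid[0]}) is below the per-classifier feature "
            f"draw size ({config.n_features})"
        )
    if p_grid[-1] > important_features.size:
        raise ValueError("p exceeds the number of important features")
    X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
    rows = []
    for p in p_grid:
        pool = important_features[:p]
        accs = []
        for r in range(repeats):
            ens = train_ensemble(
                dataset, split, config,
                n_classifiers=n_classifiers,
                mode="weighted",
                seed=seed + r,
                feature_pool=pool,
            )
            accs.append(evaluate(ens, X_te, y_te).p_true)
        rows.append((p, float(np.mean(accs))))
    table = pd.DataFrame(rows, columns=["p", "accuracy"])
    optimal_p = int(table.loc[table["accuracy"].idxmax(), "p"])  # first row wins ties
    return SelectionResult(
        important_features=important_features,
        p_grid=p_grid,
        accuracy_by_p=table,
        optimal_p=optimal_p,
        optimal_subset=important_features[:optimal_p],
    )
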