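"""Weighted random SVM cluster (WRSVMC): training, voting, evaluation.

The classifier is an ensemble of ``n`` support-vector machines, each
trained on a random subset of samples and a random subset of features
drawn from the "training and validation" set. The samples left out of a
base classifier's training draw form its validation set; its accuracy
there becomes its voting weight ``W_i``. A test sample's label is the
class ``a`` maximizing the weighted vote total

    S_a = sum_i 1[f_i(x) = a] * W_i,

so strong base classifiers influence the decision more than weak ones.
Setting every ``W_i = 1`` recovers the unweighted random SVM cluster
(RSVMC) majority vote, exposed here as the ``equal`` mode.

Defaults mirror the reference configuration: 500 base classifiers, 65
training samples and 65 features per classifier, an RBF kernel
``exp(-||u - v||^2 / (2 sigma^2))`` with sigma = 3, and a hard-margin
cost ("Inf", realized as a large finite value so fitting terminates on
non-separable draws).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .graph_metrics import FeatureIndexMap, GraphFeatureVector

logger = logging.getLogger("wrsvmc")

#: finite stand-in for an "infinite" (hard-margin) SVM cost
INF_COST = 1e8

#: reference ensemble size
DEFAULT_N_CLASSIFIERS = 500

VotingMode = Literal["weighted", "equal"]

_MAX_REDRAWS = 100


def derive_seed(base_seed: int, index: int) -> np.random.SeedSequence:
    """Deterministic, prefix-stable per-classifier seed stream.

    Classifier ``i`` of an ensemble built from ``base_seed`` always sees
    the same stream, regardless of ensemble size.
    """
    return np.random.SeedSequence(base_seed, spawn_key=(index,))


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Feature matrix with +1/-1 labels and optional feature provenance."""

    X: np.ndarray
    y: np.ndarray
    index_map: FeatureIndexMap | None = None
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.y.shape != (self.X.shape[0],):
            raise ValueError("X must be N x D with y of length N")
        if not np.isfinite(self.X).all():
            raise ValueError("non-finite entries in feature matrix")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be +1 or -1")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")
        if self.index_map is not None and len(self.index_map) != self.X.shape[1]:
            raise ValueError("index_map length does not match feature dimension")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_feature_vectors(cls, vectors: Sequence[GraphFeatureVector]) -> "Dataset":
        """Stack per-subject graph feature vectors into a dataset."""
        if not vectors:
            raise ValueError("no feature vectors given")
        labels = [v.class_label for v in vectors]
        if any(lab is None for lab in labels):
            raise ValueError("all subjects need a class label")
        return cls(
            X=np.vstack([v.values for v in vectors]),
            y=np.asarray(labels, dtype=int),
            index_map=vectors[0].index_map,
            subject_ids=[v.subject_id for v in vectors],
        )


@dataclass
class DatasetSplit:
    """Disjoint train-validation / test index partition."""

    train_val_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        self.train_val_indices = np.asarray(self.train_val_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        overlap = np.intersect1d(self.train_val_indices, self.test_indices)
        if overlap.size:
            raise ValueError("train-validation and test indices overlap")


@dataclass
class SvmConfig:
    """Base-classifier configuration.

    ``cost`` may be ``float('inf')``; it is capped at ``max_cost`` when
    fitting. The RBF kernel is ``exp(-||u-v||^2 / (2 sigma^2))``.
    ``standardize`` z-scores features using statistics of each
    classifier's own training draw (off by default: the voting and the
    feature scoring both consume raw feature values).
    """

    cost: float = float("inf")
    sigma: float = 3.0
    n_train_samples: int = 65
    n_features: int = 65
    max_cost: float = INF_COST
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.cost <= 0 or self.max_cost <= 0:
            raise ValueError("cost must be positive")
        if self.n_train_samples < 2 or self.n_features < 1:
            raise ValueError("n_train_samples >= 2 and n_features >= 1 required")

    @property
    def effective_cost(self) -> float:
        return float(min(self.cost, self.max_cost))

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)

    def to_dict(self) -> dict:
        return {
            "cost": "inf" if np.isinf(self.cost) else self.cost,
            "sigma": self.sigma,
            "n_train_samples": self.n_train_samples,
            "n_features": self.n_features,
            "max_cost": self.max_cost,
            "standardize": self.standardize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SvmConfig":
        d = dict(d)
        if d.get("cost") in ("inf", "Inf", "INF"):
            d["cost"] = float("inf")
        return cls(**d)


class _RbfVoter:
    """Minimal RBF-SVM decision function (used when deserializing models)."""

    def __init__(self, support_vectors, dual_coef, intercept, classes, gamma):
        self.support_vectors_ = np.asarray(support_vectors, dtype=float)
        self.dual_coef_ = np.asarray(dual_coef, dtype=float)
        self.intercept_ = np.asarray(intercept, dtype=float)
        self.classes_ = np.asarray(classes, dtype=int)
        self._gamma = float(gamma)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sq = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors_.T
            + (self.support_vectors_**2).sum(axis=1)[None, :]
        )
        df = np.exp(-self._gamma * np.maximum(sq, 0.0)) @ self.dual_coef_.ravel() + self.intercept_[0]
        return self.classes_[(df > 0).astype(int)]


@dataclass
class BaseClassifier:
    """One fitted SVM with its feature subset and voting weight."""

    feature_indices: np.ndarray
    model: SVC | _RbfVoter
    weight: float
    validation_accuracy: float
    sample_indices: np.ndarray | None = None
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict +1/-1 labels from full-dimension feature rows."""
        Xs = np.atleast_2d(np.asarray(X, dtype=float))[:, self.feature_indices]
        if self.scaler_mean is not None:
            Xs = (Xs - self.scaler_mean) / self.scaler_scale
        return np.asarray(self.model.predict(Xs), dtype=int)


@dataclass
class WrsvmcEnsemble:
    """The trained cluster: base classifiers, voting mode, tie-break class."""

    classifiers: list[BaseClassifier]
    mode: VotingMode
    config: SvmConfig
    rng_seed: int
    majority_label: int = -1  # train-validation majority class; Eq. tie-break

    def __post_init__(self) -> None:
        if not self.classifiers:
            raise ValueError("ensemble needs at least one classifier")

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classifiers])

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Per-classifier predictions, shape (n_classifiers, n_samples)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.vstack([c.predict(X) for c in self.classifiers])

    def prefix(self, k: int) -> "WrsvmcEnsemble":
        """The sub-ensemble made of the first ``k`` base classifiers."""
        if not 1 <= k <= self.n_classifiers:
            raise ValueError(f"prefix size {k} out of range")
        return WrsvmcEnsemble(
            classifiers=self.classifiers[:k],
            mode=self.mode,
            config=self.config,
            rng_seed=self.rng_seed,
            majority_label=self.majority_label,
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def split_dataset(dataset: Dataset, n_train_val: int, seed: int) -> DatasetSplit:
    """Uniform random split into train-validation and test parts.

    Both parts must contain both classes; the draw is repeated (bounded)
    until they do.
    """
    n = dataset.n_samples
    if not 2 <= n_train_val < n:
        raise ValueError(f"n_train_val must be in [2, {n - 1}], got {n_train_val}")
    counts = {lab: int((dataset.y == lab).sum()) for lab in (-1, 1)}
    n_test = n - n_train_val
    for lab, cnt in counts.items():
        # a class entirely inside one part leaves the other without it
        if cnt < 2 or cnt > n - 2:
            raise ValueError(f"class {lab:+d} cannot be present in both parts")
    rng = np.random.default_rng(seed)
    for _ in range(_MAX_REDRAWS):
        perm = rng.permutation(n)
        tv, te = perm[:n_train_val], perm[n_train_val:]
        if len(np.unique(dataset.y[tv])) == 2 and len(np.unique(dataset.y[te])) == 2:
            return DatasetSplit(np.sort(tv), np.sort(te))
    raise ValueError(
        "could not draw a split with both classes in both parts "
        f"(N={n}, n_train_val={n_train_val}, class counts={counts})"
    )


def train_base(
    dataset: Dataset,
    split: DatasetSplit,
    config: SvmConfig,
    seed: int | np.random.SeedSequence,
    feature_pool: np.ndarray | None = None,
) -> BaseClassifier:
    """Train one random-subspace SVM and weight it by validation accuracy.

    ``n_train_samples`` sample indices and ``n_features`` feature indices
    are drawn without replacement (the features from ``feature_pool``,
    default all columns); the train-validation samples left out of the
    draw are the validation set whose accuracy becomes the weight.
    """
    rng = np.random.default_rng(seed)
    tv = split.train_val_indices
    if config.n_train_samples >= tv.size:
        raise ValueError(
            f"n_train_samples={config.n_train_samples} leaves no validation "
            f"remainder (train-validation size {tv.size})"
        )
    pool = np.arange(dataset.n_features) if feature_pool is None else np.asarray(feature_pool, dtype=int)
    if config.n_features > pool.size:
        raise ValueError(f"n_features={config.n_features} exceeds feature pool size {pool.size}")

    for _ in range(_MAX_REDRAWS):
        drawn = rng.choice(tv, size=config.n_train_samples, replace=False)
        if len(np.unique(dataset.y[drawn])) == 2:
            break
    else:
        raise ValueError("could not draw a two-class training subset")
    feats = np.sort(rng.choice(pool, size=config.n_features, replace=False))

    X_tr = dataset.X[np.ix_(drawn, feats)]
    y_tr = dataset.y[drawn]
    mean = scale = None
    if config.standardize:
        mean = X_tr.mean(axis=0)
        scale = X_tr.std(axis=0)
        scale[scale == 0] = 1.0
        X_tr = (X_tr - mean) / scale

    model = SVC(C=config.effective_cost, kernel="rbf", gamma=config.gamma)
    model.fit(X_tr, y_tr)

    val = np.setdiff1d(tv, drawn)
    if val.size == 0:
        raise ValueError("empty validation remainder")
    X_val = dataset.X[np.ix_(val, feats)]
    if mean is not None:
        X_val = (X_val - mean) / scale
    acc = float((model.predict(X_val) == dataset.y[val]).mean())

    return BaseClassifier(
        feature_indices=feats,
        model=model,
        weight=acc,
        validation_accuracy=acc,
        sample_indices=np.sort(drawn),
        scaler_mean=mean,
        scaler_scale=scale,
    )


def train_ensemble(
    dataset: Dataset,
    split: DatasetSplit,
    config: SvmConfig,
    n_classifiers: int = DEFAULT_N_CLASSIFIERS,
    mode: VotingMode = "weighted",
    seed: int = 0,
    feature_pool: np.ndarray | None = None,
) -> WrsvmcEnsemble:
    """Train ``n_classifiers`` independent base SVMs (Figure-2 procedure).

    Per-classifier randomness derives deterministically from
    ``(seed, classifier index)``, so a smaller ensemble is always a prefix
    of a larger one trained from the same seed. In ``equal`` mode every
    voting weight is 1 (RSVMC baseline); validation accuracies are kept
    either way.
    """
    if n_classifiers < 1:
        raise ValueError("n_classifiers must be >= 1")
    if mode not in ("weighted", "equal"):
        raise ValueError(f"unknown voting mode {mode!r}")
    classifiers = []
    for i in range(n_classifiers):
        clf = train_base(dataset, split, config, derive_seed(seed, i), feature_pool)
        if mode == "equal":
            clf.weight = 1.0
        logger.debug(
            "classifier %d/%d: weight=%.4f (validation accuracy %.4f)",
            i + 1, n_classifiers, clf.weight, clf.validation_accuracy,
        )
        classifiers.append(clf)

    y_tv = dataset.y[split.train_val_indices]
    n_pos = int((y_tv == 1).sum())
    majority = 1 if n_pos > y_tv.size - n_pos else -1
    return WrsvmcEnsemble(
        classifiers=classifiers,
        mode=mode,
        config=config,
        rng_seed=seed,
        majority_label=majority,
    )


# ---------------------------------------------------------------------------
# Voting and evaluation
# ---------------------------------------------------------------------------

def vote_scores(ensemble: WrsvmcEnsemble, X: np.ndarray, votes: np.ndarray | None = None):
    """Weighted vote totals (S_plus, S_minus) for each sample."""
    if votes is None:
        votes = ensemble.votes(X)
    w = ensemble.weights[:, None]
    s_plus = (w * (votes == 1)).sum(axis=0)
    s_minus = (w * (votes == -1)).sum(axis=0)
    return s_plus, s_minus


def predict(ensemble: WrsvmcEnsemble, X: np.ndarray) -> np.ndarray:
    """Weighted-majority label for each row of ``X``.

    Exact vote ties resolve to the majority class of the train-validation
    set (deterministic).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = ensemble.classifiers[0].feature_indices
    if X.shape[1] <= int(d.max()):
        raise ValueError(
            f"feature dimension {X.shape[1]} too small for classifier "
            f"feature indices up to {int(d.max())}"
        )
    s_plus, s_minus = vote_scores(ensemble, X)
    out = np.where(s_plus > s_minus, 1, np.where(s_minus > s_plus, -1, ensemble.majority_label))
    return out.astype(int)


def predict_one(ensemble: WrsvmcEnsemble, x: np.ndarray) -> int:
    """Label of a single full-dimension feature vector."""
    return int(predict(ensemble, np.atleast_2d(x))[0])


@dataclass
class EvaluationResult:
    """Test-set accuracy and the confusion-derived rates (+1 positive)."""

    t: int
    t_true: int
    p_true: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int

    @classmethod
    def from_counts(cls, tp: int, fn: int, tn: int, fp: int) -> "EvaluationResult":
        t = tp + fn + tn + fp
        if t == 0:
            raise ValueError("empty confusion table")
        t_true = tp + tn
        return cls(
            t=t,
            t_true=t_true,
            p_true=t_true / t,
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            tp=tp, fn=fn, tn=tn, fp=fp,
        )

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "EvaluationResult":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.size == 0:
            raise ValueError("empty test set")
        return cls.from_counts(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == -1)).sum()),
            tn=int(((y_true == -1) & (y_pred == -1)).sum()),
            fp=int(((y_true == -1) & (y_pred == 1)).sum()),
        )


def evaluate(ensemble: WrsvmcEnsemble, test_X: np.ndarray, test_y: np.ndarray) -> EvaluationResult:
    """Accuracy P_true = T_true / T plus sensitivity and specificity."""
    return EvaluationResult.from_predictions(test_y, predict(ensemble, test_X))


@dataclass
class SizeSweepResult:
    table: pd.DataFrame  # columns: size, accuracy
    optimal_size: int
    ensemble: WrsvmcEnsemble  # the largest (superset) ensemble


def sweep_ensemble_size(
    dataset: Dataset,
    split: DatasetSplit,
    config: SvmConfig,
    sizes: Sequence[int],
    mode: VotingMode = "weighted",
    seed: int = 0,
) -> SizeSweepResult:
    """Test accuracy as a function of ensemble size.

    One ensemble of ``max(sizes)`` classifiers is trained; every smaller
    size reuses its leading prefix (prefixes are exact thanks to the
    per-classifier seed derivation). The optimal size is the accuracy
    argmax, smallest on ties.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or sizes[0] < 1:
        raise ValueError("sizes must be positive integers")
    big = train_ensemble(dataset, split, config, n_classifiers=sizes[-1], mode=mode, seed=seed)
    X_te, y_te = dataset.X[split.test_indices], dataset.y[split.test_indices]
    votes = big.votes(X_te)
    w = big.weights
    rows = []
    for k in sizes:
        wk = w[:k, None]
        s_plus = (wk * (votes[:k] == 1)).sum(axis=0)
        s_minus = (wk * (votes[:k] == -1)).sum(axis=0)
        pred = np.where(s_plus > s_minus, 1, np.where(s_minus > s_plus, -1, big.majority_label))
        rows.append((k, float((pred == y_te).mean())))
    table = pd.DataFrame(rows, columns=["size", "accuracy"])
    optimal = int(table.loc[table["accuracy"].idxmax(), "size"])  # idxmax → first (smallest size)
    return SizeSweepResult(table=table, optimal_size=optimal, ensemble=big)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: WrsvmcEnsemble, path: str | Path) -> None:
    """Write a JSON manifest: config, seeds, weights, feature subsets and
    the fitted kernel expansion of every base classifier."""
    clfs = []
    for c in ensemble.classifiers:
        m = c.model
        clfs.append({
            "feature_indices": c.feature_indices.tolist(),
            "weight": c.weight,
            "validation_accuracy": c.validation_accuracy,
            "scaler_mean": None if c.scaler_mean is None else c.scaler_mean.tolist(),
            "scaler_scale": None if c.scaler_scale is None else c.scaler_scale.tolist(),
            "support_vectors": np.asarray(m.support_vectors_).tolist(),
            "dual_coef": np.asarray(m.dual_coef_).tolist(),
            "intercept": np.asarray(m.intercept_).tolist(),
            "classes": np.asarray(m.classes_, dtype=int).tolist(),
        })
    doc = {
        "format": "wrsvmc-ensemble",
        "mode": ensemble.mode,
        "rng_seed": ensemble.rng_seed,
        "majority_label": ensemble.majority_label,
        "config": ensemble.config.to_dict(),
        "classifiers": clfs,
    }
    Path(path).write_text(json.dumps(doc))


def load_ensemble(path: str | Path) -> WrsvmcEnsemble:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "wrsvmc-ensemble":
        raise ValueError(f"{path} is not a wrsvmc ensemble manifest")
    config = SvmConfig.from_dict(doc["config"])
    classifiers = []
    for c in doc["classifiers"]:
        model = _RbfVoter(
            support_vectors=c["support_vectors"],
            dual_coef=c["dual_coef"],
            intercept=c["intercept"],
            classes=c["classes"],
            gamma=config.gamma,
        )
        classifiers.append(BaseClassifier(
            feature_indices=np.asarray(c["feature_indices"], dtype=int),
            model=model,
            weight=float(c["weight"]),
            validation_accuracy=float(c["validation_accuracy"]),
            scaler_mean=None if c["scaler_mean"] is None else np.asarray(c["scaler_mean"]),
            scaler_scale=None if c["scaler_scale"] is None else np.asarray(c["scaler_scale"]),
        ))
    return WrsvmcEnsemble(
        classifiers=classifiers,
        mode=doc["mode"],
        config=config,
        rng_seed=int(doc["rng_seed"]),
        majority_label=int(doc["majority_label"]),
    )
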