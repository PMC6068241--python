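"""Two-class synthetic data with planted connectivity differences.

Every pipeline stage — connectivity, graph metrics, ensemble training,
feature scoring, region mapping — can be exercised end to end without any
imaging data. Subjects come in two balanced classes (+1 "patient", -1
"control") whose connectivity differs only on a planted set of ROI pairs:

* graph mode: each subject's binary graph draws edges independently;
  non-planted pairs use a common base probability, planted pairs a
  class-specific probability.
* timeseries mode: each subject is a multivariate-Gaussian ROI series
  whose target correlation is class-specific on the planted pairs and a
  common base value elsewhere. The target matrix is identity plus
  symmetric planted entries, eigenvalue-floored and renormalized to unit
  diagonal to stay a valid correlation matrix, so achieved correlations
  can differ slightly from the request (the achieved values are
  reported). Independent observation noise further attenuates empirical
  correlations by 1/(1 + noise_sd^2).

Defaults give a desk-scale profile (30 ROIs, 60 subjects per class, 20
planted pairs concentrated on ROIs 0-9) on which the full pipeline runs
in seconds; series length defaults to 130 timepoints, the scale of a
typical resting-state acquisition after discarding initial volumes.
Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .brain_mapping import region_labels
from .connectivity import DEFAULT_CUTOFF, BinaryGraph, RoiTimeSeries, compute_fc, binarize
from .ensemble import Dataset
from .graph_metrics import assemble_features

GenerationMode = Literal["graph", "timeseries"]

_EIG_FLOOR = 1e-3


def default_planted_pairs(n_pairs: int = 20, n_rois: int = 10) -> tuple[tuple[int, int], ...]:
    """First ``n_pairs`` row-major pairs among ROIs 0..n_rois-1.

    Concentrating the planted pairs on a small ROI block makes the
    "abnormal" regions unambiguous for recovery checks.
    """
    pairs = [(i, j) for i in range(n_rois) for j in range(i + 1, n_rois)]
    if n_pairs > len(pairs):
        raise ValueError(f"cannot plant {n_pairs} pairs among {n_rois} ROIs")
    return tuple(pairs[:n_pairs])


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator."""

    n_regions: int = 30
    n_per_class: int = 60
    mode: GenerationMode = "graph"
    n_timepoints: int = 130
    planted_pairs: tuple[tuple[int, int], ...] = field(default_factory=default_planted_pairs)
    # graph mode: Bernoulli edge probabilities
    edge_p_base: float = 0.2
    edge_p_planted_pos: float = 0.9
    edge_p_planted_neg: float = 0.1
    # timeseries mode: target Pearson correlations
    corr_base: float = 0.0
    corr_planted_pos: float = 0.7
    corr_planted_neg: float = 0.1
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        seen = set()
        for (i, j) in self.planted_pairs:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions) or i == j:
                raise ValueError(f"invalid planted pair ({i}, {j}) for R={self.n_regions}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate planted pair ({i}, {j})")
            seen.add(key)
        for name in ("edge_p_base", "edge_p_planted_pos", "edge_p_planted_neg"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("corr_base", "corr_planted_pos", "corr_planted_neg"):
            c = getattr(self, name)
            if not -1.0 < c < 1.0:
                raise ValueError(f"{name}={c} outside (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def null(self) -> "SyntheticConfig":
        """The no-effect control: both classes share every parameter."""
        return replace(
            self,
            edge_p_planted_pos=self.edge_p_base,
            edge_p_planted_neg=self.edge_p_base,
            corr_planted_pos=self.corr_base,
            corr_planted_neg=self.corr_base,
        )

    @property
    def planted_rois(self) -> tuple[int, ...]:
        """Sorted ROI indices touched by at least one planted pair."""
        rois = {i for pair in self.planted_pairs for i in pair}
        return tuple(sorted(rois))

    @property
    def labels(self) -> list[str]:
        return region_labels(self.n_regions)


def _edge_probability_matrix(config: SyntheticConfig, class_label: int) -> np.ndarray:
    p = np.full((config.n_regions, config.n_regions), config.edge_p_base)
    planted = config.edge_p_planted_pos if class_label == 1 else config.edge_p_planted_neg
    for (i, j) in config.planted_pairs:
        p[i, j] = p[j, i] = planted
    np.fill_diagonal(p, 0.0)
    return p


def _correlation_target(config: SyntheticConfig, class_label: int) -> np.ndarray:
    c = np.full((config.n_regions, config.n_regions), config.corr_base)
    planted = config.corr_planted_pos if class_label == 1 else config.corr_planted_neg
    for (i, j) in config.planted_pairs:
        c[i, j] = c[j, i] = planted
    np.fill_diagonal(c, 1.0)
    return c


def class_correlation_matrix(config: SyntheticConfig, class_label: int) -> np.ndarray:
    """The achieved (floored, renormalized) correlation target of a class."""
    target = _correlation_target(config, class_label)
    vals, vecs = np.linalg.eigh(target)
    if vals.min() < _EIG_FLOOR:
        vals = np.maximum(vals, _EIG_FLOOR)
        target = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(target))
        target = target / np.outer(d, d)
    try:
        np.linalg.cholesky(target)
    except np.linalg.LinAlgError:
        raise ValueError(
            "correlation target is not positive definite even after the "
            f"eigenvalue floor (corr_base={config.corr_base}, planted "
            f"corr={config.corr_planted_pos}/{config.corr_planted_neg}, "
            f"{len(config.planted_pairs)} planted pairs)"
        )
    return target


def _subject_labels(config: SyntheticConfig) -> list[int]:
    return [1] * config.n_per_class + [-1] * config.n_per_class


def generate(config: SyntheticConfig) -> list[BinaryGraph] | list[RoiTimeSeries]:
    """Draw one balanced cohort of subjects, deterministically under the seed."""
    rng = np.random.default_rng(config.seed)
    labels = config.labels
    out: list = []
    if config.mode == "graph":
        prob = {lab: _edge_probability_matrix(config, lab) for lab in (1, -1)}
        iu, ju = np.triu_indices(config.n_regions, k=1)
        for s, y in enumerate(_subject_labels(config)):
            adj = np.zeros((config.n_regions, config.n_regions), dtype=np.int8)
            edges = rng.random(iu.size) < prob[y][iu, ju]
            adj[iu, ju] = edges
            adj[ju, iu] = edges
            out.append(BinaryGraph(
                adj=adj, region_labels=labels,
                subject_id=f"synth{s:03d}", class_label=y,
            ))
    elif config.mode == "timeseries":
        chol = {lab: np.linalg.cholesky(class_correlation_matrix(config, lab)) for lab in (1, -1)}
        for s, y in enumerate(_subject_labels(config)):
            z = rng.standard_normal((config.n_timepoints, config.n_regions))
            series = z @ chol[y].T
            if config.noise_sd > 0:
                series = series + config.noise_sd * rng.standard_normal(series.shape)
            out.append(RoiTimeSeries(
                values=series, region_labels=labels,
                subject_id=f"synth{s:03d}", class_label=y,
            ))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return out


def generate_dataset(
    config: SyntheticConfig,
    cutoff: float = DEFAULT_CUTOFF,
    threshold_mode: str = "raw",
    sentinel: float | None = None,
) -> Dataset:
    """Generate subjects and run them through to the feature matrix.

    Graph-mode subjects go straight to graph metrics; timeseries-mode
    subjects pass through Pearson connectivity and binarization first.
    """
    subjects = generate(config)
    vectors = []
    for subj in subjects:
        if isinstance(subj, RoiTimeSeries):
            graph = binarize(compute_fc(subj), cutoff=cutoff, mode=threshold_mode)
        else:
            graph = subj
        vectors.append(assemble_features(graph, sentinel=sentinel))
    return Dataset.from_feature_vectors(vectors)


def manifest(config: SyntheticConfig) -> dict:
    """Reproducibility record: parameters, labels and achieved effects."""
    doc = {
        "n_regions": config.n_regions,
        "n_per_class": config.n_per_class,
        "mode": config.mode,
        "seed": config.seed,
        "planted_pairs": [list(p) for p in config.planted_pairs],
        "planted_rois": list(config.planted_rois),
        "region_labels": config.labels,
        "class_labels": _subject_labels(config),
    }
    if config.mode == "graph":
        doc["edge_p"] = {
            "base": config.edge_p_base,
            "planted_pos": config.edge_p_planted_pos,
            "planted_neg": config.edge_p_planted_neg,
        }
    else:
        achieved = {}
        for lab, key in ((1, "pos"), (-1, "neg")):
            c = class_correlation_matrix(config, lab)
            atten = 1.0 / (1.0 + config.noise_sd**2)
            vals = [c[i, j] * atten for (i, j) in config.planted_pairs]
            achieved[key] = float(np.mean(vals)) if vals else None
        doc["corr"] = {
            "base": config.corr_base,
            "requested_planted_pos": config.corr_planted_pos,
            "requested_planted_neg": config.corr_planted_neg,
            "achieved_planted_pos_with_noise": achieved["pos"],
            "achieved_planted_neg_with_noise": achieved["neg"],
            "noise_sd": config.noise_sd,
        }
    return doc
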