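"""Graph-theory metrics on binary brain networks and the feature vector.

Four nodal/pairwise metrics are extracted from each subject's binary graph
and concatenated into one classification feature vector of length
R + C(R,2) + R + R (4,275 for the 90-ROI AAL parcellation):

* degree            — number of neighbours of each ROI;
* shortest path     — hop count between every unordered ROI pair
                      (BFS on the unweighted graph); disconnected pairs
                      receive a finite sentinel, by default R, which
                      exceeds any achievable path length;
* local efficiency  — Latora–Marchiori nodal efficiency: the global
                      efficiency (mean inverse distance) of the subgraph
                      induced by a node's neighbours; 0 for degree < 2;
* clustering coeff. — fraction of a node's neighbour pairs that are
                      themselves connected; 0 for degree < 2.

The fixed concatenation order is degrees (ROI ascending), shortest paths
(upper-triangle pairs (i, j), i < j, row-major), local efficiencies,
clustering coefficients; ``FeatureIndexMap`` records the metric and ROI(s)
behind every position so features can be mapped back to brain regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .connectivity import BinaryGraph

METRIC_DEGREE = "degree"
METRIC_SHORTEST_PATH = "shortest_path"
METRIC_LOCAL_EFFICIENCY = "local_efficiency"
METRIC_CLUSTERING = "clustering_coefficient"

NODAL_METRICS = (METRIC_DEGREE, METRIC_LOCAL_EFFICIENCY, METRIC_CLUSTERING)


@dataclass(frozen=True)
class FeatureIndexEntry:
    """Provenance of one feature-vector position."""

    metric: str
    roi_a: str
    roi_b: str | None = None  # set only for shortest-path features

    @property
    def name(self) -> str:
        prefix = {
            METRIC_DEGREE: "deg",
            METRIC_SHORTEST_PATH: "sp",
            METRIC_LOCAL_EFFICIENCY: "leff",
            METRIC_CLUSTERING: "cc",
        }[self.metric]
        if self.roi_b is not None:
            return f"{prefix}_{self.roi_a}__{self.roi_b}"
        return f"{prefix}_{self.roi_a}"


class FeatureIndexMap:
    """Ordered record of (metric, ROI(s)) for each feature position."""

    def __init__(self, region_labels: Sequence[str]):
        self.region_labels = list(region_labels)
        r = len(self.region_labels)
        entries: list[FeatureIndexEntry] = []
        entries += [FeatureIndexEntry(METRIC_DEGREE, lab) for lab in self.region_labels]
        for i in range(r):
            for j in range(i + 1, r):
                entries.append(
                    FeatureIndexEntry(
                        METRIC_SHORTEST_PATH,
                        self.region_labels[i],
                        self.region_labels[j],
                    )
                )
        entries += [FeatureIndexEntry(METRIC_LOCAL_EFFICIENCY, lab) for lab in self.region_labels]
        entries += [FeatureIndexEntry(METRIC_CLUSTERING, lab) for lab in self.region_labels]
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, idx: int) -> FeatureIndexEntry:
        return self.entries[idx]

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def pair_index(self, i: int, j: int) -> int:
        """0-based feature index of the shortest-path feature for ROI pair (i, j)."""
        r = self.n_regions
        if i == j or not (0 <= i < r and 0 <= j < r):
            raise ValueError(f"invalid ROI pair ({i}, {j}) for R={r}")
        if i > j:
            i, j = j, i
        # offset of row i in the row-major upper triangle
        return r + i * r - i * (i + 1) // 2 + (j - i - 1)


@dataclass
class GraphFeatureVector:
    """One subject's assembled metric vector plus its index map."""

    values: np.ndarray
    index_map: FeatureIndexMap
    subject_id: str = "subject"
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.index_map),):
            raise ValueError(
                f"feature vector length {self.values.shape} does not match "
                f"index map length {len(self.index_map)}"
            )


def feature_vector_length(n_regions: int) -> int:
    """R degrees + C(R,2) shortest paths + R local efficiencies + R clusterings."""
    return 3 * n_regions + n_regions * (n_regions - 1) // 2


def degree(g: BinaryGraph) -> np.ndarray:
    """Number of neighbours of each node (integer vector, length R)."""
    return g.adj.sum(axis=1).astype(np.int64)


def shortest_paths(g: BinaryGraph, sentinel: float | None = None) -> np.ndarray:
    """Hop-count distances for each unordered pair (i < j, row-major).

    Disconnected pairs receive ``sentinel`` (default R, one more than the
    longest achievable path).
    """
    r = g.n_regions
    if sentinel is None:
        sentinel = float(r)
    dist = _csgraph_shortest_path(g.adj, method="D", unweighted=True, directed=False)
    dist[np.isinf(dist)] = sentinel
    iu, ju = np.triu_indices(r, k=1)
    return dist[iu, ju]


def clustering_coefficient(g: BinaryGraph) -> np.ndarray:
    """Transitivity of each node's neighbourhood; 0 for degree < 2."""
    a = g.adj.astype(np.int64)
    k = a.sum(axis=1)
    triangles = np.diagonal(a @ a @ a) // 2  # closed triangles through each node
    denom = k * (k - 1)
    out = np.zeros(g.n_regions, dtype=float)
    mask = denom > 0
    out[mask] = 2.0 * triangles[mask] / denom[mask]
    return out


def _global_efficiency(adj: np.ndarray) -> float:
    """Mean inverse shortest-path distance over node pairs (1/inf = 0)."""
    m = adj.shape[0]
    if m < 2:
        return 0.0
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True, directed=False)
    iu, ju = np.triu_indices(m, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[iu, ju]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g: BinaryGraph) -> np.ndarray:
    """Global efficiency of each node's neighbour-induced subgraph."""
    out = np.zeros(g.n_regions, dtype=float)
    for i in range(g.n_regions):
        nbrs = np.flatnonzero(g.adj[i])
        if nbrs.size < 2:
            continue
        sub = g.adj[np.ix_(nbrs, nbrs)]
        out[i] = _global_efficiency(sub)
    return out


def assemble_features(g: BinaryGraph, sentinel: float | None = None) -> GraphFeatureVector:
    """Concatenate the four metrics into the fixed-order feature vector."""
    values = np.concatenate(
        [
            degree(g).astype(float),
            shortest_paths(g, sentinel=sentinel),
            local_efficiency(g),
            clustering_coefficient(g),
        ]
    )
    return GraphFeatureVector(
        values=values,
        index_map=FeatureIndexMap(g.region_labels),
        subject_id=g.subject_id,
        class_label=g.class_label,
    )


def features_to_frame(vectors: Iterable[GraphFeatureVector]) -> pd.DataFrame:
    """Tabulate subjects' feature vectors: one row per subject.

    Columns are the index-map feature names plus ``subject_id`` and
    ``label``; all subjects must share the same region labels.
    """
    vectors = list(vectors)
    if not vectors:
        raise ValueError("no feature vectors given")
    ref = vectors[0].index_map
    for v in vectors[1:]:
        if v.index_map.region_labels != ref.region_labels:
            raise ValueError("all subjects must share the same region labels")
    df = pd.DataFrame(
        np.vstack([v.values for v in vectors]),
        columns=ref.names,
    )
    df.insert(0, "subject_id", [v.subject_id for v in vectors])
    df.insert(1, "label", [v.class_label for v in vectors])
    return df


def write_features_csv(vectors: Iterable[GraphFeatureVector], path: str | Path) -> None:
    features_to_frame(vectors).to_csv(path, index=False)
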