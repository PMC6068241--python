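"""Functional-connectivity construction from ROI time series.

The brain network is built in two steps: (1) Pearson correlation between
every pair of ROI mean time series gives an R x R functional-connectivity
(FC) matrix; (2) a cut-off in [0, 1] binarizes the FC matrix into an
undirected, unweighted graph whose nodes are the atlas ROIs.

By default the cut-off is applied to the raw correlation (negative
correlations never form an edge); an ``absolute`` mode thresholds |r|
instead. The default cut-off is 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

DEFAULT_CUTOFF = 0.25

ThresholdMode = Literal["raw", "absolute"]


def _check_labels(labels: Sequence[str], n: int) -> list[str]:
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValueError(f"expected {n} region labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise ValueError("region labels must be unique")
    return labels


@dataclass
class RoiTimeSeries:
    """One subject's ROI-level signal matrix (timepoints x regions).

    Voxel-to-ROI averaging happens upstream (atlas handling is out of
    scope); ``values`` already holds one mean time series per ROI column.
    """

    values: np.ndarray
    region_labels: list[str]
    subject_id: str = "subject"
    class_label: int | None = None  # +1 patient, -1 control, None unknown

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series values must be a 2-D array")
        t, r = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if not np.isfinite(self.values).all():
            raise ValueError(f"non-finite values in time series of {self.subject_id!r}")
        self.region_labels = _check_labels(self.region_labels, r)
        if self.class_label not in (+1, -1, None):
            raise ValueError("class_label must be +1, -1 or None")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric matrix of pairwise Pearson correlations, unit diagonal."""

    r: np.ndarray
    region_labels: list[str]
    subject_id: str = "subject"
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(self.r, self.r.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")
        self.region_labels = _check_labels(self.region_labels, n)

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


@dataclass
class BinaryGraph:
    """Undirected unweighted graph: symmetric 0/1 adjacency, zero diagonal."""

    adj: np.ndarray
    region_labels: list[str]
    cutoff: float | None = None
    subject_id: str = "subject"
    class_label: int | None = None

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj)
        n = self.adj.shape[0]
        if self.adj.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.isin(self.adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.adj = self.adj.astype(np.int8)
        if (self.adj != self.adj.T).any():
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(self.adj).any():
            raise ValueError("adjacency diagonal must be zero")
        self.region_labels = _check_labels(self.region_labels, n)

    @property
    def n_regions(self) -> int:
        return self.adj.shape[0]


def compute_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate every pair of ROI time series.

    Raises
    ------
    ValueError
        If any ROI series has zero variance (its correlations are
        undefined), naming the offending ROI.
    """
    sd = ts.values.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        names = ", ".join(ts.region_labels[i] for i in flat[:5])
        raise ValueError(f"zero-variance time series for ROI(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        r=r,
        region_labels=list(ts.region_labels),
        subject_id=ts.subject_id,
        class_label=ts.class_label,
    )


def binarize(
    fc: ConnectivityMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    mode: ThresholdMode = "raw",
) -> BinaryGraph:
    """Threshold the FC matrix into a binary undirected graph.

    An edge (i, j), i != j, exists iff ``r_ij > cutoff`` (mode="raw") or
    ``|r_ij| > cutoff`` (mode="absolute"). The inequality is strict and the
    diagonal is always excluded.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    if mode not in ("raw", "absolute"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    vals = np.abs(fc.r) if mode == "absolute" else fc.r
    adj = (vals > cutoff).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return BinaryGraph(
        adj=adj,
        region_labels=list(fc.region_labels),
        cutoff=cutoff,
        subject_id=fc.subject_id,
        class_label=fc.class_label,
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_subject_csv(
    path: str | Path,
    subject_id: str | None = None,
    class_label: int | None = None,
    sep: str | None = None,
) -> RoiTimeSeries | ConnectivityMatrix:
    """Read a subject table: time series or precomputed connectivity.

    The file must have a header row of region labels. A square table whose
    row count equals its column count is interpreted as a precomputed
    connectivity matrix; anything else as timepoints x ROIs series.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.columns[0] == "region":  # labelled square matrix format
        df = df.drop(columns="region")
    labels = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    sid = subject_id if subject_id is not None else path.stem
    if values.shape[0] == values.shape[1] and np.allclose(values, values.T):
        return ConnectivityMatrix(values, labels, subject_id=sid, class_label=class_label)
    return RoiTimeSeries(values, labels, subject_id=sid, class_label=class_label)


def write_adjacency_csv(graph: BinaryGraph, path: str | Path) -> None:
    """Write the adjacency matrix as a labelled square CSV."""
    df = pd.DataFrame(graph.adj, columns=graph.region_labels)
    df.insert(0, "region", graph.region_labels)
    df.to_csv(path, index=False)


def read_adjacency_csv(
    path: str | Path,
    subject_id: str | None = None,
    class_label: int | None = None,
) -> BinaryGraph:
    """Read a labelled square adjacency CSV written by :func:`write_adjacency_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] == "region":
        labels = [str(x) for x in df["region"]]
        adj = df.drop(columns="region").to_numpy()
    else:
        labels = [str(c) for c in df.columns]
        adj = df.to_numpy()
    sid = subject_id if subject_id is not None else path.stem
    return BinaryGraph(adj=adj, region_labels=labels, subject_id=sid, class_label=class_label)
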