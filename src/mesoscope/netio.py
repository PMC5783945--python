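"""Containers and file I/O for weighted networks, partitions and system labels.

The central objects are :class:`WeightedNetwork` (an N x N nonnegative weight
matrix with named nodes), :class:`Partition` (node -> community labels, stored
canonically as 1..K by first appearance) and :class:`SystemLabels` (node ->
functional-system map).  File formats are deliberately plain: dense CSV/TSV
matrices, 3-column edge lists, and 2-column partition/label tables, always
keyed by node *names* rather than indices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedNetwork",
    "Partition",
    "SystemLabels",
    "read_network",
    "write_network",
    "read_partition",
    "write_partition",
    "read_system_labels",
]

_SYM_TOL = 1e-12


@dataclass
class WeightedNetwork:
    """A weighted, optionally directed network on named nodes.

    Parameters
    ----------
    weights
        N x N nonnegative real matrix; the diagonal must be zero.
    directed
        If ``False`` the matrix must be symmetric (within 1e-12).
    node_ids
        Ordered node names; defaults to ``n0..n{N-1}``.
    """

    weights: np.ndarray
    directed: bool = False
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weight matrix must be square")
        n = self.weights.shape[0]
        if n < 2:
            raise ValueError("a network needs at least 2 nodes")
        if not self.node_ids:
            self.node_ids = [f"n{i}" for i in range(n)]
        if len(self.node_ids) != n:
            raise ValueError("node_ids length does not match matrix size")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node ids")
        if np.any(self.weights < 0):
            raise ValueError("negative weight")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loop: diagonal entries must be zero")
        if not self.directed and not np.allclose(
            self.weights, self.weights.T, atol=_SYM_TOL, rtol=0.0
        ):
            raise ValueError("undirected network requires a symmetric matrix")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def binary(self) -> np.ndarray:
        """0/1 adjacency (weight > 0)."""
        return (self.weights > 0).astype(float)

    @property
    def degree(self) -> np.ndarray:
        """Binary degree: number of nonzero off-diagonal entries per row.

        For directed networks this is the out-degree; see ``in_degree``.
        """
        return (self.weights > 0).sum(axis=1)

    @property
    def in_degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=0)

    @property
    def strength(self) -> np.ndarray:
        """Weighted degree (row sums).  Out-strength when directed."""
        return self.weights.sum(axis=1)

    @property
    def in_strength(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    @property
    def total_weight(self) -> float:
        """2m for undirected networks: sum over the full matrix."""
        return float(self.weights.sum())

    def edges(self) -> list[tuple[int, int, float]]:
        """Edge list as (i, j, w); each undirected edge listed once (i < j)."""
        if self.directed:
            ii, jj = np.nonzero(self.weights)
            return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]
        ii, jj = np.nonzero(np.triu(self.weights, k=1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def index_of(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown node id: {node_id!r}") from None


@dataclass
class Partition:
    """Node -> community labels, canonicalized to 1..K by first appearance."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        raw = np.asarray(self.labels)
        if raw.ndim != 1 or raw.size == 0:
            raise ValueError("labels must be a non-empty 1-D sequence")
        seen: dict = {}
        out = np.empty(raw.size, dtype=int)
        for i, lab in enumerate(raw):
            key = lab.item() if isinstance(lab, np.generic) else lab
            if key not in seen:
                seen[key] = len(seen) + 1
            out[i] = seen[key]
        self.labels = out

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def K(self) -> int:
        return int(self.labels.max())

    @property
    def sizes(self) -> np.ndarray:
        """Community sizes n_r, index r-1 for community r."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    def members(self, r: int) -> np.ndarray:
        return np.flatnonzero(self.labels == r)

    def indicator(self) -> np.ndarray:
        """N x K one-hot community membership matrix."""
        z = np.zeros((self.n_nodes, self.K))
        z[np.arange(self.n_nodes), self.labels - 1] = 1.0
        return z

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Partition) and np.array_equal(self.labels, other.labels)


@dataclass
class SystemLabels:
    """Map node id -> functional-system name (each node exactly one system)."""

    mapping: dict[str, str]

    def for_network(self, network: WeightedNetwork) -> np.ndarray:
        missing = [n for n in network.node_ids if n not in self.mapping]
        if missing:
            raise ValueError(f"nodes without a system label: {missing}")
        return np.array([self.mapping[n] for n in network.node_ids])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if "\t" in head else ","


def read_network(path, format: str = "dense", directed: bool = False) -> WeightedNetwork:
    """Read a network from a dense matrix or an edge list.

    Dense: numeric CSV/TSV, optionally with a header row of node ids (the
    header is detected by non-numeric tokens in the first line).  Edge list:
    3-column TSV ``source  target  weight``; undirected edges are listed once
    and stored symmetrically.  Self-loops and duplicate edges are errors.
    """
    path = Path(path)
    if format == "dense":
        sep = _sniff_sep(path)
        first = path.read_text().splitlines()[0].split(sep)

        def _numeric(tok: str) -> bool:
            try:
                float(tok)
                return True
            except ValueError:
                return False

        has_header = not all(_numeric(t) for t in first if t.strip() != "")
        if has_header:
            df = pd.read_csv(path, sep=sep)
            node_ids = [str(c) for c in df.columns]
            mat = df.to_numpy(dtype=float)
        else:
            mat = pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)
            node_ids = []
        if mat.shape[0] != mat.shape[1]:
            raise ValueError("dense matrix is not square")
        return WeightedNetwork(mat, directed=directed, node_ids=node_ids)

    if format == "edgelist":
        df = pd.read_csv(path, sep="\t", header=None, names=["source", "target", "weight"])
        nodes: list[str] = []
        for col in ("source", "target"):
            for v in df[col].astype(str):
                if v not in nodes:
                    nodes.append(v)
        idx = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        mat = np.zeros((n, n))
        seen: set[tuple[int, int]] = set()
        for s, t, w in df.itertuples(index=False):
            i, j = idx[str(s)], idx[str(t)]
            if i == j:
                raise ValueError(f"self-loop on node {s!r}")
            key = (i, j) if directed else (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {s!r}-{t!r}")
            seen.add(key)
            w = float(w)
            if w < 0:
                raise ValueError("negative weight")
            mat[i, j] = w
            if not directed:
                mat[j, i] = w
        return WeightedNetwork(mat, directed=directed, node_ids=nodes)

    raise ValueError(f"unknown format {format!r}")


def write_network(network: WeightedNetwork, path, format: str = "dense") -> None:
    path = Path(path)
    if format == "dense":
        pd.DataFrame(network.weights, columns=network.node_ids).to_csv(
            path, sep="\t", index=False
        )
    elif format == "edgelist":
        rows = [
            (network.node_ids[i], network.node_ids[j], w) for i, j, w in network.edges()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_partition(path, node_ids: Sequence[str] | None = None) -> Partition:
    """Read a 2-column TSV (node_id, label); canonical relabeling applied.

    When ``node_ids`` is supplied the file must cover exactly those nodes and
    the labels are returned in that node order.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "label"])
    mapping = {str(n): lab for n, lab in df.itertuples(index=False)}
    if len(mapping) != len(df):
        raise ValueError("duplicate node in partition file")
    if node_ids is not None:
        missing = [n for n in node_ids if n not in mapping]
        if missing:
            raise ValueError(f"partition file missing nodes: {missing}")
        unknown = [n for n in mapping if n not in set(node_ids)]
        if unknown:
            raise ValueError(f"unknown node ids in partition file: {unknown}")
        labels = [mapping[n] for n in node_ids]
    else:
        labels = list(mapping.values())
    return Partition(np.asarray(labels))


def write_partition(partition: Partition, path, node_ids: Sequence[str] | None = None) -> None:
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(partition.n_nodes)]
    pd.DataFrame({"node": list(node_ids), "label": partition.labels}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_system_labels(path) -> SystemLabels:
    """Read node -> system labels from 2-column TSV or a JSON object."""
    path = Path(path)
    if path.suffix == ".json":
        return SystemLabels({str(k): str(v) for k, v in json.loads(path.read_text()).items()})
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "system"])
    return SystemLabels({str(n): str(s) for n, s in df.itertuples(index=False)})
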