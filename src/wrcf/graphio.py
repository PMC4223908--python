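"""Weighted-network container and readers/writers.

The analysis substrate is an undirected, signed, weighted graph with a
*stable node order*: every downstream index (filtration ranks, simplex
streams, scaffold tables) is a 0-based position in the node declaration
order, so reading the same file twice must produce the same order.

Supported formats: ``edgelist_csv`` (header ``source,target,weight``),
``matrix_csv`` (labelled dense square matrix, upper triangle read) and
``gexf`` (GEXF 1.2, undirected, weights in the standard ``weight`` edge
attribute).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedNetwork",
    "GraphFormatError",
    "read_network",
    "write_network",
    "FORMATS",
]

FORMATS = ("edgelist_csv", "matrix_csv", "gexf")

#: floats are written with 12 significant digits everywhere, so CSV output
#: is bit-stable across runs
FLOAT_FMT = "{:.12g}"

MATRIX_SYMMETRY_TOL = 1e-8


class GraphFormatError(ValueError):
    """Malformed input file (bad row, duplicate edge, asymmetry...)."""


@dataclass
class WeightedNetwork:
    """Undirected signed weighted graph with an ordered node list.

    Edges are keyed by the pair of node *positions* ``(i, j)`` with
    ``i < j``; self-loops and duplicate edges are rejected.
    """

    nodes: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _weights: dict[tuple[int, int], float] = field(default_factory=dict, repr=False)

    @classmethod
    def from_nodes(cls, nodes: Iterable[str]) -> "WeightedNetwork":
        net = cls()
        for n in nodes:
            net.add_node(str(n))
        return net

    # -- construction -----------------------------------------------------

    def add_node(self, label: str) -> int:
        if label in self._index:
            raise GraphFormatError(f"duplicate node label: {label!r}")
        self._index[label] = len(self.nodes)
        self.nodes.append(label)
        return self._index[label]

    def _pos(self, label: str, create: bool = False) -> int:
        if label not in self._index:
            if not create:
                raise KeyError(f"unknown node: {label!r}")
            return self.add_node(label)
        return self._index[label]

    def add_edge(self, u: str, v: str, weight: float, create_nodes: bool = True) -> None:
        if u == v:
            raise GraphFormatError(f"self-loop on node {u!r}")
        if not math.isfinite(weight):
            raise GraphFormatError(f"non-finite weight on edge ({u!r}, {v!r})")
        i, j = self._pos(u, create_nodes), self._pos(v, create_nodes)
        key = (i, j) if i < j else (j, i)
        if key in self._weights:
            raise GraphFormatError(f"duplicate edge ({u!r}, {v!r})")
        self._weights[key] = float(weight)

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._weights)

    def has_edge(self, u: str, v: str) -> bool:
        i, j = self._index.get(u), self._index.get(v)
        if i is None or j is None:
            return False
        return (min(i, j), max(i, j)) in self._weights

    def weight(self, u: str, v: str) -> float:
        i, j = self._pos(u), self._pos(v)
        return self._weights[(min(i, j), max(i, j))]

    def node_index(self, label: str) -> int:
        return self._index[label]

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as (label_u, label_v, weight), sorted by node positions."""
        for (i, j) in sorted(self._weights):
            yield self.nodes[i], self.nodes[j], self._weights[(i, j)]

    def edge_positions(self) -> Iterator[tuple[tuple[int, int], float]]:
        for key in sorted(self._weights):
            yield key, self._weights[key]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, w in self.edges():
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "WeightedNetwork":
        net = cls.from_nodes(str(n) for n in g.nodes())
        for u, v, data in g.edges(data=True):
            net.add_edge(str(u), str(v), float(data.get("weight", 1.0)), create_nodes=False)
        return net

    def to_matrix(self, fill: float = 0.0) -> pd.DataFrame:
        m = np.full((self.n_nodes, self.n_nodes), fill, dtype=float)
        np.fill_diagonal(m, 0.0)
        for (i, j), w in self._weights.items():
            m[i, j] = m[j, i] = w
        return pd.DataFrame(m, index=self.nodes, columns=self.nodes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self._weights == other._weights

    def allclose(self, other: "WeightedNetwork", tol: float = 1e-9) -> bool:
        if self.nodes != other.nodes or set(self._weights) != set(other._weights):
            return False
        return all(abs(w - other._weights[k]) <= tol for k, w in self._weights.items())


# -- readers ---------------------------------------------------------------


def _read_edgelist_csv(path: Path) -> WeightedNetwork:
    net = WeightedNetwork()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise GraphFormatError(f"{path}: empty file")
        if [h.strip().lower() for h in header[:3]] != ["source", "target", "weight"]:
            raise GraphFormatError(
                f"{path}: line 1: expected header 'source,target,weight', got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise GraphFormatError(f"{path}: line {lineno}: expected 3 fields, got {len(row)}")
            u, v, w_str = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                w = float(w_str)
            except ValueError:
                raise GraphFormatError(f"{path}: line {lineno}: bad weight {w_str!r}") from None
            try:
                net.add_edge(u, v, w)
            except GraphFormatError as exc:
                raise GraphFormatError(f"{path}: line {lineno}: {exc}") from None
    return net


def _read_matrix_csv(path: Path, zero_is_edge: bool = False) -> WeightedNetwork:
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise GraphFormatError(f"{path}: row labels do not match column labels")
    m = df.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1]:
        raise GraphFormatError(f"{path}: matrix is not square: {m.shape}")
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > MATRIX_SYMMETRY_TOL:
        raise GraphFormatError(f"{path}: matrix asymmetric (max |M - M^T| = {asym:g})")
    net = WeightedNetwork.from_nodes(labels)
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = m[i, j]
            if w != 0.0 or zero_is_edge:
                net.add_edge(labels[i], labels[j], w, create_nodes=False)
    return net


def _read_gexf(path: Path) -> WeightedNetwork:
    g = nx.read_gexf(path)
    if g.is_directed():
        g = g.to_undirected()
    # preserve declaration order from the file; read_gexf keeps it
    return WeightedNetwork.from_networkx(g)


def read_network(path: str | Path, format: str, zero_is_edge: bool = False) -> WeightedNetwork:
    """Read a weighted network from ``path`` in the named format.

    For matrix input only the upper triangle is read, the diagonal is
    ignored, and asymmetry beyond ``1e-8`` is rejected. ``zero_is_edge``
    keeps explicit 0.0 off-diagonals as edges (matrix format only).
    """
    path = Path(path)
    if format == "edgelist_csv":
        return _read_edgelist_csv(path)
    if format == "matrix_csv":
        return _read_matrix_csv(path, zero_is_edge=zero_is_edge)
    if format == "gexf":
        return _read_gexf(path)
    raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


# -- writers ---------------------------------------------------------------


def write_network(net: WeightedNetwork, path: str | Path, format: str,
                  graph_attrs: dict | None = None) -> None:
    """Write ``net`` to ``path``; ``graph_attrs`` become GEXF graph-level
    attributes (ignored by the CSV formats)."""
    path = Path(path)
    if format == "edgelist_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            for u, v, wt in net.edges():
                w.writerow([u, v, FLOAT_FMT.format(wt)])
    elif format == "matrix_csv":
        df = net.to_matrix()
        df.to_csv(path, float_format="%.12g")
    elif format == "gexf":
        g = net.to_networkx()
        for k, v in (graph_attrs or {}).items():
            g.graph[k] = v
        nx.write_gexf(g, path, version="1.2draft")
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
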