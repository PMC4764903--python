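"""Undirected simple networks: edge-list I/O, adjacency matrices, summaries.

Every other module consumes the :class:`Network` container defined here.
Networks are simple (no self-loops, no multi-edges) and undirected; node
labels are kept as given in the input, while internal indices 0..n-1 follow
a deterministic sorted order so that results are reproducible across runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


class NetworkError(ValueError):
    """Invalid network content (self-loop, unknown node, empty input)."""


class EdgeListParseError(NetworkError):
    """Malformed edge-list line; carries the offending line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def _label_sort_key(labels: Iterable):
    labels = list(labels)
    try:
        return sorted(labels, key=lambda x: int(x))
    except (TypeError, ValueError):
        return sorted(labels, key=str)


@dataclass(frozen=True)
class Network:
    """A simple undirected network with deterministically indexed nodes.

    Attributes
    ----------
    labels : tuple
        Node labels in internal index order (sorted numerically when every
        label parses as an integer, lexicographically otherwise).
    edges : frozenset of (int, int)
        Unordered edges as index pairs with i < j.
    """

    labels: tuple
    edges: frozenset

    @classmethod
    def from_edges(cls, edge_pairs: Iterable[tuple], nodes: Iterable = ()) -> "Network":
        """Build a network from label pairs, collapsing duplicates.

        Self-loops raise :class:`NetworkError`. ``nodes`` may add isolated
        nodes beyond those appearing in ``edge_pairs``.
        """
        raw_edges = []
        label_set = set(nodes)
        for u, v in edge_pairs:
            if u == v:
                raise NetworkError(f"self-loop on node {u!r} is not allowed")
            label_set.update((u, v))
            raw_edges.append((u, v))
        labels = tuple(_label_sort_key(label_set))
        index = {lab: i for i, lab in enumerate(labels)}
        edges = frozenset(
            (min(index[u], index[v]), max(index[u], index[v])) for u, v in raw_edges
        )
        return cls(labels=labels, edges=edges)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def e(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def edge_labels(self) -> set:
        """Edges as frozensets of original labels."""
        return {frozenset((self.labels[i], self.labels[j])) for i, j in self.edges}

    def adjacency(self, sparse: bool = True):
        """Binary symmetric adjacency matrix with zero diagonal."""
        if not self.edges:
            A = sp.csr_array((self.n, self.n), dtype=np.float64)
        else:
            ij = np.array(sorted(self.edges), dtype=np.int64)
            rows = np.concatenate([ij[:, 0], ij[:, 1]])
            cols = np.concatenate([ij[:, 1], ij[:, 0]])
            data = np.ones(rows.shape[0], dtype=np.float64)
            A = sp.csr_array((data, (rows, cols)), shape=(self.n, self.n))
        return A if sparse else A.toarray()

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        return self.n > 0 and nx.is_connected(self.to_networkx())


@dataclass(frozen=True)
class NetworkSummary:
    """Headline statistics: size, average degree and spectral radius."""

    n: int
    e: int
    avg_degree: float
    lambda1: float
    inv_lambda1: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "e": self.e,
            "avg_degree": self.avg_degree,
            "lambda1": self.lambda1,
            "inv_lambda1": self.inv_lambda1,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def read_edge_list(path, delimiter: str | None = None, comment_prefix: str = "#") -> Network:
    """Parse a plain-text edge list into a :class:`Network`.

    Each non-comment, non-blank line must contain exactly two node labels,
    separated by whitespace (default) or ``delimiter``. Lines whose first
    non-blank character is ``comment_prefix`` are skipped. Commas are
    auto-detected when no delimiter is given. Duplicate and reversed
    duplicate edges collapse silently; a self-loop is a hard error.
    """
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(comment_prefix):
                continue
            sep = delimiter
            if sep is None and "," in stripped and " " not in stripped and "\t" not in stripped:
                sep = ","
            tokens = [tok for tok in stripped.split(sep) if tok]
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"expected exactly two node labels, got {len(tokens)}: {stripped!r}",
                    lineno,
                )
            u, v = tokens
            if u == v:
                raise NetworkError(f"line {lineno}: self-loop on node {u!r}")
            edges.append((u, v))
    return Network.from_edges(edges)


def write_edge_list(net: Network, path, delimiter: str = " ") -> None:
    """Write one edge per line using original labels (isolated nodes are lost)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{net.labels[i]}{delimiter}{net.labels[j]}\n")


def build_adjacency(net: Network, sparse: bool = True):
    """Adjacency matrix A of a network: binary, symmetric, zero diagonal."""
    return net.adjacency(sparse=sparse)


def largest_connected_component(net: Network) -> Network:
    """Induced subgraph on the largest component.

    Ties between equally sized components are broken by the component
    containing the smallest node label (in internal sort order).
    """
    if net.n == 0:
        raise NetworkError("empty network has no components")
    comps = list(nx.connected_components(net.to_networkx()))
    best = min(comps, key=lambda c: (-len(c), min(c)))
    keep = set(best)
    edge_pairs = [
        (net.labels[i], net.labels[j]) for i, j in net.edges if i in keep and j in keep
    ]
    node_labels = [net.labels[i] for i in keep]
    return Network.from_edges(edge_pairs, nodes=node_labels)


def leading_eigenvalue(A, tol: float = 1e-10) -> float:
    """Largest eigenvalue of a symmetric matrix.

    Dense solver below n=200, sparse Lanczos (``eigsh``) above.
    """
    n = A.shape[0]
    if n < 200:
        dense = A.toarray() if sp.issparse(A) else np.asarray(A, dtype=float)
        return float(np.linalg.eigvalsh(dense)[-1])
    A = sp.csr_array(A)
    val = spla.eigsh(A, k=1, which="LA", tol=tol, return_eigenvectors=False)
    return float(val[0])


def network_summary(net: Network) -> NetworkSummary:
    """Compute n, e, average degree 2e/n, lambda1 and 1/lambda1.

    Warns (but proceeds on the input as given) when the network is
    disconnected, since the spreading analysis assumes connectivity.
    """
    if net.n == 0:
        raise NetworkError("cannot summarize an empty network")
    if not net.is_connected():
        warnings.warn(
            "network is disconnected; summary computed on the input as given",
            UserWarning,
            stacklevel=2,
        )
    lam1 = leading_eigenvalue(net.adjacency()) if net.e > 0 else 0.0
    return NetworkSummary(
        n=net.n,
        e=net.e,
        avg_degree=2.0 * net.e / net.n,
        lambda1=lam1,
        inv_lambda1=(1.0 / lam1) if lam1 > 0 else float("inf"),
    )
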