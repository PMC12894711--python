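"""Hypergraph container, readers/writers, and per-order decomposition.

A hypergraph is a set of N labeled nodes together with a multiset of
hyperedges, each a subset of nodes of size >= 2.  A hyperedge involving
d + 1 nodes is said to be of *order* d: order 1 is a pairwise edge, order 2
a triplet, and so on.  All spectral machinery in this package consumes the
per-order *generalized degrees* K^(d) (number of d-hyperedges at each node)
and the per-order adjacency matrices A^(d) (number of d-hyperedges shared
by each node pair) produced by :func:`order_decomposition`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Hypergraph",
    "OrderDecomposition",
    "order_decomposition",
    "read_hypergraph",
    "write_hypergraph",
]


class HypergraphError(ValueError):
    """Raised for invalid hypergraph structure or unparseable input."""


@dataclass(frozen=True)
class Hypergraph:
    """Immutable hypergraph over nodes indexed ``0..N-1``.

    Parameters
    ----------
    node_labels
        Ordered distinct labels; position defines the node index.
    edges
        Sequence of frozensets of node indices, each of size >= 2.
        Duplicates are permitted (multiset semantics); most constructors
        deduplicate by default.
    metadata
        Free-form key/value information (name, source file, ...).
    """

    node_labels: tuple
    edges: tuple
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        n = len(self.node_labels)
        if len(set(self.node_labels)) != n:
            raise HypergraphError("node labels must be distinct")
        for e in self.edges:
            if not isinstance(e, frozenset):
                raise HypergraphError("edges must be frozensets of node indices")
            if len(e) < 2:
                raise HypergraphError(f"hyperedge {set(e)} has size < 2")
            if not all(isinstance(i, (int, np.integer)) and 0 <= i < n for i in e):
                raise HypergraphError(f"hyperedge {set(e)} references unknown node")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[Iterable],
        nodes: Sequence | None = None,
        dedupe: bool = True,
        drop_singletons: bool = True,
        metadata: Mapping | None = None,
    ) -> "Hypergraph":
        """Build from label-valued hyperedges.

        Node labels are the union of ``nodes`` (if given) and all labels
        appearing in ``edges``, indexed in sorted order so the mapping is
        deterministic across runs.
        """
        edges = [list(e) for e in edges]
        labels = set(nodes) if nodes is not None else set()
        for e in edges:
            labels.update(e)
        ordered = tuple(sorted(labels, key=lambda x: (str(type(x)), x)))
        index = {lab: i for i, lab in enumerate(ordered)}

        n_singletons = 0
        out = []
        for e in edges:
            if len(set(e)) != len(e):
                raise HypergraphError(f"hyperedge {e} contains a repeated node")
            if len(e) < 2:
                if drop_singletons:
                    n_singletons += 1
                    continue
                raise HypergraphError(f"hyperedge {e} has size < 2")
            out.append(frozenset(index[x] for x in e))
        if n_singletons:
            logger.info("dropped %d size-1 records (nodes kept)", n_singletons)
        if dedupe:
            seen: dict = {}
            for e in out:
                seen.setdefault(e, None)
            out = list(seen)
        meta = dict(metadata or {})
        return cls(ordered, tuple(out), meta)

    # -- basic properties -------------------------------------------------

    @property
    def num_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    @property
    def d_max(self) -> int:
        """Maximum order among hyperedges (size - 1)."""
        if not self.edges:
            raise HypergraphError("empty edge set has no maximum order")
        return max(len(e) for e in self.edges) - 1

    @property
    def orders(self) -> tuple:
        """Sorted orders present in the edge multiset."""
        return tuple(sorted({len(e) - 1 for e in self.edges}))

    def edges_of_order(self, d: int) -> list:
        return [e for e in self.edges if len(e) == d + 1]

    def edge_labels(self) -> list:
        """Hyperedges as sorted lists of node labels."""
        return [sorted((self.node_labels[i] for i in e), key=str) for e in self.edges]

    def relabel_to_indices(self) -> "Hypergraph":
        return Hypergraph(tuple(range(self.num_nodes)), self.edges, dict(self.metadata))


@dataclass(frozen=True)
class OrderDecomposition:
    """Per-order degrees and adjacency matrices of a hypergraph.

    ``degrees[d]`` is the length-N vector K^(d); ``adjacency[d]`` the
    symmetric N x N matrix A^(d) with zero diagonal, counting d-hyperedges
    shared by each node pair.  ``orders`` lists the orders with at least
    one hyperedge (equivalently <K^(d)> > 0).
    """

    num_nodes: int
    degrees: dict
    adjacency: dict

    @property
    def orders(self) -> tuple:
        return tuple(sorted(self.degrees))

    def orders_up_to(self, d: int) -> tuple:
        """Existing orders <= d (the set the multiorder sum runs over)."""
        return tuple(o for o in self.orders if o <= d)

    def mean_degree(self, d: int) -> float:
        return float(self.degrees[d].mean())


def order_decomposition(H: Hypergraph) -> OrderDecomposition:
    """Split ``H`` into generalized degrees and adjacencies, order by order.

    For every order d present: K^(d)_i counts the d-hyperedges containing
    node i, and A^(d)_{ij} counts the d-hyperedges containing both i and j
    (zero diagonal).  Duplicate hyperedges, if the container holds any,
    contribute their multiplicity.
    """
    n = H.num_nodes
    degrees: dict = {}
    adjacency: dict = {}
    for e in H.edges:
        d = len(e) - 1
        if d not in degrees:
            degrees[d] = np.zeros(n, dtype=np.int64)
            adjacency[d] = np.zeros((n, n), dtype=np.int64)
        members = list(e)
        degrees[d][members] += 1
        A = adjacency[d]
        for i, j in combinations(members, 2):
            A[i, j] += 1
            A[j, i] += 1
    return OrderDecomposition(n, degrees, adjacency)


# -- file formats ---------------------------------------------------------

def _read_edgelist(path) -> tuple[list, dict]:
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = [t for t in line.replace(",", " ").split() if t]
            if len(set(tokens)) != len(tokens):
                raise HypergraphError(
                    f"{path}:{lineno}: hyperedge with repeated node: {line!r}"
                )
            edges.append(tokens)
    return edges, {}


def _read_xgi_json(path) -> tuple[list, list, dict]:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise HypergraphError(f"{path}: malformed JSON: {exc}") from exc
    if "edge-dict" not in data or "node-data" not in data:
        raise HypergraphError(f"{path}: missing 'edge-dict' or 'node-data' key")
    known = {"hypergraph-data", "node-data", "edge-data", "edge-dict"}
    for key in set(data) - known:
        logger.info("%s: ignoring unknown top-level key %r", path, key)
    nodes = list(data["node-data"])
    node_set = set(nodes)
    edges = []
    for eid, members in data["edge-dict"].items():
        for m in members:
            if m not in node_set:
                raise HypergraphError(
                    f"{path}: edge {eid!r} references unknown node {m!r}"
                )
        edges.append(list(members))
    meta = dict(data.get("hypergraph-data", {}))
    return edges, nodes, meta


def read_hypergraph(
    path,
    format: str | None = None,
    dedupe: bool = True,
    drop_singletons: bool = True,
) -> Hypergraph:
    """Read a hypergraph from an xgi-data JSON file or a plain edge list.

    ``format`` is ``"xgi-json"`` or ``"edgelist"``; if omitted it is
    inferred from the file extension (``.json`` -> xgi-json).  Duplicate
    hyperedges collapse to one when ``dedupe`` is true; size-1 records are
    discarded (with a logged count) when ``drop_singletons`` is true, their
    nodes staying in the node set.
    """
    path = str(path)
    if format is None:
        format = "xgi-json" if path.endswith(".json") else "edgelist"
    if format == "xgi-json":
        edges, nodes, meta = _read_xgi_json(path)
    elif format == "edgelist":
        edges, meta = _read_edgelist(path)
        nodes = None
    else:
        raise ValueError(f"unknown format {format!r}")
    meta.setdefault("source", path)
    return Hypergraph.from_edges(
        edges, nodes=nodes, dedupe=dedupe, drop_singletons=drop_singletons,
        metadata=meta,
    )


def write_hypergraph(H: Hypergraph, path, format: str | None = None) -> None:
    """Write ``H`` so that :func:`read_hypergraph` round-trips it.

    The edgelist format loses isolated nodes; use xgi-json to preserve the
    full node set.
    """
    path = str(path)
    if format is None:
        format = "xgi-json" if path.endswith(".json") else "edgelist"
    if format == "edgelist":
        with open(path, "w") as fh:
            for e in H.edge_labels():
                fh.write(" ".join(str(x) for x in e) + "\n")
    elif format == "xgi-json":
        data = {
            "hypergraph-data": {
                k: v for k, v in H.metadata.items() if k != "source"
            },
            "node-data": {str(lab): {} for lab in H.node_labels},
            "edge-data": {str(i): {} for i in range(H.num_edges)},
            "edge-dict": {
                str(i): [str(x) for x in e] for i, e in enumerate(H.edge_labels())
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh)
    else:
        raise ValueError(f"unknown format {format!r}")
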