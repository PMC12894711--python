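"""Structural metrics tracked alongside reducibility.

Scalar summaries of a hypergraph: edge density M/N, maximum and
heterogeneity of the total generalized degree, spectral radius of the
aggregated adjacency, the simplicial fraction (nestedness), and the
cross-order degree correlation between orders 1 and 2.  Undefined cases
(constant degree vectors, no higher-order edges) raise
:class:`UndefinedMetricError`; :func:`metric_report` collects everything
and flags the undefined entries instead of propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .hypergraph import Hypergraph, HypergraphError, order_decomposition

__all__ = [
    "UndefinedMetricError",
    "density_metric",
    "simplicial_fraction",
    "cross_order_degree_correlation",
    "degree_heterogeneity",
    "spectral_radius",
    "max_degree",
    "metric_report",
    "MetricReport",
]


class UndefinedMetricError(HypergraphError):
    """The metric is undefined on this hypergraph (e.g. zero variance)."""


def _total_degrees(H: Hypergraph) -> np.ndarray:
    """Total generalized degree K_i = Σ_d K^(d)_i."""
    dec = order_decomposition(H)
    K = np.zeros(H.num_nodes, dtype=np.int64)
    for d in dec.orders:
        K += dec.degrees[d]
    return K


def density_metric(H: Hypergraph) -> float:
    """Hyperedge density M/N."""
    if H.num_nodes == 0:
        raise HypergraphError("hypergraph has no nodes")
    return H.num_edges / H.num_nodes


def simplicial_fraction(H: Hypergraph) -> float:
    """Fraction of size >= 3 hyperedges whose every subface is present.

    A subface is any subset of size >= 2.  Equals 1 on simplicial
    complexes and is near 0 in uncorrelated random hypergraphs; undefined
    (raises) when there is no hyperedge of size >= 3.
    """
    edge_set = set(H.edges)
    top = [e for e in edge_set if len(e) >= 3]
    if not top:
        raise UndefinedMetricError("no hyperedge of size >= 3")
    closed = 0
    for e in top:
        members = sorted(e)
        ok = all(
            frozenset(sub) in edge_set
            for size in range(2, len(e))
            for sub in combinations(members, size)
        )
        closed += ok
    return closed / len(top)


def cross_order_degree_correlation(H: Hypergraph, d1: int = 1, d2: int = 2) -> float:
    """Pearson correlation of the order-d1 and order-d2 degree sequences."""
    dec = order_decomposition(H)
    for d in (d1, d2):
        if d not in dec.degrees:
            raise UndefinedMetricError(f"order {d} not present")
    x = dec.degrees[d1].astype(float)
    y = dec.degrees[d2].astype(float)
    x = x - x.mean()
    y = y - y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedMetricError("a degree sequence is constant")
    return float(x @ y / (nx * ny))


def _het(K: np.ndarray) -> float:
    k_max = float(K.max())
    if k_max == 0:
        return 0.0
    return (k_max - float(K.mean())) / k_max


def degree_heterogeneity(H: Hypergraph, aggregate: str = "per-order") -> float:
    """Generalized-degree heterogeneity (K_max − <K>)/K_max; 0 when regular.

    With ``aggregate="per-order"`` (default) the statistic is computed on
    each order's degree sequence and averaged over orders.  This keeps it
    zero for structures that are regular at every order, and makes it an
    exact invariant of any randomization preserving the per-order degree
    multisets (configuration model, node swap).  ``aggregate="total"``
    instead uses the total degree K_i = Σ_d K^(d)_i, and
    ``aggregate="pooled"`` the pooled multiset of all per-order degrees.
    """
    if not H.edges:
        raise HypergraphError("empty hypergraph")
    dec = order_decomposition(H)
    if aggregate == "per-order":
        return float(np.mean([_het(dec.degrees[d]) for d in dec.orders]))
    if aggregate == "pooled":
        return _het(np.concatenate([dec.degrees[d] for d in dec.orders]))
    if aggregate == "total":
        return _het(_total_degrees(H))
    raise ValueError(f"unknown aggregate {aggregate!r}")


def max_degree(H: Hypergraph) -> int:
    """Maximum total generalized degree."""
    if not H.edges:
        raise HypergraphError("empty hypergraph")
    return int(_total_degrees(H).max())


def spectral_radius(H: Hypergraph) -> float:
    """Largest absolute eigenvalue of the aggregated adjacency Σ_d A^(d)."""
    if not H.edges:
        raise HypergraphError("empty hypergraph")
    dec = order_decomposition(H)
    A = np.zeros((H.num_nodes, H.num_nodes))
    for d in dec.orders:
        A += dec.adjacency[d]
    return float(np.abs(np.linalg.eigvalsh(A)).max())


@dataclass(frozen=True)
class MetricReport:
    """All structural metrics of a hypergraph, with undefined ones flagged."""

    density: float
    max_degree: int
    spectral_radius: float
    simplicial_fraction: float | None
    cross_order_degree_correlation: float | None
    degree_heterogeneity: float
    flags: tuple

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "max_degree": self.max_degree,
            "spectral_radius": self.spectral_radius,
            "simplicial_fraction": self.simplicial_fraction,
            "cross_order_degree_correlation": self.cross_order_degree_correlation,
            "degree_heterogeneity": self.degree_heterogeneity,
            "flags": list(self.flags),
        }


def metric_report(H: Hypergraph) -> MetricReport:
    flags = []
    try:
        sf = simplicial_fraction(H)
    except UndefinedMetricError as exc:
        sf, _ = None, flags.append(f"simplicial_fraction undefined: {exc}")
    try:
        dc = cross_order_degree_correlation(H)
    except UndefinedMetricError as exc:
        dc, _ = None, flags.append(f"cross_order_degree_correlation undefined: {exc}")
    return MetricReport(
        density=density_metric(H),
        max_degree=max_degree(H),
        spectral_radius=spectral_radius(H),
        simplicial_fraction=sf,
        cross_order_degree_correlation=dc,
        degree_heterogeneity=degree_heterogeneity(H),
        flags=tuple(flags),
    )
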