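"""Synthetic hypergraph generators.

Random models follow the Erdős–Rényi-style construction: for each order d,
every (d+1)-subset of nodes becomes a hyperedge independently with
probability p_d.  The simplicial-complex variant closes the result
downward (every sub-face of size >= 2 is added).  Regular families —
hyperring, complete hypergraph, periodic triangular-lattice simplicial
complex — serve as analytically tractable references.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np

from .hypergraph import Hypergraph, HypergraphError

__all__ = [
    "random_hypergraph",
    "random_simplicial_complex",
    "hyperring",
    "complete_hypergraph",
    "triangular_lattice_sc",
    "downward_closure",
    "nested_contact_surrogate",
]


def _validate_probabilities(n: int, p: dict) -> None:
    for d, pd in p.items():
        if not (0.0 <= pd <= 1.0):
            raise HypergraphError(f"p[{d}]={pd} outside [0, 1]")
        if d + 1 > n:
            raise HypergraphError(f"order {d} needs {d + 1} nodes, have {n}")
        if d < 1:
            raise HypergraphError(f"order must be >= 1, got {d}")


def _sample_subsets(rng: np.random.Generator, n: int, size: int, m: int) -> set:
    """Draw ``m`` distinct node subsets of the given size uniformly."""
    chosen: set = set()
    while len(chosen) < m:
        draw = rng.choice(n, size=size, replace=False)
        chosen.add(frozenset(int(x) for x in draw))
    return chosen


def random_hypergraph(n: int, p: dict, seed=None) -> Hypergraph:
    """Random hypergraph with per-order wiring probabilities.

    Each combination of d+1 nodes becomes a d-hyperedge independently with
    probability ``p[d]``.  Rather than enumerating all C(n, d+1) subsets,
    the number of hyperedges per order is drawn from the corresponding
    binomial and that many distinct subsets are sampled uniformly — the
    same distribution, tractable at d = 4, n = 100.
    """
    _validate_probabilities(n, p)
    rng = np.random.default_rng(seed)
    edges: list = []
    for d in sorted(p):
        total = comb(n, d + 1)
        m = int(rng.binomial(total, p[d]))
        edges.extend(_sample_subsets(rng, n, d + 1, m))
    labels = tuple(range(n))
    return Hypergraph(labels, tuple(edges), {"name": "random-hypergraph"})


def downward_closure(H: Hypergraph) -> Hypergraph:
    """Add every sub-face (size >= 2) of every hyperedge."""
    closed: dict = {}
    for e in H.edges:
        closed.setdefault(e, None)
        for size in range(2, len(e)):
            for sub in combinations(sorted(e), size):
                closed.setdefault(frozenset(sub), None)
    return Hypergraph(H.node_labels, tuple(closed), dict(H.metadata))


def random_simplicial_complex(n: int, p: dict, seed=None) -> Hypergraph:
    """Random hypergraph closed downward, hence a simplicial complex."""
    H = downward_closure(random_hypergraph(n, p, seed))
    H.metadata["name"] = "random-simplicial-complex"
    return H


def hyperring(n: int) -> Hypergraph:
    """Ring of n nodes with first-neighbor pairs and consecutive triples.

    Edges are {i, i+1} and {i-1, i, i+1} (mod n) for every i: exactly n
    pairwise edges and n triangles, each node in 2 pairs and 3 triples.
    Note the (i-1, i+1) chord of each triangle is *not* a declared pairwise
    edge; the structure is generated exactly from these two families and no
    downward closure is applied, so the pairwise generalized degree is 2.
    """
    if n < 5:
        raise HypergraphError("hyperring needs n >= 5 (distinct triples)")
    edges = [frozenset((i, (i + 1) % n)) for i in range(n)]
    edges += [frozenset(((i - 1) % n, i, (i + 1) % n)) for i in range(n)]
    return Hypergraph(tuple(range(n)), tuple(edges), {"name": "hyperring"})


def complete_hypergraph(n: int, d_max: int) -> Hypergraph:
    """All node subsets of sizes 2 .. d_max + 1."""
    if d_max < 1 or d_max + 1 > n:
        raise HypergraphError(f"need 1 <= d_max <= n - 1, got d_max={d_max}, n={n}")
    edges = []
    for size in range(2, d_max + 2):
        edges.extend(frozenset(c) for c in combinations(range(n), size))
    return Hypergraph(tuple(range(n)), tuple(edges), {"name": "complete"})


def triangular_lattice_sc(rows: int, cols: int) -> Hypergraph:
    """Periodic (toroidal) triangular lattice with every triangle a 2-simplex.

    Nodes sit on a rows x cols torus; node (r, c) is linked to
    (r, c+1), (r+1, c) and (r+1, c-1), giving six neighbors each.  Each unit
    cell carries two triangles, so every node lies in six 1-simplices and
    six 2-simplices and every 1-simplex in exactly two 2-simplices — the
    proportional-Laplacian lattice with A^(2) = 2 A^(1) and B(2) = 1.
    """
    if rows < 3 or cols < 3:
        raise HypergraphError("triangular lattice needs rows, cols >= 3")

    def node(r: int, c: int) -> int:
        return (r % rows) * cols + (c % cols)

    edges: dict = {}
    for r in range(rows):
        for c in range(cols):
            a, b, d = node(r, c), node(r, c + 1), node(r + 1, c)
            e = node(r + 1, c + 1)
            for pair in ((a, b), (a, d), (b, d)):
                edges.setdefault(frozenset(pair), None)
            # two triangles per cell: "up" (a,b,d) and "down" (b,d,e)
            edges.setdefault(frozenset((a, b, d)), None)
            edges.setdefault(frozenset((b, d, e)), None)
    n = rows * cols
    return Hypergraph(
        tuple(range(n)), tuple(edges), {"name": "triangular-lattice-sc"}
    )


def nested_contact_surrogate(
    n: int = 80,
    m_pairs: int = 60,
    m_triples: int = 60,
    m_quads: int = 15,
    alpha: float = 2.0,
    seed=None,
) -> Hypergraph:
    """Nested hypergraph with heavy-tailed degrees, mimicking contact data.

    Face-to-face contact datasets combine strong nestedness (a group photo
    implies all its sub-groups met) with gregarious hub individuals.  This
    surrogate samples hyperedges with node weights drawn from a Pareto
    distribution with shape ``alpha`` (smaller = heavier tail), so a few
    hubs join many groups, then closes the structure downward.  The result
    has simplicial fraction 1, skewed generalized degrees, and strongly
    correlated degree sequences across orders.
    """
    if alpha <= 0:
        raise HypergraphError("alpha must be positive")
    rng = np.random.default_rng(seed)
    w = rng.pareto(alpha, n) + 0.1
    prob = w / w.sum()
    edges: dict = {}
    for size, m in ((2, m_pairs), (3, m_triples), (4, m_quads)):
        if m and size > n:
            raise HypergraphError(f"cannot draw size-{size} edges from {n} nodes")
        for _ in range(m):
            draw = rng.choice(n, size=size, replace=False, p=prob)
            edges.setdefault(frozenset(int(x) for x in draw), None)
    H = Hypergraph(tuple(range(n)), tuple(edges), {"name": "nested-contact-surrogate"})
    return downward_closure(H)
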