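"""Null models: configuration model, node swap, and hyperedge shuffling.

Three randomizations of increasing destructiveness, applied independently
at each interaction order:

* configuration model — rewires hyperedges by stub matching, preserving
  the generalized-degree *sequence* at every order;
* node swap — exchanges the order-d memberships of high/low-degree node
  pairs, preserving the degree *distribution* (multiset) but not which
  node holds which degree, and so destroying cross-order correlations;
* shuffle — replaces each hyperedge, with probability p_shuffle, by a
  uniformly random non-existing hyperedge of the same size, preserving
  only the per-order edge counts.
"""

from __future__ import annotations

import logging
from math import comb

import numpy as np

from .hypergraph import Hypergraph, HypergraphError, order_decomposition

logger = logging.getLogger(__name__)

__all__ = ["configuration_model", "node_swap", "shuffle_hyperedges"]


class RandomizationError(HypergraphError):
    """The randomization could not produce a valid sample."""


def _match_stubs(
    rng: np.random.Generator, stubs: np.ndarray, size: int, max_retries: int
) -> list | None:
    """Partition a shuffled stub list into groups of distinct nodes.

    Groups with repeated nodes are repaired by swapping one offending stub
    with a random stub elsewhere; gives up (returns None) after
    ``max_retries`` failed swaps so the caller can reshuffle.
    """
    stubs = stubs.copy()
    rng.shuffle(stubs)
    n_groups = stubs.size // size
    retries = 0
    for g in range(n_groups):
        lo = g * size
        while len(set(stubs[lo : lo + size])) < size:
            retries += 1
            if retries > max_retries:
                return None
            j = int(rng.integers(stubs.size))
            k = lo + int(rng.integers(size))
            stubs[j], stubs[k] = stubs[k], stubs[j]
    # a late swap may have corrupted an earlier group: verify
    groups = [frozenset(int(x) for x in stubs[g * size : (g + 1) * size])
              for g in range(n_groups)]
    if any(len(g) < size for g in groups):
        return None
    return groups


def configuration_model(
    H: Hypergraph, seed=None, max_retries: int | None = None
) -> Hypergraph:
    """Stub-matching rewiring preserving per-order degree sequences.

    Each node contributes K^(d)_i stubs at order d; stubs are matched into
    groups of d+1 distinct nodes.  Duplicate hyperedges may arise and are
    kept (and logged): the output is a multiset with exactly the input's
    per-order edge counts and degree sequences.
    """
    rng = np.random.default_rng(seed)
    dec = order_decomposition(H)
    if max_retries is None:
        max_retries = 100 * max(1, H.num_edges)
    edges: list = []
    for d in dec.orders:
        K = dec.degrees[d]
        stubs = np.repeat(np.arange(H.num_nodes), K)
        groups = None
        for _ in range(50):
            groups = _match_stubs(rng, stubs, d + 1, max_retries)
            if groups is not None:
                break
        if groups is None:
            raise RandomizationError(
                f"could not match stubs at order {d} after repeated restarts"
            )
        edges.extend(groups)
    dupes = len(edges) - len(set(edges))
    if dupes:
        logger.info("configuration model produced %d duplicate hyperedges", dupes)
    meta = dict(H.metadata)
    meta["randomization"] = "configuration"
    return Hypergraph(H.node_labels, tuple(edges), meta)


def node_swap(H: Hypergraph, seed=None) -> Hypergraph:
    """Swap order-d memberships of degree-antisorted node pairs (d > 1).

    At each order d > 1, nodes are ranked by K^(d) (ties broken by a fresh
    random permutation, so the pairing differs between orders), rank r is
    paired with rank N−1−r, and each pair exchanges all its order-d
    hyperedge memberships.  The per-order degree multiset is preserved
    exactly; the assignment of degrees to nodes — and with it the
    cross-order degree correlation — is not.  Pairwise edges are untouched;
    with an odd node count the median-rank node stays in place.
    """
    rng = np.random.default_rng(seed)
    dec = order_decomposition(H)
    n = H.num_nodes
    edges = list(H.edges_of_order(1))
    for d in dec.orders:
        if d == 1:
            continue
        K = dec.degrees[d]
        tiebreak = rng.permutation(n)
        ranked = sorted(range(n), key=lambda i: (K[i], tiebreak[i]))
        perm = np.arange(n)
        for r in range(n // 2):
            i, j = ranked[r], ranked[n - 1 - r]
            perm[i], perm[j] = j, i
        edges.extend(
            frozenset(int(perm[v]) for v in e) for e in H.edges_of_order(d)
        )
    meta = dict(H.metadata)
    meta["randomization"] = "node-swap"
    return Hypergraph(H.node_labels, tuple(edges), meta)


def shuffle_hyperedges(
    H: Hypergraph, p_shuffle: float = 1.0, seed=None, max_retries: int = 10000
) -> Hypergraph:
    """Replace each hyperedge w.p. ``p_shuffle`` by a non-existing one.

    Replacements are uniform over same-size node subsets absent from the
    evolving edge set, so per-order hyperedge counts are preserved while
    degree sequences and cross-order structure are destroyed.  At
    p_shuffle = 1 the result is statistically a random hypergraph with the
    same per-order counts.
    """
    if not (0.0 <= p_shuffle <= 1.0):
        raise HypergraphError(f"p_shuffle={p_shuffle} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n = H.num_nodes
    current = set(H.edges)
    count_by_size: dict = {}
    for e in current:
        count_by_size[len(e)] = count_by_size.get(len(e), 0) + 1
    edges = list(H.edges)
    for idx, e in enumerate(edges):
        if rng.random() >= p_shuffle:
            continue
        size = len(e)
        if comb(n, size) <= count_by_size.get(size, 0):
            raise RandomizationError(
                f"no non-existing replacement available at order {size - 1}"
            )
        for _ in range(max_retries):
            cand = frozenset(
                int(x) for x in rng.choice(n, size=size, replace=False)
            )
            if cand not in current:
                break
        else:
            raise RandomizationError("rejection sampling exhausted max_retries")
        current.discard(e)
        current.add(cand)
        edges[idx] = cand
    meta = dict(H.metadata)
    meta["randomization"] = f"shuffle(p={p_shuffle})"
    return Hypergraph(H.node_labels, tuple(edges), meta)
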