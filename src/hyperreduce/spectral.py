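"""Order-d Laplacians, the multiorder Laplacian, and its eigendecomposition.

The order-d Laplacian is L^(d)_{ij} = K^(d)_i δ_{ij} − A^(d)_{ij}/d; the
multiorder Laplacian up to order D is the sum of L^(d)/<K^(d)> over the
orders that exist (coupling weights γ_d default to 1).  It is symmetric,
positive semidefinite, and its rows sum to zero; its spectrum sets the
diffusion timescales 1/λ_max (short) and 1/λ_min-nonzero (long).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypergraph import Hypergraph, HypergraphError, OrderDecomposition, order_decomposition

__all__ = [
    "order_laplacian",
    "multiorder_laplacian",
    "spectrum",
    "timescales",
    "Spectrum",
]

#: relative eigenvalue tolerance separating the connectivity null space
#: from round-off
ZERO_TOL = 1e-12


class MissingOrderError(HypergraphError):
    """Requested an interaction order with no hyperedges."""


def order_laplacian(dec: OrderDecomposition, d: int) -> np.ndarray:
    """Laplacian of order d: diag(K^(d)) − A^(d)/d."""
    if d not in dec.degrees:
        raise MissingOrderError(f"no hyperedges of order {d}")
    K = dec.degrees[d].astype(float)
    A = dec.adjacency[d].astype(float)
    return np.diag(K) - A / d


def multiorder_laplacian(
    dec: OrderDecomposition,
    D: int | None = None,
    gamma: dict | None = None,
) -> np.ndarray:
    """Weighted sum of order Laplacians up to order ``D``.

    L^[D] = Σ_{d ∈ 𝒟} (γ_d / <K^(d)>) L^(d), with the sum over the existing
    orders 𝒟 = {d <= D : <K^(d)> > 0}; absent orders are simply not summed.
    ``D`` defaults to the maximum order present.
    """
    if D is None:
        D = max(dec.orders, default=0)
    orders = dec.orders_up_to(D)
    if not orders:
        raise MissingOrderError(f"no hyperedges of order <= {D}")
    L = np.zeros((dec.num_nodes, dec.num_nodes))
    for d in orders:
        g = 1.0 if gamma is None else float(gamma.get(d, 1.0))
        L += (g / dec.mean_degree(d)) * order_laplacian(dec, d)
    return L


@dataclass(frozen=True)
class Spectrum:
    """Eigendecomposition of a symmetric PSD Laplacian.

    ``eigenvalues`` ascend, with round-off negatives clipped to zero;
    ``eigenvectors[:, i]`` pairs with ``eigenvalues[i]``.
    ``lambda_min_nonzero`` is None for an all-zero spectrum.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def size(self) -> int:
        return self.eigenvalues.size

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues[-1])

    @property
    def lambda_min_nonzero(self) -> float | None:
        thresh = ZERO_TOL * max(1.0, self.lambda_max)
        above = self.eigenvalues[self.eigenvalues > thresh]
        return float(above[0]) if above.size else None


def spectrum(L: np.ndarray, tol: float = 1e-10) -> Spectrum:
    """Eigendecompose a symmetric Laplacian, clipping round-off negatives."""
    L = np.asarray(L, dtype=float)
    scale = max(1.0, float(np.abs(L).max()))
    if not np.allclose(L, L.T, atol=tol * scale):
        raise HypergraphError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh((L + L.T) / 2.0)
    lam_max = float(vals[-1]) if vals.size else 0.0
    floor = -ZERO_TOL * max(1.0, abs(lam_max))
    if vals.size and vals[0] < floor * 1e4:
        raise HypergraphError(f"matrix is not PSD: min eigenvalue {vals[0]}")
    vals = np.clip(vals, 0.0, None)
    return Spectrum(vals, vecs)


def timescales(H: Hypergraph) -> tuple[float, float]:
    """Short and long diffusion timescales of the full multiorder Laplacian.

    Returns (τ_short, τ_long) = (1/λ_max, 1/λ_min-nonzero) of L^[d_max].
    """
    if not H.edges:
        raise HypergraphError("empty hypergraph has no timescales")
    dec = order_decomposition(H)
    spec = spectrum(multiorder_laplacian(dec))
    lam_min = spec.lambda_min_nonzero
    if lam_min is None:
        raise HypergraphError("all-zero Laplacian spectrum")
    return 1.0 / spec.lambda_max, 1.0 / lam_min
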