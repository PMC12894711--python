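"""Diffusion density matrices, entropies, and the reducibility cost function.

A hypergraph at diffusion time τ is encoded by the Gibbs-like density
matrix ρ_τ^[d] = e^{−τ L^[d]} / Z, whose eigenvalues μ_i = e^{−τλ_i}/Z
form a probability distribution over diffusion modes.  Treating the full
structure ρ_τ^[d_max] as data and each truncation ρ_{τ'(d)}^[d] as a model
of it, the cost of truncating at order d is

    𝓛(d) = D_KL(ρ_τ^[d_max] | ρ_{τ'(d)}^[d]) + C(ρ_{τ'(d)}^[d]),

information loss plus model complexity C = log N − S (the entropic
deviation from N isolated nodes).  The diffusion time is rescaled per
order, τ'(d) = (d_max/d)·τ, so that structures whose order Laplacians are
proportional are exactly cost-flat.  The optimal order d_opt minimizes 𝓛
(smallest order on ties), and the reducibility index is
χ = (d_max − d_opt)/(d_max − 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, rel_entr

from .hypergraph import Hypergraph, HypergraphError, order_decomposition
from .spectral import Spectrum, multiorder_laplacian, spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMatrix",
    "CostCurve",
    "ReducibilityResult",
    "density_matrix",
    "von_neumann_entropy",
    "complexity",
    "kl_divergence",
    "js_divergence",
    "rescale_tau",
    "cost_curve",
    "optimal_order",
    "reducibility",
]

#: relative tolerance for the smallest-order tie-break in d_opt
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class DensityMatrix:
    """Unit-trace PSD operator e^{−τL}/Z in the Laplacian eigenbasis.

    ``mu[i]`` = e^{−τλ_i}/Z pairs with ``spectrum.eigenvectors[:, i]``.
    ``log_z`` is log Tr e^{−τL}.
    """

    spectrum: Spectrum
    tau: float
    mu: np.ndarray = field(repr=False)
    log_z: float

    @property
    def size(self) -> int:
        return self.mu.size

    def matrix(self) -> np.ndarray:
        """Dense ρ = V diag(μ) Vᵀ, reconstructed on demand."""
        V = self.spectrum.eigenvectors
        return (V * self.mu) @ V.T

    def entropy(self) -> float:
        return von_neumann_entropy(self)


def density_matrix(spec: Spectrum, tau: float) -> DensityMatrix:
    """Density matrix of a Laplacian spectrum at diffusion time τ.

    Computed on the spectrum shifted by its minimum eigenvalue, which
    leaves μ unchanged but avoids underflow at large τ; log Z recovers the
    shift.  A Laplacian always has λ_min = 0 so the shift is cosmetic
    there, but the routine accepts any PSD spectrum.
    """
    if not (np.isfinite(tau) and tau > 0):
        raise HypergraphError(f"diffusion time must be positive and finite, got {tau}")
    lam = spec.eigenvalues
    shift = float(lam[0])
    expo = -tau * (lam - shift)
    log_z_shifted = float(logsumexp(expo))
    mu = np.exp(expo - log_z_shifted)
    return DensityMatrix(spec, float(tau), mu, log_z_shifted - tau * shift)


def von_neumann_entropy(rho: DensityMatrix) -> float:
    """S = −Σ μ_i log μ_i with the 0·log 0 = 0 convention; in [0, log N]."""
    mu = rho.mu
    pos = mu > 0
    return float(-(mu[pos] * np.log(mu[pos])).sum())


def complexity(rho: DensityMatrix) -> float:
    """Model complexity C = log N − S(ρ) = D_KL(ρ | I/N); in [0, log N]."""
    return float(np.log(rho.size) - von_neumann_entropy(rho))


def _cross_entropy(rho: DensityMatrix, sigma: DensityMatrix) -> float:
    """−Tr(ρ log σ) via the Gibbs identity τ_σ·Tr(ρ L_σ) + log Z_σ.

    Exact for exponential-family density matrices; avoids taking a matrix
    logarithm of a near-singular σ.  Tr(ρ L_σ) is evaluated through the
    overlap of the two eigenbases.
    """
    if rho.size != sigma.size:
        raise HypergraphError("density matrices have different dimensions")
    M = rho.spectrum.eigenvectors.T @ sigma.spectrum.eigenvectors
    trace_rho_L = float(rho.mu @ (M**2) @ sigma.spectrum.eigenvalues)
    return sigma.tau * trace_rho_L + sigma.log_z


def kl_divergence(rho: DensityMatrix, sigma: DensityMatrix) -> float:
    """Quantum relative entropy D_KL(ρ|σ) = −S(ρ) − Tr(ρ log σ) >= 0.

    Tiny negative round-off (above −1e−10) is clipped to zero.
    """
    val = -von_neumann_entropy(rho) + _cross_entropy(rho, sigma)
    if val < -1e-10:
        raise HypergraphError(f"KL divergence evaluated to {val} < 0")
    return max(val, 0.0)


def js_divergence(rho: DensityMatrix, sigma: DensityMatrix) -> float:
    """Quantum Jensen–Shannon divergence; symmetric, in [0, log 2].

    Requires the eigenvalues of the mixture (ρ+σ)/2, so it densifies both
    operators.
    """
    if rho.size != sigma.size:
        raise HypergraphError("density matrices have different dimensions")
    mix = (rho.matrix() + sigma.matrix()) / 2.0
    vals = np.linalg.eigvalsh((mix + mix.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    pos = vals > 0
    s_mix = float(-(vals[pos] * np.log(vals[pos])).sum())
    val = s_mix - (von_neumann_entropy(rho) + von_neumann_entropy(sigma)) / 2.0
    return max(val, 0.0)


def rescale_tau(tau: float, d: int, H: Hypergraph) -> float:
    """Order-dependent diffusion time τ'(d).

    With every order 1..d_max present this is (d_max/d)·τ.  With missing
    orders the order count replaces the order index:
    τ'(d) = |𝒟(d_max)| / |𝒟(d)| · τ, where 𝒟(x) is the set of existing
    orders <= x — which keeps τ'(d_max) = τ and hence the self-divergence
    exactly zero.
    """
    orders = H.orders
    if d not in orders:
        raise HypergraphError(f"order {d} not present in hypergraph")
    n_all = len(orders)
    n_d = sum(1 for o in orders if o <= d)
    return tau * n_all / n_d


@dataclass(frozen=True)
class CostCurve:
    """Per-truncation-order cost profile at a fixed base diffusion time.

    Arrays align with ``orders`` (the ascending existing orders up to
    d_max): rescaled times τ'(d), information loss D_KL, complexity C and
    their sum, the cost 𝓛.
    """

    tau: float
    orders: tuple
    tau_rescaled: np.ndarray
    info_loss: np.ndarray
    complexity: np.ndarray

    @property
    def cost(self) -> np.ndarray:
        return self.info_loss + self.complexity

    @property
    def d_max(self) -> int:
        return self.orders[-1]

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "orders": list(self.orders),
            "tau_rescaled": self.tau_rescaled.tolist(),
            "info_loss": self.info_loss.tolist(),
            "complexity": self.complexity.tolist(),
            "cost": self.cost.tolist(),
        }


@dataclass(frozen=True)
class ReducibilityResult:
    """Optimal truncation order and reducibility index of a hypergraph.

    χ = (d_max − d_opt)/(d_max − 1) ∈ [0, 1]: 1 means the structure
    collapses to its pairwise skeleton, 0 means every order is needed.
    ``pairwise_input`` flags the degenerate d_max = 1 case, reported χ = 1.
    """

    tau: float
    d_opt: int
    chi: float
    curve: CostCurve
    pairwise_input: bool = False


def cost_curve(H: Hypergraph, tau: float) -> CostCurve:
    """Cost 𝓛(d) = D_KL(ρ_τ^[d_max] | ρ_{τ'(d)}^[d]) + C(ρ_{τ'(d)}^[d]).

    Evaluated at every existing order d <= d_max.  The top order has zero
    information loss by construction, so 𝓛(d_max) = C(ρ_τ^[d_max]) exactly.
    """
    if not H.edges:
        raise HypergraphError("cannot compute the cost curve of an empty hypergraph")
    dec = order_decomposition(H)
    orders = dec.orders
    d_max = orders[-1]
    spec_full = spectrum(multiorder_laplacian(dec, d_max))
    rho_full = density_matrix(spec_full, tau)

    taus, losses, comps = [], [], []
    for d in orders:
        tau_d = rescale_tau(tau, d, H)
        if d == d_max:
            sigma = rho_full
            loss = 0.0
        else:
            sigma = density_matrix(spectrum(multiorder_laplacian(dec, d)), tau_d)
            loss = kl_divergence(rho_full, sigma)
        taus.append(tau_d)
        losses.append(loss)
        comps.append(complexity(sigma))
    return CostCurve(
        float(tau), orders, np.array(taus), np.array(losses), np.array(comps)
    )


def optimal_order(curve: CostCurve) -> int:
    """Smallest order whose cost is within tolerance of the curve minimum.

    The tolerance is relative (1e−9 of the minimum, floored at 1e−12
    absolute) so that exactly flat curves — proportional-Laplacian
    structures — resolve to d_opt = 1 rather than whichever order numerical
    noise favors.
    """
    cost = curve.cost
    cmin = float(cost.min())
    thresh = cmin + max(TIE_RTOL * abs(cmin), 1e-12)
    for d, c in zip(curve.orders, cost):
        if c <= thresh:
            return int(d)
    return int(curve.orders[-1])  # unreachable


def reducibility(H: Hypergraph, tau: float) -> ReducibilityResult:
    """Optimal order and reducibility index χ at diffusion time τ."""
    curve = cost_curve(H, tau)
    d_opt = optimal_order(curve)
    d_max = curve.d_max
    if d_max == 1:
        logger.info("pairwise input: d_max = 1, reducibility trivially 1")
        return ReducibilityResult(float(tau), 1, 1.0, curve, pairwise_input=True)
    chi = (d_max - d_opt) / (d_max - 1)
    return ReducibilityResult(float(tau), d_opt, chi, curve)


def classical_kl(p: np.ndarray, q: np.ndarray) -> float:
    """Classical KL divergence of two probability vectors (helper)."""
    return float(rel_entr(np.asarray(p, float), np.asarray(q, float)).sum())
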