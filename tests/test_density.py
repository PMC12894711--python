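"""Density matrices, entropies, divergences, cost curves, reducibility."""

import numpy as np
import pytest
import scipy.linalg

from hyperreduce import (
    Hypergraph,
    complete_hypergraph,
    cost_curve,
    density_matrix,
    hyperring,
    js_divergence,
    kl_divergence,
    multiorder_laplacian,
    optimal_order,
    order_decomposition,
    random_hypergraph,
    reducibility,
    rescale_tau,
    spectrum,
    timescales,
    triangular_lattice_sc,
    von_neumann_entropy,
)
from hyperreduce.density import CostCurve, classical_kl, complexity
from hyperreduce.hypergraph import HypergraphError


def _density_from_L(L, tau):
    return density_matrix(spectrum(L), tau)


class TestDensityMatrix:
    def test_isolated_nodes_uniform_spectrum(self):
        rho = _density_from_L(np.zeros((7, 7)), tau=3.0)
        assert np.allclose(rho.mu, 1 / 7)
        assert np.isclose(von_neumann_entropy(rho), np.log(7))

    def test_small_tau_approaches_uniform(self, pairwise_triangle):
        L = multiorder_laplacian(order_decomposition(pairwise_triangle))
        rho = _density_from_L(L, tau=1e-12)
        assert np.allclose(rho.mu, 1 / 3, atol=1e-10)

    def test_triangle_closed_form(self, pairwise_triangle):
        L = multiorder_laplacian(order_decomposition(pairwise_triangle))
        rho = _density_from_L(L, tau=1.0)
        z = 1 + 2 * np.exp(-1.5)
        expected = np.sort([1 / z, np.exp(-1.5) / z, np.exp(-1.5) / z])
        assert np.allclose(np.sort(rho.mu), expected)

    def test_unit_trace_and_matrix_reconstruction(self):
        H = random_hypergraph(15, {1: 0.3, 2: 0.02}, seed=3)
        L = multiorder_laplacian(order_decomposition(H))
        rho = _density_from_L(L, tau=0.7)
        assert np.isclose(rho.mu.sum(), 1.0, atol=1e-12)
        M = rho.matrix()
        assert np.isclose(np.trace(M), 1.0, atol=1e-10)
        assert np.allclose(M, scipy.linalg.expm(-0.7 * L) / np.trace(
            scipy.linalg.expm(-0.7 * L)), atol=1e-10)

    def test_huge_tau_no_underflow(self):
        L = np.diag([0.0, 5.0, 10.0])
        rho = _density_from_L(L, tau=1e6)
        assert np.isclose(rho.mu[0], 1.0)  # zero mode dominates
        assert np.all(np.isfinite(rho.mu))

    @pytest.mark.parametrize("tau", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_tau_rejected(self, tau):
        with pytest.raises(HypergraphError):
            _density_from_L(np.zeros((3, 3)), tau)


class TestEntropyAndComplexity:
    def test_pure_state_zero_entropy_max_complexity(self):
        # very large tau on a connected graph concentrates on the zero mode
        L = np.diag([0.0, 1.0, 2.0, 3.0])
        rho = _density_from_L(L, tau=1e4)
        assert von_neumann_entropy(rho) < 1e-10
        assert np.isclose(complexity(rho), np.log(4), atol=1e-10)

    def test_complete_hypergraph_entropy_limits(self):
        H = complete_hypergraph(10, 2)
        L = multiorder_laplacian(order_decomposition(H))
        s_small = von_neumann_entropy(_density_from_L(L, 1e-8))
        s_large = von_neumann_entropy(_density_from_L(L, 1e8))
        assert np.isclose(s_small, np.log(10), atol=1e-6)
        assert s_large < 1e-10

    def test_complexity_monotone_limits_on_connected_hypergraph(self):
        H = hyperring(20)
        L = multiorder_laplacian(order_decomposition(H))
        c_small = complexity(_density_from_L(L, 1e-6))
        c_large = complexity(_density_from_L(L, 1e6))
        assert c_small < 1e-4
        assert c_small < c_large
        assert np.isclose(c_large, np.log(20), atol=1e-6)


class TestDivergences:
    def test_self_divergence_zero(self):
        H = random_hypergraph(12, {1: 0.3, 2: 0.03}, seed=1)
        rho = _density_from_L(multiorder_laplacian(order_decomposition(H)), 0.5)
        assert kl_divergence(rho, rho) <= 1e-12
        assert js_divergence(rho, rho) < 1e-12

    def test_kl_against_uniform_equals_complexity(self):
        H = random_hypergraph(12, {1: 0.3, 2: 0.03}, seed=2)
        rho = _density_from_L(multiorder_laplacian(order_decomposition(H)), 0.5)
        iso = _density_from_L(np.zeros((12, 12)), 0.5)
        assert abs(kl_divergence(rho, iso) - complexity(rho)) < 1e-10

    def test_gibbs_shortcut_matches_matrix_logarithm(self):
        """Cross-entropy identity vs dense logm on random 30-node instances."""
        for seed in range(3):
            H = random_hypergraph(30, {1: 0.15, 2: 0.005}, seed=seed)
            dec = order_decomposition(H)
            tau = timescales(H)[0]
            rho = _density_from_L(multiorder_laplacian(dec), tau)
            sigma = _density_from_L(
                multiorder_laplacian(dec, 1), rescale_tau(tau, 1, H)
            )
            direct = -np.trace(rho.matrix() @ scipy.linalg.logm(sigma.matrix())).real
            shortcut = kl_divergence(rho, sigma) + von_neumann_entropy(rho)
            assert abs(shortcut - direct) < 1e-8

    def test_commuting_circulant_kl_matches_classical(self):
        """On the hyperring all matrices commute: matrix KL = classical KL."""
        n, tau = 10, 0.4
        H = hyperring(n)
        dec = order_decomposition(H)
        rho = _density_from_L(multiorder_laplacian(dec, 2), tau)
        sigma = _density_from_L(multiorder_laplacian(dec, 1), 2 * tau)
        k = np.arange(n)
        lam1 = 1 - np.cos(2 * np.pi * k / n)
        lam2 = 2 - (5 / 3) * np.cos(2 * np.pi * k / n) - (1 / 3) * np.cos(
            4 * np.pi * k / n
        )
        p = np.exp(-tau * lam2)
        p /= p.sum()
        q = np.exp(-2 * tau * lam1)
        q /= q.sum()
        assert abs(kl_divergence(rho, sigma) - classical_kl(p, q)) < 1e-10

    def test_js_symmetric_and_bounded(self):
        a = _density_from_L(np.diag([0.0, 1, 2, 3, 4]), 0.8)
        b = _density_from_L(np.diag([0.0, 4, 3, 2, 1]), 0.3)
        jab, jba = js_divergence(a, b), js_divergence(b, a)
        assert abs(jab - jba) < 1e-12
        assert 0 <= jab <= np.log(2) + 1e-12

    def test_js_commuting_diagonal_matches_classical(self):
        lam_a, lam_b = np.array([0.0, 1, 2, 3, 4]), np.array([0.0, 2, 2, 5, 9])
        a = _density_from_L(np.diag(lam_a), 0.7)
        b = _density_from_L(np.diag(lam_b), 0.7)
        p = np.exp(-0.7 * lam_a)
        p /= p.sum()
        q = np.exp(-0.7 * lam_b)
        q /= q.sum()
        m = (p + q) / 2
        expected = 0.5 * classical_kl(p, m) + 0.5 * classical_kl(q, m)
        assert abs(js_divergence(a, b) - expected) < 1e-10

    def test_dimension_mismatch_rejected(self):
        a = _density_from_L(np.zeros((3, 3)), 1.0)
        b = _density_from_L(np.zeros((4, 4)), 1.0)
        with pytest.raises(HypergraphError):
            kl_divergence(a, b)
        with pytest.raises(HypergraphError):
            js_divergence(a, b)


class TestRescaleTau:
    def test_all_orders_present(self):
        H = Hypergraph.from_edges([[0, 1], [0, 1, 2], [0, 1, 2, 3], [0, 1, 2, 3, 4]])
        assert np.isclose(rescale_tau(0.1, 1, H), 0.4)
        assert rescale_tau(0.1, 4, H) == 0.1

    def test_missing_orders_use_order_counts(self):
        H = Hypergraph.from_edges([[0, 1], [0, 1, 2, 3]])  # orders {1, 3}
        assert rescale_tau(1.0, 1, H) == 2.0
        assert rescale_tau(1.0, 3, H) == 1.0

    def test_absent_order_rejected(self, pairwise_triangle):
        with pytest.raises(HypergraphError):
            rescale_tau(1.0, 2, pairwise_triangle)


class TestCostCurveAndReducibility:
    def test_flat_curve_on_complete_hypergraph(self):
        H = complete_hypergraph(20, 3)
        tau = timescales(H)[0]
        curve = cost_curve(H, tau)
        assert curve.cost.max() - curve.cost.min() < 1e-9
        assert optimal_order(curve) == 1

    def test_top_order_loss_exactly_zero(self):
        H = random_hypergraph(25, {1: 0.2, 2: 0.01}, seed=4)
        curve = cost_curve(H, 0.3)
        assert curve.info_loss[-1] == 0.0
        assert np.all(curve.info_loss >= 0)

    def test_hyperring_info_loss_vanishes_at_tau_extremes(self):
        H = hyperring(30)
        for tau in (1e-9, 1e9):
            curve = cost_curve(H, tau)
            assert curve.info_loss.max() < 1e-6

    def test_pairwise_only_single_point(self, pairwise_triangle):
        curve = cost_curve(pairwise_triangle, 0.5)
        assert curve.orders == (1,)
        rho = _density_from_L(
            multiorder_laplacian(order_decomposition(pairwise_triangle)), 0.5
        )
        assert np.isclose(curve.cost[0], complexity(rho))

    def test_proportional_structures_have_equal_density_matrices(self):
        for H in (complete_hypergraph(12, 3), triangular_lattice_sc(4, 5)):
            tau = timescales(H)[0]
            dec = order_decomposition(H)
            full = _density_from_L(multiorder_laplacian(dec), tau).matrix()
            for d in dec.orders[:-1]:
                sub = _density_from_L(
                    multiorder_laplacian(dec, d), rescale_tau(tau, d, H)
                ).matrix()
                assert np.abs(sub - full).max() < 1e-9

    def test_strictly_decreasing_curve_picks_top_order(self):
        curve = CostCurve(
            0.1, (1, 2, 3), np.array([0.3, 0.15, 0.1]),
            np.array([0.5, 0.2, 0.0]), np.array([0.1, 0.1, 0.1]),
        )
        assert optimal_order(curve) == 3

    def test_reducibility_extremes(self):
        flat = reducibility(complete_hypergraph(10, 3), 0.2)
        assert flat.d_opt == 1 and flat.chi == 1.0
        # chi = (d_max - d_opt)/(d_max - 1) is exact
        assert flat.curve.d_max == 3

    def test_pairwise_input_flagged(self, pairwise_triangle):
        res = reducibility(pairwise_triangle, 0.5)
        assert res.pairwise_input and res.chi == 1.0

    def test_empty_rejected(self):
        with pytest.raises(HypergraphError):
            cost_curve(Hypergraph.from_edges([], nodes=[0, 1]), 1.0)
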