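"""Penalized symmetric-NMF fitting: objective, update rule, extraction."""

import numpy as np
import pytest

from linknmf import (
    Network,
    extract_params,
    fit,
    objective,
    update_step,
)
from linknmf.sym_nmf import _init_factor


def naive_objective(X, A, lam, m):
    """Brute-force elementwise evaluation, independent of the fast path."""
    A = np.asarray(A, dtype=float)
    n, c = X.shape
    loss = 0.0
    for i in range(n):
        for j in range(n):
            pred = sum(X[i, z] * X[j, z] for z in range(c))
            loss += (A[i, j] - pred) ** 2
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += sum(X[i, z] * X[j, z] for z in range(c))
    return loss + lam * (total - 2.0 * m) ** 2


def naive_update(X, A, lam, m, eta=0.25):
    """Entrywise multiplicative update written straight from the gradient split."""
    A = np.asarray(A, dtype=float)
    n, c = X.shape
    s = X.sum(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        for z in range(c):
            num = sum(A[i, j] * X[j, z] for j in range(n)) + 2.0 * m * lam * s[z]
            den = sum(
                X[i, y] * sum(X[j, y] * X[j, z] for j in range(n)) for y in range(c)
            ) + lam * float(s @ s) * s[z]
            out[i, z] = X[i, z] * (num / max(den, 1e-12)) ** eta
    return np.maximum(out, 1e-12)


def random_instance(rng, n=6, c=2):
    M = rng.random((n, n))
    A = np.triu(M) + np.triu(M, 1).T  # symmetric, nonnegative
    X = rng.random((n, c)) + 0.1
    m = A.sum() / 2.0
    return A, X, m


class TestObjective:
    def test_zero_at_exact_factorization(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        A = X @ X.T
        m = A.sum() / 2.0
        assert objective(X, A, 1000.0, m) == pytest.approx(0.0, abs=1e-12)

    def test_zero_factor_gives_frobenius_norm(self):
        A = np.array([[0.0, 2.0], [2.0, 0.0]])
        X = np.zeros((2, 1))
        assert objective(X, A, 0.0, 2.0) == pytest.approx(8.0)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            objective(np.ones((2, 1)), np.eye(2), -1.0, 1.0)

    @pytest.mark.parametrize("lam", [0.0, 1.0, 1000.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_naive_summation(self, lam, seed):
        rng = np.random.default_rng(seed)
        A, X, m = random_instance(rng)
        fast = objective(X, A, lam, m)
        slow = naive_objective(X, A, lam, m)
        assert fast == pytest.approx(slow, rel=1e-10)


class TestUpdateStep:
    def test_fixed_point_at_exact_factorization(self):
        X = np.array([[1.0, 0.2], [0.7, 1.1], [0.3, 0.5]])
        A = X @ X.T
        out = update_step(X, A, 0.0, A.sum() / 2.0)
        assert np.allclose(out, X, rtol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 1000.0])
    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_naive_update(self, lam, seed):
        rng = np.random.default_rng(seed)
        A, X, m = random_instance(rng, n=8, c=3)
        fast = update_step(X, A, lam, m)
        slow = naive_update(X, A, lam, m)
        assert np.allclose(fast, slow, rtol=1e-10)

    def test_objective_never_increases_100_steps(self):
        rng = np.random.default_rng(6)
        A, X, m = random_instance(rng, n=8, c=2)
        prev = objective(X, A, 0.0, m)
        for _ in range(100):
            X = update_step(X, A, 0.0, m)
            cur = objective(X, A, 0.0, m)
            assert cur <= prev * (1 + 1e-10) + 1e-12
            prev = cur

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(7)
        A, X, m = random_instance(rng)
        for _ in range(20):
            X = update_step(X, A, 1000.0, m)
            assert np.all(X >= 0)

    def test_kkt_residual_vanishes_at_convergence(self):
        rng = np.random.default_rng(8)
        A, X, m = random_instance(rng, n=6, c=2)
        for _ in range(4000):
            X = update_step(X, A, 0.0, m)
        # numerical gradient of the objective via central differences
        grad = np.zeros_like(X)
        h = 1e-6
        for i in range(X.shape[0]):
            for z in range(X.shape[1]):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, z] += h
                Xm[i, z] -= h
                grad[i, z] = (
                    objective(Xp, A, 0.0, m) - objective(Xm, A, 0.0, m)
                ) / (2 * h)
        residual = np.minimum(X, np.abs(grad))
        assert np.max(residual) < 1e-3


class TestExtractParams:
    def test_uniform_column(self):
        params = extract_params(np.full((4, 1), 0.5))
        assert params.omega[0] == pytest.approx(4.0)
        assert np.allclose(params.phi[:, 0], 0.25)

    def test_one_hot_column(self):
        params = extract_params(np.array([[1.0], [0.0], [0.0]]))
        assert params.omega[0] == pytest.approx(1.0)
        assert np.allclose(params.phi[:, 0], [1, 0, 0])

    def test_round_trip_through_factor(self):
        rng = np.random.default_rng(9)
        X = rng.random((5, 3)) + 0.01
        params = extract_params(X)
        assert np.allclose(params.to_factor(), X, rtol=1e-12)

    def test_zero_columns_dropped(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        params = extract_params(X)
        assert params.c == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            extract_params(np.zeros((3, 2)))


class TestFit:
    def test_single_edge_rank_one(self):
        net = Network(["a", "b"], [(0, 1, 1.0)])
        res = fit(net, c=1, seed=0, restarts=3)
        # closed form: the 2x2 block [[0,1],[1,0]] has best symmetric
        # rank-1 nonnegative factor x = (1/sqrt(2))(1,1) scaled to
        # sum(omega) = 2; omega = (sum x)^2 = 2, phi = (1/2, 1/2)
        assert res.params.omega.sum() == pytest.approx(2.0, rel=0.02)
        assert np.allclose(res.params.phi[:, 0], 0.5, atol=0.01)

    def test_two_clique_fixture_exact_recovery(
        self, two_clique_network, two_clique_truth
    ):
        from linknmf import hard_partition, soft_membership

        res = fit(two_clique_network, c=2, seed=1)
        part = hard_partition(soft_membership(res.params, two_clique_network))
        assert part.c == 2
        sizes = sorted(len(v) for v in part.communities().values())
        assert sizes == [10, 10]
        # the recovered split is the planted one up to label swap
        got = {e: z for e, z in part.assignment.items()}
        want = two_clique_truth.assignment
        agree = sum(got[e] == want[e] for e in want) / len(want)
        assert agree in (0.0, 1.0)
        assert np.sum(res.params.omega) == pytest.approx(40.0, rel=0.01)

    def test_disjoint_cliques_block_support(self, disjoint_cliques):
        res = fit(disjoint_cliques, c=2, seed=2)
        phi = res.params.phi
        # each column's mass concentrates on a single clique
        block1 = phi[:5].sum(axis=0)
        block2 = phi[5:].sum(axis=0)
        for z in range(2):
            assert max(block1[z], block2[z]) > 0.99

    def test_monotone_trace_within_each_phase(self, two_clique_network):
        res = fit(two_clique_network, c=2, seed=3, restarts=1)
        tr = res.objective_trace
        b = res.phase_boundary
        for phase in (tr[:b], tr[b:]):
            assert np.all(np.diff(phase) <= np.abs(phase[:-1]) * 1e-10 + 1e-12)

    def test_more_communities_than_links_warns(self):
        net = Network(["a", "b"], [(0, 1, 1.0)])
        with pytest.warns(RuntimeWarning, match="communities"):
            fit(net, c=3, seed=0, restarts=1, max_iter=20)

    def test_non_convergence_still_returns(self, two_clique_network):
        res = fit(two_clique_network, c=2, seed=0, restarts=1, max_iter=2,
                  tol=1e-300)
        assert res.converged is False
        assert res.params.c >= 1

    def test_deterministic_given_seed(self, two_clique_network):
        r1 = fit(two_clique_network, c=2, seed=5, restarts=2)
        r2 = fit(two_clique_network, c=2, seed=5, restarts=2)
        assert np.array_equal(r1.X, r2.X)
        assert np.array_equal(r1.objective_trace, r2.objective_trace)

    def test_initialization_satisfies_size_constraint(self):
        rng = np.random.default_rng(11)
        X = _init_factor(7, 3, m=13.0, rng=rng)
        s = X.sum(axis=0)
        assert float(s @ s) == pytest.approx(26.0)

    def test_per_iteration_cost_scales_linearly_in_m(self):
        # ring lattices of growing size; time per update should grow
        # far slower than quadratically in m
        import time

        times = []
        sizes = [200, 800]
        for n in sizes:
            edges = [(i, (i + d) % n, 1.0) for i in range(n) for d in (1, 2, 3)]
            net = Network([str(i) for i in range(n)], edges)
            A = net.adjacency()
            X = _init_factor(n, 2, net.m, np.random.default_rng(0))
            t0 = time.perf_counter()
            for _ in range(30):
                X = update_step(X, A, 1000.0, net.m)
            times.append(time.perf_counter() - t0)
        ratio = times[1] / max(times[0], 1e-9)
        assert ratio < 16.0  # 4x the edges; quadratic scaling would give ~16x
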