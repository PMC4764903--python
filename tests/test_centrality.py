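import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dscentrality import (
    Network,
    build_adjacency,
    compute_centrality,
    degree,
    ds_centrality,
    ds_centrality_limit,
    ds_spectral,
    eigenvector_centrality,
    infection_probabilities,
    kendall_tau,
    kshell,
    propagation_matrix,
    random_graph,
    spectral_decomposition,
    toy_graph,
)
from dscentrality.centrality import ConvergenceError, SpreadingParams
from dscentrality.network import leading_eigenvalue


class TestSpreadingParams:
    @pytest.mark.parametrize(
        "kwargs", [{"beta": -0.1}, {"beta": 1.5}, {"beta": 0.1, "mu": 2.0},
                   {"beta": 0.1, "t": 0}, {"beta": 0.1, "t": 1.5}]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpreadingParams(**kwargs)


class TestBenchmarkCentralities:
    def test_degree_examples(self, star4, path3, k4):
        np.testing.assert_array_equal(degree(build_adjacency(star4)), [4, 1, 1, 1, 1])
        np.testing.assert_array_equal(degree(build_adjacency(path3)), [1, 2, 1])
        np.testing.assert_array_equal(degree(build_adjacency(k4)), [3, 3, 3, 3])

    def test_kshell_tree_is_all_ones(self):
        np.testing.assert_array_equal(kshell(toy_graph("path", 6)), np.ones(6))
        np.testing.assert_array_equal(kshell(toy_graph("star", 5)), np.ones(6))

    def test_kshell_k4_and_triangle_pendant(self, k4, triangle_pendant):
        np.testing.assert_array_equal(kshell(k4), [3, 3, 3, 3])
        np.testing.assert_array_equal(kshell(triangle_pendant), [2, 2, 2, 1])

    def test_kshell_isolated_node_is_zero(self):
        net = Network.from_edges([(0, 1)], nodes=[0, 1, 2])
        np.testing.assert_array_equal(kshell(net), [1, 1, 0])

    def test_eigenvector_uniform_on_complete_graph(self, k4):
        np.testing.assert_allclose(
            eigenvector_centrality(build_adjacency(k4)), np.full(4, 0.25), atol=1e-9
        )

    def test_eigenvector_exact_ratios(self, path3):
        v = eigenvector_centrality(build_adjacency(path3))
        assert v[1] / v[0] == pytest.approx(np.sqrt(2), abs=1e-8)
        star3 = toy_graph("star", 3)
        w = eigenvector_centrality(build_adjacency(star3))
        assert w[0] / w[1] == pytest.approx(np.sqrt(3), abs=1e-8)

    def test_eigenvector_positive_unit_sum_matches_dense_solver(self, er50):
        A = build_adjacency(er50)
        v = eigenvector_centrality(A)
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(1.0)
        _, vecs = spectral_decomposition(A)
        q1 = vecs[:, 0] / vecs[:, 0].sum()
        np.testing.assert_allclose(v, q1, atol=1e-8)

    def test_eigenvector_nonconvergence_reports_residual(self, er50):
        with pytest.raises(ConvergenceError, match="did not converge"):
            eigenvector_centrality(build_adjacency(er50), tol=1e-16, max_iter=3)


class TestPropagationMatrix:
    def test_mu_one_is_beta_A(self, path3):
        A = build_adjacency(path3, sparse=False)
        H = propagation_matrix(A, SpreadingParams(beta=0.2, mu=1.0, t=1))
        np.testing.assert_allclose(H, 0.2 * A)

    def test_beta_zero_mu_zero_is_identity(self, path3):
        H = propagation_matrix(
            build_adjacency(path3, sparse=False), SpreadingParams(beta=0.0, mu=0.0, t=1)
        )
        np.testing.assert_allclose(H, np.eye(3))

    def test_path3_entries(self, path3):
        H = propagation_matrix(
            build_adjacency(path3), SpreadingParams(beta=0.1, mu=0.5, t=1)
        ).toarray()
        expected = 0.1 * build_adjacency(path3, sparse=False) + 0.5 * np.eye(3)
        np.testing.assert_allclose(H, expected)


class TestInfectionProbabilities:
    def test_t1_is_beta_on_neighbors(self, star4):
        x = infection_probabilities(
            build_adjacency(star4), SpreadingParams(beta=0.3, mu=1.0, t=1), seed=0
        )
        np.testing.assert_allclose(x, [0, 0.3, 0.3, 0.3, 0.3])

    def test_path3_hand_value(self, path3):
        x = infection_probabilities(
            build_adjacency(path3), SpreadingParams(beta=0.1, mu=1.0, t=2), seed=1
        )
        np.testing.assert_allclose(x, [0.1, 0.02, 0.1])

    def test_beta_zero_gives_zero_vector(self, er50):
        x = infection_probabilities(
            build_adjacency(er50), SpreadingParams(beta=0.0, mu=0.5, t=4), seed=3
        )
        np.testing.assert_array_equal(x, np.zeros(er50.n))

    def test_seed_out_of_range(self, path3):
        with pytest.raises(IndexError):
            infection_probabilities(
                build_adjacency(path3), SpreadingParams(beta=0.1), seed=3
            )


class TestDSCentrality:
    def test_path3_hand_value(self, path3):
        S = ds_centrality(build_adjacency(path3), SpreadingParams(beta=0.1, mu=1.0, t=2))
        np.testing.assert_allclose(S, [0.12, 0.22, 0.12])

    def test_triangle_symmetry(self, triangle):
        S = ds_centrality(build_adjacency(triangle), SpreadingParams(beta=0.4, mu=0.3, t=5))
        assert S[0] == pytest.approx(S[1]) == pytest.approx(S[2])

    def test_t1_is_beta_times_degree(self, er50):
        A = build_adjacency(er50)
        S = ds_centrality(A, SpreadingParams(beta=0.07, mu=0.4, t=1))
        np.testing.assert_allclose(S, 0.07 * degree(A))

    def test_mu1_walk_count_form(self, er50):
        # with mu=1, S(t) must equal sum_r beta^r A^r 1 (dense powers as oracle)
        A = build_adjacency(er50, sparse=False)
        beta, t = 0.05, 6
        expected = np.zeros(er50.n)
        P = np.eye(er50.n)
        for r in range(1, t + 1):
            P = P @ A
            expected += beta**r * (P @ np.ones(er50.n))
        S = ds_centrality(A, SpreadingParams(beta=beta, mu=1.0, t=t))
        np.testing.assert_allclose(S, expected, atol=1e-10)

    def test_scores_nonnegative_and_monotone_in_t(self, ba200):
        A = build_adjacency(ba200)
        prev = np.zeros(ba200.n)
        for t in range(1, 12):
            S = ds_centrality(A, SpreadingParams(beta=0.03, mu=0.6, t=t))
            assert np.all(S >= 0)
            assert np.all(S >= prev - 1e-12)
            prev = S

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(perm_seed=st.integers(0, 10_000))
    def test_permutation_equivariance(self, perm_seed):
        net = random_graph("er", 11, n=30, p=0.15)
        A = build_adjacency(net, sparse=False)
        perm = np.random.default_rng(perm_seed).permutation(net.n)
        A_perm = A[np.ix_(perm, perm)]
        params = SpreadingParams(beta=0.06, mu=0.5, t=4)
        np.testing.assert_allclose(
            ds_centrality(A_perm, params), ds_centrality(A, params)[perm], atol=1e-12
        )
        np.testing.assert_allclose(
            eigenvector_centrality(A_perm), eigenvector_centrality(A)[perm], atol=1e-8
        )
        # node perm[i] of the relabeled network corresponds to node i
        net_perm = Network.from_edges([(perm[i], perm[j]) for i, j in net.edges])
        np.testing.assert_array_equal(kshell(net_perm)[perm], kshell(net))

    def test_contact_kernel_is_uniform_constant(self, triangle_pendant):
        # row-normalized kernel: each infected node yields expected beta new
        # infections per step, so the linearized score is seed-independent
        beta, mu, t = 0.3, 0.5, 4
        S = ds_centrality(
            build_adjacency(triangle_pendant), SpreadingParams(beta=beta, mu=mu, t=t),
            kernel="contact",
        )
        expected = beta * sum((beta + 1 - mu) ** r for r in range(t))
        np.testing.assert_allclose(S, np.full(4, expected))

    def test_contact_kernel_isolated_node_errors(self):
        net = Network.from_edges([(0, 1)], nodes=[0, 1, 2])
        with pytest.raises(ValueError, match="isolated"):
            ds_centrality(build_adjacency(net), SpreadingParams(beta=0.1), kernel="contact")

    def test_unknown_kernel_errors(self, path3):
        with pytest.raises(ValueError, match="kernel"):
            ds_centrality(build_adjacency(path3), SpreadingParams(beta=0.1), kernel="bogus")


class TestDSLimit:
    def test_k2_geometric_series(self, k2):
        S = ds_centrality_limit(build_adjacency(k2), beta=0.5, mu=1.0)
        np.testing.assert_allclose(S, [1.0, 1.0])

    def test_beta_zero_gives_zero(self, er50):
        np.testing.assert_array_equal(
            ds_centrality_limit(build_adjacency(er50), beta=0.0, mu=1.0),
            np.zeros(er50.n),
        )

    def test_above_threshold_errors(self, path3):
        # lambda1 = sqrt(2); beta = 0.8 puts beta*lambda1 above 1
        with pytest.raises(ValueError, match="diverges"):
            ds_centrality_limit(build_adjacency(path3), beta=0.8, mu=1.0)

    def test_below_threshold_accepted_on_path3(self, path3):
        S = ds_centrality_limit(build_adjacency(path3), beta=0.5, mu=1.0)
        assert np.all(np.isfinite(S)) and np.all(S > 0)

    def test_limit_matches_long_horizon_sum(self, ba200):
        A = build_adjacency(ba200)
        lim = ds_centrality_limit(A, beta=0.05, mu=1.0)
        S200 = ds_centrality(A, SpreadingParams(beta=0.05, mu=1.0, t=200))
        assert np.max(np.abs(S200 - lim)) <= 1e-6


class TestSpectralForm:
    def test_decomposition_invariants(self, er50):
        A = build_adjacency(er50, sparse=False)
        vals, vecs = spectral_decomposition(A)
        assert np.all(np.diff(vals) <= 1e-12)
        assert np.all(vecs[:, 0] > 0)
        np.testing.assert_allclose(A @ vecs, vecs * vals, atol=1e-8)

    @pytest.mark.parametrize("mu", [0.0, 0.3, 0.7, 1.0])
    def test_matches_iterative_form(self, er50, mu):
        A = build_adjacency(er50)
        params = SpreadingParams(beta=0.06, mu=mu, t=8)
        np.testing.assert_allclose(
            ds_spectral(A, params), ds_centrality(A, params), atol=1e-8
        )

    def test_t1_reduces_to_beta_degree(self, ba200):
        A = build_adjacency(ba200)
        np.testing.assert_allclose(
            ds_spectral(A, SpreadingParams(beta=0.04, mu=1.0, t=1)),
            0.04 * degree(A),
            atol=1e-8,
        )

    def test_ranking_converges_to_eigenvector_above_threshold(self, ba200):
        # the leading-mode weight diverges only for beta*lambda1 + 1 - mu >= 1;
        # there the DS ranking approaches the eigenvector-centrality ranking
        A = build_adjacency(ba200)
        lam1 = leading_eigenvalue(A)
        ev = eigenvector_centrality(A)
        S = ds_centrality(A, SpreadingParams(beta=1.05 / lam1, mu=1.0, t=60))
        assert kendall_tau(S, ev) >= 0.99


class TestComputeCentralityDispatch:
    def test_ds_requires_params(self, path3):
        with pytest.raises(ValueError, match="requires"):
            compute_centrality(path3, "ds")

    def test_unknown_method(self, path3):
        with pytest.raises(ValueError, match="unknown method"):
            compute_centrality(path3, "pagerank")

    def test_dash_alias(self, path3):
        S = compute_centrality(path3, "ds-limit", SpreadingParams(beta=0.2, mu=1.0, t=1))
        assert S.shape == (3,)
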