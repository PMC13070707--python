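"""Transition kernels against independent brute-force enumeration oracles."""

import numpy as np
import pytest

import hyperwalk as hw
from conftest import brute_force_comem, brute_force_diphw, brute_force_edvw, random_incidence


def make_incidence(I):
    V, E = I.shape
    return hw.IncidenceMatrix(I, np.ones(E), [f"v{i}" for i in range(V)], [f"e{j}" for j in range(E)])


class TestBuildHypergraph:
    def test_transposition_identity(self, toy_matrix):
        h = hw.build_hypergraph(toy_matrix)
        assert h.I_H.shape == (4, 4)
        np.testing.assert_array_equal(h.I_H, toy_matrix.dense().T)
        np.testing.assert_array_equal(h.edge_weights, np.ones(4))
        assert h.node_ids == toy_matrix.cell_ids
        assert h.edge_ids == toy_matrix.gene_ids

    def test_zero_column_rejected(self):
        m = hw.ExpressionMatrix(np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="drop_zero"):
            hw.build_hypergraph(m)


class TestDiphw:
    def test_worked_two_cell_example(self):
        # cells v1, v2; genes e1, e2; gamma: v1 only in e1
        h = make_incidence(np.array([[2.0, 0.0], [1.0, 1.0]]))
        P = hw.diphw_transition(h, alpha=1.0)
        np.testing.assert_allclose(P.P, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)

    def test_single_edge_uniform(self, rng):
        # one hyperedge containing all nodes with equal weight -> uniform P
        I = np.full((5, 1), 3.0)
        for alpha in (0.0, 1.0, 2.5):
            P = hw.diphw_transition(make_incidence(I), alpha)
            np.testing.assert_allclose(P.P, np.full((5, 5), 0.2), atol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0, 2.0])
    def test_matches_brute_force_oracle(self, rng, alpha):
        for _ in range(30):
            I = random_incidence(rng, rng.integers(2, 9), rng.integers(2, 9))
            omega = rng.random(I.shape[1]) + 0.5
            h = hw.IncidenceMatrix(I, omega, [str(i) for i in range(I.shape[0])],
                                   [str(j) for j in range(I.shape[1])])
            P = hw.diphw_transition(h, alpha)
            np.testing.assert_allclose(P.P, brute_force_diphw(I, omega, alpha), atol=1e-12)

    def test_row_stochastic_on_random_inputs(self, rng):
        for _ in range(20):
            I = random_incidence(rng, rng.integers(2, 10), rng.integers(2, 10))
            P = hw.diphw_transition(make_incidence(I), rng.random() * 3)
            np.testing.assert_allclose(P.P.sum(axis=1), 1.0, atol=1e-8)
            assert (P.P >= 0).all()

    def test_negative_alpha_rejected(self):
        h = make_incidence(np.array([[1.0, 1.0], [1.0, 2.0]]))
        with pytest.raises(ValueError, match="alpha"):
            hw.diphw_transition(h, -0.5)

    def test_preference_concentrates_with_alpha(self, rng):
        # as alpha grows, the edge-to-node mass concentrates on argmax gamma
        I = random_incidence(rng, 6, 4)
        maxima = []
        for alpha in (0.5, 1.0, 2.0, 4.0, 8.0):
            W = np.where(I > 0, I ** alpha, 0.0).T
            P_ve = W / W.sum(axis=1, keepdims=True)
            maxima.append(P_ve.max(axis=1))
        for lo, hi in zip(maxima, maxima[1:]):
            assert (hi >= lo - 1e-12).all()


class TestEdvw:
    def test_worked_example_and_oracle(self):
        I = np.array([[2.0, 0.0], [1.0, 1.0]])
        h = make_incidence(I)
        P = hw.edvw_transition(h)
        np.testing.assert_allclose(P.P, brute_force_edvw(I, np.ones(2)), atol=1e-12)
        # v1 belongs only to e1 -> must pick e1; then cells prop to gamma
        np.testing.assert_allclose(P.P[0], [2 / 3, 1 / 3], atol=1e-12)

    def test_equals_diphw_when_edges_internally_uniform(self, rng):
        # all gamma equal within each edge -> EDVW == DIPHW(alpha=1)
        I = (random_incidence(rng, 6, 5) > 0).astype(float) * 2.5
        h = make_incidence(I)
        np.testing.assert_allclose(hw.edvw_transition(h).P,
                                   hw.diphw_transition(h, 1.0).P, atol=1e-12)

    def test_matches_oracle_random(self, rng):
        for _ in range(20):
            I = random_incidence(rng, rng.integers(2, 8), rng.integers(2, 8))
            omega = rng.random(I.shape[1]) + 0.5
            h = hw.IncidenceMatrix(I, omega, [str(i) for i in range(I.shape[0])],
                                   [str(j) for j in range(I.shape[1])])
            np.testing.assert_allclose(hw.edvw_transition(h).P,
                                       brute_force_edvw(I, omega), atol=1e-12)


def random_similarity(rng, n):
    S = rng.random((n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 0.0)
    return S


class TestComem:
    def test_uniform_similarity_reduces_to_memoryless_nonlazy(self, rng):
        # all-ones off-diagonal similarities: memory factors constant, so the
        # kernel equals the composite walk restricted to non-lazy moves
        I = random_incidence(rng, 5, 5, density=1.0)
        h = make_incidence(I)
        GV = np.ones((5, 5)) - np.eye(5)
        GE = np.ones((5, 5)) - np.eye(5)
        gv = hw.SimilarityNetwork(GV, h.node_ids, "cell")
        ge = hw.SimilarityNetwork(GE, h.edge_ids, "gene")
        P = hw.comem_transition(h, gv, ge, mode="comem")
        np.testing.assert_allclose(P.P, brute_force_comem(I, GV, GE), atol=1e-12)
        np.testing.assert_allclose(np.diag(P.P), 0.0, atol=1e-12)

    @pytest.mark.parametrize("mode,alpha", [("comem", None), ("comem-diphw", 0.7),
                                            ("comem-diphw", 2.0)])
    def test_matches_triple_loop_oracle(self, rng, mode, alpha):
        for _ in range(15):
            n_v, n_e = rng.integers(3, 7), rng.integers(3, 7)
            I = random_incidence(rng, n_v, n_e, density=0.9, min_edges_per_node=2)
            h = make_incidence(I)
            GV = random_similarity(rng, n_v)
            GE = random_similarity(rng, n_e)
            gv = hw.SimilarityNetwork(GV, h.node_ids, "cell")
            ge = hw.SimilarityNetwork(GE, h.edge_ids, "gene")
            P = hw.comem_transition(h, gv, ge, mode=mode,
                                    alpha=1.0 if alpha is None else alpha)
            expect = brute_force_comem(I, GV, GE, alpha=alpha)
            np.testing.assert_allclose(P.P, expect, atol=1e-12)

    def test_block_similarity_confines_walker(self, rng):
        # zero similarity across two cell blocks -> no cross-block transitions
        I = random_incidence(rng, 6, 6, density=1.0)
        h = make_incidence(I)
        GV = np.zeros((6, 6))
        GV[:3, :3] = 1.0
        GV[3:, 3:] = 1.0
        np.fill_diagonal(GV, 0.0)
        GE = random_similarity(rng, 6)
        P = hw.comem_transition(h, hw.SimilarityNetwork(GV, h.node_ids, "cell"),
                                hw.SimilarityNetwork(GE, h.edge_ids, "gene"))
        np.testing.assert_allclose(P.P[:3, 3:], 0.0, atol=1e-15)
        np.testing.assert_allclose(P.P[3:, :3], 0.0, atol=1e-15)

    def test_dimension_mismatch_rejected(self, rng):
        I = random_incidence(rng, 4, 5)
        h = make_incidence(I)
        gv = hw.SimilarityNetwork(random_similarity(rng, 3), ["a", "b", "c"], "cell")
        ge = hw.SimilarityNetwork(random_similarity(rng, 5), [str(i) for i in range(5)], "gene")
        with pytest.raises(ValueError, match="G_V"):
            hw.comem_transition(h, gv, ge)

    def test_zero_mass_node_errors_without_floor(self):
        # a cell expressing a single gene is trapped by the non-lazy rule
        I = np.array([[4.0, 0.0], [1.0, 1.0], [0.0, 3.0]])
        h = make_incidence(I)
        GV = np.ones((3, 3)) - np.eye(3)
        GE = np.zeros((2, 2))  # no edge similar to any other
        gv = hw.SimilarityNetwork(GV, h.node_ids, "cell")
        ge = hw.SimilarityNetwork(GE, h.edge_ids, "gene")
        with pytest.raises(ValueError, match="similarity_floor"):
            hw.comem_transition(h, gv, ge)
        # with a floor the matrix is valid and row-stochastic
        P = hw.comem_transition(h, gv, ge, similarity_floor=1e-6)
        np.testing.assert_allclose(P.P.sum(axis=1), 1.0, atol=1e-8)


class TestSampleWalks:
    def test_deterministic_two_state_chain(self):
        P = hw.TransitionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        corpus = hw.sample_walks(P, hw.WalkParams(walks_per_node=2, walk_length=6, seed=0))
        assert corpus.paths.shape == (4, 6)
        for path in corpus.paths:
            assert all(path[i] != path[i + 1] for i in range(5))

    def test_corpus_size_contract(self, rng):
        n = 7
        M = rng.random((n, n)) + 0.01
        M /= M.sum(axis=1, keepdims=True)
        P = hw.TransitionMatrix(M, [str(i) for i in range(n)])
        corpus = hw.sample_walks(P, hw.WalkParams(walks_per_node=3, walk_length=11, seed=1))
        assert corpus.paths.shape == (3 * n, 11)
        # every node starts r walks
        starts = np.bincount(corpus.paths[:, 0], minlength=n)
        assert (starts == 3).all()

    def test_reproducible_with_seed(self, rng):
        M = rng.random((5, 5)) + 0.01
        M /= M.sum(axis=1, keepdims=True)
        P = hw.TransitionMatrix(M, [str(i) for i in range(5)])
        p1 = hw.sample_walks(P, hw.WalkParams(seed=9, walks_per_node=2, walk_length=10)).paths
        p2 = hw.sample_walks(P, hw.WalkParams(seed=9, walks_per_node=2, walk_length=10)).paths
        np.testing.assert_array_equal(p1, p2)

    def test_visit_frequencies_match_stationary_distribution(self):
        # 5-node chain: empirical visits converge to the left eigenvector
        rng = np.random.default_rng(3)
        M = rng.random((5, 5)) + 0.05
        M /= M.sum(axis=1, keepdims=True)
        P = hw.TransitionMatrix(M, [str(i) for i in range(5)])
        corpus = hw.sample_walks(P, hw.WalkParams(walks_per_node=4, walk_length=5000, seed=2))
        visits = np.bincount(corpus.paths[:, 100:].ravel(), minlength=5).astype(float)
        visits /= visits.sum()
        evals, evecs = np.linalg.eig(M.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
        assert 0.5 * np.abs(visits - pi).sum() < 0.05

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            hw.TransitionMatrix(np.array([[0.5, 0.2], [0.3, 0.7]]), ["a", "b"])
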