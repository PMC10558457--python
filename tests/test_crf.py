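"""Pairwise graphical model: structure learning, Bethe/exact agreement,
model selection, decoding readouts, shuffle-calibrated ensembles."""

import numpy as np
import pytest

from fearcond.crf import (
    CRFStructure,
    PairwiseCRF,
    connectivity_scores,
    crf_ensemble,
    default_lambda_s_grid,
    exact_loglik,
    learn_parameters,
    learn_structure,
    node_decoding_auc,
    select_model,
)
from fearcond.synth import sample_ising_raster


@pytest.fixture(scope="module")
def chain_model():
    """A 5-node chain fit on Gibbs samples from a known Ising model."""
    n = 5
    h = np.array([-0.5, 0.2, -0.3, 0.1, -0.2])
    J = np.zeros((n, n))
    for i in range(n - 1):
        J[i, i + 1] = J[i + 1, i] = 1.0
    X = sample_ising_raster(h, J, 1500, rng=0)
    structure = CRFStructure(n, [(i, i + 1) for i in range(n - 1)], 0.01)
    model = learn_parameters(X, structure, 1.0, engine="exact")
    return model, X


class TestStructureLearning:
    def test_independent_nodes_sparse(self):
        rng = np.random.default_rng(1)
        X = (rng.random((2000, 12)) < 0.2).astype(np.int8)
        st = learn_structure(X, 0.05)
        possible = 12 * 11 / 2
        assert st.n_edges / possible <= 0.05

    def test_coupled_pair_recovered_across_lambda_range(self):
        h = np.full(6, -1.5)
        J = np.zeros((6, 6))
        J[0, 1] = J[1, 0] = 2.5
        X = sample_ising_raster(h, J, 3000, rng=2)
        for ls in (0.005, 0.02, 0.05):
            st = learn_structure(X, ls)
            assert (0, 1) in st.edges, f"edge lost at lambda_s={ls}"

    def test_huge_lambda_empties_graph(self):
        rng = np.random.default_rng(3)
        X = (rng.random((500, 8)) < 0.3).astype(np.int8)
        assert learn_structure(X, 10.0).n_edges == 0

    def test_constant_node_isolated_with_warning(self):
        rng = np.random.default_rng(4)
        X = (rng.random((300, 5)) < 0.3).astype(np.int8)
        X[:, 2] = 0
        with pytest.warns(UserWarning, match="constant"):
            st = learn_structure(X, 0.01)
        assert all(2 not in e for e in st.edges)

    def test_edge_density_shrinks_with_lambda(self):
        rng = np.random.default_rng(5)
        X = (rng.random((1000, 10)) < 0.25).astype(np.int8)
        sizes = [learn_structure(X, ls).n_edges for ls in (0.002, 0.02, 0.2)]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestParameterLearning:
    def test_tree_bethe_equals_exact(self, chain_model):
        """On a tree the Bethe log-likelihood matches exhaustive
        enumeration to 1e-6 relative."""
        model, X = chain_model
        ll_exact = exact_loglik(model, X)
        model_bp = PairwiseCRF(lambda_s=0.01, lambda_p=1.0,
                               structure=model.structure_, engine="bp")
        model_bp.structure_ = model.structure_
        model_bp.node_potentials_ = model.node_potentials_
        model_bp.edge_potentials_ = model.edge_potentials_
        from fearcond.crf import _BPState
        model_bp._bp = _BPState(model.structure_)
        ll_bethe = model_bp.log_likelihood(X)
        assert abs(ll_bethe - ll_exact) / abs(ll_exact) <= 1e-6

    def test_learned_marginals_match_empirical(self, chain_model):
        model, X = chain_model
        from fearcond.crf import _exact_inference
        _, node_marg, _ = _exact_inference(model.node_potentials_,
                                           model.edge_potentials_,
                                           model.structure_.edges, 5)
        np.testing.assert_allclose(node_marg[:, 1], X.mean(axis=0), atol=1e-3)

    def test_objective_trace_reaches_stationary_maximum(self, chain_model):
        model, _ = chain_model
        trace = model.objective_trace_
        assert trace[-1] >= trace[0]
        assert np.max(trace) - trace[-1] <= 1e-6 * abs(trace[-1]) + 1e-3

    def test_huge_ridge_flattens_potentials(self):
        rng = np.random.default_rng(6)
        X = (rng.random((400, 4)) < 0.4).astype(np.int8)
        st = CRFStructure(4, [(0, 1), (2, 3)], 0.01)
        m = learn_parameters(X, st, 1e7, engine="exact")
        assert np.abs(m.node_potentials_).max() < 0.05
        assert np.abs(m.edge_potentials_).max() < 0.05
        # near-zero potentials: the model is close to independent uniform
        assert m.log_likelihood(X, per_frame=True) == pytest.approx(
            -4 * np.log(2), abs=0.05)

    def test_empty_graph_recovers_node_log_odds(self):
        """With no edges the penalized MLE reproduces each node's empirical
        log-odds (up to the weak ridge), matching the closed form."""
        rng = np.random.default_rng(7)
        p1 = np.array([0.2, 0.5, 0.7])
        X = (rng.random((4000, 3)) < p1[None, :]).astype(np.int8)
        st = CRFStructure(3, [], 0.01)
        m = learn_parameters(X, st, 1.0, engine="exact")
        odds = m.node_potentials_[:, 1] - m.node_potentials_[:, 0]
        expected = np.log(X.mean(0) / (1 - X.mean(0)))
        np.testing.assert_allclose(odds, expected, atol=0.05)


class TestExactLoglik:
    def test_uniform_model(self):
        st = CRFStructure(6, [], 0.01)
        m = PairwiseCRF(structure=st, engine="exact")
        m.structure_ = st
        m.node_potentials_ = np.zeros((6, 2))
        m.edge_potentials_ = np.zeros((0, 2, 2))
        from fearcond.crf import _BPState
        m._bp = _BPState(st)
        X = np.zeros((10, 6), dtype=np.int8)
        assert exact_loglik(m, X) == pytest.approx(-10 * 6 * np.log(2))

    def test_two_node_hand_enumeration(self):
        """Z computed by hand for a 2-node model with set potentials."""
        st = CRFStructure(2, [(0, 1)], 0.01)
        m = PairwiseCRF(structure=st, engine="exact")
        m.structure_ = st
        m.node_potentials_ = np.array([[0.0, 1.0], [0.0, -0.5]])
        m.edge_potentials_ = np.array([[[0.2, 0.0], [0.0, 0.7]]])
        from fearcond.crf import _BPState
        m._bp = _BPState(st)
        # states (x0,x1): 00,01,10,11 with scores .2, -.5, 1, 1.2
        scores = np.array([0.2, -0.5, 1.0, 0.7 + 1.0 - 0.5])
        Z = np.exp(scores).sum()
        X = np.array([[1, 1]], dtype=np.int8)
        assert exact_loglik(m, X) == pytest.approx(scores[3] - np.log(Z))

    def test_refuses_large_graphs(self):
        st = CRFStructure(25, [], 0.01)
        m = PairwiseCRF(structure=st)
        m.structure_ = st
        with pytest.raises(ValueError, match="20"):
            exact_loglik(m, np.zeros((1, 25), dtype=np.int8))


class TestModelSelection:
    def test_single_point_grid_returned(self):
        rng = np.random.default_rng(8)
        X = (rng.random((600, 8)) < 0.25).astype(np.int8)
        sel = select_model(X, [0.05], [10.0], rng=0)
        assert sel.lambda_s == 0.05 and sel.lambda_p == 10.0

    def test_planted_graph_recovered_with_good_f1(self):
        h = np.full(12, -1.8)
        J = np.zeros((12, 12))
        planted = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (0, 4)]
        for i, j in planted:
            J[i, j] = J[j, i] = 2.2
        X = sample_ising_raster(h, J, 2500, rng=9)
        sel = select_model(X, default_lambda_s_grid(25), (1.0, 10.0, 100.0),
                          rng=1)
        found = set(sel.model.structure_.edges)
        tp = len(found & set(planted))
        f1 = 2 * tp / (len(found) + len(planted)) if found else 0.0
        assert f1 >= 0.7

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        X = (rng.random((500, 6)) < 0.3).astype(np.int8)
        s1 = select_model(X, [0.01, 0.05], [1.0, 10.0], rng=3)
        s2 = select_model(X, [0.01, 0.05], [1.0, 10.0], rng=3)
        assert (s1.lambda_s, s1.lambda_p) == (s2.lambda_s, s2.lambda_p)
        assert s1.heldout_loglik == pytest.approx(s2.heldout_loglik)

    def test_best_not_below_worst_grid_member(self):
        rng = np.random.default_rng(11)
        X = (rng.random((500, 6)) < 0.3).astype(np.int8)
        sel = select_model(X, [0.005, 0.05, 0.3], [1.0, 100.0], rng=4)
        assert sel.heldout_loglik >= max(min(r["heldout_loglik"] for r in sel.table),
                                         sel.table[0]["heldout_loglik"] - 1e9)
        assert sel.heldout_loglik == max(r["heldout_loglik"] for r in sel.table)


class TestReadouts:
    def test_connectivity_scores_empty_complete_star(self):
        for edges, expected in [
            ([], [0.0] * 5),
            ([(i, j) for i in range(5) for j in range(i + 1, 5)], [1.0] * 5),
            ([(0, i) for i in range(1, 5)], [1.0, 0.25, 0.25, 0.25, 0.25]),
        ]:
            st = CRFStructure(5, edges, 0.01)
            m = PairwiseCRF(structure=st)
            m.structure_ = st
            np.testing.assert_allclose(connectivity_scores(m), expected)
        assert sum(CRFStructure(5, [(0, 1), (1, 2)], 0.1).degrees()) % 2 == 0

    def test_stimulus_locked_ensemble_decodes_and_independent_does_not(self):
        """The clamped log-ratio of a node varies through its neighbors, so
        decoding requires a stimulus-locked *ensemble*: mutually coupled
        locked nodes read the stimulus off each other, while a node embedded
        in noise stays at chance."""
        rng = np.random.default_rng(12)
        m_frames = 2000
        labels = (rng.random(m_frames) < 0.4).astype(int)
        X = (rng.random((m_frames, 5)) < 0.2).astype(np.int8)
        for i in (0, 1, 2):
            X[:, i] = (rng.random(m_frames) < np.where(labels, 0.85, 0.05)).astype(np.int8)
        model = PairwiseCRF(lambda_s=0.02, lambda_p=10.0).fit(X)
        nd = node_decoding_auc(model, X, labels)
        assert nd.auc[0] > 0.8 and nd.auc[1] > 0.8
        assert abs(nd.auc[4] - 0.5) < 0.12

    def test_llr_antisymmetric_under_clamp_swap(self, chain_model):
        """Swapping the clamp states flips the sign of the log-ratio."""
        model, X = chain_model
        llr = model.node_llr(X[:50])
        flipped = -llr
        # recompute with potentials swapped between states 0 and 1
        m2 = PairwiseCRF(structure=model.structure_, engine="exact")
        m2.structure_ = model.structure_
        m2.node_potentials_ = model.node_potentials_[:, ::-1].copy()
        m2.edge_potentials_ = model.edge_potentials_[:, ::-1, ::-1].copy()
        llr2 = m2.node_llr(1 - X[:50])
        np.testing.assert_allclose(llr2, flipped, atol=1e-12)

    def test_crf_ensemble_null_mostly_empty_and_planted_recovered(self):
        rng = np.random.default_rng(13)
        m_frames = 1200
        labels = np.zeros(m_frames, dtype=int)
        labels[rng.choice(m_frames, m_frames // 3, replace=False)] = 1
        planted = [0, 1, 2]
        X = (rng.random((m_frames, 10)) < 0.15).astype(np.int8)
        for i in planted:
            X[:, i] = (rng.random(m_frames) < np.where(labels, 0.7, 0.05)).astype(np.int8)
        model = PairwiseCRF(lambda_s=0.02, lambda_p=10.0).fit(X)
        res = crf_ensemble(model, X, labels, n_shuffled=12, rng=0)
        members = set(res["members"].tolist())
        assert len(members & set(planted)) >= 2  # recall >= 0.7 on 3 planted
        # null input: fully shuffled raster carries no stimulus ensemble
        from fearcond.crf import _shuffle_raster
        Xs = _shuffle_raster(X, np.random.default_rng(1))
        model_s = PairwiseCRF(lambda_s=0.02, lambda_p=10.0).fit(Xs)
        res_null = crf_ensemble(model_s, Xs, labels, n_shuffled=12, rng=2)
        assert res_null["members"].size <= 1
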