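import math

import networkx as nx
import numpy as np
import pytest

from indepth.errors import ValidationError
from indepth.hubs import assign_weights, compute_delta, hub_scores
from indepth.network import DEGNetwork, Edge, connect_downstream, select_upstream, simplify_graph
from indepth.query_signature import QuerySignature
from conftest import toy_cascade
from oracles import hits_eigen_oracle


def graph_from_matrix(w):
    return nx.from_numpy_array(np.asarray(w, float), create_using=nx.DiGraph)


class TestComputeDelta:
    def test_stated_ratio(self, tiny_db):
        # r1 up-regulates {A, B} (2 genes); 50 UP DEGs would cap, 1 gives 0.5
        query = QuerySignature(up_degs=frozenset({"A"}), down_degs=frozenset({"E"}),
                               gene_ratio={"A": 3.0, "E": 0.3})
        d_up, d_down = compute_delta("r1", query, tiny_db)
        assert d_up == pytest.approx(0.5)   # 1 UP DEG / 2 up-regulated genes
        assert d_down == pytest.approx(1.0)  # 1 DOWN DEG / 1 down-regulated gene

    def test_capped_at_one(self, tiny_db, simple_query):
        # 2 UP DEGs / 2 up-regulated landmark genes = 1; more DEGs would exceed
        query = QuerySignature(
            up_degs=frozenset({"A", "C", "F"}), down_degs=frozenset({"E"}),
            gene_ratio={})
        d_up, _ = compute_delta("r1", query, tiny_db)
        assert d_up == 1.0

    def test_empty_regulated_set_gives_zero(self, tiny_db, simple_query):
        # r3 has all-zero z: no regulated genes at all
        assert compute_delta("r3", simple_query, tiny_db) == (0.0, 0.0)


class TestAssignWeights:
    @pytest.fixture
    def weighted_toy(self):
        db, query, scores, _ = toy_cascade()
        kept = select_upstream(scores, 0.5, query, db)
        net = simplify_graph(connect_downstream(kept, db, query), kept)
        return db, query, net

    def test_alpha_times_best_delta(self, weighted_toy):
        db, query, net = weighted_toy
        assign_weights(net, query, db)
        # D->E supported by k1 (delta_down = 2 DOWN DEGs / 2 down genes = 1)
        # and k2 (2/2 = 1); alpha(D) = 0.25 raw
        assert net.graph["D"]["E"]["weight"] == pytest.approx(0.25 * 1.0)

    def test_symmetric_alpha_inverts_down_ratios(self, weighted_toy):
        db, query, net = weighted_toy
        assign_weights(net, query, db, alpha_mode="symmetric")
        assert net.graph["D"]["E"]["weight"] == pytest.approx(4.0 * 1.0)

    def test_merged_edge_uses_max_delta(self, tiny_db):
        query = QuerySignature(up_degs=frozenset({"A"}), down_degs=frozenset({"E", "D"}),
                               gene_ratio={"A": 3.0, "E": 0.3, "D": 0.2})
        net = simplify_graph([
            Edge("E", "A", "up", ("r1",)),   # delta_up(r1) = 1/2
            Edge("E", "A", "up", ("r2",)),   # delta_up(r2) = 1/2 (up_set {C, D})
        ])
        assign_weights(net, query, tiny_db)
        d1 = compute_delta("r1", query, tiny_db)[0]
        d2 = compute_delta("r2", query, tiny_db)[0]
        assert net.graph["E"]["A"]["weight"] == pytest.approx(0.3 * max(d1, d2))

    def test_missing_alpha_rejected(self, weighted_toy):
        db, query, net = weighted_toy
        query.gene_ratio.pop("D")
        with pytest.raises(ValidationError, match="alpha"):
            assign_weights(net, query, db)


class TestHubScores:
    def test_single_edge(self):
        g = nx.DiGraph([("u", "d")])
        res = hub_scores(g)
        assert res.hub["u"] == 1.0 and res.hub["d"] == 0.0
        assert res.authority["d"] == 1.0 and res.converged

    def test_star_plus_spoke_closed_form(self):
        # W W^T = [[3, 1], [1, 1]]; principal eigenvalue 2 + sqrt(2);
        # normalised second component = lambda - 3 = sqrt(2) - 1
        g = nx.DiGraph([("u", "d1"), ("u", "d2"), ("u", "d3"), ("v", "d1")])
        res = hub_scores(g)
        assert res.hub["u"] == 1.0
        assert res.hub["v"] == pytest.approx(math.sqrt(2) - 1, abs=1e-8)

    def test_edge_free_graph_all_zero(self):
        g = nx.DiGraph()
        g.add_nodes_from(["a", "b"])
        res = hub_scores(g)
        assert res.hub == {"a": 0.0, "b": 0.0} and res.converged

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        w = np.where(rng.random((10, 10)) < 0.4, rng.uniform(0.1, 2, (10, 10)), 0)
        np.fill_diagonal(w, 0)
        h1 = hub_scores(graph_from_matrix(w)).hub
        h2 = hub_scores(graph_from_matrix(17.3 * w)).hub
        for k in h1:
            assert h2[k] == pytest.approx(h1[k], abs=1e-9)

    def test_max_normalisation_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = rng.integers(2, 15)
            w = np.where(rng.random((n, n)) < 0.5, rng.uniform(0.1, 1, (n, n)), 0)
            np.fill_diagonal(w, 0)
            if not w.any():
                continue
            res = hub_scores(graph_from_matrix(w))
            assert max(res.hub.values()) == 1.0
            assert min(res.hub.values()) >= 0.0

    def test_adding_out_edge_never_hurts_prenormal_hub(self):
        """Monotone influence, checked against the eigen oracle directly."""
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = 8
            w = np.where(rng.random((n, n)) < 0.35, rng.uniform(0.1, 1, (n, n)), 0)
            np.fill_diagonal(w, 0)
            if not w.any():
                continue
            zeros = np.argwhere(w == 0)
            zeros = zeros[zeros[:, 0] != zeros[:, 1]]
            if not len(zeros):
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = rng.uniform(0.1, 1)

            def prenormal_hub(mat):
                m = mat @ mat.T
                vals, vecs = np.linalg.eigh(m)
                v = np.abs(vecs[:, -1]) * math.sqrt(max(vals[-1], 0))
                return v

            # compare the node's share of spectral mass before/after
            h_before = prenormal_hub(w)
            h_after = prenormal_hub(w2)
            assert h_after[i] >= h_before[i] - 1e-9

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(2, 20))
            w = np.where(rng.random((n, n)) < 0.3, rng.uniform(0.1, 2, (n, n)), 0)
            np.fill_diagonal(w, 0)
            if not w.any():
                continue
            res = hub_scores(graph_from_matrix(w), tol=1e-13, max_iter=50000)
            hub_o, auth_o = hits_eigen_oracle(w)
            got_h = np.array([res.hub[i] for i in range(n)])
            got_a = np.array([res.authority[i] for i in range(n)])
            assert np.abs(got_h - hub_o).max() < 1e-8
            assert np.abs(got_a - auth_o).max() < 1e-8

    def test_non_convergence_flagged(self):
        g = nx.DiGraph([("a", "b"), ("c", "b")])
        res = hub_scores(g, tol=0.0, max_iter=3)
        assert not res.converged and res.iterations == 3
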