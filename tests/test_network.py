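import numpy as np
import pandas as pd
import pytest

import networkx as nx

from indepth.network import (
    Edge,
    connect_downstream,
    select_upstream,
    simplify_graph,
    write_graphml,
    write_sif,
)
from conftest import toy_cascade


@pytest.fixture
def cascade():
    return toy_cascade()


class TestSelectUpstream:
    def test_filter_cascade_counts(self, cascade):
        db, query, scores, expected = cascade
        audit = {}
        kept = select_upstream(scores, 0.5, query, db, audit=audit)
        assert audit == expected
        assert {(c.record_id, c.gene) for c in kept} == {("k1", "D"), ("k2", "D")}

    def test_direction_rule_rejects_regardless_of_score(self, cascade):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        assert "k5" not in {c.record_id for c in kept}  # scored 0.95 but A is UP

    def test_single_shrna_knockdown_rejected(self, cascade):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        assert "E" not in {c.gene for c in kept}

    def test_overexpression_not_subject_to_two_clone_rule(self, cascade):
        db, query, scores, _ = cascade
        scores = scores.copy()
        scores.loc[scores["record_id"] == "k4", ["pert_type", "target_gene"]] = \
            ["overexpression", "C"]
        kept = select_upstream(scores, 0.5, query, db)
        assert ("k4", "C") in {(c.record_id, c.gene) for c in kept}

    def test_raising_cutoff_shrinks_selection(self, cascade):
        db, query, scores, _ = cascade
        sizes = [len(select_upstream(scores, c, query, db))
                 for c in (0.0, 0.5, 0.85, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_selection_is_valid(self, cascade):
        db, query, scores, _ = cascade
        assert select_upstream(scores, 2.0, query, db) == []


class TestConnectDownstream:
    def test_edges_follow_regulated_set_intersections(self, cascade):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        edges = connect_downstream(kept, db, query)
        got = {(e.source, e.target, e.direction) for e in edges}
        # k1: C up, E down (D->D self-loop kept until simplification)
        # k2: A up, E down
        assert got == {("D", "C", "up"), ("D", "E", "down"),
                       ("D", "A", "up"), ("D", "D", "down")}

    def test_direction_mismatch_produces_no_edge(self, cascade):
        db, query, _, _ = cascade
        # k4 up-regulates F (not a DEG) and down-regulates E; if we pretend it
        # was retained for E, only the E down-edge appears
        from indepth.network import UpstreamCandidate
        cand = [UpstreamCandidate(gene="E", pert_type="knockdown", pert_id="sh9",
                                  record_id="k4", score=0.85)]
        edges = connect_downstream(cand, db, query)
        assert {(e.target, e.direction) for e in edges} == {("E", "down")}

    def test_intersection_mode_requires_all_records(self, cascade):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        edges = connect_downstream(kept, db, query, combine="intersection")
        # only D->E (and the D->D loop) are supported by both k1 and k2
        assert {(e.source, e.target) for e in edges} == {("D", "E"), ("D", "D")}


class TestSimplifyGraph:
    def test_removes_loops_and_merges_parallel_edges(self):
        edges = [
            Edge("G", "G", "down", ("r1",)),
            Edge("G", "A", "up", ("r1",)),
            Edge("G", "A", "up", ("r2",)),
        ]
        net = simplify_graph(edges)
        assert net.n_nodes == 2 and net.n_edges == 1
        assert net.graph["G"]["A"]["supporting_records"] == ("r1", "r2")

    def test_isolated_upstream_gene_kept_as_node(self):
        from indepth.network import UpstreamCandidate
        cand = UpstreamCandidate(gene="G", pert_type="knockdown", pert_id="sh",
                                 record_id="r", score=0.9)
        net = simplify_graph([], upstream=[cand])
        assert net.n_nodes == 1 and net.n_edges == 0

    def test_matches_set_dedup_oracle_on_random_multigraph(self):
        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(8)]
        edges = [
            Edge(rng.choice(nodes), rng.choice(nodes), "up", (f"r{i}",))
            for i in range(60)
        ]
        net = simplify_graph(edges)
        expected = {(e.source, e.target) for e in edges if e.source != e.target}
        assert set(net.graph.edges) == expected

    def test_edge_targets_are_same_direction_degs(self, cascade):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        net = simplify_graph(connect_downstream(kept, db, query), kept)
        for _, tgt, attrs in net.graph.edges(data=True):
            expected = query.up_degs if attrs["direction"] == "up" else query.down_degs
            assert tgt in expected


class TestExports:
    def test_sif_and_graphml_round_trip(self, cascade, tmp_path):
        db, query, scores, _ = cascade
        kept = select_upstream(scores, 0.5, query, db)
        net = simplify_graph(connect_downstream(kept, db, query), kept)
        write_sif(net, tmp_path / "net.sif")
        write_graphml(net, tmp_path / "net.graphml")
        sif = (tmp_path / "net.sif").read_text().splitlines()
        assert "D\tregulates_up\tC" in sif
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert set(g.edges) == set(net.graph.edges)
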