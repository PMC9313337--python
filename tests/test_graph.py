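"""Graph model, I/O round trips, SCC/cycle machinery vs brute-force oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from pathbn.graph import (
    EdgeRecord,
    GraphFormatError,
    NodeRecord,
    PathwayGraph,
    canonical_cycle,
    example_pathway,
    example_pathway_path,
    find_sccs,
    is_acyclic,
    read_edgelist,
    read_edgelist_full,
    remove_self_loops,
    would_create_cycle,
    write_edgelist,
    write_graphml,
)

from conftest import make_graph, random_digraph


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_sccs(g: PathwayGraph) -> set[frozenset[str]]:
    """SCCs from the reachability closure: u~v iff u reaches v and v reaches u."""
    nodes = list(g.nodes)
    reach = {u: {u} for u in nodes}
    for _ in nodes:
        for e in g.edges:
            reach[e.source] |= reach[e.target] | {e.target}
    loops = {e.source for e in g.edges if e.source == e.target}
    out = set()
    for u in nodes:
        comp = frozenset(v for v in nodes if v in reach[u] and u in reach[v])
        if len(comp) >= 2 or (comp == {u} and u in loops):
            out.add(comp)
    return out


def brute_simple_cycles(g: PathwayGraph, max_len: int) -> set[tuple[str, ...]]:
    """All simple cycles (length >= 2) by enumerating node tuples."""
    keys = {e.key for e in g.edges}
    nodes = sorted(g.nodes)
    found = set()
    for k in range(2, max_len + 1):
        for seq in itertools.permutations(nodes, k):
            if all((seq[i], seq[(i + 1) % k]) in keys for i in range(k)):
                found.add(canonical_cycle(seq))
    return found


# ---------------------------------------------------------------------------
# model and I/O
# ---------------------------------------------------------------------------


def test_duplicate_edges_rejected_by_model():
    with pytest.raises(GraphFormatError):
        PathwayGraph.from_edges("g", [EdgeRecord("A", "B"), EdgeRecord("A", "B")])


def test_edge_endpoint_must_be_node():
    with pytest.raises(GraphFormatError):
        PathwayGraph("g", {"A": NodeRecord("A")}, [EdgeRecord("A", "B")])


def test_read_header_only_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("source\ttarget\tinteraction\n")
    g = read_edgelist(path)
    assert g.n_nodes == 0 and g.n_edges == 0


def test_read_collapses_duplicates_with_warning(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("source\ttarget\nA\tB\nA\tB\n")
    with pytest.warns(UserWarning, match="duplicate"):
        g = read_edgelist(path)
    assert g.n_edges == 1


def test_read_missing_column_errors(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("source\nA\n")
    with pytest.raises(GraphFormatError, match="target"):
        read_edgelist(path)


def test_node_table_overrides_compartment(tmp_path):
    epath, npath = tmp_path / "e.tsv", tmp_path / "n.tsv"
    epath.write_text("source\ttarget\nA\tB\n")
    npath.write_text("id\tcompartment\nA\tnucleus\n")
    g = read_edgelist(epath, node_table=npath)
    assert g.nodes["A"].compartment == "nucleus"
    assert g.nodes["B"].compartment == "unknown"


def test_packaged_example_file_parses(fig_graph):
    g = read_edgelist(example_pathway_path(), name="example")
    assert g.n_nodes == 7 and g.n_edges == 9
    assert g == fig_graph


def test_edgelist_round_trip(tmp_path, fig_graph):
    path = tmp_path / "g.tsv"
    write_edgelist(fig_graph, path)
    assert read_edgelist(path, name="example") == fig_graph


def test_round_trip_preserves_added_provenance(tmp_path):
    g = PathwayGraph.from_edges(
        "g", [EdgeRecord("A", "B"), EdgeRecord("B", "C", provenance="added")]
    )
    path = tmp_path / "g.tsv"
    write_edgelist(g, path)
    back = read_edgelist_full(path, name="g")
    assert back.get_edge("B", "C").provenance == "added"
    assert back.get_edge("A", "B").provenance == "original"


def test_zero_edge_graph_writes_header_only(tmp_path):
    g = PathwayGraph.from_edges("g", [], [NodeRecord("A")])
    path = tmp_path / "g.tsv"
    write_edgelist(g, path)
    assert len(path.read_text().strip().splitlines()) == 1


def test_graphml_export_carries_annotations(tmp_path, fig_graph):
    path = tmp_path / "g.graphml"
    write_graphml(fig_graph, path)
    back = nx.read_graphml(path)
    assert back.nodes["D"]["compartment"] == "nucleus"
    assert back.edges["D", "A"]["interaction"] == "inhibition"
    assert back.edges["D", "A"]["provenance"] == "original"


# ---------------------------------------------------------------------------
# worked example
# ---------------------------------------------------------------------------


def test_example_pathway_has_three_canonical_cycles(fig_graph):
    report = find_sccs(fig_graph)
    assert report.scc_list == [frozenset("ABCDE")]
    assert set(report.simple_cycles) == {("D", "E"), ("A", "B", "D"), ("A", "C", "D")}
    assert report.self_loops == []


def test_example_pathway_acyclic_after_removing_both_feedback_edges(fig_graph):
    pruned = fig_graph.replace_edges(
        [e for e in fig_graph.edges if e.key not in {("D", "A"), ("E", "D")}]
    )
    assert is_acyclic(pruned)
    # removing either edge alone leaves a cycle
    for key in (("D", "A"), ("E", "D")):
        partial = fig_graph.replace_edges([e for e in fig_graph.edges if e.key != key])
        assert not is_acyclic(partial)


# ---------------------------------------------------------------------------
# self-loops, SCCs, cycles
# ---------------------------------------------------------------------------


def test_remove_self_loops():
    g = make_graph([("X", "X"), ("X", "Y")])
    g2, removed = remove_self_loops(g)
    assert [e.key for e in removed] == [("X", "X")]
    assert [e.key for e in g2.edges] == [("X", "Y")]
    g3, removed3 = remove_self_loops(g2)
    assert removed3 == [] and g3.edges == g2.edges


@pytest.mark.parametrize("seed", range(8))
def test_self_loop_count_accounting(seed):
    rng = np.random.default_rng(seed)
    g = random_digraph(int(rng.integers(3, 9)), 0.3, rng, self_loop_prob=1.0)
    k = sum(1 for e in g.edges if e.source == e.target)
    g2, removed = remove_self_loops(g)
    assert len(removed) == k and g2.n_edges == g.n_edges - k


@pytest.mark.parametrize("seed", range(25))
def test_find_sccs_matches_reachability_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    g = random_digraph(int(rng.integers(2, 10)), rng.uniform(0.1, 0.5), rng, self_loop_prob=0.4)
    report = find_sccs(g)
    assert set(report.scc_list) == brute_sccs(g)
    # SCCs partition their nodes
    flat = [n for s in report.scc_list for n in s]
    assert len(flat) == len(set(flat))


@pytest.mark.parametrize("seed", range(5))
def test_simple_cycles_match_brute_force_on_8_nodes(seed):
    rng = np.random.default_rng(200 + seed)
    g = random_digraph(8, 0.2, rng)
    report = find_sccs(g)
    assert set(report.simple_cycles) == brute_simple_cycles(g, 8)


def test_cycles_reported_in_canonical_rotation():
    g = make_graph([("C", "B"), ("B", "A"), ("A", "C")])
    report = find_sccs(g)
    assert report.simple_cycles == [("A", "C", "B")]


def test_dag_has_no_nontrivial_scc():
    g = make_graph([("A", "B"), ("B", "C"), ("A", "C")])
    report = find_sccs(g)
    assert report.scc_list == [] and report.simple_cycles == []


# ---------------------------------------------------------------------------
# incremental acyclicity
# ---------------------------------------------------------------------------


def test_would_create_cycle_basics():
    empty = nx.DiGraph()
    assert would_create_cycle(empty, ("A", "B")) is False
    chain = nx.DiGraph([("A", "B"), ("B", "C")])
    assert would_create_cycle(chain, ("C", "A")) is True
    assert would_create_cycle(chain, ("A", "C")) is False


def test_would_create_cycle_rejects_cyclic_input():
    cyc = nx.DiGraph([("A", "B"), ("B", "A")])
    with pytest.raises(ValueError):
        would_create_cycle(cyc, ("A", "C"))


def test_would_create_cycle_agrees_with_add_then_check_oracle():
    rng = np.random.default_rng(7)
    checked = 0
    while checked < 500:
        n = int(rng.integers(3, 10))
        nodes = [f"n{i}" for i in range(n)]
        dag = nx.DiGraph()
        dag.add_nodes_from(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    dag.add_edge(nodes[i], nodes[j])
        u, v = rng.choice(nodes, size=2, replace=False)
        predicted = would_create_cycle(dag, (u, v))
        trial = dag.copy()
        trial.add_edge(u, v)
        assert predicted == (not nx.is_directed_acyclic_graph(trial))
        checked += 1
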