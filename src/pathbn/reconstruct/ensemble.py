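"""Hierarchy-voting DAG reconstruction.

Two node rankings (Gaussian skill rating and minimum social agony, see
:mod:`.ranking`) are each combined with three removal heuristics —
forward, backward, greedy — giving six decycling methods.  Each method
marks, per nontrivial SCC, the hierarchy-violating edges it would remove;
an edge's vote score is the number of methods (0-6) that remove it.  The
final DAG is assembled by inserting edges in ascending vote order
(ties broken by stable input order), skipping any insertion that would
close a cycle, so high-vote edges are the ones sacrificed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from ..graph import EdgeRecord, PathwayGraph, nontrivial_sccs, remove_self_loops
from ._result import (
    REASON_SELF_LOOP,
    REASON_VOTE,
    ReconstructionResult,
    RemovedEdge,
    creates_cycle,
)
from .ranking import agony_rank, skill_rank

RANKING_METRICS = ("skill", "agony")
REMOVAL_HEURISTICS = ("forward", "backward", "greedy")


def ensemble_members() -> list[tuple[str, str]]:
    """The (ranking metric, removal heuristic) pairs voted over."""
    return [(m, h) for m in RANKING_METRICS for h in REMOVAL_HEURISTICS]


Key = tuple[str, str]


def _violating(edges: Sequence[EdgeRecord], r: Mapping[str, float]) -> list[tuple[float, int, EdgeRecord]]:
    """(rank gap, input index, edge) for edges going against the hierarchy."""
    return [
        (r[e.source] - r[e.target], i, e)
        for i, e in enumerate(edges)
        if r[e.source] >= r[e.target]
    ]


def _forward(subg: nx.DiGraph, edges: Sequence[EdgeRecord], r: Mapping[str, float]) -> set[Key]:
    """Scan violating edges by descending gap; remove those still on a cycle."""
    work = subg.copy()
    removed: set[Key] = set()
    for gap, i, e in sorted(_violating(edges, r), key=lambda t: (-t[0], t[1])):
        if nx.is_directed_acyclic_graph(work):
            break
        if nx.has_path(work, e.target, e.source):
            work.remove_edge(*e.key)
            removed.add(e.key)
    return removed


def _backward(subg: nx.DiGraph, edges: Sequence[EdgeRecord], r: Mapping[str, float]) -> set[Key]:
    """Remove the minimal largest-gap suffix of the ascending violation list."""
    viol = sorted(_violating(edges, r), key=lambda t: (t[0], t[1]))
    work = subg.copy()
    removed: set[Key] = set()
    while not nx.is_directed_acyclic_graph(work) and viol:
        gap, i, e = viol.pop()
        work.remove_edge(*e.key)
        removed.add(e.key)
    return removed


def _greedy(subg: nx.DiGraph, edges: Sequence[EdgeRecord], r: Mapping[str, float]) -> set[Key]:
    """Repeatedly remove the max-gap violating edge on a cycle, re-checking."""
    work = subg.copy()
    removed: set[Key] = set()
    viol = sorted(_violating(edges, r), key=lambda t: (-t[0], t[1]))
    while not nx.is_directed_acyclic_graph(work):
        for gap, i, e in viol:
            if e.key not in removed and nx.has_path(work, e.target, e.source):
                work.remove_edge(*e.key)
                removed.add(e.key)
                break
        else:  # pragma: no cover - a cycle always contains a violating edge
            raise RuntimeError("no removable violating edge found")
    return removed


_HEURISTICS = {"forward": _forward, "backward": _backward, "greedy": _greedy}


def ensemble_reconstruct(g: PathwayGraph, seed: int) -> ReconstructionResult:
    g2, loops = remove_self_loops(g)
    removed = [RemovedEdge(e, REASON_SELF_LOOP) for e in loops]
    rng = np.random.default_rng(seed)
    votes: dict[Key, int] = {e.key: 0 for e in g2.edges}

    sccs = nontrivial_sccs(g2)
    if sccs:
        edge_keys = [e.key for e in g2.edges]
        rankings = {
            "skill": skill_rank(list(g2.nodes), edge_keys, rng),
            "agony": agony_rank(list(g2.nodes), edge_keys),
        }
        for comp in sccs:
            scc_edges = [e for e in g2.edges if e.source in comp and e.target in comp]
            subg = nx.DiGraph()
            subg.add_nodes_from(comp)
            subg.add_edges_from(e.key for e in scc_edges)
            for metric in RANKING_METRICS:
                for name in REMOVAL_HEURISTICS:
                    for key in _HEURISTICS[name](subg, scc_edges, rankings[metric]):
                        votes[key] += 1

    dag = nx.DiGraph()
    dag.add_nodes_from(g2.nodes)
    kept: set[Key] = set()
    for i in sorted(range(g2.n_edges), key=lambda i: (votes[g2.edges[i].key], i)):
        e = g2.edges[i]
        if creates_cycle(dag, e.source, e.target):
            removed.append(RemovedEdge(e, REASON_VOTE, votes[e.key]))
        else:
            dag.add_edge(*e.key)
            kept.add(e.key)

    result = ReconstructionResult(
        strategy="ensemble",
        dag=g.replace_edges([e for e in g2.edges if e.key in kept]),
        removed=removed,
        seed=seed,
        extras={"votes": votes},
    )
    result.validate(g)
    return result
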