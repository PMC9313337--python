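"""Evidence-ranked DAG reconstruction.

Each edge's strength is the two-sided p-value of the slope in a simple
linear regression of the child gene on the parent gene, fitted on control
(non-tumor) training samples.  Edges are inserted greedily from the most
to the least significant; an edge that would close a cycle is dropped, so
the removed edges are exactly those with the weakest expression support
among their cycles.  Deterministic given the data (p-value ties broken by
stable input edge order).
"""

from __future__ import annotations

import warnings

import networkx as nx
from scipy import stats

from ..expression import ExpressionMatrix
from ..graph import PathwayGraph, remove_self_loops
from ._result import (
    REASON_SELF_LOOP,
    REASON_WEAK_EDGE,
    ConfigurationError,
    ReconstructionResult,
    RemovedEdge,
    creates_cycle,
)


def edge_p_values(
    g: PathwayGraph,
    expr: ExpressionMatrix,
    condition: str = "non_tumor",
    split: str | None = "train",
) -> dict[tuple[str, str], float]:
    """Slope-test p-value for every (parent -> child) edge.

    A zero-variance parent (or child) makes the test undefined; such
    edges get p = 1 with a warning, i.e. the weakest possible evidence.
    """
    data = expr.subset(condition=condition, split=split)
    if len(data) < 3:
        raise ConfigurationError(
            f"need >= 3 {condition} samples for edge regressions, got {len(data)}"
        )
    missing = {n for e in g.edges for n in e.key} - set(data.columns)
    if missing:
        raise ConfigurationError(f"genes missing from expression data: {sorted(missing)}")
    pvals: dict[tuple[str, str], float] = {}
    for e in g.edges:
        if e.source == e.target:
            continue
        x = data[e.source].to_numpy()
        y = data[e.target].to_numpy()
        if x.std() == 0 or y.std() == 0:
            warnings.warn(
                f"zero-variance gene on edge {e.source}->{e.target}; p-value set to 1"
            )
            pvals[e.key] = 1.0
        else:
            pvals[e.key] = float(stats.linregress(x, y).pvalue)
    return pvals


def clipper_reconstruct(
    g: PathwayGraph,
    expr: ExpressionMatrix,
    condition: str = "non_tumor",
    split: str | None = "train",
) -> ReconstructionResult:
    g2, loops = remove_self_loops(g)
    removed = [RemovedEdge(e, REASON_SELF_LOOP) for e in loops]
    pvals = edge_p_values(g2, expr, condition=condition, split=split)

    order = sorted(range(g2.n_edges), key=lambda i: (pvals[g2.edges[i].key], i))
    dag = nx.DiGraph()
    dag.add_nodes_from(g2.nodes)
    kept: set[tuple[str, str]] = set()
    for idx in order:
        e = g2.edges[idx]
        if creates_cycle(dag, e.source, e.target):
            removed.append(RemovedEdge(e, REASON_WEAK_EDGE, pvals[e.key]))
        else:
            dag.add_edge(e.source, e.target)
            kept.add(e.key)

    result = ReconstructionResult(
        strategy="clipper",
        dag=g.replace_edges([e for e in g2.edges if e.key in kept]),
        removed=removed,
        extras={"p_values": pvals},
    )
    result.validate(g)
    return result
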