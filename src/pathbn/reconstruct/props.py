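"""Random-insertion DAG reconstruction.

Starting from an empty graph over the pathway's genes, edges are visited
in a uniformly random (seed-determined) order and each is inserted unless
it would close a directed cycle.  No biological or statistical evidence
is used: every cycle edge is equally likely to be the one dropped.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from ..graph import PathwayGraph, remove_self_loops
from ._result import (
    REASON_RANDOM_CYCLE,
    REASON_SELF_LOOP,
    ReconstructionResult,
    RemovedEdge,
    creates_cycle,
)


def props_reconstruct(g: PathwayGraph, seed: int) -> ReconstructionResult:
    g2, loops = remove_self_loops(g)
    removed = [RemovedEdge(e, REASON_SELF_LOOP) for e in loops]
    rng = np.random.default_rng(seed)
    order = rng.permutation(g2.n_edges)

    dag = nx.DiGraph()
    dag.add_nodes_from(g2.nodes)
    kept: set[tuple[str, str]] = set()
    for idx in order:
        e = g2.edges[int(idx)]
        if creates_cycle(dag, e.source, e.target):
            removed.append(RemovedEdge(e, REASON_RANDOM_CYCLE))
        else:
            dag.add_edge(e.source, e.target)
            kept.add(e.key)

    kept_edges = [e for e in g2.edges if e.key in kept]  # stable input order
    result = ReconstructionResult(
        strategy="props",
        dag=g.replace_edges(kept_edges),
        removed=removed,
        seed=seed,
    )
    result.validate(g)
    return result
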