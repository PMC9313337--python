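"""Cyclegroup rebuild: remove cycle edges wholesale, then compensate.

Cyclegroups (sets of cycles sharing nodes) are realized as nontrivial
SCCs.  For each group, every edge between two members is deleted, the
members are numbered by a seed-determined random permutation, and an
edge i -> j is added for every ordered member pair with number(i) <
number(j) — a complete acyclic tournament that preserves as much of the
broken connectivity as a DAG allows.  Every external parent of any group
member is additionally fanned out to all members that were not already
its children.  The removal set is deterministic; only the orientation of
the tournament depends on the seed.
"""

from __future__ import annotations

import numpy as np

from ..graph import EdgeRecord, PathwayGraph, nontrivial_sccs, remove_self_loops
from ._result import (
    REASON_CYCLEGROUP,
    REASON_SELF_LOOP,
    ReconstructionResult,
    RemovedEdge,
)


def bpa_reconstruct(g: PathwayGraph, seed: int) -> ReconstructionResult:
    g2, loops = remove_self_loops(g)
    removed = [RemovedEdge(e, REASON_SELF_LOOP) for e in loops]
    rng = np.random.default_rng(seed)

    groups = nontrivial_sccs(g2)  # sorted by smallest member: deterministic
    member_of: dict[str, int] = {}
    for gi, comp in enumerate(groups):
        for node in comp:
            member_of[node] = gi

    kept: list[EdgeRecord] = []
    for e in g2.edges:
        gi, gj = member_of.get(e.source), member_of.get(e.target)
        if gi is not None and gi == gj:
            removed.append(RemovedEdge(e, REASON_CYCLEGROUP))
        else:
            kept.append(e)

    existing = {e.key for e in kept}
    added: list[EdgeRecord] = []

    def add(source: str, target: str) -> None:
        if (source, target) not in existing:
            added.append(EdgeRecord(source, target, "unknown", provenance="added"))
            existing.add((source, target))

    for comp in groups:
        members = sorted(comp)
        numbering = {m: int(k) for m, k in zip(members, rng.permutation(len(members)))}
        ordered = sorted(members, key=numbering.get)
        for i, mi in enumerate(ordered):
            for mj in ordered[i + 1 :]:
                add(mi, mj)
        parents = {
            e.source
            for e in g2.edges
            if e.target in comp and e.source not in comp
        }
        for p in sorted(parents):
            for m in members:
                add(p, m)

    result = ReconstructionResult(
        strategy="bpa",
        dag=g.replace_edges(kept + added),
        removed=removed,
        added=added,
        seed=seed,
    )
    result.validate(g)
    return result
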