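"""Edge-removal accounting and cross-strategy overlap reports."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..graph import PathwayGraph
from ._result import REASON_SELF_LOOP, ReconstructionResult


def jaccard(a: set, b: set) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 for two empty sets."""
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


@dataclass
class ReconstructionReport:
    summary: pd.DataFrame          # per-strategy removal/addition accounting
    removed_jaccard: pd.DataFrame  # pairwise Jaccard of cycle-driven removals
    kept_jaccard: pd.DataFrame     # pairwise Jaccard of retained original edges


def reconstruction_report(
    results: list[ReconstructionResult], original: PathwayGraph
) -> ReconstructionReport:
    """Per-strategy accounting and pairwise overlap of removal decisions.

    Percent edge loss counts self-loop and cycle-driven removals together
    over the original edge total.  Overlaps compare cycle-driven removal
    sets (self-loops are removed identically by every strategy) and the
    retained original edges (superimposition of two reconstructions).
    """
    original_keys = {e.key for e in original.edges}
    rows = []
    for res in results:
        accounted = res.kept_keys() | res.removed_keys(include_self_loops=True)
        if accounted != original_keys:
            raise ValueError(
                f"result for {res.strategy!r} does not derive from the given original"
            )
        n_self = sum(1 for r in res.removed if r.reason == REASON_SELF_LOOP)
        n_cycle = len(res.removed) - n_self
        rows.append(
            {
                "strategy": res.strategy,
                "n_original_edges": original.n_edges,
                "n_self_loop_removed": n_self,
                "n_cycle_removed": n_cycle,
                "n_added": len(res.added),
                "pct_edge_loss": 100.0 * (n_self + n_cycle) / max(original.n_edges, 1),
            }
        )
    summary = pd.DataFrame(rows)

    names = [r.strategy for r in results]
    removed_sets = {r.strategy: r.removed_keys() for r in results}
    kept_sets = {r.strategy: r.kept_keys() for r in results}
    removed_j = pd.DataFrame(
        [[jaccard(removed_sets[a], removed_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    kept_j = pd.DataFrame(
        [[jaccard(kept_sets[a], kept_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return ReconstructionReport(summary, removed_j, kept_j)


def edge_overlap(a: ReconstructionResult, b: ReconstructionResult) -> dict[str, float]:
    """Superimposition statistics for two reconstructions of one pathway.

    ``dag_jaccard`` compares the full output DAGs (added edges included)
    — the coincidence measure for superimposing two random
    reconstructions; ``kept_jaccard`` restricts to retained original
    edges.
    """
    return {
        "kept_jaccard": jaccard(a.kept_keys(), b.kept_keys()),
        "dag_jaccard": jaccard({e.key for e in a.dag.edges}, {e.key for e in b.dag.edges}),
        "removed_jaccard": jaccard(a.removed_keys(), b.removed_keys()),
    }
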