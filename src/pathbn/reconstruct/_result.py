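"""Shared result type and bookkeeping for the five reconstruction strategies."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx

from ..graph import EdgeRecord, PathwayGraph

STRATEGIES = ("props", "clipper", "bnrich", "bpa", "ensemble")

#: reason codes used in removal ledgers
REASON_SELF_LOOP = "self_loop"
REASON_RANDOM_CYCLE = "random_cycle"
REASON_WEAK_EDGE = "weak_edge"
REASON_RULE = "rule"
REASON_LASSO = "lasso_zero"
REASON_CYCLEGROUP = "cyclegroup"
REASON_VOTE = "vote"


class ReconstructionError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RemovedEdge:
    """One removed edge with the reason code and supporting evidence.

    Evidence is reason-specific: a p-value for ``weak_edge``, a rule id
    for ``rule``, the pair of per-condition LASSO coefficients for
    ``lasso_zero``, the 0-6 vote score for ``vote``, None for random
    removals.
    """

    edge: EdgeRecord
    reason: str
    evidence: Any = None


@dataclass
class ReconstructionResult:
    strategy: str
    dag: PathwayGraph
    removed: list[RemovedEdge]
    added: list[EdgeRecord] = field(default_factory=list)
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def removed_keys(self, include_self_loops: bool = False) -> set[tuple[str, str]]:
        return {
            r.edge.key
            for r in self.removed
            if include_self_loops or r.reason != REASON_SELF_LOOP
        }

    def kept_keys(self) -> set[tuple[str, str]]:
        """Original edges retained in the DAG (added edges excluded)."""
        added = {e.key for e in self.added}
        return {e.key for e in self.dag.edges if e.key not in added}

    def validate(self, original: PathwayGraph) -> None:
        """Check the accounting invariants against the input graph."""
        if self.strategy not in STRATEGIES:
            raise ReconstructionError(f"unknown strategy {self.strategy!r}")
        if not nx.is_directed_acyclic_graph(self.dag.to_networkx()):
            raise ReconstructionError(f"{self.strategy}: result is not acyclic")
        if self.added and self.strategy != "bpa":
            raise ReconstructionError(f"{self.strategy}: only bpa may add edges")
        original_no_loops = {e.key for e in original.edges if e.source != e.target}
        accounted = self.kept_keys() | self.removed_keys()
        if accounted != original_no_loops:
            raise ReconstructionError(
                f"{self.strategy}: removed+kept does not partition the input edges "
                f"(missing {original_no_loops - accounted}, "
                f"extra {accounted - original_no_loops})"
            )
        loops = {e.key for e in original.edges if e.source == e.target}
        logged = {r.edge.key for r in self.removed if r.reason == REASON_SELF_LOOP}
        if logged != loops:
            raise ReconstructionError(f"{self.strategy}: self-loop ledger mismatch")


def creates_cycle(dag: nx.DiGraph, source: str, target: str) -> bool:
    """Unchecked hot-path variant of graph.would_create_cycle."""
    if source == target:
        return True
    return nx.has_path(dag, target, source)
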