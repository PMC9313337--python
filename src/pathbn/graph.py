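"""Pathway graph data model, TSV/GraphML I/O, and cycle/SCC machinery.

A pathway is a directed, possibly cyclic graph whose nodes are genes
(annotated with a cellular compartment) and whose edges are regulatory
interactions (activation, inhibition, ...).  Every downstream
reconstruction strategy consumes this model and produces a DAG from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

COMPARTMENTS = ("extracellular", "membrane", "cytoplasm", "nucleus", "unknown")
#: depth of each compartment along the signalling axis; ``unknown`` has no depth
COMPARTMENT_RANK = {"extracellular": 0, "membrane": 1, "cytoplasm": 2, "nucleus": 3}

INTERACTIONS = (
    "activation",
    "inhibition",
    "binding",
    "expression",
    "state_transition",
    "unknown",
)


class GraphFormatError(ValueError):
    """Raised when an edge-list or node-table file violates the format."""


@dataclass(frozen=True)
class NodeRecord:
    """A gene node with its cellular compartment annotation."""

    id: str
    compartment: str = "unknown"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise GraphFormatError(
                f"unknown compartment {self.compartment!r} for node {self.id!r}"
            )


@dataclass(frozen=True)
class EdgeRecord:
    """A directed regulatory edge.

    ``provenance`` is ``original`` for parsed edges; only the BPA
    strategy emits ``added`` edges.
    """

    source: str
    target: str
    interaction: str = "unknown"
    provenance: str = "original"

    def __post_init__(self) -> None:
        if self.interaction not in INTERACTIONS:
            raise GraphFormatError(
                f"unknown interaction {self.interaction!r} on edge "
                f"{self.source}->{self.target}"
            )
        if self.provenance not in ("original", "added"):
            raise GraphFormatError(f"bad provenance {self.provenance!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass
class PathwayGraph:
    """An annotated directed graph with stable, duplicate-free edge order."""

    name: str
    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    edges: list[EdgeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.key in seen:
                raise GraphFormatError(f"duplicate edge {e.source}->{e.target}")
            seen.add(e.key)
            for endpoint in e.key:
                if endpoint not in self.nodes:
                    raise GraphFormatError(f"edge endpoint {endpoint!r} not a node")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[EdgeRecord],
        nodes: Iterable[NodeRecord] = (),
    ) -> "PathwayGraph":
        """Build a graph, inducing unannotated nodes from edge endpoints."""
        node_map = {n.id: n for n in nodes}
        edge_list = list(edges)
        for e in edge_list:
            for endpoint in e.key:
                node_map.setdefault(endpoint, NodeRecord(endpoint))
        return cls(name=name, nodes=node_map, edges=edge_list)

    # -- basic accessors ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_keys(self) -> list[tuple[str, str]]:
        return [e.key for e in self.edges]

    def get_edge(self, source: str, target: str) -> EdgeRecord:
        for e in self.edges:
            if e.key == (source, target):
                return e
        raise KeyError((source, target))

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in {e.key for e in self.edges}

    def parents(self, node: str) -> list[str]:
        return [e.source for e in self.edges if e.target == node]

    def replace_edges(self, edges: Sequence[EdgeRecord], name: str | None = None) -> "PathwayGraph":
        """New graph with the same node table but a different edge list."""
        return PathwayGraph(
            name=self.name if name is None else name,
            nodes=dict(self.nodes),
            edges=list(edges),
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        for n in self.nodes.values():
            g.add_node(n.id, compartment=n.compartment)
        for e in self.edges:
            g.add_edge(e.source, e.target, interaction=e.interaction, provenance=e.provenance)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return (
            self.name == other.name
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


@dataclass
class CycleReport:
    """Nontrivial SCCs, canonical simple cycles, and self-loop edges."""

    scc_list: list[frozenset[str]]
    simple_cycles: list[tuple[str, ...]]
    self_loops: list[EdgeRecord]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_EDGE_COLS = ["source", "target", "interaction", "source_compartment", "target_compartment"]


def read_edgelist(path: str | Path, node_table: str | Path | None = None, name: str | None = None) -> PathwayGraph:
    """Read a pathway from an edge-list TSV.

    Required columns: ``source``, ``target``.  Optional: ``interaction``,
    ``source_compartment``, ``target_compartment`` (default ``unknown``).
    Duplicate (source, target) rows collapse to the first occurrence with
    a warning.  An optional node table TSV (columns ``id``,
    ``compartment``) overrides/extends compartment annotations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source", "target"):
        if col not in df.columns:
            raise GraphFormatError(f"{path}: missing required column {col!r}")
    compartment: dict[str, str] = {}
    edges: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        d = row._asdict()
        key = (d["source"], d["target"])
        if key in seen:
            warnings.warn(f"{path}: duplicate edge {key[0]}->{key[1]} ignored")
            continue
        seen.add(key)
        edges.append(
            EdgeRecord(
                source=d["source"],
                target=d["target"],
                interaction=d.get("interaction") or "unknown",
            )
        )
        for node_col, comp_col in (("source", "source_compartment"), ("target", "target_compartment")):
            comp = d.get(comp_col) or ""
            if comp:
                compartment[d[node_col]] = comp
    if node_table is not None:
        ndf = pd.read_csv(node_table, sep="\t", dtype=str, keep_default_na=False)
        if "id" not in ndf.columns:
            raise GraphFormatError(f"{node_table}: missing required column 'id'")
        for row in ndf.itertuples(index=False):
            d = row._asdict()
            compartment[d["id"]] = d.get("compartment") or "unknown"
    nodes = [NodeRecord(i, c) for i, c in compartment.items()]
    return PathwayGraph.from_edges(name or path.stem, edges, nodes)


def write_edgelist(g: PathwayGraph, path: str | Path) -> None:
    """Write the graph as TSV; round-trips through :func:`read_edgelist`."""
    rows = [
        {
            "source": e.source,
            "target": e.target,
            "interaction": e.interaction,
            "source_compartment": g.nodes[e.source].compartment,
            "target_compartment": g.nodes[e.target].compartment,
            "provenance": e.provenance,
        }
        for e in g.edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLS + ["provenance"]).to_csv(path, sep="\t", index=False)


def read_edgelist_full(path: str | Path, name: str | None = None) -> PathwayGraph:
    """Like :func:`read_edgelist` but honours a ``provenance`` column."""
    g = read_edgelist(path, name=name)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "provenance" in df.columns:
        prov = {
            (d["source"], d["target"]): d["provenance"] or "original"
            for d in (r._asdict() for r in df.itertuples(index=False))
        }
        edges = [replace(e, provenance=prov.get(e.key, "original")) for e in g.edges]
        g = g.replace_edges(edges)
    return g


def write_graphml(g: PathwayGraph, path: str | Path) -> None:
    nx.write_graphml(g.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# Worked example
# ---------------------------------------------------------------------------


def example_pathway_path() -> Path:
    """Path of the packaged edge-list TSV of the worked-example network."""
    return Path(__file__).parent / "data" / "example_pathway.tsv"


def example_pathway() -> PathwayGraph:
    """A small hypothetical gene network: 7 nodes, 9 edges, 3 cycles.

    Cycles: {A->B->D->A}, {A->C->D->A} and {D->E->D}.  D and E sit in the
    nucleus, their upstream regulators in the cytoplasm, so the two
    feedback edges (D->A, an inhibition against the signalling axis, and
    E->D, a nucleus-sourced expression edge inside a cycle) are the ones a
    biology-rules strategy removes.  E->G is a deliberately "weak" acyclic
    edge for LASSO-pruning demonstrations.
    """
    c, n = "cytoplasm", "nucleus"
    nodes = [
        NodeRecord("A", c), NodeRecord("B", c), NodeRecord("C", c),
        NodeRecord("D", n), NodeRecord("E", n), NodeRecord("F", c), NodeRecord("G", c),
    ]
    edges = [
        EdgeRecord("A", "C", "activation"),        # 1
        EdgeRecord("A", "B", "activation"),        # 2
        EdgeRecord("D", "A", "inhibition"),        # 3
        EdgeRecord("B", "D", "activation"),        # 4
        EdgeRecord("C", "D", "activation"),        # 5
        EdgeRecord("E", "D", "expression"),        # 6
        EdgeRecord("D", "E", "activation"),        # 7
        EdgeRecord("E", "F", "activation"),        # 8
        EdgeRecord("E", "G", "activation"),        # 9
    ]
    return PathwayGraph.from_edges("example", edges, nodes)


# ---------------------------------------------------------------------------
# Cycle / SCC machinery
# ---------------------------------------------------------------------------


def remove_self_loops(g: PathwayGraph) -> tuple[PathwayGraph, list[EdgeRecord]]:
    """Drop every edge whose source equals its target."""
    removed = [e for e in g.edges if e.source == e.target]
    kept = [e for e in g.edges if e.source != e.target]
    return g.replace_edges(kept), removed


def canonical_cycle(cycle: Sequence[str]) -> tuple[str, ...]:
    """Rotate a simple cycle to start at its lexicographically smallest node."""
    i = min(range(len(cycle)), key=lambda k: cycle[k])
    return tuple(cycle[i:]) + tuple(cycle[:i])


def find_sccs(g: PathwayGraph) -> CycleReport:
    """Nontrivial SCCs (Tarjan) plus canonical simple cycles (Johnson).

    An SCC is reported when it has >= 2 nodes or consists of a node with a
    self-loop.  Self-loops are length-1 cycles and listed separately, not
    among ``simple_cycles``.
    """
    nxg = g.to_networkx()
    self_loops = [e for e in g.edges if e.source == e.target]
    loop_nodes = {e.source for e in self_loops}
    sccs = [
        frozenset(c)
        for c in nx.strongly_connected_components(nxg)
        if len(c) >= 2 or next(iter(c)) in loop_nodes
    ]
    sccs.sort(key=lambda s: min(s))
    nxg.remove_edges_from([(e.source, e.target) for e in self_loops])
    cycles = sorted(
        (canonical_cycle(c) for c in nx.simple_cycles(nxg)),
        key=lambda c: (len(c), c),
    )
    return CycleReport(scc_list=sccs, simple_cycles=cycles, self_loops=self_loops)


def nontrivial_sccs(g: PathwayGraph) -> list[frozenset[str]]:
    """Multi-node SCCs only (self-loop singletons excluded)."""
    nxg = g.to_networkx()
    sccs = [frozenset(c) for c in nx.strongly_connected_components(nxg) if len(c) >= 2]
    sccs.sort(key=lambda s: min(s))
    return sccs


def is_acyclic(g: PathwayGraph) -> bool:
    return nx.is_directed_acyclic_graph(g.to_networkx())


def would_create_cycle(dag: nx.DiGraph, edge: tuple[str, str]) -> bool:
    """True iff adding ``edge`` to the acyclic ``dag`` creates a cycle.

    Equivalent to: a path target -> source already exists.  ``dag`` must be
    acyclic (contract violation otherwise).
    """
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("would_create_cycle requires an acyclic graph")
    source, target = edge
    if source == target:
        return True
    if source not in dag or target not in dag:
        return False
    return nx.has_path(dag, target, source)
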