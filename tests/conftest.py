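"""Shared fixtures: small graphs, random-graph factories, synthetic expression."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathbn.expression import ExpressionMatrix
from pathbn.graph import EdgeRecord, NodeRecord, PathwayGraph, example_pathway


@pytest.fixture
def fig_graph() -> PathwayGraph:
    return example_pathway()


def make_graph(edge_keys, name="g", compartments=None, interactions=None) -> PathwayGraph:
    """Terse graph builder: make_graph([("A","B"), ...])."""
    compartments = compartments or {}
    interactions = interactions or {}
    edges = [
        EdgeRecord(s, t, interactions.get((s, t), "unknown")) for s, t in edge_keys
    ]
    nodes = {n for k in edge_keys for n in k}
    return PathwayGraph.from_edges(
        name, edges, [NodeRecord(n, compartments.get(n, "unknown")) for n in sorted(nodes)]
    )


def random_digraph(n: int, p: float, rng: np.random.Generator, self_loop_prob=0.0) -> PathwayGraph:
    """Erdos-Renyi style directed graph, optional self-loop."""
    edges = [
        (f"n{i:02d}", f"n{j:02d}")
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    if rng.random() < self_loop_prob:
        k = f"n{int(rng.integers(n)):02d}"
        if (k, k) not in edges:
            edges.append((k, k))
    g = make_graph(edges) if edges else PathwayGraph.from_edges(
        "g", [], [NodeRecord(f"n{i:02d}") for i in range(n)]
    )
    for i in range(n):  # keep isolated nodes
        g.nodes.setdefault(f"n{i:02d}", NodeRecord(f"n{i:02d}"))
    return g


def expr_from_values(values: pd.DataFrame, conditions=None) -> ExpressionMatrix:
    """Wrap a plain values frame as paired tumor/non-tumor training samples.

    Rows are interpreted as pairs: row i becomes samples S{i}_T and S{i}_N
    holding the same values unless ``conditions`` maps two frames.
    """
    if conditions is None:
        conditions = {"tumor": values, "non_tumor": values}
    n = len(values)
    pairs = [f"S{i:03d}" for i in range(n)]
    index = [f"{p}_T" for p in pairs] + [f"{p}_N" for p in pairs]
    samples = pd.DataFrame(
        {
            "pair": pairs * 2,
            "condition": ["tumor"] * n + ["non_tumor"] * n,
            "split": "train",
        },
        index=pd.Index(index, name="sample"),
    )
    vals = pd.concat(
        [
            conditions["tumor"].set_index(pd.Index(index[:n])),
            conditions["non_tumor"].set_index(pd.Index(index[n:])),
        ]
    )
    return ExpressionMatrix(samples, vals)


def random_bn(n_nodes: int, rng: np.random.Generator, edge_p: float = 0.4):
    """Random DAG with random linear-Gaussian parameters."""
    from pathbn.bn import GaussianBN, NodeParams

    nodes = [f"g{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_p
    ]
    dag = (
        make_graph(edges)
        if edges
        else PathwayGraph.from_edges("g", [], [NodeRecord(n) for n in nodes])
    )
    for n in nodes:
        dag.nodes.setdefault(n, NodeRecord(n))
    params = {
        n: NodeParams(
            intercept=float(rng.normal(0, 2)),
            coefficients={p: float(rng.normal(0, 1)) for p in dag.parents(n)},
            variance=float(rng.uniform(0.3, 2.0)),
        )
        for n in nodes
    }
    return GaussianBN(dag=dag, node_params=params, n_train=0)


def mvn_moments(bn) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Joint-normal moments of a linear-Gaussian system by matrix algebra:
    mu = (I-B)^-1 b and Sigma = (I-B)^-1 D (I-B)^-T — the independent
    oracle for the factorized log-likelihood."""
    genes = list(bn.dag.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    B, b, D = np.zeros((n, n)), np.zeros(n), np.zeros((n, n))
    for node, p in bn.node_params.items():
        b[idx[node]] = p.intercept
        D[idx[node], idx[node]] = p.variance
        for parent, beta in p.coefficients.items():
            B[idx[node], idx[parent]] = beta
    inv = np.linalg.inv(np.eye(n) - B)
    return genes, inv @ b, inv @ D @ inv.T


def random_expr(genes, n_pairs: int, rng: np.random.Generator) -> ExpressionMatrix:
    """Unstructured (iid normal) expression for the given genes."""
    frame = lambda: pd.DataFrame(  # noqa: E731
        rng.normal(6.0, 1.0, (n_pairs, len(genes))), columns=list(genes)
    )
    return expr_from_values(frame(), {"tumor": frame(), "non_tumor": frame()})
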