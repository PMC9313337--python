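"""Linear-Gaussian Bayesian networks over pathway DAGs.

Each node Y with parents X_1..X_k follows Y = b0 + sum_i b_i X_i + eps,
eps ~ N(0, sigma^2).  Parameters are fitted by maximum likelihood on
control (non-tumor) training samples: per-node ordinary least squares
with the MLE residual variance (sum of squared residuals divided by n,
floored at 1e-8 so degenerate fits keep finite densities).  The joint
log-likelihood of a sample factorizes over nodes as the sum of the
conditional Gaussian log-densities (natural log), and equals the
log-density of the multivariate normal the system induces.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .graph import PathwayGraph

VARIANCE_FLOOR = 1e-8


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class NodeParams:
    """Conditional Gaussian of one node given its parents."""

    intercept: float
    coefficients: dict[str, float]  # parent -> slope
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("residual variance must be positive")


@dataclass
class GaussianBN:
    dag: PathwayGraph
    node_params: dict[str, NodeParams]
    n_train: int

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            params = self.node_params.get(node)
            if params is None:
                raise ValueError(f"missing parameters for node {node!r}")
            if set(params.coefficients) != set(self.dag.parents(node)):
                raise ValueError(f"coefficient keys of {node!r} do not match its parents")

    @property
    def n_parameters(self) -> int:
        """Free parameters: per node, |parents| coefficients + intercept + variance."""
        return sum(len(p.coefficients) + 2 for p in self.node_params.values())

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_train": self.n_train,
            "nodes": {
                node: {
                    "intercept": p.intercept,
                    "coefficients": p.coefficients,
                    "variance": p.variance,
                }
                for node, p in self.node_params.items()
            },
            "edges": [[e.source, e.target] for e in self.dag.edges],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, payload: dict, dag: PathwayGraph | None = None) -> "GaussianBN":
        if dag is None:
            from .graph import EdgeRecord, NodeRecord

            dag = PathwayGraph.from_edges(
                "bn",
                [EdgeRecord(s, t) for s, t in payload["edges"]],
                [NodeRecord(n) for n in payload["nodes"]],
            )
        params = {
            node: NodeParams(d["intercept"], dict(d["coefficients"]), d["variance"])
            for node, d in payload["nodes"].items()
        }
        return cls(dag=dag, node_params=params, n_train=payload["n_train"])

    @classmethod
    def from_json(cls, path: str | Path, dag: PathwayGraph | None = None) -> "GaussianBN":
        return cls.from_dict(json.loads(Path(path).read_text()), dag)


def fit_gaussian_bn(
    dag: PathwayGraph,
    expr: ExpressionMatrix,
    condition: str = "non_tumor",
    split: str | None = "train",
) -> GaussianBN:
    """Per-node OLS of each gene on its parents (intercept-only for roots)."""
    if not nx.is_directed_acyclic_graph(dag.to_networkx()):
        raise FitError("parameter learning requires an acyclic graph")
    data = expr.subset(condition=condition, split=split)
    max_in = max((len(dag.parents(n)) for n in dag.nodes), default=0)
    if len(data) < max_in + 2:
        raise FitError(
            f"need >= {max_in + 2} samples (max in-degree {max_in} + 2), got {len(data)}"
        )
    missing = set(dag.nodes) - set(data.columns)
    if missing:
        raise FitError(f"genes missing from expression data: {sorted(missing)}")

    n = len(data)
    params: dict[str, NodeParams] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        y = data[node].to_numpy()
        X = np.column_stack([np.ones(n)] + [data[p].to_numpy() for p in parents])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"rank-deficient parent matrix for {node!r}; using pseudo-inverse"
            )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = max(float(resid @ resid) / n, VARIANCE_FLOOR)
        params[node] = NodeParams(
            intercept=float(beta[0]),
            coefficients={p: float(b) for p, b in zip(parents, beta[1:])},
            variance=sigma2,
        )
    return GaussianBN(dag=dag, node_params=params, n_train=n)


def loglik(bn: GaussianBN, sample: Mapping[str, float] | pd.Series) -> float:
    """Joint log-density of one sample under the factorized Gaussian model."""
    total = 0.0
    for node, p in bn.node_params.items():
        try:
            x = float(sample[node])
            mean = p.intercept + sum(b * float(sample[parent]) for parent, b in p.coefficients.items())
        except KeyError as exc:
            raise KeyError(f"sample is missing gene {exc.args[0]!r}") from None
        total += -0.5 * (math.log(2 * math.pi * p.variance) + (x - mean) ** 2 / p.variance)
    return total


def loglik_matrix(bn: GaussianBN, values: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`loglik` for every row of a samples x genes frame."""
    missing = set(bn.node_params) - set(values.columns)
    if missing:
        raise KeyError(f"samples are missing genes {sorted(missing)}")
    total = np.zeros(len(values))
    for node, p in bn.node_params.items():
        mean = np.full(len(values), p.intercept, dtype=float)
        for parent, b in p.coefficients.items():
            mean += b * values[parent].to_numpy()
        resid = values[node].to_numpy() - mean
        total += -0.5 * (np.log(2 * np.pi * p.variance) + resid**2 / p.variance)
    return pd.Series(total, index=values.index, name="loglik")


def bic(
    bn: GaussianBN,
    expr: ExpressionMatrix,
    condition: str = "non_tumor",
    split: str | None = "train",
) -> float:
    """k*ln(n) - 2*sum(loglik); lower means better penalized fit."""
    data = expr.subset(condition=condition, split=split)
    if len(data) == 0:
        raise FitError("BIC requires a non-empty sample set")
    ll = float(loglik_matrix(bn, data).sum())
    return bn.n_parameters * math.log(len(data)) - 2.0 * ll


def average_bic_ranks(bic_table: pd.DataFrame) -> pd.Series:
    """Average per-pathway rank of each strategy's BIC (1 = best = lowest).

    ``bic_table``: rows = pathways, columns = strategies, values = BIC.
    """
    ranks = bic_table.rank(axis=1, method="average", ascending=True)
    return ranks.mean(axis=0).rename("mean_bic_rank")
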