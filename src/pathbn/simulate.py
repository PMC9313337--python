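"""Synthetic pathways and paired two-condition expression with known truth.

The generator emulates the study design the pipeline expects: a cyclic
annotated pathway graph (an acyclic "truth" plus feedback back-edges),
linear-Gaussian expression sampled ancestrally from the truth for paired
tumor / non-tumor samples on a log2(n+1)-like scale, a parameter
perturbation defining the tumor condition, and a paired 75/25
train/test split.

Construction guarantees used by tests:

* back-edges run from a strictly deeper compartment to a shallower one
  (when annotated), so the biology-rules strategy removes exactly the
  back-edges and recovers the truth DAG;
* every back-edge targets an ancestor of its source, so each one closes
  at least one directed cycle;
* node means are all ~6 (log2-FPKM-like) regardless of topology, with
  unit residual noise and coefficients drawn from +/-[0.5, 2.0] —
  effects detectable at tens of sample pairs without being degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bn import NodeParams
from .expression import ExpressionMatrix, paired_split, shuffle_expression  # noqa: F401
from .graph import COMPARTMENT_RANK, EdgeRecord, NodeRecord, PathwayGraph
from .utils import derive_seed

BASELINE_MEAN = 6.0
NOISE_SD = 1.0
COEF_RANGE = (0.5, 2.0)


@dataclass
class SyntheticScenario:
    """One pathway's ground truth: topology, parameters, perturbation."""

    name: str
    truth: PathwayGraph
    observed: PathwayGraph
    params: dict[str, NodeParams]
    perturbed_edges: list[tuple[str, str]] = field(default_factory=list)
    delta: float = 0.0
    n_pairs: int = 60
    seed: int = 0

    def condition_params(self, condition: str) -> dict[str, NodeParams]:
        """Control parameters, or the perturbed tumor variant."""
        if condition == "non_tumor" or not self.perturbed_edges:
            return self.params
        perturbed = set(self.perturbed_edges)
        out = {}
        for node, p in self.params.items():
            coeffs = {
                parent: b + (self.delta if (parent, node) in perturbed else 0.0)
                for parent, b in p.coefficients.items()
            }
            out[node] = NodeParams(p.intercept, coeffs, p.variance)
        return out


def gen_pathway(
    n_nodes: int,
    n_extra_cycle_edges: int,
    seed: int,
    annotate: bool = True,
    name: str = "synthetic",
    gene_prefix: str = "",
    mean_parents: float = 1.8,
) -> tuple[PathwayGraph, PathwayGraph]:
    """Random annotated cyclic pathway; returns (observed, acyclic truth)."""
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    ids = [f"{gene_prefix}G{i:02d}" for i in range(n_nodes)]

    def compartment(i: int) -> str:
        if not annotate:
            return "unknown"
        f = i / max(n_nodes - 1, 1)
        return "membrane" if f < 1 / 3 else ("cytoplasm" if f < 2 / 3 else "nucleus")

    nodes = [NodeRecord(ids[i], compartment(i)) for i in range(n_nodes)]
    edges: list[EdgeRecord] = []
    for j in range(1, n_nodes):
        k = min(j, 1 + rng.poisson(max(mean_parents - 1.0, 0.0)))
        for i in sorted(rng.choice(j, size=k, replace=False)):
            interaction = "activation" if rng.random() < 0.8 else "binding"
            edges.append(EdgeRecord(ids[int(i)], ids[j], interaction))
    truth = PathwayGraph.from_edges(name, edges, nodes)

    nxt = truth.to_networkx()
    existing = {e.key for e in edges}
    candidates = []
    for u in range(n_nodes):
        for v in nx.ancestors(nxt, ids[u]):
            vi = ids.index(v)
            deeper = COMPARTMENT_RANK.get(compartment(u), -1) > COMPARTMENT_RANK.get(
                compartment(vi), -1
            )
            if (ids[u], v) not in existing and (not annotate or deeper):
                candidates.append((ids[u], v))
    candidates.sort()
    if len(candidates) < n_extra_cycle_edges:
        raise ValueError(
            f"cannot place {n_extra_cycle_edges} cycle edges; only "
            f"{len(candidates)} feasible back-edges"
        )
    back: list[EdgeRecord] = []
    if n_extra_cycle_edges:
        chosen = rng.choice(len(candidates), size=n_extra_cycle_edges, replace=False)
        for idx in sorted(chosen):
            u, v = candidates[int(idx)]
            interaction = "inhibition" if rng.random() < 0.5 else "expression"
            back.append(EdgeRecord(u, v, interaction))
    observed = PathwayGraph.from_edges(name, edges + back, nodes)
    return observed, truth


def gen_scenario(
    n_nodes: int = 25,
    n_extra_cycle_edges: int = 4,
    n_pairs: int = 60,
    seed: int = 0,
    n_perturb_edges: int = 0,
    delta: float = 0.0,
    annotate: bool = True,
    name: str = "P00",
    gene_prefix: str = "",
) -> SyntheticScenario:
    """Draw topology and linear-Gaussian parameters for one pathway."""
    observed, truth = gen_pathway(
        n_nodes,
        n_extra_cycle_edges,
        derive_seed(seed, "graph", name),
        annotate=annotate,
        name=name,
        gene_prefix=gene_prefix,
    )
    rng = np.random.default_rng(derive_seed(seed, "params", name))
    params: dict[str, NodeParams] = {}
    for node in truth.nodes:
        parents = truth.parents(node)
        coeffs = {
            p: float(rng.choice([-1.0, 1.0]) * rng.uniform(*COEF_RANGE)) for p in parents
        }
        # intercept keeps every node mean at the baseline
        intercept = BASELINE_MEAN * (1.0 - sum(coeffs.values()))
        params[node] = NodeParams(intercept, coeffs, NOISE_SD**2)
    perturbed: list[tuple[str, str]] = []
    if n_perturb_edges:
        keys = [e.key for e in truth.edges]
        if n_perturb_edges > len(keys):
            raise ValueError("more perturbed edges requested than truth edges")
        chosen = rng.choice(len(keys), size=n_perturb_edges, replace=False)
        perturbed = [keys[int(i)] for i in sorted(chosen)]
    return SyntheticScenario(
        name=name,
        truth=truth,
        observed=observed,
        params=params,
        perturbed_edges=perturbed,
        delta=delta,
        n_pairs=n_pairs,
        seed=seed,
    )


def _sample_condition(
    scenario: SyntheticScenario, condition: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    params = scenario.condition_params(condition)
    order = list(nx.topological_sort(scenario.truth.to_networkx()))
    data = pd.DataFrame(index=range(n), columns=order, dtype=float)
    for node in order:
        p = params[node]
        mean = np.full(n, p.intercept)
        for parent, b in p.coefficients.items():
            mean += b * data[parent].to_numpy()
        data[node] = mean + rng.normal(0.0, np.sqrt(p.variance), size=n)
    return data[[n_.id for n_ in scenario.truth.nodes.values()]]


def gen_expression(
    scenario: SyntheticScenario, split_seed: int | None = None
) -> ExpressionMatrix:
    """Ancestral samples for n_pairs paired tumor / non-tumor samples."""
    rng = np.random.default_rng(derive_seed(scenario.seed, "expr", scenario.name))
    n = scenario.n_pairs
    tumor = _sample_condition(scenario, "tumor", n, rng)
    control = _sample_condition(scenario, "non_tumor", n, rng)
    return _assemble(tumor, control, scenario.seed if split_seed is None else split_seed)


def _assemble(tumor: pd.DataFrame, control: pd.DataFrame, split_seed: int) -> ExpressionMatrix:
    n = len(tumor)
    pairs = [f"S{i:03d}" for i in range(n)]
    index = [f"{p}_T" for p in pairs] + [f"{p}_N" for p in pairs]
    samples = pd.DataFrame(
        {
            "pair": pairs + pairs,
            "condition": ["tumor"] * n + ["non_tumor"] * n,
            "split": "train",
        },
        index=pd.Index(index, name="sample"),
    )
    values = pd.concat(
        [tumor.set_index(pd.Index(index[:n])), control.set_index(pd.Index(index[n:]))]
    )
    split = paired_split(
        samples["pair"], 0.75, np.random.default_rng(derive_seed(split_seed, "split", 0))
    )
    samples["split"] = split
    return ExpressionMatrix(samples, values)


def gen_study(
    n_pathways: int = 12,
    n_nodes: int = 25,
    n_extra_cycle_edges: int = 4,
    n_pairs: int = 60,
    seed: int = 0,
    perturb_pathway: int | None = 0,
    n_perturb_edges: int = 3,
    delta: float = 1.5,
    annotate: bool = True,
) -> tuple[dict[str, SyntheticScenario], ExpressionMatrix]:
    """A multi-pathway study sharing one set of paired samples.

    Pathways have disjoint gene namespaces (``P03_G07``); at most one
    pathway (``perturb_pathway``, None = none) carries the tumor
    perturbation — the ground truth for enrichment ranking.
    """
    scenarios: dict[str, SyntheticScenario] = {}
    tumor_blocks, control_blocks = [], []
    for i in range(n_pathways):
        name = f"P{i:02d}"
        perturb = n_perturb_edges if i == perturb_pathway else 0
        sc = gen_scenario(
            n_nodes=n_nodes,
            n_extra_cycle_edges=n_extra_cycle_edges,
            n_pairs=n_pairs,
            seed=seed,
            n_perturb_edges=perturb,
            delta=delta if perturb else 0.0,
            annotate=annotate,
            name=name,
            gene_prefix=f"{name}_",
        )
        scenarios[name] = sc
        rng = np.random.default_rng(derive_seed(seed, "expr", name))
        tumor_blocks.append(_sample_condition(sc, "tumor", n_pairs, rng))
        control_blocks.append(_sample_condition(sc, "non_tumor", n_pairs, rng))
    expr = _assemble(
        pd.concat(tumor_blocks, axis=1), pd.concat(control_blocks, axis=1), seed
    )
    return scenarios, expr


def truth_covariance(scenario: SyntheticScenario, condition: str = "non_tumor") -> pd.DataFrame:
    """Closed-form covariance (I-B)^-1 D (I-B)^-T of the linear system."""
    genes = list(scenario.truth.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    B = np.zeros((n, n))
    D = np.zeros((n, n))
    for node, p in scenario.condition_params(condition).items():
        for parent, b in p.coefficients.items():
            B[idx[node], idx[parent]] = b
        D[idx[node], idx[node]] = p.variance
    inv = np.linalg.inv(np.eye(n) - B)
    return pd.DataFrame(inv @ D @ inv.T, index=genes, columns=genes)
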