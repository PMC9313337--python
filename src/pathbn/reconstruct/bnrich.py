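"""Biology-rules DAG reconstruction plus LASSO network simplification.

Stage 1 removes cycle edges by ordered biological rules based on the main
direction of signalling flux (extracellular -> membrane -> cytoplasm ->
nucleus) and the feedback character of nucleus-sourced regulation:

R1  anti-flux edges: source compartment strictly deeper than target
    (e.g. nucleus -> cytoplasm feedback);
R2  expression / state-transition edges sourced at a nucleus node that
    sit inside a cycle (transcriptional feedback loops);
R3  inhibition edges that still close a cycle after R1-R2 (negative
    feedback, e.g. SOCS-style inhibition of upstream kinases).

Rules touch only edges participating in a nontrivial SCC.  If cycles
survive all three rules the behaviour follows ``fallback``: raise
(default) or delegate the residual graph to the evidence-ranked
(clipper) strategy.

Stage 2 (:func:`bnrich_lasso_simplify`) prunes edges of an acyclic graph
whose LASSO coefficient is exactly zero in *both* the tumor and the
non-tumor fit — weak edges unsupported by either condition's expression
profile — with the penalty chosen per fit by cross-validated mean
squared error.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from ..expression import ExpressionMatrix
from ..graph import (
    COMPARTMENT_RANK,
    PathwayGraph,
    find_sccs,
    remove_self_loops,
)
from ._result import (
    REASON_LASSO,
    REASON_RULE,
    REASON_SELF_LOOP,
    ConfigurationError,
    ReconstructionError,
    ReconstructionResult,
    RemovedEdge,
)
from .clipper import clipper_reconstruct

RULE_ANTI_FLUX = "R1_anti_flux"
RULE_NUCLEAR_FEEDBACK = "R2_nuclear_feedback"
RULE_NEGATIVE_FEEDBACK = "R3_negative_feedback"


def _scc_edge_keys(g: PathwayGraph) -> set[tuple[str, str]]:
    nxg = g.to_networkx()
    keys: set[tuple[str, str]] = set()
    for comp in nx.strongly_connected_components(nxg):
        if len(comp) < 2:
            continue
        keys |= {e.key for e in g.edges if e.source in comp and e.target in comp}
    return keys


def bnrich_rules(
    g: PathwayGraph,
    fallback: str = "error",
    expr: ExpressionMatrix | None = None,
    condition: str = "non_tumor",
    split: str | None = "train",
) -> ReconstructionResult:
    if fallback not in ("error", "clipper"):
        raise ConfigurationError(f"fallback must be 'error' or 'clipper', got {fallback!r}")
    g2, loops = remove_self_loops(g)
    removed = [RemovedEdge(e, REASON_SELF_LOOP) for e in loops]
    cyclic_keys = _scc_edge_keys(g2)

    remaining = list(g2.edges)

    def rank(node: str) -> int | None:
        return COMPARTMENT_RANK.get(g2.nodes[node].compartment)

    # R1: against the signalling axis
    kept = []
    for e in remaining:
        rs, rt = rank(e.source), rank(e.target)
        if e.key in cyclic_keys and rs is not None and rt is not None and rs > rt:
            removed.append(RemovedEdge(e, REASON_RULE, RULE_ANTI_FLUX))
        else:
            kept.append(e)
    remaining = kept

    # R2: transcriptional feedback out of the nucleus
    kept = []
    for e in remaining:
        if (
            e.key in cyclic_keys
            and g2.nodes[e.source].compartment == "nucleus"
            and e.interaction in ("expression", "state_transition")
        ):
            removed.append(RemovedEdge(e, REASON_RULE, RULE_NUCLEAR_FEEDBACK))
        else:
            kept.append(e)
    remaining = kept

    # R3: inhibition edges still closing a cycle in the pruned graph
    work = nx.DiGraph()
    work.add_nodes_from(g2.nodes)
    work.add_edges_from(e.key for e in remaining)
    kept = []
    for e in remaining:
        if (
            e.key in cyclic_keys
            and e.interaction == "inhibition"
            and work.has_edge(*e.key)
        ):
            work.remove_edge(*e.key)
            if nx.has_path(work, e.target, e.source):
                removed.append(RemovedEdge(e, REASON_RULE, RULE_NEGATIVE_FEEDBACK))
                continue
            work.add_edge(*e.key)
        kept.append(e)
    remaining = kept

    interim = g.replace_edges(remaining)
    if not nx.is_directed_acyclic_graph(interim.to_networkx()):
        if fallback == "error":
            report = find_sccs(interim)
            cycles = ["->".join(c) for c in report.simple_cycles]
            raise ReconstructionError(
                "biological rules left cycles: " + "; ".join(cycles)
            )
        if expr is None:
            raise ConfigurationError("fallback='clipper' requires expression data")
        delegated = clipper_reconstruct(interim, expr, condition=condition, split=split)
        removed.extend(r for r in delegated.removed if r.reason != REASON_SELF_LOOP)
        interim = delegated.dag

    result = ReconstructionResult(strategy="bnrich", dag=interim, removed=removed)
    result.validate(g)
    return result


def bnrich_lasso_simplify(
    dag: PathwayGraph,
    expr: ExpressionMatrix,
    seed: int = 0,
    folds: int = 5,
    split: str | None = "train",
) -> ReconstructionResult:
    """Remove edges whose LASSO coefficient is exactly zero in both conditions.

    One LASSO per (child, condition) with all parents as predictors; the
    penalty grid spans [1e-4 * lambda_max, lambda_max]; K-fold
    cross-validated mean squared error anchors the choice, taken as the
    largest penalty within one standard error of the CV minimum (the
    glmnet-style 1-SE rule, which shrinks unsupported edges to exact
    zero far more reliably than the raw minimizer).  Removal cannot
    create cycles, so the output stays acyclic.
    """
    if not nx.is_directed_acyclic_graph(dag.to_networkx()):
        raise ConfigurationError("LASSO simplification requires an acyclic graph")
    per_condition = {}
    for cond in ("tumor", "non_tumor"):
        data = expr.subset(condition=cond, split=split)
        if len(data) < folds:
            raise ConfigurationError(
                f"need >= {folds} {cond} samples for {folds}-fold CV, got {len(data)}"
            )
        per_condition[cond] = data
    missing = {n for e in dag.edges for n in e.key} - set(expr.values.columns)
    if missing:
        raise ConfigurationError(f"genes missing from expression data: {sorted(missing)}")

    children: dict[str, list[str]] = {}
    for e in dag.edges:
        children.setdefault(e.target, []).append(e.source)

    coefs: dict[tuple[str, str], dict[str, float]] = {}
    for child, parents in children.items():
        for cond, data in per_condition.items():
            X = data[parents].to_numpy()
            y = data[child].to_numpy()
            if len(parents) == 1 and X.std() == 0:
                warnings.warn(
                    f"zero-variance single parent {parents[0]} of {child}; edge retained"
                )
                coefs[(parents[0], child)] = coefs.get((parents[0], child), {})
                coefs[(parents[0], child)][cond] = np.inf
                continue
            cv = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**32 - 1))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # LassoCV convergence chatter
                model = LassoCV(eps=1e-4, alphas=60, cv=cv, max_iter=5000).fit(X, y)
                # one-standard-error rule anchored at the CV-minimum mean error:
                # the largest penalty whose mean CV error is within one SE of
                # the minimum, so weak edges shrink reliably to exact zero
                mean_mse = model.mse_path_.mean(axis=1)
                se = model.mse_path_.std(axis=1, ddof=1) / np.sqrt(folds)
                cutoff = mean_mse.min() + se[int(mean_mse.argmin())]
                alpha = float(model.alphas_[mean_mse <= cutoff].max())
                beta_at = Lasso(alpha=alpha, max_iter=5000).fit(X, y).coef_
            for parent, beta in zip(parents, beta_at):
                coefs.setdefault((parent, child), {})[cond] = float(beta)

    kept, removed = [], []
    for e in dag.edges:
        c = coefs.get(e.key)
        if c is not None and c.get("tumor", np.inf) == 0.0 and c.get("non_tumor", np.inf) == 0.0:
            removed.append(RemovedEdge(e, REASON_LASSO, (c["tumor"], c["non_tumor"])))
        else:
            kept.append(e)

    result = ReconstructionResult(
        strategy="bnrich",
        dag=dag.replace_edges(kept),
        removed=removed,
        seed=seed,
        extras={"lasso_coefficients": coefs},
    )
    result.validate(dag)
    return result


def bnrich_reconstruct(
    g: PathwayGraph,
    expr: ExpressionMatrix,
    fallback: str = "error",
    seed: int = 0,
    folds: int = 5,
    condition: str = "non_tumor",
    split: str | None = "train",
    lasso: bool = True,
) -> ReconstructionResult:
    """Full strategy: biological rules, then optional LASSO simplification."""
    stage1 = bnrich_rules(g, fallback=fallback, expr=expr, condition=condition, split=split)
    if not lasso:
        return stage1
    stage2 = bnrich_lasso_simplify(stage1.dag, expr, seed=seed, folds=folds, split=split)
    result = ReconstructionResult(
        strategy="bnrich",
        dag=stage2.dag,
        removed=stage1.removed + stage2.removed,
        seed=seed,
        extras=stage2.extras,
    )
    result.validate(g)
    return result
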