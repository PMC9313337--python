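"""Data-driven strategies: regression-evidence ranking and rules+LASSO."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pathbn.bn import NodeParams
from pathbn.graph import EdgeRecord, NodeRecord, PathwayGraph, is_acyclic
from pathbn.reconstruct import (
    ConfigurationError,
    ReconstructionError,
    bnrich_lasso_simplify,
    bnrich_reconstruct,
    bnrich_rules,
    clipper_reconstruct,
    edge_p_values,
)
from pathbn.simulate import gen_expression, gen_scenario

from conftest import expr_from_values, make_graph, random_expr


def slope_pvalue_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form two-sided p of the OLS slope via the correlation t-test."""
    from scipy import stats

    n = len(x)
    r = np.corrcoef(x, y)[0, 1]
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return 2 * stats.t.sf(abs(t), n - 2)


# ---------------------------------------------------------------------------
# clipper
# ---------------------------------------------------------------------------


def test_clipper_identity_on_acyclic_input():
    g = make_graph([("A", "B"), ("B", "C")])
    rng = np.random.default_rng(0)
    res = clipper_reconstruct(g, random_expr(["A", "B", "C"], 10, rng))
    assert res.dag == g and res.removed == []


def test_clipper_p_values_match_closed_form_oracle():
    g = make_graph([("A", "B"), ("B", "C")])
    rng = np.random.default_rng(1)
    expr = random_expr(["A", "B", "C"], 20, rng)
    pvals = edge_p_values(g, expr)
    data = expr.subset(condition="non_tumor", split="train")
    for key, p in pvals.items():
        oracle = slope_pvalue_oracle(data[key[0]].to_numpy(), data[key[1]].to_numpy())
        assert p == pytest.approx(oracle, rel=1e-9)


def test_clipper_removes_weakest_edge_of_three_cycle():
    """A->B tight, B->C medium, C->A weakest: the weakest closes the cycle."""
    rng = np.random.default_rng(2)
    n = 40
    a = rng.normal(0, 1, n)
    b = a + 0.05 * rng.normal(0, 1, n)      # corr(A,B) ~ 0.999
    c = 0.5 * b + 2.0 * rng.normal(0, 1, n)  # corr(B,C) moderate, corr(C,A) weaker
    values = pd.DataFrame({"A": a + 6, "B": b + 6, "C": c + 6})
    expr = expr_from_values(values)
    g = make_graph([("A", "B"), ("B", "C"), ("C", "A")])
    pvals = edge_p_values(g, expr)
    assert pvals[("A", "B")] < pvals[("B", "C")] < pvals[("C", "A")]
    res = clipper_reconstruct(g, expr)
    assert res.removed_keys() == {("C", "A")}
    assert res.removed[0].evidence == pytest.approx(pvals[("C", "A")])


def test_clipper_missing_gene_is_named():
    g = make_graph([("A", "B")])
    rng = np.random.default_rng(3)
    with pytest.raises(ConfigurationError, match="B"):
        clipper_reconstruct(g, random_expr(["A"], 10, rng))


def test_clipper_zero_variance_parent_gets_p_one():
    values = pd.DataFrame({"A": np.ones(10), "B": np.arange(10.0)})
    expr = expr_from_values(values)
    g = make_graph([("A", "B")])
    with pytest.warns(UserWarning, match="zero-variance"):
        pvals = edge_p_values(g, expr)
    assert pvals[("A", "B")] == 1.0


def test_clipper_requires_three_samples():
    g = make_graph([("A", "B")])
    rng = np.random.default_rng(4)
    with pytest.raises(ConfigurationError, match=">= 3"):
        clipper_reconstruct(g, random_expr(["A", "B"], 2, rng))


# ---------------------------------------------------------------------------
# bnrich rules
# ---------------------------------------------------------------------------


def test_rules_remove_exactly_the_two_feedback_edges(fig_graph):
    res = bnrich_rules(fig_graph)
    assert res.removed_keys() == {("D", "A"), ("E", "D")}
    rules = {r.edge.key: r.evidence for r in res.removed}
    assert rules[("D", "A")] == "R1_anti_flux"
    assert rules[("E", "D")] == "R2_nuclear_feedback"
    assert is_acyclic(res.dag)


def test_rules_error_when_unannotated_cycles_survive():
    g = make_graph([("X", "Y"), ("Y", "X")])
    with pytest.raises(ReconstructionError, match="X->Y|Y->X"):
        bnrich_rules(g, fallback="error")


def test_rules_leave_forward_chain_untouched():
    comp = {"A": "membrane", "B": "cytoplasm", "C": "nucleus"}
    g = make_graph([("A", "B"), ("B", "C")], compartments=comp)
    res = bnrich_rules(g)
    assert res.dag == g and res.removed == []


def test_rules_ignore_anti_flux_edges_outside_cycles():
    """R1 fires only on edges participating in a nontrivial SCC."""
    comp = {"N": "nucleus", "C": "cytoplasm"}
    g = make_graph([("N", "C")], compartments=comp)
    res = bnrich_rules(g)
    assert res.removed == []


def test_rules_negative_feedback_inhibition_removed():
    comp = {n: "cytoplasm" for n in "XYZ"}
    g = make_graph(
        [("X", "Y"), ("Y", "Z"), ("Z", "X")],
        compartments=comp,
        interactions={("Z", "X"): "inhibition"},
    )
    res = bnrich_rules(g)
    assert res.removed_keys() == {("Z", "X")}
    assert res.removed[0].evidence == "R3_negative_feedback"


def test_rules_fallback_delegates_residual_cycles():
    g = make_graph([("X", "Y"), ("Y", "X")])
    rng = np.random.default_rng(5)
    expr = random_expr(["X", "Y"], 15, rng)
    res = bnrich_rules(g, fallback="clipper", expr=expr)
    assert is_acyclic(res.dag) and len(res.removed) == 1


# ---------------------------------------------------------------------------
# bnrich LASSO simplification
# ---------------------------------------------------------------------------


def _two_parent_expr(coef2: float, n: int, rng) -> "pd.DataFrame":
    p1 = rng.normal(0, 1, n)
    p2 = rng.normal(0, 1, n)
    child = 3.0 * p1 + coef2 * p2 + 0.5 * rng.normal(0, 1, n)
    return pd.DataFrame({"P1": p1 + 6, "P2": p2 + 6, "C": child + 6})


def test_lasso_removes_independent_parent_keeps_real_one():
    rng = np.random.default_rng(6)
    frames = {c: _two_parent_expr(0.0, 200, rng) for c in ("tumor", "non_tumor")}
    expr = expr_from_values(frames["tumor"], frames)
    dag = make_graph([("P1", "C"), ("P2", "C")])
    res = bnrich_lasso_simplify(dag, expr, seed=0)
    assert res.removed_keys() == {("P2", "C")}
    assert res.dag.has_edge("P1", "C")


def test_lasso_keeps_edge_strong_in_one_condition_only():
    """Zero coefficient in a single condition is not enough for removal."""
    rng = np.random.default_rng(7)
    frames = {
        "tumor": _two_parent_expr(2.0, 200, rng),
        "non_tumor": _two_parent_expr(0.0, 200, rng),
    }
    expr = expr_from_values(frames["tumor"], frames)
    dag = make_graph([("P1", "C"), ("P2", "C")])
    res = bnrich_lasso_simplify(dag, expr, seed=0)
    assert ("P2", "C") not in res.removed_keys()


def test_lasso_removes_zero_coefficient_edge_of_example(fig_graph):
    """Generate from the example DAG with the E->G coefficient forced to 0."""
    dag = bnrich_rules(fig_graph).dag
    rng = np.random.default_rng(8)
    params = {}
    for node in dag.nodes:
        coeffs = {p: (0.0 if (p, node) == ("E", "G") else 1.2) for p in dag.parents(node)}
        params[node] = NodeParams(6.0 * (1 - sum(coeffs.values())), coeffs, 1.0)

    def sample(n):
        import networkx as nx

        order = list(nx.topological_sort(dag.to_networkx()))
        data = pd.DataFrame(index=range(n), columns=list(dag.nodes), dtype=float)
        for node in order:
            p = params[node]
            mean = np.full(n, p.intercept)
            for parent, b in p.coefficients.items():
                mean += b * data[parent].to_numpy()
            data[node] = mean + rng.normal(0, 1, n)
        return data

    expr = expr_from_values(sample(150), {"tumor": sample(150), "non_tumor": sample(150)})
    res = bnrich_lasso_simplify(dag, expr, seed=0)
    assert ("E", "G") in res.removed_keys()
    # strong edges survive
    assert res.dag.has_edge("D", "E") and res.dag.has_edge("A", "B")


@pytest.mark.parametrize("seed", range(10))
def test_lasso_never_removes_strong_edges(seed):
    """|beta| >= 1 at n=500 per condition survives CV-selected shrinkage."""
    sc = gen_scenario(n_nodes=8, n_extra_cycle_edges=0, n_pairs=500, seed=seed)
    strong = {
        (p, node)
        for node, prm in sc.params.items()
        for p, b in prm.coefficients.items()
        if abs(b) > 1.0
    }
    expr = gen_expression(sc)
    res = bnrich_lasso_simplify(sc.truth, expr, seed=seed)
    assert not (strong & res.removed_keys())


def test_lasso_single_zero_variance_parent_retained():
    values = pd.DataFrame({"P": np.ones(20), "C": np.arange(20.0)})
    expr = expr_from_values(values)
    dag = make_graph([("P", "C")])
    with pytest.warns(UserWarning, match="zero-variance"):
        res = bnrich_lasso_simplify(dag, expr, seed=0)
    assert res.removed == []


def test_full_bnrich_recovers_truth_on_annotated_scenario():
    sc = gen_scenario(n_nodes=14, n_extra_cycle_edges=3, n_pairs=80, seed=11)
    expr = gen_expression(sc)
    res = bnrich_reconstruct(sc.observed, expr, fallback="error", seed=0, lasso=False)
    assert {e.key for e in res.dag.edges} == {e.key for e in sc.truth.edges}
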