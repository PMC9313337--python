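"""Graph-hierarchy node rankings: Gaussian skill rating and social agony.

Both metrics assign every node a rank such that edges are expected to
point from lower- to higher-ranked nodes (downstream = higher).  Edges
violating the inferred hierarchy are the candidates for cycle breaking.

Skill rating treats every node as a player and every edge u -> v as a
match won by v.  Each node's skill is a Gaussian belief N(mu, sigma^2)
updated by the standard two-player rule (truncated-normal moment
matching, no draws); the final rank is the posterior mean.

Social agony of a ranking r is sum over edges u -> v of
max(0, r(u) - r(v) + 1).  Minimizing it is a linear program whose
constraint matrix is a totally unimodular difference system, so the LP
optimum is integral and exact at any graph size.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog
from scipy.stats import norm

#: priors of the skill-rating system
MU0 = 25.0
SIGMA0 = MU0 / 3.0
BETA = SIGMA0 / 2.0


def _v_w(t: float) -> tuple[float, float]:
    # truncated-normal correction factors, computed in log space for stability
    v = math.exp(norm.logpdf(t) - norm.logcdf(t))
    return v, v * (v + t)


def skill_rank(
    nodes: Iterable[str],
    edges: Sequence[tuple[str, str]],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Posterior mean skill per node after one seed-shuffled pass over edges."""
    mu = {n: MU0 for n in nodes}
    var = {n: SIGMA0**2 for n in nodes}
    order = rng.permutation(len(edges))
    for idx in order:
        loser, winner = edges[int(idx)]
        c2 = 2 * BETA**2 + var[winner] + var[loser]
        c = math.sqrt(c2)
        v, w = _v_w((mu[winner] - mu[loser]) / c)
        mu[winner] += var[winner] / c * v
        mu[loser] -= var[loser] / c * v
        var[winner] *= max(1.0 - var[winner] / c2 * w, 1e-12)
        var[loser] *= max(1.0 - var[loser] / c2 * w, 1e-12)
    return mu


def agony(ranks: Mapping[str, float], edges: Iterable[tuple[str, str]]) -> float:
    """Total hierarchy violation of a ranking."""
    return float(sum(max(0.0, ranks[u] - ranks[v] + 1.0) for u, v in edges))


def agony_rank(nodes: Sequence[str], edges: Sequence[tuple[str, str]]) -> dict[str, int]:
    """Integer ranking minimizing total agony (exact, via the LP relaxation)."""
    nodes = list(nodes)
    if not edges:
        return {n: 0 for n in nodes}
    n, m = len(nodes), len(edges)
    index = {node: i for i, node in enumerate(nodes)}
    rows, cols, vals = [], [], []
    for e, (u, v) in enumerate(edges):
        rows += [e, e, e]
        cols += [index[u], index[v], n + e]
        vals += [1.0, -1.0, -1.0]
        if u == v:  # self-loop: r_u - r_u - s <= -1 -> s >= 1, constant agony
            cols[-3:] = [index[u], index[u], n + e]
    a_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n + m))
    c = np.concatenate([np.zeros(n), np.ones(m)])
    bounds = [(0, n - 1)] * n + [(0, None)] * m
    res = linprog(c, A_ub=a_ub, b_ub=-np.ones(m), bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - TU system is always feasible
        raise RuntimeError(f"agony LP failed: {res.message}")
    return {node: int(round(res.x[i])) for node, i in index.items()}
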