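"""Five strategies for turning a cyclic pathway graph into a DAG.

============  =====================================================
strategy      decycling principle
============  =====================================================
``props``     random insertion order, drop cycle-closing edges
``clipper``   insert by regression-evidence rank, drop weakest
``bnrich``    biological rules, then LASSO simplification
``bpa``       rebuild each cyclegroup as a random tournament
``ensemble``  vote of 6 (hierarchy metric x removal heuristic) pairs
============  =====================================================
"""

from __future__ import annotations

from ..expression import ExpressionMatrix
from ..graph import PathwayGraph
from ._result import (
    STRATEGIES,
    ConfigurationError,
    ReconstructionError,
    ReconstructionResult,
    RemovedEdge,
)
from .bnrich import bnrich_lasso_simplify, bnrich_reconstruct, bnrich_rules
from .bpa import bpa_reconstruct
from .clipper import clipper_reconstruct, edge_p_values
from .ensemble import ensemble_members, ensemble_reconstruct
from .props import props_reconstruct
from .report import ReconstructionReport, edge_overlap, jaccard, reconstruction_report

__all__ = [
    "STRATEGIES",
    "ConfigurationError",
    "ReconstructionError",
    "ReconstructionResult",
    "ReconstructionReport",
    "RemovedEdge",
    "bnrich_lasso_simplify",
    "bnrich_reconstruct",
    "bnrich_rules",
    "bpa_reconstruct",
    "clipper_reconstruct",
    "edge_overlap",
    "edge_p_values",
    "ensemble_members",
    "ensemble_reconstruct",
    "jaccard",
    "props_reconstruct",
    "reconstruct",
    "reconstruction_report",
]


def reconstruct(
    strategy: str,
    g: PathwayGraph,
    expr: ExpressionMatrix | None = None,
    seed: int | None = None,
    condition: str = "non_tumor",
    split: str | None = "train",
    fallback: str = "error",
    lasso: bool = True,
) -> ReconstructionResult:
    """Dispatch to one strategy by name.

    ``expr`` is required for the data-driven strategies (clipper, bnrich);
    ``seed`` for the randomized ones (props, bpa, ensemble, and the LASSO
    fold assignment of bnrich).
    """
    if strategy not in STRATEGIES:
        raise ConfigurationError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy in ("props", "bpa", "ensemble") and seed is None:
        raise ConfigurationError(f"strategy {strategy!r} requires a seed")
    if strategy in ("clipper", "bnrich") and expr is None:
        raise ConfigurationError(f"strategy {strategy!r} requires expression data")
    if strategy == "props":
        return props_reconstruct(g, seed)
    if strategy == "bpa":
        return bpa_reconstruct(g, seed)
    if strategy == "ensemble":
        return ensemble_reconstruct(g, seed)
    if strategy == "clipper":
        return clipper_reconstruct(g, expr, condition=condition, split=split)
    return bnrich_reconstruct(
        g,
        expr,
        fallback=fallback,
        seed=0 if seed is None else seed,
        condition=condition,
        split=split,
        lasso=lasso,
    )
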