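"""End-to-end orchestration: simulate -> reconstruct -> fit -> score -> enrich.

A :class:`RunConfig` (YAML-serializable) drives one fully seeded run.
Every random draw is derived from the single master seed by named
derivations, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import reconstruct as rec
from .bn import GaussianBN, bic, fit_gaussian_bn
from .enrichment import (
    EnrichmentResult,
    build_feature_table,
    compare_rankings,
    grid_search_rf,
    train_eval_rf_refit,
)
from .expression import ExpressionMatrix, write_expression
from .graph import PathwayGraph, write_edgelist
from .simulate import SyntheticScenario, gen_study
from .utils import derive_seed

log = logging.getLogger("pathbn")


@dataclass
class RunConfig:
    strategies: list[str] = field(default_factory=lambda: list(rec.STRATEGIES))
    seed: int = 0
    repeats: int = 10
    train_fraction: float = 0.75
    n_pathways: int = 12
    n_nodes: int = 25
    n_extra_cycle_edges: int = 4
    n_pairs: int = 60
    perturb_pathway: int | None = 0
    n_perturb_edges: int = 3
    delta: float = 1.5
    ntree_grid: list[int] = field(default_factory=lambda: [200, 500, 1000])
    mtry_grid: list[int] | None = None
    grid_search: bool = True
    lasso_folds: int = 5
    bnrich_fallback: str = "clipper"
    out_dir: str = "pathbn_run"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.strategies) - set(rec.STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def reconstruct_pathways(
    strategy: str,
    scenarios: dict[str, SyntheticScenario],
    expr: ExpressionMatrix,
    seed: int,
    lasso_folds: int = 5,
    fallback: str = "clipper",
) -> dict[str, rec.ReconstructionResult]:
    out = {}
    for name, sc in scenarios.items():
        out[name] = rec.reconstruct(
            strategy,
            sc.observed,
            expr=expr,
            seed=derive_seed(seed, strategy, name),
            fallback=fallback,
        )
    return out


def fit_pathway_bns(
    results: dict[str, rec.ReconstructionResult], expr: ExpressionMatrix
) -> dict[str, GaussianBN]:
    return {name: fit_gaussian_bn(res.dag, expr) for name, res in results.items()}


def _combined_original(scenarios: dict[str, SyntheticScenario]) -> PathwayGraph:
    """Disjoint union of the observed pathway graphs (namespaces disjoint)."""
    nodes, edges = [], []
    for sc in scenarios.values():
        nodes.extend(sc.observed.nodes.values())
        edges.extend(sc.observed.edges)
    return PathwayGraph.from_edges("study", edges, nodes)


def _combined_result(
    strategy: str, results: dict[str, rec.ReconstructionResult], original: PathwayGraph
) -> rec.ReconstructionResult:
    removed, added, kept = [], [], []
    for res in results.values():
        removed.extend(res.removed)
        added.extend(res.added)
        kept.extend(res.dag.edges)
    combined = rec.ReconstructionResult(
        strategy=strategy,
        dag=original.replace_edges(kept),
        removed=removed,
        added=added,
    )
    combined.validate(original)
    return combined


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full comparison; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("simulating study (seed=%d)", config.seed)
    scenarios, expr = gen_study(
        n_pathways=config.n_pathways,
        n_nodes=config.n_nodes,
        n_extra_cycle_edges=config.n_extra_cycle_edges,
        n_pairs=config.n_pairs,
        seed=config.seed,
        perturb_pathway=config.perturb_pathway,
        n_perturb_edges=config.n_perturb_edges,
        delta=config.delta,
    )
    write_expression(expr, out / "expression.tsv")
    graphs_dir = out / "graphs"
    graphs_dir.mkdir(exist_ok=True)
    for name, sc in scenarios.items():
        write_edgelist(sc.observed, graphs_dir / f"{name}.tsv")

    original = _combined_original(scenarios)
    enrichments: dict[str, EnrichmentResult] = {}
    combined_results = []
    bic_rows = {}
    seeds_log: dict[str, int] = {}
    for strategy in config.strategies:
        s_seed = derive_seed(config.seed, "reconstruct", strategy)
        seeds_log[f"reconstruct/{strategy}"] = s_seed
        log.info("strategy %s: reconstructing %d pathways", strategy, len(scenarios))
        results = reconstruct_pathways(
            strategy, scenarios, expr, s_seed,
            lasso_folds=config.lasso_folds, fallback=config.bnrich_fallback,
        )
        combined_results.append(_combined_result(strategy, results, original))
        bns = fit_pathway_bns(results, expr)
        bic_rows[strategy] = {
            name: bic(bn, expr, condition="non_tumor", split="train")
            for name, bn in bns.items()
        }
        table = build_feature_table(bns, expr)
        hp_seed = derive_seed(config.seed, "grid", strategy)
        if config.grid_search:
            hyper = grid_search_rf(
                table,
                tuple(config.ntree_grid),
                tuple(config.mtry_grid) if config.mtry_grid else None,
                seed=hp_seed,
            )
        else:
            hyper = (config.ntree_grid[0], max(1, int(len(table.pathways) ** 0.5)))
        eval_seed = derive_seed(config.seed, "eval", strategy)
        seeds_log[f"eval/{strategy}"] = eval_seed
        log.info("strategy %s: RF with ntree=%d mtry=%d", strategy, *hyper)
        enrichments[strategy] = train_eval_rf_refit(
            {name: res.dag for name, res in results.items()},
            expr,
            hyper,
            seed=eval_seed,
            repeats=config.repeats,
            train_fraction=config.train_fraction,
        )
        enrichments[strategy].to_json(out / f"enrichment_{strategy}.json")

    report = rec.reconstruction_report(combined_results, original)
    report.summary.to_csv(out / "reconstruction_report.tsv", sep="\t", index=False)
    report.removed_jaccard.to_csv(out / "removed_overlap.tsv", sep="\t")
    report.kept_jaccard.to_csv(out / "kept_overlap.tsv", sep="\t")
    long_df, rho = compare_rankings(enrichments)
    long_df.to_csv(out / "compare_rankings.tsv", sep="\t", index=False)
    rho.to_csv(out / "rank_spearman.tsv", sep="\t")
    pd.DataFrame(bic_rows).to_csv(out / "bic.tsv", sep="\t")
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config": dataclasses.asdict(config),
                "derived_seeds": seeds_log,
                "perturbed_pathway": (
                    f"P{config.perturb_pathway:02d}"
                    if config.perturb_pathway is not None
                    else None
                ),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return out
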