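"""Pathway-level features, Random-Forest classification, pathway ranking.

The feature of sample s for pathway p is the log-likelihood of s under
pathway p's Bayesian network (trained on control training samples only).
A Random Forest classifies tumor vs non-tumor from these features; its
impurity-based importance (mean decrease in Gini) scores each pathway's
contribution, and descending importance defines the enrichment ranking.
Accuracy-type metrics are reported at the threshold maximizing the
Matthews correlation coefficient on test scores; AUC is threshold-free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .bn import GaussianBN, loglik_matrix
from .expression import ExpressionMatrix, paired_split
from .utils import derive_seed

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc")

DEFAULT_NTREE_GRID = (200, 500, 1000)


class EnrichmentError(RuntimeError):
    pass


@dataclass
class FeatureTable:
    """Samples x pathways log-likelihood features with labels and pairing."""

    features: pd.DataFrame   # rows = samples, columns = pathways
    labels: pd.Series        # sample -> tumor / non_tumor
    pairs: pd.Series         # sample -> pair id
    split: pd.Series         # sample -> train / test

    def __post_init__(self) -> None:
        for s in (self.labels, self.pairs, self.split):
            if not s.index.equals(self.features.index):
                raise EnrichmentError("feature rows and metadata indices differ")
        if self.features.isna().any().any():
            raise EnrichmentError("feature table has missing cells")
        by_pair = self.split.groupby(self.pairs)
        if (by_pair.nunique() != 1).any():
            raise EnrichmentError("paired samples must share the split assignment")

    @property
    def pathways(self) -> list[str]:
        return list(self.features.columns)

    def y(self) -> np.ndarray:
        return (self.labels == "tumor").to_numpy().astype(int)


def build_feature_table(bns: dict[str, GaussianBN], expr: ExpressionMatrix) -> FeatureTable:
    """Score every sample under every pathway BN."""
    cols = {}
    for pathway, bn in bns.items():
        try:
            cols[pathway] = loglik_matrix(bn, expr.values)
        except KeyError as exc:
            raise EnrichmentError(f"pathway {pathway!r}: {exc.args[0]}") from None
    features = pd.DataFrame(cols, index=expr.values.index)
    return FeatureTable(
        features=features,
        labels=expr.samples["condition"],
        pairs=expr.samples["pair"],
        split=expr.samples["split"],
    )


def default_mtry_grid(n_features: int) -> tuple[int, ...]:
    """sqrt(p), p/3 and p, deduplicated and floored at 1."""
    cand = {max(1, int(round(np.sqrt(n_features)))), max(1, n_features // 3), n_features}
    return tuple(sorted(cand))


def _make_rf(ntree: int, mtry: int, seed: int, oob: bool = False) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        oob_score=oob,
        random_state=seed,
        n_jobs=1,
    )


def grid_search_rf(
    table: FeatureTable,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    mtry_grid: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[int, int]:
    """Pick (ntree, mtry) by out-of-bag AUC on the training rows.

    Ties prefer the smaller ntree, then the smaller mtry.
    """
    if mtry_grid is None:
        mtry_grid = default_mtry_grid(len(table.pathways))
    train = table.split == "train"
    X = table.features.loc[train].to_numpy()
    y = table.y()[train.to_numpy()]
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise EnrichmentError("grid search needs >= 2 training samples per class")
    best: tuple[float, int, int] | None = None
    for ntree in sorted(ntree_grid):
        for mtry in sorted(mtry_grid):
            rf = _make_rf(ntree, min(mtry, X.shape[1]), seed, oob=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # few-tree OOB coverage warnings
                rf.fit(X, y)
            scores = rf.oob_decision_function_[:, 1]
            mask = ~np.isnan(scores)
            auc = roc_auc_score(y[mask], scores[mask])
            if best is None or auc > best[0] + 1e-12:
                best = (auc, ntree, mtry)
    return best[1], best[2]


def mcc_threshold(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Midpoint of sorted unique scores maximizing the MCC."""
    uniq = np.unique(scores)
    if len(uniq) < 2:
        return 0.5
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best_t, best_mcc = candidates[0], -2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-class predictions give MCC 0
        for t in candidates:
            m = matthews_corrcoef(y_true, (scores > t).astype(int))
            if m > best_mcc + 1e-12:
                best_t, best_mcc = float(t), m
    return best_t


@dataclass
class EnrichmentResult:
    metrics: dict[str, tuple[float, float]]  # name -> (mean, sd) over repeats
    importances: pd.Series                   # pathway -> mean impurity importance
    ranks: pd.Series                         # pathway -> dense rank, 1 = top
    threshold: float                         # mean MCC-optimal threshold
    hyperparams: tuple[int, int]             # (ntree, mtry)
    n_repeats: int = 0
    per_repeat: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
            "importances": self.importances.to_dict(),
            "ranks": {k: int(v) for k, v in self.ranks.items()},
            "threshold": self.threshold,
            "hyperparams": {"ntree": self.hyperparams[0], "mtry": self.hyperparams[1]},
            "n_repeats": self.n_repeats,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _dense_ranks(importances: pd.Series) -> pd.Series:
    return importances.rank(method="dense", ascending=False).astype(int)


def _eval_split(
    features: pd.DataFrame,
    y: pd.Series,
    train_mask: pd.Series,
    ntree: int,
    mtry: int,
    seed: int,
) -> tuple[dict, np.ndarray, float] | None:
    """Fit a forest on the train rows, evaluate on the test rows.

    Returns (metric row, importances, threshold), or None when the test
    side is single-class.
    """
    y_test = y[~train_mask].to_numpy()
    if len(np.unique(y_test)) < 2:
        return None
    rf = _make_rf(ntree, min(mtry, features.shape[1]), seed)
    rf.fit(features.loc[train_mask].to_numpy(), y[train_mask].to_numpy())
    scores = rf.predict_proba(features.loc[~train_mask].to_numpy())[:, 1]
    t = mcc_threshold(y_test, scores)
    y_hat = (scores > t).astype(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-division precision on bad repeats
        row = {
            "accuracy": accuracy_score(y_test, y_hat),
            "precision": precision_score(y_test, y_hat, zero_division=0),
            "recall": recall_score(y_test, y_hat, zero_division=0),
            "f1": f1_score(y_test, y_hat, zero_division=0),
            "auc": roc_auc_score(y_test, scores),
        }
    return row, rf.feature_importances_, t


def _aggregate_repeats(rows, importance_rows, thresholds, pathways, hyperparams) -> "EnrichmentResult":
    if not rows:
        raise EnrichmentError("every repeat had a single-class test fold")
    per_repeat = pd.DataFrame(rows)
    used = len(rows)
    metrics = {
        name: (
            float(per_repeat[name].mean()),
            float(per_repeat[name].std(ddof=1)) if used > 1 else 0.0,
        )
        for name in METRIC_NAMES
    }
    importances = pd.Series(
        np.mean(importance_rows, axis=0), index=pathways, name="mdg"
    )
    return EnrichmentResult(
        metrics=metrics,
        importances=importances,
        ranks=_dense_ranks(importances),
        threshold=float(np.mean(thresholds)),
        hyperparams=tuple(hyperparams),
        n_repeats=used,
        per_repeat=per_repeat,
    )


def train_eval_rf(
    table: FeatureTable,
    hyperparams: tuple[int, int],
    seed: int = 0,
    repeats: int = 10,
    train_fraction: float = 0.75,
) -> EnrichmentResult:
    """Repeatedly re-split pairs 75/25, fit on train, evaluate on test.

    Per repeat: forest fitted on the training side, scores on the test
    side; threshold = MCC-optimal midpoint of test scores; accuracy,
    precision, recall and F1 at that threshold plus threshold-free AUC.
    Metrics aggregate as mean +/- sd over repeats; importances as the
    mean impurity importance.  A repeat whose test side is single-class
    is skipped with a warning.
    """
    ntree, mtry = hyperparams
    y_all = pd.Series(table.y(), index=table.features.index)
    rows, importance_rows, thresholds = [], [], []
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, "split", rep))
        split = paired_split(table.pairs, train_fraction, rng)
        outcome = _eval_split(
            table.features, y_all, split == "train", ntree, mtry, derive_seed(seed, "rf", rep)
        )
        if outcome is None:
            warnings.warn(f"repeat {rep}: single-class test fold skipped")
            continue
        row, imp, t = outcome
        rows.append({"repeat": rep, **row})
        importance_rows.append(imp)
        thresholds.append(t)
    return _aggregate_repeats(rows, importance_rows, thresholds, table.pathways, (ntree, mtry))


def train_eval_rf_refit(
    dags: dict[str, "object"],
    expr,
    hyperparams: tuple[int, int],
    seed: int = 0,
    repeats: int = 10,
    train_fraction: float = 0.75,
) -> EnrichmentResult:
    """Leakage-free repeated hold-out: re-split, refit every BN, then classify.

    Per repeat the paired 75/25 split is redrawn and the pathway BNs are
    refitted on that repeat's control *training* samples before features
    are computed, so no test sample ever contributes to parameter
    learning — the full protocol behind the per-split evaluation.
    ``dags`` maps pathway -> acyclic PathwayGraph.
    """
    from .bn import fit_gaussian_bn  # local import: avoids cycle at module load

    ntree, mtry = hyperparams
    pathways = list(dags)
    rows, importance_rows, thresholds = [], [], []
    for rep in range(repeats):
        rng = np.random.default_rng(derive_seed(seed, "split", rep))
        split = paired_split(expr.samples["pair"], train_fraction, rng)
        expr_rep = expr.with_split(split)
        bns = {
            name: fit_gaussian_bn(dag, expr_rep, condition="non_tumor", split="train")
            for name, dag in dags.items()
        }
        table = build_feature_table(bns, expr_rep)
        y_all = pd.Series(table.y(), index=table.features.index)
        outcome = _eval_split(
            table.features,
            y_all,
            table.split == "train",
            ntree,
            mtry,
            derive_seed(seed, "rf", rep),
        )
        if outcome is None:
            warnings.warn(f"repeat {rep}: single-class test fold skipped")
            continue
        row, imp, t = outcome
        rows.append({"repeat": rep, **row})
        importance_rows.append(imp)
        thresholds.append(t)
    return _aggregate_repeats(rows, importance_rows, thresholds, pathways, (ntree, mtry))


def rank_pathways(result: EnrichmentResult) -> pd.DataFrame:
    """Ranking table sorted from most to least important pathway."""
    df = pd.DataFrame(
        {"pathway": result.importances.index, "mdg": result.importances.to_numpy()}
    )
    df["rank"] = _dense_ranks(result.importances).to_numpy()
    return df.sort_values(["rank", "pathway"], kind="stable").reset_index(drop=True)


def compare_rankings(results: dict[str, EnrichmentResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-strategy ranks plus pairwise Spearman correlations."""
    universes = {name: tuple(res.importances.index) for name, res in results.items()}
    reference = next(iter(universes.values()), ())
    if any(set(u) != set(reference) for u in universes.values()):
        raise EnrichmentError("strategies rank different pathway sets")
    long_rows = []
    for name, res in results.items():
        for pathway in reference:
            long_rows.append(
                {
                    "pathway": pathway,
                    "strategy": name,
                    "rank": int(res.ranks[pathway]),
                    "mdg": float(res.importances[pathway]),
                }
            )
    long_df = pd.DataFrame(long_rows)
    names = list(results)
    rho = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ra = results[a].ranks.reindex(reference).to_numpy()
            rb = results[b].ranks.reindex(reference).to_numpy()
            r = spearmanr(ra, rb).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return long_df, rho
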