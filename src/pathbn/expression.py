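"""Samples x genes expression container with condition labels and paired splits.

Values live on a log2(n+1)-like scale.  Samples come in pairs (one tumor,
one non-tumor per pair id); both members of a pair always share the
train/test split assignment so that splitting never separates a patient
from their matched control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("tumor", "non_tumor")
SPLITS = ("train", "test")

_META_COLS = ["sample", "pair", "condition", "split"]


class ExpressionFormatError(ValueError):
    """Raised when an expression TSV violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """Expression values plus per-sample metadata.

    ``samples`` is a DataFrame indexed by sample id with columns
    ``pair``, ``condition``, ``split``; ``values`` is a float DataFrame
    with the same index and one column per gene.
    """

    samples: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.samples.index.equals(self.values.index):
            raise ExpressionFormatError("sample metadata and values indices differ")
        for col in ("pair", "condition", "split"):
            if col not in self.samples.columns:
                raise ExpressionFormatError(f"missing metadata column {col!r}")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ExpressionFormatError(f"unknown condition labels {sorted(bad)}")
        bad = set(self.samples["split"]) - set(SPLITS)
        if bad:
            raise ExpressionFormatError(f"unknown split labels {sorted(bad)}")
        if self.values.isna().any().any():
            raise ExpressionFormatError("missing expression values")
        counts = self.samples.groupby("pair").size()
        if len(counts) and not (counts == 2).all():
            raise ExpressionFormatError("every pair id must appear exactly twice")
        if len(counts):
            per_pair = self.samples.groupby("pair")
            if (per_pair["condition"].nunique() != 2).any():
                raise ExpressionFormatError("each pair needs one tumor and one non_tumor sample")
            if (per_pair["split"].nunique() != 1).any():
                raise ExpressionFormatError("pair members must share the split assignment")

    # -- accessors ---------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def subset(self, condition: str | None = None, split: str | None = None) -> pd.DataFrame:
        """Value rows for the requested condition/split (None = all)."""
        mask = pd.Series(True, index=self.samples.index)
        if condition is not None:
            mask &= self.samples["condition"] == condition
        if split is not None:
            mask &= self.samples["split"] == split
        return self.values.loc[mask]

    def with_split(self, split: pd.Series) -> "ExpressionMatrix":
        samples = self.samples.copy()
        samples["split"] = split.reindex(samples.index)
        return ExpressionMatrix(samples, self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.samples.equals(other.samples) and self.values.equals(other.values)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a TSV with columns sample, pair, condition, split, <genes...>."""
    df = pd.read_csv(path, sep="\t")
    for col in _META_COLS:
        if col not in df.columns:
            raise ExpressionFormatError(f"{path}: missing column {col!r}")
    gene_cols = [c for c in df.columns if c not in _META_COLS]
    values = df[gene_cols]
    non_numeric = values.select_dtypes(exclude="number").columns
    if len(non_numeric) and len(values):
        col = non_numeric[0]
        row = values[col].map(lambda v: not isinstance(v, (int, float))).idxmax()
        raise ExpressionFormatError(f"{path}: non-numeric value at row {row}, column {col!r}")
    samples = df[_META_COLS].astype({"sample": str, "pair": str}).set_index("sample")
    values = values.astype(float)
    values.index = samples.index
    return ExpressionMatrix(samples, values)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    meta = expr.samples.reset_index().rename(columns={"index": "sample"})
    if "sample" not in meta.columns:
        meta = meta.rename(columns={meta.columns[0]: "sample"})
    out = pd.concat([meta.reset_index(drop=True), expr.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def shuffle_expression(expr: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Independently permute each gene's values across samples.

    Destroys gene-gene and gene-label association while preserving every
    per-gene marginal exactly — the negative control for data-driven
    reconstruction.
    """
    rng = np.random.default_rng(seed)
    values = expr.values.copy()
    n = len(values)
    for gene in values.columns:
        values[gene] = values[gene].to_numpy()[rng.permutation(n)]
    return ExpressionMatrix(expr.samples.copy(), values)


def paired_split(pairs: pd.Series, train_fraction: float, rng: np.random.Generator) -> pd.Series:
    """Assign train/test per *pair* so matched samples stay together.

    ``pairs`` maps sample id -> pair id.  Returns sample id -> split.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    unique = pd.unique(pairs)
    n_train = int(round(train_fraction * len(unique)))
    n_train = min(max(n_train, 1), len(unique) - 1) if len(unique) > 1 else len(unique)
    shuffled = list(unique)
    rng.shuffle(shuffled)
    train_pairs = set(shuffled[:n_train])
    return pairs.map(lambda p: "train" if p in train_pairs else "test")
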