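"""Shared data containers for the concordance pipeline.

The pipeline moves three kinds of tabular objects around: integer count
matrices with sample metadata, real-valued log2 expression matrices, and
per-contrast differential-expression tables.  All of them wrap pandas
DataFrames so that gene and sample identifiers travel with the numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("sample_id", "source", "condition", "batch")


def _check_sample_table(samples: pd.DataFrame, columns: pd.Index) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table missing columns {missing}")
    samples = samples.copy()
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in sample table")
    samples.index = pd.Index(samples["sample_id"], name="sample_id")
    if not samples.index.equals(pd.Index(columns, name="sample_id")):
        if set(samples.index) != set(columns):
            raise ValueError("sample table does not cover matrix columns")
        samples = samples.loc[list(columns)]
    return samples


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts plus sample metadata.

    ``values``: DataFrame indexed by gene id, columns are sample ids.
    ``samples``: one row per column with sample_id, source, condition, batch.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids in count matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample ids in count matrix")
        arr = self.values.to_numpy()
        if arr.size and arr.min() < 0:
            raise ValueError("negative entries in count matrix")
        self.samples = _check_sample_table(self.samples, self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(gene_ids)], self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        sample_ids = list(sample_ids)
        return CountMatrix(self.values[sample_ids], self.samples.loc[sample_ids])


@dataclass
class ExpressionMatrix:
    """Gene x sample real-valued (log2-scale) expression with metadata."""

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated gene ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite entries in expression matrix")
        self.samples = _check_sample_table(self.samples, self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.samples.loc[sample_ids])


def plain_sample_table(sample_ids, source: str, condition: str, batch: str = "-") -> pd.DataFrame:
    """Minimal metadata table for externally supplied matrices (e.g. a patient cohort)."""
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "source": source,
            "condition": condition,
            "batch": batch,
        }
    )


@dataclass
class EBayesParams:
    """Hyperparameters of the hierarchical variance/DE model.

    d0: prior degrees of freedom of the scaled inverse-chi-squared variance
        prior (may be ``inf``); s0_sq: prior variance; p1: prior probability
    that a gene is differentially expressed; v0: prior variance of the
    contrast coefficient for DE genes (on the unscaled-variance scale).
    """

    d0: float
    s0_sq: float
    p1: float
    v0: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive (possibly inf)")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")
        if not (0 < self.p1 < 1):
            raise ValueError("p1 must lie in (0, 1)")
        if self.v0 < 0:
            raise ValueError("v0 must be non-negative")


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one named contrast.

    ``table`` is indexed by gene id with columns ``lfc`` (log2 fold change),
    ``t`` (moderated t), ``p_value``, ``B`` (log posterior odds of DE) and
    ``posterior`` = logistic(B).
    """

    table: pd.DataFrame
    contrast: str
    priors: EBayesParams | None = None
    info: dict = field(default_factory=dict)

    REQUIRED = ("lfc", "t", "p_value", "B", "posterior")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"DE table missing columns {missing}")
        if self.table.index.duplicated().any():
            raise ValueError("duplicated gene ids in DE table")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index
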