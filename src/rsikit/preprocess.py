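"""Library-size normalization and expression transforms.

Implements trimmed-mean-of-M-values (TMM) scaling factors, log2-CPM with a
prior count, a low-expression filter, quantile normalization for merging
cohorts measured on different platforms, and row z-scoring for heatmaps.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

MIN_TRIMMED_GENES = 10


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors (geometric mean constrained to 1)."""

    factors: pd.Series
    ref_sample: str

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(float)
        if (f <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = np.exp(np.mean(np.log(f)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError("normalization factors must have geometric mean 1")


def _quantile75(y: np.ndarray, lib: np.ndarray) -> np.ndarray:
    """Per-sample 75th percentile of counts scaled by library size."""
    return np.quantile(y / lib, 0.75, axis=0)


def _tmm_pair(
    y: np.ndarray,
    n_k: float,
    ref: np.ndarray,
    n_r: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one library against the reference library.

    M-values are trimmed by ``trim_m`` at each tail and A-values by
    ``trim_a``; the factor is 2**(precision-weighted mean of surviving M)
    where the weight of a gene is the inverse of the asymptotic (delta
    method, binomial) variance of its M-value.
    """
    pos = (y > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("sample shares no positively expressed genes with the reference")
    obs = y[pos] / n_k
    rf = ref[pos] / n_r
    m = np.log2(obs / rf)
    a = 0.5 * np.log2(obs * rf)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    v = (n_k - y[pos]) / (n_k * y[pos]) + (n_r - ref[pos]) / (n_r * ref[pos])

    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < MIN_TRIMMED_GENES:
        warnings.warn(
            f"only {int(keep.sum())} genes survive TMM trimming; "
            "falling back to the untrimmed weighted mean",
            RuntimeWarning,
            stacklevel=3,
        )
        keep = np.ones_like(keep)
    w = 1.0 / v[keep]
    return float(2.0 ** (np.sum(m[keep] * w) / np.sum(w)))


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors for each library.

    The reference library is the one whose 75th-percentile scaled count is
    closest to the across-sample mean, unless ``ref_sample`` names one
    explicitly.  Factors are rescaled to geometric mean 1.
    """
    if counts.values.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    y = counts.values.to_numpy(float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.sample_ids[lib <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    if ref_sample is None:
        f75 = _quantile75(y, lib)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.sample_ids.get_loc(ref_sample)
    f = np.array(
        [
            _tmm_pair(y[:, k], lib[k], y[:, ref_idx], lib[ref_idx], trim_m, trim_a)
            for k in range(y.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return NormFactors(
        factors=pd.Series(f, index=counts.sample_ids, name="tmm_factor"),
        ref_sample=str(counts.sample_ids[ref_idx]),
    )


def log_cpm(
    counts: CountMatrix,
    factors: NormFactors | None = None,
    prior_count: float = 0.5,
) -> ExpressionMatrix:
    """log2 counts per million on TMM-effective library sizes.

    value = log2((y + prior) / (N_k * f_k + 2 * prior) * 1e6).
    """
    y = counts.values.to_numpy(float)
    lib = y.sum(axis=0)
    if factors is not None:
        f = factors.factors.loc[counts.sample_ids].to_numpy(float)
        lib = lib * f
    if (lib <= 0).any():
        raise ValueError("zero effective library size")
    vals = np.log2((y + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    df = pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, counts.samples)


def _default_min_samples(counts: CountMatrix) -> int:
    sizes = counts.samples.groupby(["source", "condition"], observed=True).size()
    return int(sizes.min())


def filter_low_expression(
    counts: CountMatrix,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> CountMatrix:
    """Keep genes with CPM > ``min_cpm`` in at least ``min_samples`` libraries.

    ``min_samples`` defaults to the smallest (source, condition) group size,
    so a gene expressed in every sample of one group survives.
    """
    if min_samples is None:
        min_samples = _default_min_samples(counts)
    if min_samples > counts.values.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    y = counts.values.to_numpy(float)
    cpm = y / y.sum(axis=0) * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError(
            "no genes survive the expression filter; lower min_cpm or min_samples"
        )
    logger.info("expression filter kept %d of %d genes", int(keep.sum()), keep.size)
    return CountMatrix(counts.values.loc[keep], counts.samples)


def _quantile_normalize_values(x: np.ndarray) -> np.ndarray:
    """Map every column onto the mean of the column-wise order statistics.

    Ties within a column receive the mean of their target quantiles
    (average-rank policy).
    """
    n, _ = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j])  # average ranks for ties
        out[:, j] = np.interp(ranks, positions, target)
    return out


def quantile_normalize(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Merge expression matrices on their shared genes and quantile-normalize.

    After merging, every column has an identical empirical distribution:
    the across-column mean of order statistics.
    """
    if not matrices:
        raise ValueError("no matrices to merge")
    shared = matrices[0].gene_ids
    for m in matrices[1:]:
        shared = shared.intersection(m.gene_ids)
    if len(shared) == 0:
        raise ValueError("gene intersection of input matrices is empty")
    logger.info(
        "quantile normalization over %d shared genes (inputs had %s)",
        len(shared),
        [len(m.gene_ids) for m in matrices],
    )
    values = pd.concat([m.values.loc[shared] for m in matrices], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicated sample ids across merged matrices")
    samples = pd.concat([m.samples for m in matrices], axis=0)
    normed = _quantile_normalize_values(values.to_numpy(float))
    out = pd.DataFrame(normed, index=values.index, columns=values.columns)
    return ExpressionMatrix(out, samples)


def row_zscore(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene to mean 0, sd 1 (sample sd, n-1).

    Constant rows are mapped to all zeros with a warning.
    """
    x = matrix.values.to_numpy(float)
    if x.shape[1] < 2:
        raise ValueError("row z-scoring requires at least 2 samples")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    const = sd[:, 0] == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant rows mapped to zero in row_zscore",
            RuntimeWarning,
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    df = pd.DataFrame(z, index=matrix.gene_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(df, matrix.samples)
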