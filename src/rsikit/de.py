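"""Per-gene linear models with empirical-Bayes variance moderation.

For every gene g a linear model ``E[y_g] = X beta_g`` is fitted by ordinary
least squares on log2-CPM values; the contrast of interest ``c'beta_g`` is the
log2 fold change.  Residual variances are shrunk toward a scaled
inverse-chi-squared prior (hyperparameters d0, s0^2 fitted by moment matching
on log s^2), giving the moderated t-statistic with d0 + d_g degrees of
freedom.  A two-component mixture (a gene is differentially expressed with
prior probability p1, in which case its contrast coefficient has prior
variance v0 * sigma_g^2) yields the log posterior odds of differential
expression, B, and the posterior probability logistic(B) that feeds the
response similarity index.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import CountMatrix, DEResult, EBayesParams, ExpressionMatrix
from .preprocess import filter_low_expression, log_cpm, tmm_factors

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design matrices and contrasts
# ---------------------------------------------------------------------------

def build_design(
    samples: pd.DataFrame,
    condition_order: list[str] | None = None,
    covariates: tuple[str, ...] = ("batch",),
) -> pd.DataFrame:
    """Treatment-coded design: intercept + condition indicators + covariates.

    The first condition in ``condition_order`` (default: order of first
    appearance) is the reference level absorbed into the intercept.
    Covariate columns with a single level are dropped.
    """
    if condition_order is None:
        condition_order = list(dict.fromkeys(samples["condition"]))
    missing = set(samples["condition"]) - set(condition_order)
    if missing:
        raise ValueError(f"conditions not in condition_order: {sorted(missing)}")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for cond in condition_order[1:]:
        cols[f"condition[{cond}]"] = (samples["condition"] == cond).to_numpy(float)
    for cov in covariates:
        levels = list(dict.fromkeys(samples[cov]))
        for lev in levels[1:]:
            cols[f"{cov}[{lev}]"] = (samples[cov] == lev).to_numpy(float)
    design = pd.DataFrame(cols, index=samples.index)
    check_full_rank(design)
    return design


def check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify columns that do not increase the rank when added in order
        collinear = []
        r = 0
        for j in range(x.shape[1]):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                collinear.append(design.columns[j])
            r = rj
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def make_contrast(design: pd.DataFrame, cond_a: str, cond_b: str) -> pd.Series:
    """Coefficient vector estimating condition ``cond_a`` minus ``cond_b``."""
    c = pd.Series(0.0, index=design.columns)
    for cond, sign in ((cond_a, 1.0), (cond_b, -1.0)):
        col = f"condition[{cond}]"
        if col in c.index:
            c[col] = sign
        # reference condition contributes 0 (absorbed in the intercept)
    if (c == 0).all():
        raise ValueError(f"contrast {cond_a} vs {cond_b} is identically zero")
    return c


# ---------------------------------------------------------------------------
# gene-wise least squares
# ---------------------------------------------------------------------------

@dataclass
class GeneFits:
    """Vectorized per-gene OLS results for one contrast.

    beta_hat: contrast estimate (log2 FC); s2: residual variance; df_residual:
    residual degrees of freedom (shared across genes); u: unscaled variance of
    the contrast estimator, c'(X'X)^-1 c (shared across genes).
    """

    gene_ids: pd.Index
    beta_hat: np.ndarray
    s2: np.ndarray
    df_residual: float
    u: float
    contrast: str = ""
    info: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)


def fit_linear_models(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    contrast: pd.Series,
    contrast_name: str = "",
) -> GeneFits:
    """Ordinary least squares per gene; returns the contrast estimate,
    residual variance, residual df and the unscaled contrast variance."""
    if list(design.index) != list(expr.sample_ids):
        raise ValueError("design rows do not align with expression columns")
    check_full_rank(design)
    x = design.to_numpy(float)
    c = contrast.loc[design.columns].to_numpy(float)
    if not np.any(c):
        raise ValueError("contrast vector is identically zero")
    n, p = x.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    y = expr.values.to_numpy(float)  # genes x samples
    xtx_inv = np.linalg.inv(x.T @ x)
    hat = xtx_inv @ x.T  # p x n
    beta = y @ hat.T  # genes x p
    resid = y - beta @ x.T
    rss = np.einsum("ij,ij->i", resid, resid)
    s2 = rss / df_resid
    u = float(c @ xtx_inv @ c)
    return GeneFits(
        gene_ids=expr.gene_ids,
        beta_hat=beta @ c,
        s2=s2,
        df_residual=float(df_resid),
        u=u,
        contrast=contrast_name,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes hyperparameters
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x = x + dif
        if -dif / x < tol:
            return x
    raise RuntimeError(
        f"trigamma inversion did not converge after {max_iter} iterations "
        f"(target {y}, last x {x})"
    )


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed residual variances.

    Models s2_g ~ s0^2 * F(df, d0).  On the log scale the moments involve
    digamma/trigamma functions; d0 solves trigamma(d0/2) = Var[e] where
    e_g = log s2_g - digamma(df/2) + log(df/2).  If the empirical variance
    of e does not exceed trigamma(df/2), the prior is degenerate (d0 = inf).

    Returns (d0, s0_sq).
    """
    s2 = np.asarray(s2, float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least 2 positive variances to fit the prior")
    z = np.log(s2)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(s2.mean())
    return d0, s0_sq


def squeeze_var(s2: np.ndarray, df: float, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior (shrunken) variances s~^2 = (d0 s0^2 + df s^2) / (d0 + df)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s0_sq)
    return (d0 * s0_sq + df * np.asarray(s2, float)) / (d0 + df)


def _tmixture(
    t_abs: np.ndarray,
    u: float,
    df_total: float,
    p1: float,
    v0_lim: tuple[float, float] | None,
) -> float:
    """Estimate v0 by matching the upper tail of |t| to the DE component.

    The ceil(p1/2 * G) largest |t| values are treated as draws from the
    alternative; each implies a value of v0 through the scaled-t tail
    quantile, and the (optionally clamped) values are averaged.
    """
    ngenes = t_abs.size
    ntarget = int(np.ceil(p1 / 2.0 * ngenes))
    if ntarget < 1:
        return 0.0
    p = max(ntarget / ngenes, p1)
    order = np.argsort(t_abs)[::-1][:ntarget]
    tstat = t_abs[order]
    r = np.arange(1, ntarget + 1, dtype=float)
    p0 = 2.0 * stats.t.sf(tstat, df_total)
    ptarget = ((r - 0.5) / ngenes - (1.0 - p) * p0) / p
    v0 = np.zeros(ntarget)
    pos = ptarget > p0
    if pos.any():
        qtarget = stats.t.isf(ptarget[pos] / 2.0, df_total)
        v0[pos] = u * ((tstat[pos] / qtarget) ** 2 - 1.0)
    if v0_lim is not None:
        v0 = np.clip(v0, v0_lim[0], v0_lim[1])
    return float(max(v0.mean(), 0.0))


def _pooled_df_total(fits: GeneFits, d0: float) -> float:
    """Total df for the moderated t, capped at the pooled residual df.

    The cap (sum of residual df over genes) keeps the reference distribution
    finite even when the variance prior is degenerate (d0 = inf).
    """
    pooled = fits.df_residual * len(fits)
    return float(min(fits.df_residual + d0, pooled))


def estimate_ebayes_priors(
    fits: GeneFits,
    p1: float = 0.01,
    stdev_coef_lim: tuple[float, float] | None = (0.1, 4.0),
) -> EBayesParams:
    """Fit all hyperparameters of the hierarchical model from the gene fits.

    d0 and s0^2 come from moment-matching the scaled-F prior on the residual
    variances; v0 comes from the tail of the moderated-t distribution.  Each
    tail gene's implied v0 is clamped to ``stdev_coef_lim**2 / s0_sq`` before
    averaging (the conventional stabilization bounding the prior standard
    deviation of a DE log fold change).  Genes with s2 = 0 are excluded from
    prior estimation.
    """
    positive = fits.s2 > 0
    if positive.sum() < 20:
        raise ValueError(
            f"only {int(positive.sum())} genes with positive residual variance; "
            "need at least 20 to estimate empirical-Bayes priors"
        )
    d0, s0_sq = fit_f_dist(fits.s2[positive], fits.df_residual)
    s_tilde2 = squeeze_var(fits.s2[positive], fits.df_residual, d0, s0_sq)
    t_mod = np.abs(fits.beta_hat[positive]) / np.sqrt(s_tilde2 * fits.u)
    df_total = _pooled_df_total(fits, d0)
    v0_lim = None
    if stdev_coef_lim is not None:
        v0_lim = (stdev_coef_lim[0] ** 2 / s0_sq, stdev_coef_lim[1] ** 2 / s0_sq)
    v0 = _tmixture(t_mod, fits.u, df_total, p1, v0_lim)
    return EBayesParams(d0=d0, s0_sq=s0_sq, p1=p1, v0=v0)


# ---------------------------------------------------------------------------
# moderated statistics and the posterior probability of DE
# ---------------------------------------------------------------------------

def moderated_stats(
    fits: GeneFits, priors: EBayesParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t-statistics and two-sided p-values.

    Returns (t_mod, p_value, flagged) where flagged marks genes whose
    shrunken variance is exactly zero (t forced to +-inf, p to 0).
    """
    s_tilde2 = squeeze_var(fits.s2, fits.df_residual, priors.d0, priors.s0_sq)
    flagged = s_tilde2 == 0
    denom = np.sqrt(np.where(flagged, 1.0, s_tilde2) * fits.u)
    t_mod = fits.beta_hat / denom
    df_total = _pooled_df_total(fits, priors.d0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} genes with zero shrunken variance; "
            "t set to +-inf and p to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t_mod = np.where(flagged, np.sign(fits.beta_hat) * np.inf, t_mod)
        p = np.where(flagged, 0.0, p)
    return t_mod, p, flagged


def lods_posterior(
    t_mod: np.ndarray, fits: GeneFits, priors: EBayesParams
) -> tuple[np.ndarray, np.ndarray]:
    """Log posterior odds of differential expression, B, and logistic(B).

    B = logit(p1) - (1/2) log r + ((d0 + d_g + 1)/2) *
        log((t^2 + d0 + d_g) / (t^2 / r + d0 + d_g)),   r = (u + v0) / u.
    In the d0 -> inf limit the kernel becomes t^2 (1 - 1/r) / 2.
    """
    prior_lo = float(np.log(priors.p1 / (1.0 - priors.p1)))
    if priors.v0 == 0:
        warnings.warn(
            "v0 = 0: degenerate DE prior, B equals the prior log-odds for every gene",
            RuntimeWarning,
            stacklevel=2,
        )
        b = np.full(len(fits), prior_lo)
        return b, 1.0 / (1.0 + np.exp(-b))
    r = (fits.u + priors.v0) / fits.u
    t2 = np.asarray(t_mod, float) ** 2
    df_total = _pooled_df_total(fits, priors.d0)
    if priors.d0 > 1e6:
        # degenerate variance prior: normal-limit quadratic kernel
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    b = prior_lo - 0.5 * np.log(r) + kernel
    posterior = special.expit(b)
    return b, posterior


# ---------------------------------------------------------------------------
# one-call contrast runner
# ---------------------------------------------------------------------------

def run_contrast(
    counts: CountMatrix,
    condition_pair: tuple[str, str],
    covariates: tuple[str, ...] = ("batch",),
    source: str | None = None,
    p1: float = 0.01,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
    prior_count: float = 0.5,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> DEResult:
    """Full differential-expression analysis for one condition contrast.

    Composes filtering, TMM normalization, log2-CPM, gene-wise OLS with
    condition + covariate design, empirical-Bayes moderation and the
    posterior probability of DE.  ``condition_pair = (a, b)`` estimates
    a minus b on the log2 scale.  When ``source`` is given, only samples of
    that tumor source are analyzed (each line independently).
    """
    cond_a, cond_b = condition_pair
    sub = counts
    if source is not None:
        keep = counts.samples["source"] == source
        if not keep.any():
            raise ValueError(f"no samples with source {source!r}")
        sub = counts.subset_samples(counts.sample_ids[keep.to_numpy()])
    for cond in condition_pair:
        n = int((sub.samples["condition"] == cond).sum())
        if n < 2:
            raise ValueError(f"condition {cond!r} has {n} samples; need at least 2")
    filtered = filter_low_expression(sub, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered, trim_m=trim_m, trim_a=trim_a)
    expr = log_cpm(filtered, factors, prior_count=prior_count)
    usable_cov = tuple(c for c in covariates if sub.samples[c].nunique() > 1)
    design = build_design(expr.samples, covariates=usable_cov)
    contrast = make_contrast(design, cond_a, cond_b)
    name = f"{cond_a}_vs_{cond_b}"
    fits = fit_linear_models(expr, design, contrast, contrast_name=name)
    priors = estimate_ebayes_priors(fits, p1=p1)
    t_mod, p, flagged = moderated_stats(fits, priors)
    b, posterior = lods_posterior(t_mod, fits, priors)
    table = pd.DataFrame(
        {
            "lfc": fits.beta_hat,
            "t": t_mod,
            "p_value": p,
            "B": b,
            "posterior": posterior,
            "flagged": flagged,
        },
        index=fits.gene_ids,
    )
    logger.info(
        "contrast %s: %d genes, d0=%.3g, s0^2=%.3g, v0=%.3g, p1=%.3g",
        name, len(table), priors.d0, priors.s0_sq, priors.v0, priors.p1,
    )
    return DEResult(
        table=table,
        contrast=name,
        priors=priors,
        info={
            "source": source,
            "n_genes": len(table),
            "covariates": list(usable_cov),
            "tmm_reference": factors.ref_sample,
        },
    )
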