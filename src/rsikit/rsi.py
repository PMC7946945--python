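"""Response similarity index (RSI) and concordance summaries.

For a gene measured in two contrasts (each summarized by a posterior
probability of differential expression and a log2 fold change), the RSI is
the joint posterior probability of differential expression signed by the
sign of the product of the two log fold changes:

    rsi_g = sign(lfc1_g * lfc2_g) * posterior1_g * posterior2_g

Values near +1 flag confident joint change in the same direction
(concordance), near -1 confident change in opposite directions
(discordance), near 0 lack of joint change.  This operationalizes an
intersection-union test: a gene counts as jointly differentially expressed
only if it is differentially expressed in both contrasts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DEResult

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.9
REPORT_TAUS = (0.5, 0.8, 0.9, 0.95)


@dataclass
class RSITable:
    """Per-gene RSI for an ordered pair of contrasts.

    ``table`` is indexed by gene id with columns rsi, posterior_1,
    posterior_2, lfc_1, lfc_2.
    """

    table: pd.DataFrame
    contrast_1: str
    contrast_2: str

    @property
    def rsi(self) -> pd.Series:
        return self.table["rsi"]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


@dataclass
class ConcordanceSummary:
    """Counts of concordant/discordant genes at a threshold tau, the
    asymmetry (n_con - n_dis)/(n_con + n_dis), and a histogram of RSI."""

    tau: float
    n_concordant: int
    n_discordant: int
    asymmetry: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    counts_by_tau: dict = field(default_factory=dict)


def compute_rsi(a: DEResult, b: DEResult) -> RSITable:
    """RSI over the shared gene universe of two DE results (symmetric)."""
    for res in (a, b):
        if res.table.index.duplicated().any():
            raise ValueError("duplicated gene ids in DE result")
    shared = a.gene_ids.intersection(b.gene_ids)
    if len(shared) == 0:
        raise ValueError("DE results share no genes")
    dropped = (len(a.gene_ids) - len(shared)) + (len(b.gene_ids) - len(shared))
    if dropped:
        logger.info("compute_rsi: dropped %d non-shared gene entries", dropped)
    ta = a.table.loc[shared]
    tb = b.table.loc[shared]
    sign = np.sign(ta["lfc"].to_numpy() * tb["lfc"].to_numpy())
    rsi = sign * ta["posterior"].to_numpy() * tb["posterior"].to_numpy()
    table = pd.DataFrame(
        {
            "rsi": rsi,
            "posterior_1": ta["posterior"].to_numpy(),
            "posterior_2": tb["posterior"].to_numpy(),
            "lfc_1": ta["lfc"].to_numpy(),
            "lfc_2": tb["lfc"].to_numpy(),
        },
        index=shared,
    )
    return RSITable(table=table, contrast_1=a.contrast, contrast_2=b.contrast)


def concordance_summary(
    rsi: RSITable,
    tau: float = DEFAULT_TAU,
    n_bins: int = 40,
    report_taus: tuple[float, ...] = REPORT_TAUS,
) -> ConcordanceSummary:
    """Concordant/discordant gene counts at |rsi| >= tau plus an RSI histogram."""
    if not (0 < tau < 1):
        raise ValueError("tau must lie in (0, 1)")
    values = rsi.rsi.to_numpy()
    n_con = int((values >= tau).sum())
    n_dis = int((values <= -tau).sum())
    total = n_con + n_dis
    asymmetry = 0.0 if total == 0 else (n_con - n_dis) / total
    counts, edges = np.histogram(values, bins=n_bins, range=(-1.0, 1.0))
    by_tau = {
        t: {
            "n_concordant": int((values >= t).sum()),
            "n_discordant": int((values <= -t).sum()),
        }
        for t in report_taus
    }
    return ConcordanceSummary(
        tau=tau,
        n_concordant=n_con,
        n_discordant=n_dis,
        asymmetry=asymmetry,
        hist_edges=edges,
        hist_counts=counts,
        counts_by_tau=by_tau,
    )


def compare_models(
    reference: DEResult,
    candidates: dict[str, DEResult],
    tau: float = DEFAULT_TAU,
) -> pd.DataFrame:
    """Rank candidate model systems by concordance with a reference contrast.

    For each candidate the RSI against the reference is computed and the
    number and proportion of concordant genes at ``tau`` recorded.  Ranking
    is by concordant count, ties broken by proportion then name.
    """
    if not candidates:
        raise ValueError("need at least one candidate model")
    rows = []
    for name, cand in candidates.items():
        table = compute_rsi(reference, cand)
        summ = concordance_summary(table, tau=tau)
        n_genes = len(table.gene_ids)
        rows.append(
            {
                "model": name,
                "n_genes": n_genes,
                "n_concordant": summ.n_concordant,
                "n_discordant": summ.n_discordant,
                "prop_concordant": summ.n_concordant / n_genes,
                "asymmetry": summ.asymmetry,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        by=["n_concordant", "prop_concordant", "model"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("model")
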