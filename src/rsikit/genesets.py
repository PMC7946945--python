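"""Gene-set collections (GMT files) and rank-based set enrichment on RSI.

The set-level concordance test ranks all genes by RSI and asks, for each
set, whether its members sit unusually high (concordant enrichment) or
unusually low (discordant enrichment) in that ranking, via a Wilcoxon
rank-sum comparison of member vs non-member ranks.  A concordance curve
counts, per candidate model, how many sets are concordantly enriched at
each p-value threshold, which is how model systems are compared at the
pathway level.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DEResult, ExpressionMatrix
from .preprocess import row_zscore
from .rsi import RSITable, compute_rsi

logger = logging.getLogger(__name__)

EXACT_GROUP_MAX = 25  # both groups at or below this -> exact null distribution
ENUMERATION_MAX = 200_000  # largest C(n, k) we fully enumerate (handles ties)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Drop members outside ``universe`` (and sets left empty)."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inside = [m for m in members if m in uni]
            if inside:
                kept[name] = inside
        return GeneSetCollection(kept, dict(self.descriptions))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (tab-separated: name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: malformed GMT line (fewer than 3 fields)")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                logger.info(
                    "set %s: removed %d duplicate members", name, len(members) - len(deduped)
                )
            if not deduped:
                logger.info("set %s: empty after parsing, dropped", name)
                continue
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# rank-sum machinery
# ---------------------------------------------------------------------------

def _enumerate_rank_p(ranks: np.ndarray, n_members: int, observed: float) -> tuple[float, float]:
    """Exact one-sided p-values for the member rank sum by full enumeration.

    Enumerates every C(n, k) assignment of which genes form the set,
    conditional on the observed (mid-)ranks, so ties are handled exactly.
    Returns (p_up, p_down) = P(sum >= obs), P(sum <= obs).
    """
    n = ranks.size
    total = math.comb(n, n_members)
    ge = le = 0
    for combo in combinations(range(n), n_members):
        s = ranks[list(combo)].sum()
        if s >= observed - 1e-9:
            ge += 1
        if s <= observed + 1e-9:
            le += 1
    return ge / total, le / total


def _rank_sum_pvalues(values: np.ndarray, member_mask: np.ndarray) -> tuple[float, float, float]:
    """One-sided Wilcoxon rank-sum p-values for members vs non-members.

    Returns (p_up, p_down, u_statistic).  Uses the exact null distribution
    unless both groups exceed 25 observations (full enumeration when ties
    are present and C(n, k) is small enough), and the tie-corrected normal
    approximation with continuity correction otherwise.
    """
    m = values[member_mask]
    rest = values[~member_mask]
    n1, n2 = m.size, rest.size
    has_ties = np.unique(values).size < values.size
    exact_ok = n1 <= EXACT_GROUP_MAX or n2 <= EXACT_GROUP_MAX
    if exact_ok and has_ties and math.comb(n1 + n2, min(n1, n2)) <= ENUMERATION_MAX:
        ranks = stats.rankdata(values)
        observed = ranks[member_mask].sum()
        p_up, p_down = _enumerate_rank_p(ranks, n1, observed)
        u = observed - n1 * (n1 + 1) / 2.0
        return p_up, p_down, float(u)
    method = "exact" if (exact_ok and not has_ties) else "asymptotic"
    up = stats.mannwhitneyu(m, rest, alternative="greater", method=method)
    down = stats.mannwhitneyu(m, rest, alternative="less", method=method)
    return float(up.pvalue), float(down.pvalue), float(up.statistic)


def rank_set_test(
    rsi: RSITable,
    sets: GeneSetCollection,
    min_size: int = 5,
) -> pd.DataFrame:
    """Rank-based enrichment of each gene set in the RSI ranking.

    For every set whose overlap with the RSI gene universe reaches
    ``min_size``, tests whether member RSI values rank high (p_up;
    concordant direction ``+``) or low (p_down; discordant ``-``).
    Returns a DataFrame indexed by set name with columns size, direction,
    p_up, p_down, p, statistic.
    """
    values = rsi.rsi.to_numpy()
    index = {g: i for i, g in enumerate(rsi.gene_ids)}
    rows = []
    for name, members in sets.sets.items():
        idx = [index[g] for g in members if g in index]
        if len(idx) < min_size:
            logger.info(
                "set %s: overlap %d below min_size %d, skipped", name, len(idx), min_size
            )
            continue
        if len(idx) == len(values):
            logger.info("set %s covers the whole universe, skipped", name)
            continue
        mask = np.zeros(values.size, dtype=bool)
        mask[idx] = True
        p_up, p_down, u = _rank_sum_pvalues(values, mask)
        direction = "+" if p_up <= p_down else "-"
        rows.append(
            {
                "set": name,
                "size": len(idx),
                "direction": direction,
                "p_up": p_up,
                "p_down": p_down,
                "p": min(p_up, p_down),
                "statistic": u,
            }
        )
    if not rows:
        raise ValueError("no gene set reached the minimum overlap with the RSI universe")
    return pd.DataFrame(rows).set_index("set")


def top_sets(results: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top ``k`` concordant and discordant sets by ascending p (name tie-break)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    res = results.reset_index()
    con = res[res["direction"] == "+"].sort_values(
        by=["p_up", "set"], kind="mergesort"
    )
    dis = res[res["direction"] == "-"].sort_values(
        by=["p_down", "set"], kind="mergesort"
    )
    return con.head(k).set_index("set"), dis.head(k).set_index("set")


def concordance_curve(
    reference: DEResult,
    candidates: dict[str, DEResult],
    sets: GeneSetCollection,
    thresholds: np.ndarray | None = None,
    min_size: int = 5,
) -> pd.DataFrame:
    """Number of concordantly enriched sets per candidate at each p threshold.

    A set counts as concordant at threshold t when its direction is ``+``
    and its one-sided p_up <= t.  The symmetric discordant counts are also
    returned.  Rows are thresholds; columns are ``<model>_concordant`` and
    ``<model>_discordant``.
    """
    if thresholds is None:
        thresholds = np.linspace(0.05 / 200, 0.05, 200)
    thresholds = np.asarray(thresholds, float)
    if thresholds.min() <= 0 or thresholds.max() > 0.05 + 1e-12:
        warnings.warn(
            "thresholds outside the conventional (0, 0.05] range", RuntimeWarning,
            stacklevel=2,
        )
    cols = {}
    for name, cand in candidates.items():
        table = compute_rsi(reference, cand)
        res = rank_set_test(table, sets, min_size=min_size)
        con_p = res.loc[res["direction"] == "+", "p_up"].to_numpy()
        dis_p = res.loc[res["direction"] == "-", "p_down"].to_numpy()
        cols[f"{name}_concordant"] = (con_p[None, :] <= thresholds[:, None]).sum(axis=1)
        cols[f"{name}_discordant"] = (dis_p[None, :] <= thresholds[:, None]).sum(axis=1)
    return pd.DataFrame(cols, index=pd.Index(thresholds, name="p_threshold"))


def sample_set_score(expr: ExpressionMatrix, sets: GeneSetCollection) -> pd.DataFrame:
    """Per-sample set scores: mean of row-z-scored expression over members.

    A deliberately simple summary for pathway-level heatmaps; sets with no
    overlap with the expression universe are skipped.
    """
    z = row_zscore(expr)
    uni = set(expr.gene_ids)
    rows = {}
    for name, members in sets.sets.items():
        inside = [m for m in members if m in uni]
        if not inside:
            logger.info("set %s: no overlap with expression matrix, skipped", name)
            continue
        rows[name] = z.values.loc[inside].mean(axis=0)
    if not rows:
        raise ValueError("no gene set overlaps the expression matrix")
    return pd.DataFrame(rows).T
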