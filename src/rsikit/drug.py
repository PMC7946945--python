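"""Drug-response statistics for luciferase growth assays.

A standard curve (known cell counts vs luminescence) calibrates luciferase
readings to cell-number estimates; treatment groups are compared to control
by one-way ANOVA followed by per-group-vs-control tests corrected with the
Benjamini-Krieger-Yekutieli two-stage step-up FDR procedure, reported as
q-values.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurve:
    """Linear calibration luminescence = intercept + slope * cells."""

    slope: float
    intercept: float
    r_squared: float
    usable: bool
    points: pd.DataFrame | None = None


def fit_standard_curve(points: pd.DataFrame) -> StandardCurve:
    """Ordinary least-squares line through (cells, luminescence) points.

    A non-positive slope or fewer than 2 distinct cell counts makes the
    curve unusable; R^2 below 0.9 triggers a warning.
    """
    cells = points["cells"].to_numpy(float)
    lum = points["luminescence"].to_numpy(float)
    if np.unique(cells).size < 2:
        raise ValueError("standard curve needs at least 2 distinct cell counts")
    fit = stats.linregress(cells, lum)
    r2 = float(fit.rvalue**2)
    usable = fit.slope > 0
    if not usable:
        warnings.warn(
            "standard curve has non-positive slope; flagged unusable",
            RuntimeWarning,
            stacklevel=2,
        )
    elif r2 < 0.9:
        warnings.warn(f"standard curve R^2 = {r2:.3f} < 0.9", RuntimeWarning, stacklevel=2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        usable=usable,
        points=points.copy(),
    )


def estimate_cell_number(assay: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Invert the standard curve: cells = (luminescence - intercept) / slope.

    Negative estimates are floored at 0 and flagged.  Returns the assay
    table with added ``cells`` and ``floored`` columns.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero")
    if not curve.usable:
        raise ValueError("standard curve flagged unusable (non-positive slope)")
    cells = (assay["luminescence"].to_numpy(float) - curve.intercept) / curve.slope
    floored = cells < 0
    cells = np.where(floored, 0.0, cells)
    out = assay.copy()
    out["cells"] = cells
    out["floored"] = floored
    return out


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float, bool]:
    """Classical one-way ANOVA; returns (F, p, degenerate_flag).

    Degenerate inputs: identical values everywhere -> F = 0, p = 1 (flagged);
    zero within-group variance with unequal means -> F = inf, p = 0 (flagged).
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    groups = [np.asarray(g, float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    within_ss = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if within_ss == 0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0, True
        return np.inf, 0.0, True
    f, p = stats.f_oneway(*groups)
    return float(f), float(p), False


def _bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg linear step-up rejection mask at level alpha."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    crit = alpha * np.arange(1, m + 1) / m
    below = sorted_p <= crit
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0]))
        reject[order[: k + 1]] = True
    return reject


def bky_rejections(p_values: np.ndarray, q_level: float) -> np.ndarray:
    """Two-stage step-up rejection set at FDR level ``q_level``.

    Stage 1: linear step-up at q' = q/(1+q), giving r1 rejections.  If
    r1 = 0 nothing is rejected; if r1 = m everything is.  Otherwise the
    number of true nulls is estimated as m - r1 and stage 2 re-runs the
    step-up at level q' * m / (m - r1).
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q_level < 1):
        raise ValueError("q_level must lie in (0, 1)")
    m = p.size
    q_prime = q_level / (1.0 + q_level)
    stage1 = _bh_stepup(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return stage1
    if r1 == m:
        return stage1
    return _bh_stepup(p, q_prime * m / (m - r1))


def bky_two_stage_fdr(
    p_values: np.ndarray, q_level: float = 0.05, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Per-hypothesis q-values and the rejection set at ``q_level``.

    The two-stage procedure defines rejections, not q-values; the q-value of
    a hypothesis is therefore defined as the smallest FDR level at which it
    is rejected, found by bisection (the rejection set grows monotonically
    with the level).  Returns (q_values, rejected_at_q_level).
    """
    p = np.asarray(p_values, float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    rejected = bky_rejections(p, q_level)
    rejectable = bky_rejections(p, 1.0 - 1e-12)
    q_values = np.ones(p.size)
    for i in range(p.size):
        if not rejectable[i]:
            q_values[i] = 1.0
            continue
        lo, hi = 0.0, 1.0 - 1e-12
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if bky_rejections(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        q_values[i] = hi
    return q_values, rejected


@dataclass
class GroupComparison:
    """Per-group cell-number summaries and FDR-corrected contrasts vs control."""

    group_stats: pd.DataFrame  # mean, ci_low, ci_high, n per group
    anova_f: float
    anova_p: float
    anova_degenerate: bool
    vs_control: pd.DataFrame  # p_value, q_value, rejected per non-control group
    control: str = "control"
    q_level: float = 0.05
    cells: pd.DataFrame | None = field(default=None, repr=False)


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    mean = float(x.mean())
    if x.size < 2:
        return mean, np.nan, np.nan
    sem = x.std(ddof=1) / np.sqrt(x.size)
    half = float(stats.t.ppf(0.5 + level / 2.0, x.size - 1) * sem)
    return mean, mean - half, mean + half


def compare_groups(
    assay: pd.DataFrame,
    curve: StandardCurve,
    control: str = "control",
    q_level: float = 0.05,
) -> GroupComparison:
    """Full drug-response analysis of a luciferase assay table.

    ``assay`` needs columns group and luminescence (well_id/run optional).
    Estimates per-well cell numbers, summarizes each group with a t-based
    95% CI, runs one-way ANOVA over all groups, then pooled-variance t tests
    of each treated group against control corrected by the two-stage FDR.
    """
    cells = estimate_cell_number(assay, curve)
    if control not in set(cells["group"]):
        raise ValueError(f"control group {control!r} missing from assay")
    names = list(dict.fromkeys(cells["group"]))
    arrays = {g: cells.loc[cells["group"] == g, "cells"].to_numpy(float) for g in names}
    stats_rows = []
    for g in names:
        mean, lo, hi = _mean_ci(arrays[g])
        stats_rows.append(
            {"group": g, "n": arrays[g].size, "mean": mean, "ci_low": lo, "ci_high": hi}
        )
    f, p_anova, degenerate = anova_oneway([arrays[g] for g in names])
    treated = [g for g in names if g != control]
    p_vs_control = np.array(
        [
            stats.ttest_ind(arrays[g], arrays[control], equal_var=True).pvalue
            for g in treated
        ]
    )
    q_values, rejected = bky_two_stage_fdr(p_vs_control, q_level=q_level)
    vs_control = pd.DataFrame(
        {"p_value": p_vs_control, "q_value": q_values, "rejected": rejected},
        index=pd.Index(treated, name="group"),
    )
    return GroupComparison(
        group_stats=pd.DataFrame(stats_rows).set_index("group"),
        anova_f=f,
        anova_p=p_anova,
        anova_degenerate=degenerate,
        vs_control=vs_control,
        control=control,
        q_level=q_level,
        cells=cells,
    )
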