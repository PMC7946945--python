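"""Synthetic multi-condition RNA-seq studies with planted ground truth.

Emulates the design the concordance analysis assumes: for each tumor source,
n samples per growth condition (2D static culture, the perfused
microenvironment system, mouse xenograft), negative-binomial gene counts
(variance = mu + phi * mu^2, gene-wise dispersion phi log-normal) with
planted per-gene effects in two contrasts sharing the 2D baseline:

* concordant_up / concordant_down - same-sign log2 fold change in both
  contrasts;
* discordant - opposite signs;
* c1_only / c2_only - changed in a single contrast;
* null - no change.

A batch covariate (additive log2 offset for half the samples of each
condition) and log-normal library-size factors provide nuisance structure
for the design-matrix and TMM code paths.  Companion generators produce
gene-set collections with planted enrichment, patient-like cohort matrices
derived from the xenograft condition, and luciferase drug-assay tables with
a known standard curve.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .genesets import GeneSetCollection

GENE_CLASSES = ("concordant_up", "concordant_down", "discordant", "c1_only", "c2_only", "null")

DEFAULT_PROPORTIONS = {
    "concordant_up": 0.15,
    "concordant_down": 0.15,
    "discordant": 0.05,
    "c1_only": 0.05,
    "c2_only": 0.05,
    "null": 0.55,
}


@dataclass
class SimulationConfig:
    """Parameters of the count-study generator.

    Defaults mirror the emulated study design: three growth conditions with
    n = 6 samples each, two contrasts sharing the 2D-static baseline, and a
    transcriptome in which concordant responses outnumber discordant ones.
    """

    n_genes: int = 2000
    n_per_group: int = 6
    conditions: tuple[str, ...] = ("static2D", "TMES", "xenograft")
    sources: tuple[str, ...] = ("line1",)
    baseline_logmean_params: tuple[float, float] = (5.0, 2.0)  # log2 scale
    dispersion_params: tuple[float, float] = (math.log(0.1), 0.5)  # ln phi
    effect_size_range: tuple[float, float] = (1.0, 3.0)  # |log2 FC|
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    batch_sd: float = 0.5
    library_size_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2 (variance inestimable)")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.conditions) < 2:
            raise ValueError("need at least 2 conditions")
        if self.baseline_logmean_params[1] <= 0 or self.dispersion_params[1] <= 0:
            raise ValueError("scale parameters must be positive")
        lo, hi = self.effect_size_range
        if not (0 < lo <= hi):
            raise ValueError("effect_size_range must satisfy 0 < lo <= hi")
        if self.batch_sd < 0 or self.library_size_sd < 0:
            raise ValueError("batch_sd and library_size_sd must be non-negative")


@dataclass
class PlantedTruth:
    """Per-gene simulation labels for parameter-recovery tests."""

    gene_class: pd.Series  # label per gene
    lfc_contrast1: pd.Series  # contrast 1 (e.g. TMES vs 2D), log2
    lfc_contrast2: pd.Series  # contrast 2 (e.g. xenograft vs 2D), log2
    baseline_log2: pd.Series
    dispersion: pd.Series
    enriched_sets: dict[str, str] = field(default_factory=dict)  # set -> "+"/"-"

    def __post_init__(self) -> None:
        null = self.gene_class == "null"
        if ((self.lfc_contrast1[null] != 0) | (self.lfc_contrast2[null] != 0)).any():
            raise ValueError("null genes must have zero planted fold changes")

    @property
    def gene_ids(self) -> pd.Index:
        return self.gene_class.index


@dataclass
class SyntheticStudy:
    counts: CountMatrix
    truth: PlantedTruth
    sets: GeneSetCollection | None = None

    def __post_init__(self) -> None:
        if not self.counts.gene_ids.equals(self.truth.gene_ids):
            raise ValueError("counts and truth cover different genes")
        if self.sets is not None:
            uni = set(self.counts.gene_ids)
            for name, members in self.sets.sets.items():
                outside = [m for m in members if m not in uni]
                if outside:
                    raise ValueError(f"set {name!r} has members outside the study: {outside[:3]}")


def _assign_classes(n_genes: int, proportions: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    counts = {c: int(round(proportions.get(c, 0.0) * n_genes)) for c in GENE_CLASSES}
    # absorb rounding drift into the null class
    drift = n_genes - sum(counts.values())
    counts["null"] += drift
    if counts["null"] < 0:
        raise ValueError("class proportions leave no room for null genes")
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    return rng.permutation(labels)


def _planted_lfcs(
    classes: np.ndarray, effect_range: tuple[float, float], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = classes.size
    lo, hi = effect_range
    mag1 = rng.uniform(lo, hi, size=n)
    mag2 = rng.uniform(lo, hi, size=n)
    flip = rng.integers(0, 2, size=n) * 2 - 1  # random +-1 per gene
    lfc1 = np.zeros(n)
    lfc2 = np.zeros(n)
    up = classes == "concordant_up"
    dn = classes == "concordant_down"
    dis = classes == "discordant"
    c1 = classes == "c1_only"
    c2 = classes == "c2_only"
    lfc1[up], lfc2[up] = mag1[up], mag2[up]
    lfc1[dn], lfc2[dn] = -mag1[dn], -mag2[dn]
    lfc1[dis], lfc2[dis] = flip[dis] * mag1[dis], -flip[dis] * mag2[dis]
    lfc1[c1] = flip[c1] * mag1[c1]
    lfc2[c2] = flip[c2] * mag2[c2]
    return lfc1, lfc2


def _nb_counts(mu: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws with variance mu + phi * mu^2 (phi per gene)."""
    r = 1.0 / phi[:, None]
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def generate_counts_from_lfc(
    lfc_by_condition: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    baseline: np.ndarray | None = None,
    dispersion: np.ndarray | None = None,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Low-level count sampler given a genes x conditions log2-effect matrix.

    Returns (counts, baseline_log2, dispersion).  The batch covariate splits
    every (source, condition) group in half, with a gene-wise N(0, batch_sd)
    log2 offset applied to the second half.
    """
    n_genes = lfc_by_condition.shape[0]
    conditions = list(lfc_by_condition.columns)
    if baseline is None:
        b_mean, b_sd = config.baseline_logmean_params
        baseline = rng.normal(b_mean, b_sd, size=n_genes)
    if dispersion is None:
        d_mean, d_sd = config.dispersion_params
        dispersion = np.exp(rng.normal(d_mean, d_sd, size=n_genes))
    batch_effect = rng.normal(0.0, config.batch_sd, size=n_genes) if config.batch_sd else np.zeros(n_genes)

    blocks = []
    meta_rows = []
    half = config.n_per_group // 2
    for source in config.sources:
        for cond in conditions:
            log2_mu = baseline + lfc_by_condition[cond].to_numpy()
            for i in range(config.n_per_group):
                batch = "b1" if i < config.n_per_group - half else "b2"
                lib_factor = (
                    np.exp(rng.normal(0.0, config.library_size_sd))
                    if config.library_size_sd
                    else 1.0
                )
                mu = 2.0 ** (log2_mu + (batch_effect if batch == "b2" else 0.0)) * lib_factor
                blocks.append(_nb_counts(mu[:, None], dispersion, rng)[:, 0])
                meta_rows.append(
                    {
                        "sample_id": f"{source}_{cond}_{i + 1}",
                        "source": source,
                        "condition": cond,
                        "batch": batch,
                    }
                )
    gene_ids = lfc_by_condition.index
    values = pd.DataFrame(
        np.column_stack(blocks),
        index=gene_ids,
        columns=[r["sample_id"] for r in meta_rows],
    )
    counts = CountMatrix(values, pd.DataFrame(meta_rows))
    return counts, baseline, dispersion


def generate_counts(config: SimulationConfig) -> SyntheticStudy:
    """Generate a full planted count study; deterministic given the seed.

    Contrast 1 is conditions[1] vs conditions[0], contrast 2 is
    conditions[2] vs conditions[0] (when a third condition exists).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = pd.Index([f"g{i + 1:05d}" for i in range(config.n_genes)], name="gene")
    classes = _assign_classes(config.n_genes, config.class_proportions, rng)
    lfc1, lfc2 = _planted_lfcs(classes, config.effect_size_range, rng)
    effects = {config.conditions[0]: np.zeros(config.n_genes)}
    if len(config.conditions) > 1:
        effects[config.conditions[1]] = lfc1
    if len(config.conditions) > 2:
        effects[config.conditions[2]] = lfc2
    for extra in config.conditions[3:]:
        effects[extra] = np.zeros(config.n_genes)
    lfc_df = pd.DataFrame(effects, index=gene_ids)[list(config.conditions)]
    counts, baseline, dispersion = generate_counts_from_lfc(lfc_df, config, rng)
    truth = PlantedTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        lfc_contrast1=pd.Series(lfc1, index=gene_ids, name="lfc_contrast1"),
        lfc_contrast2=pd.Series(lfc2, index=gene_ids, name="lfc_contrast2"),
        baseline_log2=pd.Series(baseline, index=gene_ids, name="baseline_log2"),
        dispersion=pd.Series(dispersion, index=gene_ids, name="dispersion"),
    )
    return SyntheticStudy(counts=counts, truth=truth)


def generate_gene_sets(
    truth: PlantedTruth,
    n_sets: int = 50,
    set_size: int = 50,
    n_enriched: int = 5,
    purity: float = 0.8,
    seed: int = 0,
    kind: str = "concordant",
) -> GeneSetCollection:
    """Random gene sets, some enriched for planted concordant (or discordant)
    genes at the given purity.  Enrichment labels are recorded in
    ``truth.enriched_sets`` ("+" for concordant, "-" for discordant)."""
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    if not (0 <= purity <= 1):
        raise ValueError("purity must lie in [0, 1]")
    genes = truth.gene_ids.to_numpy()
    if set_size > genes.size:
        raise ValueError("set_size exceeds the number of genes")
    if kind == "concordant":
        pool_mask = truth.gene_class.isin(["concordant_up", "concordant_down"]).to_numpy()
        label = "+"
    elif kind == "discordant":
        pool_mask = (truth.gene_class == "discordant").to_numpy()
        label = "-"
    else:
        raise ValueError("kind must be 'concordant' or 'discordant'")
    pool = genes[pool_mask]
    rng = np.random.default_rng(seed)
    n_planted = int(round(purity * set_size))
    if n_enriched > 0 and n_planted > pool.size:
        raise ValueError(
            f"not enough {kind} genes ({pool.size}) for {n_planted} planted members"
        )
    sets: dict[str, list[str]] = {}
    for j in range(n_sets):
        name = f"set{j + 1:03d}"
        if j < n_enriched:
            planted = rng.choice(pool, size=n_planted, replace=False)
            remainder_pool = np.setdiff1d(genes, planted, assume_unique=False)
            filler = rng.choice(remainder_pool, size=set_size - n_planted, replace=False)
            members = np.concatenate([planted, filler])
            truth.enriched_sets[name] = label
        else:
            members = rng.choice(genes, size=set_size, replace=False)
            truth.enriched_sets.setdefault(name, "none")
        sets[name] = sorted(members.tolist())
    return GeneSetCollection(sets, {name: "synthetic gene set" for name in sets})


def generate_cohort(
    truth: PlantedTruth,
    n_patients: int = 8,
    patient_noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-like log2-expression matrix derived from the xenograft state.

    Each patient column equals the xenograft-condition mean log2 profile
    (baseline + contrast-2 effect) plus gene-wise N(0, patient_noise_sd)
    heterogeneity.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if patient_noise_sd < 0:
        raise ValueError("patient_noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    profile = (truth.baseline_log2 + truth.lfc_contrast2).to_numpy()
    noise = (
        rng.normal(0.0, patient_noise_sd, size=(profile.size, n_patients))
        if patient_noise_sd
        else np.zeros((profile.size, n_patients))
    )
    cols = [f"patient_{i + 1}" for i in range(n_patients)]
    return pd.DataFrame(profile[:, None] + noise, index=truth.gene_ids, columns=cols)


@dataclass
class LuciferaseAssay:
    """Simulated luciferase assay with its noiseless standard curve."""

    wells: pd.DataFrame  # well_id, group, run, luminescence
    curve_points: pd.DataFrame  # cells, luminescence
    true_cells: pd.DataFrame  # group, cells (ground truth per group)


def generate_drug_assay(
    n_control: int = 6,
    n_treated_groups: int = 2,
    n_per_group: int = 6,
    effect_fractions: tuple[float, ...] = (0.5, 0.8),
    curve_slope: float = 50.0,
    curve_intercept: float = 1000.0,
    noise_cv: float = 0.2,
    seed: int = 0,
    control_cells: float = 10000.0,
    n_runs: int = 2,
) -> LuciferaseAssay:
    """Luciferase readings for control plus treated groups.

    True cell number of treated group j is control_cells * effect_fractions[j];
    luminescence = intercept + slope * cells, multiplied by log-normal noise
    with coefficient of variation ``noise_cv``.  Standard-curve points are
    noiseless.
    """
    if curve_slope <= 0:
        raise ValueError("curve slope must be positive")
    if len(effect_fractions) != n_treated_groups:
        raise ValueError("effect_fractions length must equal n_treated_groups")
    if any(not (0 < f <= 1) for f in effect_fractions):
        raise ValueError("effect fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0
    groups = [("control", float(control_cells), n_control)] + [
        (f"drug{j + 1}", float(control_cells) * effect_fractions[j], n_per_group)
        for j in range(n_treated_groups)
    ]
    rows = []
    well = 0
    for group, cells, n in groups:
        for i in range(n):
            noise = math.exp(rng.normal(0.0, sigma)) if sigma else 1.0
            lum = (curve_intercept + curve_slope * cells) * noise
            rows.append(
                {
                    "well_id": f"w{well + 1:03d}",
                    "group": group,
                    "run": f"run{i % n_runs + 1}",
                    "luminescence": lum,
                }
            )
            well += 1
    curve_cells = np.linspace(0.05, 1.5, 6) * control_cells
    curve_points = pd.DataFrame(
        {"cells": curve_cells, "luminescence": curve_intercept + curve_slope * curve_cells}
    )
    true_cells = pd.DataFrame(
        {"group": [g for g, _, _ in groups], "cells": [c for _, c, _ in groups]}
    )
    return LuciferaseAssay(
        wells=pd.DataFrame(rows), curve_points=curve_points, true_cells=true_cells
    )


def generate_model_comparison(
    config: SimulationConfig | None = None,
    share_a: float = 0.4,
    share_b: float = 0.1,
    effect_fraction: float = 0.3,
    seed: int = 0,
    n_blocks: int = 20,
    n_random_sets: int = 20,
    set_size: int = 20,
    purity: float = 0.8,
) -> tuple[SyntheticStudy, dict[str, np.ndarray]]:
    """Study for ranking candidate models against a reference condition.

    Conditions are (baseline, modelA, modelB, reference).  A fraction
    ``effect_fraction`` of genes carry a reference effect, partitioned into
    ``n_blocks`` co-regulated expression programs; model A reproduces the
    reference effects of ``share_a`` of the programs (model B ``share_b``),
    mirroring how a model system recapitulates whole pathways rather than
    isolated genes.  One gene set is planted per program (a ``purity``
    fraction of members from the program, remainder random), plus
    ``n_random_sets`` uniform sets, so pathway-level concordance tracks
    program-level sharing.  Returns (study, shared_masks) with a boolean
    per-gene sharing indicator per model.
    """
    if config is None:
        config = SimulationConfig(
            n_genes=1200,
            conditions=("static2D", "modelA", "modelB", "reference"),
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    n = config.n_genes
    gene_ids = pd.Index([f"g{i + 1:05d}" for i in range(n)], name="gene")
    n_effect = int(round(effect_fraction * n))
    block_size = n_effect // n_blocks
    n_effect = block_size * n_blocks
    effect_idx = rng.choice(n, size=n_effect, replace=False)
    blocks = effect_idx.reshape(n_blocks, block_size)
    effect_mask = np.zeros(n, dtype=bool)
    effect_mask[effect_idx] = True
    lo, hi = config.effect_size_range
    signs = rng.integers(0, 2, size=n) * 2 - 1
    ref_lfc = np.where(effect_mask, signs * rng.uniform(lo, hi, size=n), 0.0)
    block_order = rng.permutation(n_blocks)
    shared_blocks = {
        "modelA": set(block_order[: int(round(share_a * n_blocks))].tolist()),
        "modelB": set(block_order[: int(round(share_b * n_blocks))].tolist()),
    }
    shared_masks: dict[str, np.ndarray] = {}
    model_lfc: dict[str, np.ndarray] = {}
    for model in ("modelA", "modelB"):
        mask = np.zeros(n, dtype=bool)
        for b in shared_blocks[model]:
            mask[blocks[b]] = True
        shared_masks[model] = mask
        model_lfc[model] = np.where(mask, ref_lfc, 0.0)
    lfc_df = pd.DataFrame(
        {
            config.conditions[0]: np.zeros(n),
            "modelA": model_lfc["modelA"],
            "modelB": model_lfc["modelB"],
            "reference": ref_lfc,
        },
        index=gene_ids,
    )
    counts, baseline, dispersion = generate_counts_from_lfc(lfc_df, config, rng)
    classes = np.where(effect_mask, "c2_only", "null")  # reference effect only
    truth = PlantedTruth(
        gene_class=pd.Series(classes, index=gene_ids, name="gene_class"),
        lfc_contrast1=pd.Series(model_lfc["modelA"], index=gene_ids, name="lfc_contrast1"),
        lfc_contrast2=pd.Series(ref_lfc, index=gene_ids, name="lfc_contrast2"),
        baseline_log2=pd.Series(baseline, index=gene_ids, name="baseline_log2"),
        dispersion=pd.Series(dispersion, index=gene_ids, name="dispersion"),
    )
    n_planted = min(int(round(purity * set_size)), block_size)
    all_genes = gene_ids.to_numpy()
    sets: dict[str, list[str]] = {}
    for b in range(n_blocks):
        name = f"program{b + 1:03d}"
        planted = rng.choice(all_genes[blocks[b]], size=n_planted, replace=False)
        filler = rng.choice(
            np.setdiff1d(all_genes, planted), size=set_size - n_planted, replace=False
        )
        sets[name] = sorted(np.concatenate([planted, filler]).tolist())
        truth.enriched_sets[name] = "+"
    for j in range(n_random_sets):
        name = f"random{j + 1:03d}"
        sets[name] = sorted(rng.choice(all_genes, size=set_size, replace=False).tolist())
        truth.enriched_sets[name] = "none"
    collection = GeneSetCollection(sets, {s: "synthetic gene set" for s in sets})
    return SyntheticStudy(counts=counts, truth=truth, sets=collection), shared_masks
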