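"""End-to-end demo pipeline on synthetic data.

One configuration object drives the whole analysis: simulate (or load) a
count study, run differential expression for the two contrasts sharing the
baseline condition, compute the response similarity index and its
concordance summary, rank-based gene-set tests with top concordant and
discordant sets, the pathway-concordance curve ranking candidate models
against the reference contrast, the patient-cohort similarity report, and
the drug-response statistics.  Every stage writes a TSV intermediate and a
machine-readable JSON summary of the headline statistics; stages whose
outputs already exist can be skipped on resume.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .cohort import cohort_report
from .containers import ExpressionMatrix, plain_sample_table
from .de import run_contrast
from .drug import compare_groups, fit_standard_curve
from .genesets import concordance_curve, rank_set_test, read_gmt, top_sets, write_gmt
from .preprocess import filter_low_expression, log_cpm, tmm_factors
from .rsi import compute_rsi, concordance_summary
from .synthetic import (
    SimulationConfig,
    generate_cohort,
    generate_counts,
    generate_drug_assay,
    generate_gene_sets,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the demo pipeline needs, in one reproducible artifact."""

    out_dir: str = "rsikit_run"
    seed: int = 0
    # inputs; when counts_path is None a synthetic study is generated
    counts_path: str | None = None
    samples_path: str | None = None
    gmt_path: str | None = None
    # simulation
    n_genes: int = 2000
    n_per_group: int = 6
    conditions: tuple[str, ...] = ("static2D", "TMES", "xenograft")
    effect_size_range: tuple[float, float] = (1.0, 3.0)
    n_sets: int = 40
    set_size: int = 40
    n_enriched: int = 5
    set_purity: float = 0.8
    n_patients: int = 8
    patient_noise_sd: float = 0.5
    # stage parameters
    p1: float = 0.01
    trim_m: float = 0.30
    trim_a: float = 0.05
    min_cpm: float = 1.0
    prior_count: float = 0.5
    tau: float = 0.9
    min_set_size: int = 5
    top_k: int = 10
    n_top_cohort: int = 500
    q_level: float = 0.05
    drug_effect_fractions: tuple[float, ...] = (0.5, 0.8)
    drug_noise_cv: float = 0.2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("conditions", "effect_size_range", "drug_effect_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate_paths(self) -> None:
        for name in ("counts_path", "samples_path", "gmt_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name} does not exist: {value}")


@dataclass
class PipelineReport:
    summary: dict
    out_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_full_pipeline(config: PipelineConfig, resume: bool = False) -> PipelineReport:
    """Execute the whole concordance analysis; see module docstring."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    summary: dict = {"seed": config.seed, "parameters": config.to_dict()}

    # --- stage: counts -----------------------------------------------------
    if config.counts_path is not None:
        counts = rio.read_counts(config.counts_path, config.samples_path)
        truth = None
        sets = read_gmt(config.gmt_path) if config.gmt_path else None
        logger.info("loaded %d x %d count matrix", *counts.values.shape)
    else:
        sim = SimulationConfig(
            n_genes=config.n_genes,
            n_per_group=config.n_per_group,
            conditions=config.conditions,
            effect_size_range=config.effect_size_range,
            seed=config.seed,
        )
        study = generate_counts(sim)
        counts, truth = study.counts, study.truth
        sets = generate_gene_sets(
            truth,
            n_sets=config.n_sets,
            set_size=config.set_size,
            n_enriched=config.n_enriched,
            purity=config.set_purity,
            seed=config.seed + 1,
        )
        rio.write_counts(counts, out / "study", mtx=False)
        write_gmt(sets, out / "study_sets.gmt")
        rio.write_table(
            truth.gene_class.to_frame().assign(
                lfc_contrast1=truth.lfc_contrast1, lfc_contrast2=truth.lfc_contrast2
            ),
            out / "study_truth.tsv",
        )

    conditions = list(dict.fromkeys(counts.samples["condition"]))
    if len(conditions) < 3:
        raise ValueError("the demo pipeline expects at least 3 conditions")
    baseline, model_cond, reference_cond = conditions[0], conditions[1], conditions[2]

    # --- stage: differential expression ------------------------------------
    de_results = {}
    for cond in (model_cond, reference_cond):
        name = f"{cond}_vs_{baseline}"
        path = out / f"de_{name}.tsv"
        if resume and path.exists():
            de_results[cond] = rio.read_de_result(path)
            logger.info("resumed DE result %s", name)
            continue
        res = run_contrast(
            counts,
            (cond, baseline),
            p1=config.p1,
            min_cpm=config.min_cpm,
            prior_count=config.prior_count,
            trim_m=config.trim_m,
            trim_a=config.trim_a,
        )
        rio.write_de_result(res, path)
        artifacts[f"de_{name}"] = path
        de_results[cond] = res
    de_model = de_results[model_cond]
    de_reference = de_results[reference_cond]
    summary["de"] = {
        res.contrast: {
            "n_genes": int(res.table.shape[0]),
            "n_posterior_ge_0.9": int((res.table["posterior"] >= 0.9).sum()),
            "d0": float(res.priors.d0) if res.priors else None,
            "s0_sq": float(res.priors.s0_sq) if res.priors else None,
            "v0": float(res.priors.v0) if res.priors else None,
        }
        for res in de_results.values()
    }

    # --- stage: RSI and concordance ----------------------------------------
    rsi_table = compute_rsi(de_model, de_reference)
    rio.write_table(rsi_table.table, out / "rsi.tsv",
                    params={"contrast_1": rsi_table.contrast_1, "contrast_2": rsi_table.contrast_2})
    summ = concordance_summary(rsi_table, tau=config.tau)
    summary["rsi"] = {
        "tau": config.tau,
        "n_concordant": summ.n_concordant,
        "n_discordant": summ.n_discordant,
        "asymmetry": summ.asymmetry,
        "counts_by_tau": summ.counts_by_tau,
    }

    # --- stage: gene-set enrichment ----------------------------------------
    if sets is not None:
        set_results = rank_set_test(rsi_table, sets, min_size=config.min_set_size)
        rio.write_table(set_results, out / "set_enrichment.tsv")
        con, dis = top_sets(set_results, k=config.top_k)
        rio.write_table(con, out / "top_concordant_sets.tsv")
        rio.write_table(dis, out / "top_discordant_sets.tsv")
        curve = concordance_curve(
            de_reference,
            {model_cond: de_model},
            sets,
            min_size=config.min_set_size,
        )
        rio.write_table(curve, out / "concordance_curve.tsv")
        summary["gene_sets"] = {
            "n_tested": int(set_results.shape[0]),
            "n_concordant_p05": int(
                ((set_results["direction"] == "+") & (set_results["p_up"] <= 0.05)).sum()
            ),
            "n_discordant_p05": int(
                ((set_results["direction"] == "-") & (set_results["p_down"] <= 0.05)).sum()
            ),
            "top_concordant": con.index[:3].tolist(),
        }

    # --- stage: cohort similarity ------------------------------------------
    if truth is not None:
        factors = tmm_factors(filter_low_expression(counts), config.trim_m, config.trim_a)
        model_expr = log_cpm(
            filter_low_expression(counts), factors, prior_count=config.prior_count
        )
        patients = generate_cohort(
            truth,
            n_patients=config.n_patients,
            patient_noise_sd=config.patient_noise_sd,
            seed=config.seed + 2,
        )
        patient_expr = ExpressionMatrix(
            patients.loc[patients.index.intersection(model_expr.gene_ids)],
            plain_sample_table(patients.columns, source="cohort", condition="patient"),
        )
        report = cohort_report(
            model_expr, patient_expr, de_model, n_top=config.n_top_cohort
        )
        rio.write_table(report.cluster_labels.to_frame(), out / "cohort_clusters.tsv")
        rio.write_table(report.mw_table, out / "cohort_mann_whitney.tsv")
        labels = report.cluster_labels
        xeno_ids = counts.sample_ids[
            (counts.samples["condition"] == reference_cond).to_numpy()
        ]
        patient_ids = patient_expr.sample_ids
        xeno_major = labels.loc[xeno_ids].mode().iloc[0]
        patient_major = labels.loc[patient_ids].mode().iloc[0]
        summary["cohort"] = {
            "n_top_genes": config.n_top_cohort,
            "patients_cocluster_with_reference": bool(xeno_major == patient_major),
            "n_mw_p05": int((report.mw_table["p_value"] < 0.05).sum()),
        }

    # --- stage: drug response ----------------------------------------------
    assay = generate_drug_assay(
        n_per_group=config.n_per_group,
        effect_fractions=config.drug_effect_fractions,
        noise_cv=config.drug_noise_cv,
        seed=config.seed + 3,
    )
    curve_fit = fit_standard_curve(assay.curve_points)
    drug = compare_groups(assay.wells, curve_fit, q_level=config.q_level)
    rio.write_table(drug.group_stats, out / "drug_groups.tsv")
    rio.write_table(drug.vs_control, out / "drug_vs_control.tsv")
    summary["drug"] = {
        "anova_F": drug.anova_f,
        "anova_p": drug.anova_p,
        "q_values": {g: float(q) for g, q in drug.vs_control["q_value"].items()},
        "n_rejected": int(drug.vs_control["rejected"].sum()),
        "curve_r_squared": curve_fit.r_squared,
    }

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    artifacts["summary"] = summary_path
    return PipelineReport(summary=summary, out_dir=out, artifacts=artifacts)
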