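# rsikit

Concordance analysis of transcriptional responses across tumor model
systems via the **response similarity index (RSI)**.

## The problem

When a new culture system (a perfused multicellular tumor-microenvironment
device, a 3D spheroid, ...) claims to reproduce in-vivo tumor biology, the
claim must be quantified: of the genes whose expression shifts when cells
move from 2D static culture into a xenograft, how many shift the same way
in the candidate model?  `rsikit` implements a complete, tested pipeline
for that question, driven by a synthetic-data generator that emulates a
multi-condition bulk RNA-seq design (three growth conditions, n = 6
samples per condition, negative-binomial counts, batch nuisance
structure), so every statistical property of the method can be verified
against planted ground truth.

## The statistic

For each gene *g* and contrast *c* (e.g. TMES vs 2D static), a linear
model on TMM-normalized log2-CPM yields a log2 fold change and an
empirical-Bayes posterior probability of differential expression

&nbsp;&nbsp;p<sub>g,c</sub> = logistic(B<sub>g,c</sub>),

where B is the moderated-t log-odds: gene-wise residual variances s²_g are
shrunk toward a scaled inverse-χ² prior (hyperparameters d₀, s₀² fitted by
moment matching), t̃_g = β̂_g /(s̃_g √u_g) has d₀ + d_g degrees of freedom,
and a two-component mixture with prior DE probability p₁ and DE-coefficient
prior variance v₀ gives the posterior odds.  For two contrasts sharing a
baseline, the RSI is the signed joint posterior

&nbsp;&nbsp;RSI_g = sign(lfc₁·lfc₂) · p<sub>g,1</sub> · p<sub>g,2</sub> ∈ [−1, 1],

an operational intersection–union test: +1 means confidently changed in
the same direction in both contrasts, −1 confidently opposite, 0 no joint
change.  On top of the per-gene RSI the package builds concordance counts
and asymmetry, rank-based (Wilcoxon) gene-set concordance tests,
pathway-concordance curves for ranking candidate models, quantile-normalized
patient-cohort co-clustering, and luciferase drug-response statistics
(standard-curve calibration, one-way ANOVA, Benjamini–Krieger–Yekutieli
two-stage FDR q-values).

## Worked example

```python
from rsikit import (SimulationConfig, generate_counts, run_contrast,
                    compute_rsi, concordance_summary)

study = generate_counts(SimulationConfig(n_genes=2000, seed=1))
de_tmes = run_contrast(study.counts, ("TMES", "static2D"))
de_xeno = run_contrast(study.counts, ("xenograft", "static2D"))
rsi = compute_rsi(de_tmes, de_xeno)
summ = concordance_summary(rsi, tau=0.9)
print(summ.n_concordant, summ.n_discordant, round(summ.asymmetry, 3))
```

prints

```
205 36 0.701
```

— 205 genes are jointly differentially expressed in the same direction in
both contrasts (|RSI| ≥ 0.9), 36 in opposite directions, and the asymmetry
(n_con − n_dis)/(n_con + n_dis) = 0.701 reflects the generator's planted
excess of concordant over discordant responses (30% vs 5% of genes).

The same analysis, end to end with gene-set tests, cohort co-clustering
and drug statistics, is one command:

```bash
rsikit run-all --out-dir demo_run --seed 1
```

which writes per-stage TSVs and a `summary.json` with every headline
statistic and parameter (byte-identical across reruns of the same
configuration).  Individual stages are exposed as `rsikit simulate`,
`normalize`, `de`, `rsi`, `enrich`, `curve`, `cohort`, `drug`.

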