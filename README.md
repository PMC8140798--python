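# methcascade

Marker-discovery cascade for Illumina 450K-style DNA-methylation cohorts.

Pretreatment tumour methylation can predict which patients with
*EGFR*-mutant lung adenocarcinoma obtain no benefit from EGFR tyrosine
kinase inhibitors (intrinsic resistance, operationalised as progressive
disease — PD — at first RECIST assessment). `methcascade` implements the
probe-selection pipeline used for this kind of study as a tested, reusable
library plus CLI, together with a synthetic-cohort generator so that every
stage can be verified against planted ground truth:

1. **Variance pre-filter** — per-probe coefficient of variation
   (CV = s/x̄ of beta values, n−1 standard deviation); the top-q fraction
   of the full probe universe is retained, `floor(q·N)` probes
   (q = 0.05 on a 482,421-probe array keeps exactly 24,121).
2. **Response association** — one-way ANOVA of beta values across
   PD/SD/PR response groups, with Tukey HSD pairwise adjusted p-values
   (reported, not filtered on).
3. **Disease-control selection** — per-probe univariate and multivariate
   (beta + clinical covariates) logistic regression of the disease-control
   outcome (SD/PR/CR vs PD); a probe survives when the ANOVA p and both
   logistic p-values clear their thresholds.
4. **Cis-repression screen** — Spearman correlation of each probe's betas
   with its own gene's expression; significantly negative sites
   ("transcription-repressive", ρ ≤ −0.3, p ≤ .05 by default) are kept.
5. **Annotation filters & enrichment** — transcription-factor and
   enhancer flags, promoter/CpG-island context distributions, and
   binomial / hypergeometric / proportion-z enrichment tests for
   annotation classes and term maps.
6. **Marker evaluation** — AUROC (tie-aware cross-pair probability),
   Youden-index cutoff (J = sensitivity + specificity − 1), 2×2 odds
   ratio with Woolf 95% CI and two-sided Fisher exact p, stratified
   re-evaluation, one-sided Wilcoxon rank-sum validation testing and
   marker-quartile summaries.

The selection stages are scikit-learn-style feature selectors
(`CVFilter`, `AnovaTukeySelector`, `DcrLogisticSelector`,
`RepressionScreen`) with `fit` / `transform` / `get_support`, so they
compose with sklearn tooling; `run_cascade` chains them in the fixed
published order.

## Worked example

```python
from methcascade import (SimulationConfig, generate_cohort,
                         CascadeConfig, run_cascade)

cfg = SimulationConfig(seed=1, n_samples=150, n_probes=20_000,
                       n_informative=100, n_repressive=20)
samples, meth, manifest, expression, truth = generate_cohort(cfg)
result = run_cascade(meth, samples, manifest, None,
                     CascadeConfig(evaluate_markers=False))
for stage in result.stages:
    print(stage["name"], stage["n_input"], "->", stage["n_retained"])
final = set(result.final_probes)
hits = final & truth.informative_probe_ids
print("precision", len(hits) / len(final), "sensitivity", len(hits) / 100)
```

prints

```
cv_filter 20000 -> 1000
anova_tukey 1000 -> 132
dcr_logistic 132 -> 98
precision 0.8367346938775511 sensitivity 0.82
```

i.e. the CV filter keeps the top 5% (1,000 probes, including all 100
planted differentially methylated sites), the ANOVA stage keeps 132 at
p ≤ .05, the joint logistic filter keeps 98 — of which 82 are planted
probes (84% precision, 82% sensitivity against ground truth).

The same pipeline is available from the shell:

```bash
methcascade simulate --seed 1 --outdir cohort/
methcascade run --meth cohort/methylation.tsv --samples cohort/samples.tsv \
    --manifest cohort/manifest.tsv --outdir results/
methcascade evaluate --meth cohort/methylation.tsv \
    --samples cohort/samples.tsv --marker cg00000042 --stratify egfr_mutant
```

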