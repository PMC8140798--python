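# Methods

## The selection cascade

The package models a discovery study in which pretreatment tumour
methylation (Illumina 450K beta values, one value in [0,1] per probe and
sample) is screened for association with EGFR-TKI response. The cascade
runs in a fixed order — stages can be switched off but never reordered —
and each stage can only shrink the retained probe set:

1. **CV filter.** Per probe, mean and n−1 standard deviation of beta over
   non-missing samples; CV = sd/mean. Probes with fewer than three
   non-missing values or a zero mean are flagged `excluded` and carry no
   CV. The retained count is `floor(q · N)` with N the *full* probe
   universe (excluded probes included), so the count is a fixed property
   of the array: q = 0.05 of 482,421 probes retains exactly 24,121.
   Ordering is CV-descending with probe-id-ascending tie-break, making the
   selection invariant to input row/column order. CV is computed on beta
   values, not M-values, because the screened quantity and all downstream
   plots are on the beta scale.
2. **ANOVA + Tukey HSD.** One-way fixed-effects F test of beta across the
   PD/SD/PR groups; p from the F distribution. Pairwise Tukey
   (Tukey-Kramer for unequal group sizes) adjusted p-values come from the
   studentized-range distribution (`scipy.stats.studentized_range`,
   numerical integration; the test suite validates it against direct
   Monte-Carlo simulation of the range statistic). Tukey results are
   reported but not used as a filter — a probe significant by ANOVA is
   retained regardless of which pair drives the difference. Degenerate
   input with zero within-group variance and equal means yields F = 0,
   p = 1; groups with fewer than two samples are dropped and their pairs
   flagged.
3. **Disease-control logistic selection.** The binary outcome is disease
   control (SD/PR/CR = 1) vs progressive disease (PD = 0). Each probe is
   fitted univariately (intercept + beta) and multivariately (adding the
   clinical covariates, by default EGFR-mutation status, sex and smoking),
   by IRLS (tolerance 1e-8, 100 iterations). The significance of the
   probe term defaults to a likelihood-ratio test against the model
   without it. This is a deliberate choice: beta values that separate the
   outcome almost perfectly drive the Wald standard error to infinity
   (the Hauck-Donner effect), so a Wald filter discards exactly the
   strongest markers; the LR statistic remains well behaved. When IRLS
   overflows under quasi-complete separation the likelihood is
   re-maximised directly (L-BFGS), which recovers the bounded likelihood
   supremum. `p_method="wald"` restores the classical test. Complete
   separation and constant predictors are flagged, never raised; flagged
   fits carry no p-values and cannot pass the filter. A probe survives
   when ANOVA p ≤ α₁ and both logistic p-values ≤ α₂ (defaults .05/.05).
   The AND-rule and both alphas are configurable; thresholds use ≤ so
   that α = 1 is a true pass-through.
4. **Cis-repression screen.** Spearman ρ between each probe's betas and
   the expression of the gene it annotates to (manifest `gene_symbol`;
   probes without a mapped gene or without expression data are flagged
   and never retained). ρ is the Pearson correlation of midranks; the
   two-sided p uses the t approximation for n > 9 and exact permutation
   enumeration for n ≤ 9, where the approximation is poor. Default calls:
   ρ ≤ −0.3 and p ≤ .05, both configurable and recorded in the stage
   report.
5. **Annotation filters.** Optional transcription-factor flag filter and
   genomic-context filter (gene region within a configurable set, default
   promoter subregions TSS1500/TSS200, optionally requiring the enhancer
   flag). Gene regions are single-valued per probe; multi-region
   annotations are collapsed promoter-first
   (TSS200 > TSS1500 > 5'UTR > first exon > body > 3'UTR) so that context
   proportions are well defined.
6. **Marker evaluation.** For surviving candidates: AUROC
   (P(marker_PD > marker_DC) + ½P(tie), via `sklearn.roc_auc_score`;
   the tests check it against explicit cross-pair enumeration), Youden
   cutoff evaluated at every observed value (predict PD when
   value ≥ cutoff; ties break toward the smallest cutoff; an external
   cutoff entry point exists because published cutoffs often sit between
   observed values), odds ratio ad/bc with Woolf log-normal 95% CI
   (chosen because published CIs of this kind are symmetric on the log
   scale; any zero cell gets the Haldane-Anscombe +0.5 for OR and CI
   only), and a two-sided Fisher exact p under the
   "sum of table probabilities ≤ observed" convention. The validation
   test is the one-sided Wilcoxon rank-sum (PD stochastically greater),
   exact for m+n ≤ 20 without ties, otherwise normal approximation with
   midrank-tie and continuity corrections. Stratified evaluation applies
   the cohort-level cutoff within each stratum; strata missing a class
   are reported not-evaluable.

Descriptive layers outside the filtering path: the PD-vs-PR per-probe
mean contrast with its above-diagonal fraction (methylation gain in PD),
per-covariate probe regressions flagged at p < .05 (a report, never a
filter), genomic-context distributions for any probe set, and
annotation/term enrichment. Enrichment requires the caller to name the
test variant (`binomial_exact` upper tail, `hypergeometric` upper tail,
or two-sided `proportion_z`): published enrichment p-values rarely state
the variant, so none is hard-coded as the default truth. Three natural
background universes are supported — the full array, the most-variable
set, and any selected set. Percentage reports truncate (floor) to two
decimals, matching the convention of printed proportion pairs such as
34,129/482,421 → 7.07% and 30/216 → 13.88%. No multiplicity correction is
applied across probes or terms by default, mirroring the raw-count
reporting style this cascade emulates; BH-style correction can be layered
on by the caller.

## Synthetic cohorts

`generate_cohort` draws beta values as the inverse logit of
`mu_probe + delta·1[PD]·direction + covariate_effect·1[EGFRm]·1[cov probe]
+ Normal(0, noise_sd)`. The logit-normal choice keeps every beta strictly
inside (0,1) and makes the planted group effect additive on the scale on
which it is defined. Defaults describe the emulated study conditions:

- `n_samples = 79` (discovery cohort size), response probabilities
  PD .25 / SD .35 / PR .40 — the PD share matches the 20–30% of
  non-responders the clinical setting reports. CR is not generated in the
  discovery cohort; it appears only in validation, where it merges into
  disease control anyway.
- Group sizes are deterministic: slot i takes the group whose
  cumulative-probability bracket contains (i+0.5)/n, and the slot order
  is then shuffled with the seeded generator. Tests can therefore rely on
  exact group sizes (163 patients at PD fraction 25/163 give exactly
  25/138) while the assignment stays random.
- `effect_delta = 2.0` logit units, `noise_sd = 0.5`, and
  `hypo_fraction = 0.06`: a small minority of informative probes is
  methylated *lower* in PD, mirroring the ~6% opposite-trend sites
  (13 of 216) such landscapes show.
- Baseline probe means `mu_probe ~ Normal(0, 1.5)`; informative
  hyper-direction probes instead draw `Normal(−2, 0.5)` (and hypo probes
  `Normal(+2, 0.5)`). Clinically useful methylation markers of poor
  response gain methylation from a near-unmethylated base — validated
  markers of this kind sit at beta ≈ 0.15 or a few percent methylation —
  and a low base plus a group shift is also what gives such probes a
  high CV.
- TF/enhancer flags and CpG-island/gene-region categories are drawn with
  background rates close to 450K array composition (TF 7.07%, island
  31.15%, open sea 35.89%, TSS1500 11.65%) and enriched rates on
  informative probes (TF 13.88%, island 81.94%), so annotation-enrichment
  statistics have a planted signal to find.
- `n_repressive` informative probes couple to expression:
  `expr = 8 + repression_slope·beta + Normal(0, expression_noise_sd)`
  with slope −5 by default; all other genes are independent noise.
  Repressive probes are forced to be gene-mapped.
- The validation generator emulates pyrosequencing percentages:
  Normal(base_mean [+ shift for PD], sd) clamped to [0,100], defaults
  base 5%, shift +5, sd 4 on 163 patients — low percent-scale values
  around the few-percent cutoffs typical of such assays.

What the generator does *not* emulate — Infinium I/II probe-chemistry
differences, batch effects, copy-number contamination, correlated probe
blocks, non-Gaussian expression noise — bounds what passing tests show:
they demonstrate that the statistics and the cascade logic are correct
and well calibrated under the declared model, not that the pipeline is
robust to every artefact of real array data.

## Problem sizes and numerical choices

End-to-end checks run at 150 samples × 20,000 probes with 100 planted
informative sites (the cascade recovers ≥70% precision and ≥60%
sensitivity there; measured ≈0.84/0.82 at the default seed), null
calibration at 120 × 4,000 probes with no planted effect, and the
full-array CV count at 79 × 482,421. These sizes keep a complete run in
minutes on a single core while leaving the binomial standard errors of
the calibration checks small.

Tolerances and tie-breaks worth knowing: CV selection breaks CV ties by
probe id; Youden breaks J ties toward the smallest cutoff; the two-sided
Fisher p includes tables with probability ≤ observed × (1 + 1e-7) (the
common float guard); Spearman exact enumeration treats |ρ| within 1e-12
as tied; the constant-predictor guard uses a 1e-12 relative tolerance on
the standard deviation. Empty probe sets yield flagged undefined
proportions rather than NaN surprises, and an empty stage output aborts
the cascade with an error naming the stage.

## Known limitations

- The cascade tests each probe marginally; no joint modelling or
  multiplicity control across probes (by design, matching the emulated
  workflow).
- The cis screen is cis-only and one-gene-per-probe; trans effects and
  multi-gene annotations are out of scope.
- Exact Spearman enumeration is limited to n ≤ 9 pairs; beyond that the
  t approximation is used regardless of ties.
- AUROC is reported without a confidence interval; no DeLong test, no
  survival endpoints.
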