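# metscore

Continuous metabolic-syndrome (MetS) severity scoring and candidate-SNP
association testing for small epidemiological cohorts, with a
synthetic-cohort generator that makes the whole pipeline reproducible
end to end without any study data.

## The problem and the method

Metabolic syndrome is usually diagnosed dichotomously — at least three of
five features (abdominal obesity, low HDL, high triglycerides, elevated
blood pressure, hyperglycemia) under the harmonized criteria — but a
yes/no phenotype wastes statistical power in genetic association studies.
`metscore` instead builds a *continuous* severity score from the six
measured traits (waist circumference, DBP, SBP, glucose, HDL, TG):

1. **Normalization.** Non-normal traits receive fixed monotone
   transforms: SBP → log₁₀(log₁₀ SBP), glucose → 1/(log₁₀ glucose)¹⁰,
   HDL → (ln HDL)², TG → log₁₀(log₁₀ TG); waist and DBP enter untransformed.
2. **PCA.** Principal components are extracted from the correlation
   matrix of the standardized transformed traits; components with
   eigenvalue > 1 are retained (typically two: a blood-pressure /
   adiposity / glycemia axis and a lipid axis) and varimax-rotated.
3. **Scoring.** Each individual's score is
   `score_i = Σ_k w_k · s_ik`, where `s_ik` are unit-variance component
   scores and `w_k` either the components' relative explained-variance
   shares (`proportional`) or 1 (`equal`; two uncorrelated components
   then give SD = √2 ≈ 1.41). Components are oriented so a higher score
   always means a worse metabolic profile.
4. **Genetics.** Per SNP: Hardy–Weinberg χ² check, dominance grouping
   (major-allele homozygotes vs carriers), pooled-variance t-test of the
   score between groups with Bonferroni correction, additive
   risk-genotype trend (ANOVA linear contrast), covariate-adjusted
   linear model (covariates screened at 5% incremental R²), and the
   normal-approximation minimum detectable difference
   `δ = (z₁₋α/₂ + z_power)·σ·√(1/n₁ + 1/n₂)`.

The package also accepts published per-group summaries `(n, mean, SD)`
directly, so the association and power arithmetic of a printed table can
be recomputed without raw data.

## Worked example

Simulate a 206-person cohort with a protective dominance effect
(−0.8 latent SD for carriers of the rs4244285 minor allele) and run the
full pipeline:

```sh
metscore simulate --out demo --n 206 --seed 1 --effect rs4244285:-0.8
metscore run --pheno demo/phenotypes.csv --geno demo/genotypes.csv --out demo/out
```

which prints

```
n = 206 complete records
MetS prevalence: 59.22% (52.51-65.93%)
score mean +/- SD: -0.00 +/- 0.72 (proportional weights)
trend across risk counts: F=234.208, p=1.65e-35
MetS vs non-MetS score: 0.39 vs -0.56 (t p=6.48e-26)
```

The score behaves like a severity index: it rises with the number of
dichotomous risk factors and separates affected from unaffected
individuals. `demo/out/association.tsv` holds the per-SNP tests; rounded
to 3 decimals:

```
   snp_id  n_ref  n_carrier  mean_diff  ci_low  ci_high  p_raw  p_bonferroni
rs4244285    153         53      0.563   0.350    0.775  0.000         0.000
 rs279871     77        129     -0.063  -0.267    0.142  0.546         1.000
  rs16147     57        149      0.071  -0.150    0.292  0.526         1.000
rs1142345    191         15      0.171  -0.209    0.551  0.376         1.000
```

Only the SNP that actually carries an effect is detected
(mean difference reference − carrier = 0.563, raw p = 4.3×10⁻⁷,
Bonferroni-corrected p = 1.7×10⁻⁶); the three null SNPs are flat. The
minimum detectable difference for a 156/50 split at σ = 1.41:

```sh
$ metscore power --n1 156 --n2 50 --sigma 1.41
0.642
```

Further outputs in `demo/out/`: `scores.tsv`, `status.tsv` (five
features, risk count, MetS flag), `hwe_maf.tsv`, `adjusted.tsv` +
`screening.tsv` (covariate-adjusted effects), `power.tsv`, and `run.log`.
Every stage is also invokable on its own intermediate files
(`metscore score|classify|associate|adjust`), and `metscore run` equals
their composition exactly.

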