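# Methods

## The continuous MetS score

The score treats metabolic-syndrome severity as a low-dimensional latent
quantity expressed in six measured traits. Let `x = (waist, DBP, SBP,
glucose, HDL, TG)` be the raw traits. Four traits are first mapped
toward normality with fixed monotone transforms

| trait   | transform            | direction  |
|---------|----------------------|------------|
| SBP     | log₁₀(log₁₀ x)       | increasing |
| glucose | 1/(log₁₀ x)¹⁰        | decreasing |
| HDL     | (ln x)²              | increasing |
| TG      | log₁₀(log₁₀ x)       | increasing |

with waist and DBP left as measured. The doubled-log transforms need
log₁₀(x) > 0, so the domain guard is x > 1 (not x > 0); clinical values
sit orders of magnitude above the bound. Because the glucose transform
is decreasing, a *negative* loading of transformed glucose on a
component still means higher raw glucose raises that component. The
default pipeline mode (`fixed`) applies exactly these four transforms so
results do not depend on which traits a particular sample happens to
flag; a `screen` mode (Shapiro–Wilk at α = 0.05, transforming only
failing traits) is provided for generality.

Transformed traits are z-scored (sample SD, ddof = 1) and PCA is run on
their correlation matrix — the traits' units differ wildly, and the
loadings are then directly interpretable as trait–component
correlations. Components with eigenvalue strictly greater than 1 are
retained (Kaiser rule); on data with the expected two-axis structure
this retains K = 2: a blood-pressure/adiposity/glycemia axis and a lipid
axis. The retained loadings are varimax-rotated (explained-variance
shares are recomputed from the rotated loadings) to sharpen the axis
interpretation.

**Component scores** use the regression method: `W = R⁻¹L` applied to
the standardized traits, rescaled to unit sample variance. For
correlation-matrix PCA this gives `L'R⁻¹L = I`, so the retained
component scores are exactly uncorrelated with unit variance on the
fitting sample — which is what makes "summing component scores"
well-defined.

**Weighting.** `score_i = Σ_k w_k s_ik` with either
`w_k = v_k/Σv_k` (proportional to explained variance, the default) or
`w_k = 1` (equal). Under equal weighting with K = 2 the score's sample
SD is exactly √2 ≈ 1.41; under proportional weighting it is
`√(Σw_k²) < 1`. Both conventions are exposed and tested because the
wording "weighted by the relative contribution to the explained
variance" in the field is ambiguous while a reported score SD of 1.41 is
consistent only with (near-)equal weights.

**Sign convention.** PCA component signs are arbitrary, so each retained
component is oriented deterministically. For the six canonical traits a
component is flipped so its loadings point toward severity, using the
direction vector (waist +, DBP +, SBP +, glucose −, HDL −, TG +) on the
transformed scale; this guarantees that raising any adverse trait raises
the score. A largest-|loading|-positive rule would *not* achieve this:
on data with the expected structure the lipid component's
largest-magnitude loading is HDL, which a severity score must carry
negatively. For generic (non-trait) columns the largest-positive rule is
the fallback.

## Dichotomous classification

The harmonized criteria: waist ≥ 94 cm (men) / ≥ 80 cm (women); HDL
< 40 (men) / < 50 mg/dL (women); TG ≥ 150 mg/dL; SBP ≥ 130 **or** DBP
≥ 85 mmHg (the slash in "130/85" is read as a logical OR, the standard
harmonized-criteria interpretation); glucose ≥ 100 mg/dL. Boundary
handling follows the printed criteria exactly: four features inclusive,
HDL strict. Medication is an alternative indicator for its feature;
lipid-lowering medication maps to *both* lipid features by default
(configurable, since criteria texts do not pin the mapping down). MetS =
at least 3 of 5 features. Prevalence intervals use the Wald normal
approximation by default (it reproduces the conventional printed
intervals); Wilson is available behind a flag.

## Genetic association

Genotypes are minor-allele dosages. Per SNP:

* **HWE**: χ² goodness of fit (1 df, no continuity correction) of the
  genotype counts against (1−q)², 2q(1−q), q² at the observed allele
  frequency. Monomorphic SNPs are flagged, not tested. At small n the
  χ² p-values are discrete and only approximately uniform; an exact test
  is the right tool below ~5 expected counts per cell.
* **Dominance association**: reference homozygotes vs carriers of ≥ 1
  minor allele, pooled-variance (Student) two-sample t-test. Pooled
  rather than Welch because published group summaries with their CIs and
  p-values are reproduced exactly by the pooled form; Welch is a flag.
  The reported mean difference is reference − carrier. `t_test_raw` and
  `t_test_summary` agree to machine precision by construction.
* **Bonferroni**: min(1, m·p); m defaults to the number of SNPs actually
  tested in a run (a fixed family size, e.g. a 37-SNP panel, can be
  forced).
* **Per-trait tests** dispatch on Shapiro–Wilk normality of both groups:
  pooled t when both pass at α = 0.05, Mann–Whitney otherwise (exact
  null distribution when both groups ≤ 8 and untied, midranks + tie
  correction asymptotically otherwise).
* **Additive risk trend**: per-individual count of risk genotypes across
  a panel, with the risk orientation *explicit* per SNP (a protective
  minor allele makes the non-carrier state the risk state); a missing
  dosage at any panel SNP makes the count missing. The score is tested
  across counts with the ANOVA linear contrast (centered group codes,
  within-group MSE error term, df = N − G). With two levels this
  coincides exactly with the OLS slope test; with more levels they
  differ by the lack-of-fit component.
* **Power**: minimum detectable difference
  δ = (z₁₋α/₂ + z_power)·σ·√(1/n₁+1/n₂); a noncentral-t inversion is
  available behind `exact=True` and gives slightly larger values (t
  tails are heavier than normal).

## Covariate adjustment

`score ~ carrier + covariates` by OLS with treatment coding; the
adjusted mean difference is (minus) the carrier coefficient with its
t-based CI and p. Covariates are screened by *marginal* incremental R² —
the R² of the covariate alone against an intercept-only model — and kept
if above 5%. Marginal (rather than partial) R² is the simplest reading
of "contributing more than x% of the score's variation"; a partial-η²
variant would differ when covariates are correlated. The genotype term
is always retained regardless of screening. Binary covariates are coded
0/1 with female = 1 (direction affects only the coefficient sign). With
no covariates the model reduces exactly to the pooled t-test.

## The synthetic generator

The generator defines the study conditions for every simulation-backed
test. Its generative model:

* Two latent standard-normal factors per individual. Transformed-scale
  traits are `z_j = l_j1·f_1 + l_j2·f_2 + √ψ_j·ε_j` with the default
  loading matrix shaped like the two-axis structure above (waist
  0.650/0.255, DBP 0.771/0.320, SBP 0.826/0.057, glucose −0.598/0.147,
  HDL 0.079/−0.885, TG 0.305/0.818) and ψ = 1 − communality, so each
  standardized trait has unit variance.
* Affine location/scale constants map standardized values to the
  transformed scale, then the trait transforms are inverted to produce
  raw clinical units. The constants derive from target raw moments
  (waist 95.5 ± 12.6 cm, DBP 80.7 ± 10.0, SBP 131.7 ± 20.0, glucose
  103.3 ± 33.9, HDL 53.5 ± 13.3, TG 107.7 ± 60.3) by the delta method at
  the mean. For glucose, whose transformed-scale domain is bounded below
  at 0, the transformed SD is capped at (mean − bound)/4 so invalid
  draws are ~Φ(−4) rare; the rare invalid row is redrawn (bounded
  retries), keeping rejection from truncating the latent distribution.
* Genotypes are Binomial(2, q) per SNP — exactly HWE — at configured
  minor-allele frequencies (defaults 0.129, 0.434, 0.450, 0.032 for a
  four-SNP candidate panel). Dominance effects shift carriers' latent
  factor 1 (configurable) by β *before* trait generation, and the
  post-shift factor is returned as the ground-truth latent score for
  recovery tests.
* Covariates are drawn independently at fixed prevalences (female 0.578,
  smoker 0.180, excessive alcohol 0.087, inactivity 0.597, unhealthy
  diet 0.359, antihypertensive 0.262, lipid-lowering 0.126, antidiabetic
  0.073); age ~ N(56.4, 16.2²) truncated to [18, 100]. Two switches make
  confounding testable: `age_slope` (age → latent factor, per SD of age)
  and `carrier_age_shift_sd` (carriers older by a fixed number of age
  SDs). All draws come from one seeded generator.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: trait distributions are exactly
transform-normal (real glucose and TG are more skewed; the synthetic raw
glucose SD ≈ 13 mg/dL understates a survey-like 34, and raw TG
mean/SD overshoot their targets through the convex doubled-exponential
inverse); covariates are independent of traits unless the confounding
switches are on (so the synthetic MetS prevalence, ≈ 50–60%, is emergent
rather than calibrated); there is no linkage disequilibrium between
SNPs, no measurement error model, and no survey design (nonresponse,
clustering).

One structural consequence worth stating: with the default *factor*
loadings and positive uniqueness, the top-2 principal components of the
generative correlation matrix carry ≈ 74% of the variance — necessarily
*more* than the 63% communality share, because PCA components absorb
unique noise along with common variance. Fit recovery is therefore
checked against the population value of the same functional
(`expected_explained_variance`, the top-K eigenvalue share of
LL' + diag(ψ)), not against the communality. An exact two-factor model
cannot reproduce a real-data top-2 share equal to its communality.

## Numerical conventions and degenerate inputs

* Standardization and all SDs use ddof = 1; the correlation matrix is
  computed as Z'Z/(n−1) on z-scored data so the component-score identity
  holds to machine precision.
* Eigenvalue retention uses strict "> 1.0"; ties at the threshold drop.
* Varimax: standard SVD iteration, γ = 1, tolerance 1e−10.
* Missing values propagate through transforms; records incomplete on any
  trait are excluded listwise before PCA. Genotype missingness is
  handled pairwise per SNP (sample size varies by SNP).
* Degenerate inputs raise typed errors rather than NaN: constant vectors
  (Shapiro–Wilk, standardization), rank-deficient trait matrices,
  monomorphic SNPs, empty dominance groups, zero pooled variance,
  zero-margin 2×2 tables, collinear adjustment designs (offending
  columns are named).
* Report TSVs carry full double precision; rounding to 3-decimal style
  happens only in the human-readable summary.

## Problem sizes used in tests and acceptance

Simulation-backed checks use cohorts of n = 5000 for structure recovery
(loading and explained-variance tolerances ±0.05), n = 206 × 500
SNP-tests for the null type-I rate (5% ± 2%), and n = 1000 × 100
replicates for dominance-effect recovery (±0.1 around the injected 0.8).
These sizes put Monte-Carlo error comfortably inside each tolerance
while keeping the full suite around ten seconds.
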