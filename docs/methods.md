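# Methods

## The question and the estimand

The package tests whether the intrauterine environment — proxied by
maternal genetic variants that influence offspring birth weight —
causally affects childhood neurodevelopmental difficulties (NDDs).  No
exposure-scaled causal effect is estimated: per-allele effects on the
latent intrauterine exposure are unavailable, and birth weight is only
an imperfect marker of it, so a two-stage instrumental-variable
estimate would not be well defined.  The estimand is the **causal
null**: the coefficient of the maternal allele score on an NDD outcome
conditional on the offspring (and, where available, paternal) scores at
the same loci.  Conditioning on the offspring score blocks the
transmission path from maternal genotype to offspring phenotype;
conditioning on the paternal score closes the collider opened by
conditioning on offspring genotype, and the paternal coefficient itself
is a negative control, since paternal alleles cannot act through the
womb.

## Generative model of the synthetic cohort

Parents are drawn in Hardy–Weinberg equilibrium at independent loci
(the score panel is assumed LD-pruned, r² < 0.01); offspring receive
one Bernoulli(g/2) allele from each parent per locus.  Per child, with
`S_m`, `S_o`, `S_f` the true weighted scores of mother, offspring and
father centred at their HWE expectation:

```
U    = gamma_mU * S_m + N(0, 1)                    latent intrauterine factor
bwz  = delta_U_bw * U + beta_fetal_scale * S_o
       + rho_confound * C + 0.1 * (ga - 39.5) + N(0, sigma_bw)
L_k  = delta_U_ndd * U + theta_pleio * S_o + theta_pat * S_f
       + rho_confound * C + covariate terms + e_k
```

`C` is a per-family standard-normal confounder shared by siblings;
`e_k` is equicorrelated noise (default correlation 0.4) across the 20
named questionnaire outcomes; birth weight in kg is `3.6/3.5 + 0.45 *
bwz` by sex.  Item-level questionnaire responses add N(0, 1.5²) item
noise to the liability and can be masked at a configurable rate; scales
are scored as item sums with person-mean imputation when at least half
the items are observed.  Covariates (gestational age 39.5 ± 1.5 weeks,
maternal age 30.1 ± 4.5, paternal age 32.5 ± 5.1, birth years
1999–2009, three genotyping batches) carry small fixed effects and
exist to exercise the adjustment code, not to model any population.
Sibling families (a configurable fraction) reuse parental genotypes
with an independent transmission and are the only source of
off-diagonal GRM structure.

### Scenario presets and effect sizes

Five presets set the causal paths: `null` (all zero),
`intrauterine_causal` (gamma_mU = 3, delta_U_bw = delta_U_ndd = 0.5),
`fetal_pleiotropic` (theta_pleio = −1), `postnatal_paternal`
(theta_pat = 1) and `confounding` (rho_confound = 0.5); the non-null
presets all keep the birth-weight architecture (beta_fetal_scale = 1).
The 50-SNP replicate panel draws per-allele effects half-normal
(maternal SD 0.03, fetal SD 0.05 on the birth-weight z scale, effect
alleles oriented positive), putting the maternal score at roughly 2%
and the fetal score at roughly 5% of birth-weight variance — the
weak-maternal / stronger-fetal asymmetry reported for real partitioned
scores.  These values were fixed once from a closed-form power
calculation: at 2,000 families the conditional maternal z statistic is
≈ 7 under the intrauterine preset, so mechanism discrimination at the
corrected threshold operates in a genuinely high-power regime.  The
replicate studies use 2,000-family cohorts with a single outcome and no
item matrices; the full 205-variant panel (set sizes 205/71/31/143/63
with the nested membership structure) exercises the set machinery.

### Paternal selection mode

To reproduce the hypothesised participation-bias mechanism, paternal
missingness can track a paternal liability
`L = s * (z(S_f) + C) + N(0,1)`: retaining only fathers below the top
quantile couples the paternal score with the family confounder
(collider), biasing the paternal-dyad paternal coefficient away from
zero.  The selection arm of the negative-control study therefore runs
under the confounding preset with s = 1 and 40% paternal dropout — a
confounded outcome is a precondition for the mechanism.

## Phenotype preparation

QC exclusions follow perinatal convention with fixed precedence:
anomaly/multiple-birth flags, then gestation < 37.0 weeks, then birth
weight ≤ 2.5 kg or ≥ 5 kg (both boundaries excluded; 37.0 weeks
retained).  NDD scales are rank-inverse-normal transformed,
Φ⁻¹((rank − c)/(n − 2c + 1)) with the Blom offset c = 3/8 (offset
configurable; ties share the average rank).  The transform is applied
before modelling rather than after covariate residualisation — the
alternative ordering is a known variant and is not implemented.  Birth
weight is z-standardised within sex (n − 1 denominator).

## Scores, GRM and the mixed model

Unweighted scores sum effect-allele dosages over a set; weighted scores
use the maternal effects for M sets and fetal effects for F sets.
Missing dosages are imputed at the expected dosage 2·eaf (an
expectation-preserving choice); per-person rescaling by available SNP
count is available behind a flag.  Effect-allele orientation is taken
from the SNP table and mismatching allele labels are an error — no
strand harmonisation is attempted, since the generator controls both
sides.  Raw (unstandardised) scores enter the models, so coefficients
are per allele (unweighted) or per weighted-allele unit.

The GRM is the standard centred-and-scaled average
`A_jk = (1/m) Σ_i (g_ij − 2p_i)(g_ik − 2p_i) / (2p_i(1−p_i))` over
background loci, with sample allele frequencies for centring, ±1 Mb
windows around score SNPs excluded (merged when overlapping, half-open
intervals) and zero-variance loci dropped.

The LMM `y = Xβ + g + e`, `g ~ N(0, σ²_g A)`, is fitted by exact
spectral REML: A is eigendecomposed once, the restricted likelihood is
profiled over λ = σ²_g/σ²_e and maximised by bounded 1-D search on
log λ (λ = 0 checked explicitly so the boundary is attainable), with
GLS fixed effects and standard errors at the optimum.  An
average-information scheme is unnecessary with one random effect at
desk scale.  Identity GRM (or none) short-circuits to OLS — with A = I
only σ²_g + σ²_e is identified, and the replicate cohorts contain no
relatedness, so this fast path carries the Monte-Carlo studies.  Wald
tests use the normal reference, as GREML software does (`use_t` flag
for the t reference).  Batch and birth year enter as categorical
dummies, gestational age and parental ages as centred linear terms;
analyses are complete-case per outcome.  Negative GRM eigenvalues are
clipped at zero with a warning; rank-deficient designs are an error
naming the collinear terms.

Instrument strength uses the plain partial F of the instrument in an
OLS of the exposure on instrument + conditioning scores + covariates
(the squared t for a single score); the conditional-F variant with
heteroskedasticity corrections is out of scope.

Weighted sensitivity analyses adjust for the *other* roles' per-locus
dosages (one fitted model per focal role) rather than their scores,
capped at the score-set loci; with ≤ 205 extra columns the design stays
full rank at the simulated sample sizes.

## Multiple testing and interpretation

The corrected threshold is 0.05 divided by the effective number of
independent outcomes, computed from the eigenvalues of the outcome
correlation matrix with the eigenvalue-magnitude (Li–Ji) rule
`Meff = Σ I(λ ≥ 1) + (λ − ⌊λ⌋)`; a PCs-explaining-99.5%-variance rule
is available behind a flag.  For 20 outcomes at equicorrelation 0.4
this lands near 0.05/12 ≈ 0.004, the same order as thresholds used with
real outcome batteries.  The verdict rule per outcome: maternal
significant with paternal null → intrauterine effect; both maternal and
paternal significant → postnatal/shared; offspring-only significant →
fetal pleiotropy; nothing significant → null; anything else (including
missing roles or a paternal-only signal) → inconclusive.

## What the Monte-Carlo studies show — and what they do not

The acceptance studies establish: 5% type-I calibration of the maternal
conditional test under the null; unbiased recovery (the generative
conditional coefficient gamma_mU·delta_U_ndd is exact for the
maternal-weighted score on the liability scale, which is why the
recovery and coverage studies skip the rank-INT step) with nominal 95%
CI coverage; ≥ 95% correct mechanism classification in the high-power
regime; an unbiased paternal negative control that breaks down, as
predicted, under selective paternal participation; agreement of the
spectral REML optimum with an independent 2-D grid search of the
restricted likelihood (coarse grid, then 10⁻³-step refinement around
the coarse optimum); GRM kinship expectations (0.5 full sibs, 0
unrelateds, exact allele-relabel invariance); exact transform
behaviour; and conditional F ≈ 100 ≫ 10 for a score explaining 2% of
exposure variance at n = 10,000.

They do **not** show robustness to features the generator omits: LD
between loci, population stratification, assortative mating, imputation
uncertainty, X-chromosome loci, non-normal or categorical outcomes,
dynastic effects beyond the modelled paths, or real questionnaire
psychometrics (scales are item sums, not factor models).  Passing tests
demonstrate that the estimators and decision rules behave as designed
under the stated model, not that real-data analyses are unbiased.

## Numerical choices and degenerate inputs

Profiled REML is optimised on log λ ∈ [−12, 12] with xatol 10⁻¹⁰;
monomorphic background loci are dropped; an all-monomorphic background,
an all-missing outcome vector, sex strata smaller than 2, zero-width
item matrices and design matrices with fewer complete cases than
columns are all errors rather than silent degradation.  Same-seed
cohort generation is byte-identical on disk (floats are written with
round-trip precision).  Outcome skipping (fewer than 50 complete cases)
is logged, mirroring per-outcome sample-size variation in real tables.
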