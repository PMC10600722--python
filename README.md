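# triomr — within-family Mendelian randomization of intrauterine growth

Observational cohorts consistently report that lower birth weight
predicts more neurodevelopmental difficulties (NDDs) in childhood —
language and motor delays, inattention, hyperactivity, social
communication problems.  Whether the *intrauterine environment* causes
those difficulties is a different question: the association could just
as well reflect familial confounding or pleiotropy.  `triomr`
implements a within-family Mendelian randomization design that attacks
this question with genotyped parent–offspring trios, together with a
synthetic trio-cohort generator so the whole pipeline runs and is
testable at desk scale without access-restricted registry data.

## The design

Birth-weight-associated SNPs can act on fetal growth through the
**maternal** genome (shaping the intrauterine environment) or through
the **fetal** genome (direct growth effects).  Taking that partition as
given, six nested allele-score sets are built (M1 ⊇ M2 ⊇ M3 with
maternal effects, F1 ⊇ F2 ⊇ F3 with fetal effects) and, for each
family role *r* ∈ {maternal, offspring, paternal}, the score

&nbsp;&nbsp;&nbsp;&nbsp;S_r = Σ_i w_i · g_ri ,

with w_i = 1 (unweighted, primary) or the maternal/fetal per-allele
effect (weighted sensitivity).  Because per-allele effects on the
*latent* intrauterine exposure are unknown, no causal effect is
estimated; the pipeline tests the **causal null** with the conditional
mixed model

&nbsp;&nbsp;&nbsp;&nbsp;y = β_m S_m + β_o S_o + β_f S_f + covariates + g + e ,
&nbsp;&nbsp;&nbsp;&nbsp;g ~ N(0, σ²_g A), e ~ N(0, σ²_e I)

fitted by spectral REML, where y is the rank-inverse-normal NDD score
and A a genetic relationship matrix built from background loci (±1 Mb
around score SNPs excluded).  Conditioning on the offspring score
blocks the transmitted-genotype path; the paternal score is a negative
control — fathers cannot act through the womb, so:

| pattern of conditional associations | reading |
|---|---|
| maternal ≠ 0, paternal ≈ 0 | intrauterine effect |
| maternal ≈ paternal ≠ 0 | postnatal / shared environment |
| offspring only ≠ 0 | pleiotropy through the offspring genome |
| none | null |

Trio, mother–offspring-dyad and father–offspring-dyad designs are all
supported (dyads drop the missing parent's score and covariates), with
sex stratification, a conditional-F instrument-strength diagnostic, and
a multiplicity threshold of 0.05 divided by the eigenvalue-based
effective number of independent outcomes.

## Worked example

```python
import triomr as t

panel = t.replicate_panel(n_snps=50, seed=7)
cfg = t.ScenarioConfig.intrauterine_causal(n_families=2000, seed=1,
                                           n_outcomes=1, item_level=False)
cohort = t.simulate_cohort(panel, cfg)
res = t.run_mr(cohort, design="trio", set_id="M1", weighting="unweighted")
print(res[["focal_role", "n", "beta", "se", "p"]].to_string(index=False))
verdict = t.interpret(res, threshold=0.005)
print(next(iter(verdict.values())).pattern)
```

prints

```
focal_role    n      beta       se        p
  maternal 2000  0.027295 0.005791 0.000002
 offspring 2000 -0.002313 0.006702 0.729974
  paternal 2000  0.001507 0.005940 0.799787
intrauterine_effect
```

The cohort was generated with an intrauterine causal path only: the
maternal score associates strongly with the (rank-INT) outcome after
conditioning on the offspring and paternal scores, both of which are
null — exactly the signature the verdict rule reads as an intrauterine
effect.  The same workflow is available from the shell via the `triomr`
CLI (`simulate`, `transform`, `score`, `grm`, `mr`, `interpret`,
`report`).

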