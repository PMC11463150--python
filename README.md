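# dopascore

Candidate-gene analysis of dopamine signaling and eating behavior: a
tested, reusable implementation of the **multilocus genetic score (MLGS)**
approach for four dopamine-pathway variants, together with everything
needed to run the downstream association analysis — Hardy–Weinberg
checks, eating-behavior instrument scoring, a stratified nonparametric
test battery, and a synthetic-cohort generator so the whole pipeline can
be exercised without any subject-level data.

## The science

Reward-deficiency models of overeating posit that genotypes associated
with *low* dopamine signaling predispose to compulsive eating.  Rather
than testing single SNPs, a multilocus genetic score aggregates a small
set of pathway variants.  Four biallelic loci are used here:

| Locus | Gene | Low-signaling allele | High-signaling allele |
|---|---|---|---|
| rs1800497 (Taq1A) | ANKK1 | A1 (= T) | A2 (= C) |
| rs1799732 (−141C Ins/Del) | DRD2 | Ins (= G) | Del |
| rs6277 (C957T) | DRD2 | T | C |
| rs4680 (Val158Met) | COMT | Met (= A) | Val (= G) |

Each locus contributes a score s ∈ {0, 0.5, 1}: 1 for the low-signaling
genotype, 0 for the high-signaling genotype, 0.5 for intermediate
heterozygotes — with the exception that the DRD2 −141C heterozygote
scores 0 (Del *carriers* are treated as high-signaling).  The MLGS is
the additive total over the four loci,

    MLGS = Σᵢ sᵢ  ∈ {0, 0.5, …, 4},

and is dichotomized at 2.0: subjects with MLGS ≥ 2.0 form the putatively
**low-dopamine-signaling** group.  Subjects must be genotyped at all
four loci to receive a score (complete-case); per-locus frequency tables
and Hardy–Weinberg goodness-of-fit X² tests (df = 1) use all non-missing
calls at each locus.

Phenotypes cover anthropometry (BMI, WHO weight classes with
normal < 25, overweight 25–29.9, obese ≥ 30 kg/m²; waist-to-height
ratio), the TFEQ-R18 (cognitive restraint / uncontrolled eating /
emotional eating, each the mean of its items on a 1–4 scale), the RVFQ
snack-choice percentage with its progressive press schedule (20 → 240),
the YFAS (first version; diagnosis = ≥ 3 of 7 symptoms **and** clinical
distress) and 24-h-recall nutrient intakes.  Group contrasts are
rank-based (Mann–Whitney, Kruskal–Wallis), overall, per weight-status
stratum and per sex; food-addiction prevalence is compared between
signaling groups by Fisher's exact test; correlations are Spearman.

## Worked example

Simulate a 221-subject cohort, score it and tabulate the score
distribution:

```bash
dopascore simulate --seed 7 --outdir cohort
dopascore score --genotypes cohort/genotypes.csv --out scores.csv
dopascore table2 --scores scores.csv
```

```
 score  n  percent
   0.0  0      0.0
   0.5  9      4.4
   1.0 22     10.7
   1.5 45     22.0
   2.0 47     22.9
   2.5 52     25.4
   3.0 24     11.7
   3.5  6      2.9
   4.0  0      0.0
score >= 2: 63% (129/205)
```

205 of 221 subjects are genotyped at all four loci (the generator blanks
calls at the study's attrition rate); 63% of them fall in the
low-signaling group.  The full analysis then writes every report table:

```bash
dopascore analyze --genotypes cohort/genotypes.csv \
                  --phenotypes cohort/phenotypes.csv --outdir report
cat report/fa_prevalence.tsv
```

```
stratum     n_low  n_high  fa_pct_low_signaling  fa_pct_high_signaling  test    p_value
all         129    76      25.5814               19.7368                fisher  0.395179
normal      50     32      14                    25                     fisher  0.248615
overweight  18     9       16.6667               22.2222                fisher  1
obese       61     35      37.7049               14.2857                fisher  0.0193766
```

At this sample size only the obesity stratum shows the configured
food-addiction contrast (prevalence higher in the low-signaling group,
Fisher p ≈ 0.02); the other strata are generated with no group
difference.  `report/` also contains `table1.tsv` (genotype frequencies
and HWE X² per locus), `table2.tsv`, `table3.tsv`/`table4.tsv`
(mean ± SD by group with Mann–Whitney p, per stratum and sex),
`correlations.tsv` and a `manifest.json` accounting for every subject
(`n_subjects = n_complete_case + n_excluded_missing`).

The same functionality is available as a library
(`dopascore.compute_mlgs`, `dopascore.hwe_chi_square`,
`dopascore.generate_cohort`, `dopascore.pipeline.run_full_analysis`, …).

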