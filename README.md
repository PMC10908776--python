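# psygrs

Genetic risk score (GRS) construction and treatment-response stratification
for psychotic depression cohorts.

Psychotic depression is a severe subtype of major depressive disorder with a
markedly elevated rate of treatment resistance. A small weighted GRS built
from treatment-resistant-depression GWAS summary statistics can stratify
patients by their risk of antidepressant nonresponse before treatment
starts. `psygrs` implements that analysis end to end, for biostatisticians
and psychiatric-genetics researchers who want to apply or replicate it:

- **Scoring engine** — harmonization of GWAS weights to a genotype panel
  (allele orientation, sign flips, strand-ambiguous exclusion), variant QC
  (MAF > 0.05, call rate > 98%, Hardy–Weinberg χ² p > 10⁻⁶), greedy windowed
  LD pruning (window 50, step 5, r² ≤ 0.5), and the weighted score
  S_i = Σ_j β_j · d_ij over effect-allele dosages d ∈ {0, 1, 2}, as a raw
  sum or a per-allele average S_i / (2m).
- **Population structure** — genotype PCA on the standardized dosage matrix
  (columns centered at 2p̂ and scaled by √(2p̂(1−p̂))), iterative SD-rule
  outlier flagging, and PC covariates for the regression models.
- **Risk stratification** — top-fraction membership (10%…50%), the 2×2
  table (a, b, c, d) of events by group, PPV = a/(a+b), NPV = d/(c+d),
  accuracy, sensitivity, specificity, the cross-product odds ratio
  OR = (a/b)/(c/d) with Wald 95% CI exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))
  and the z-test on ln OR, plus Haldane–Anscombe zero-cell correction.
- **Models and ROC** — point-biserial/Pearson correlations with Fisher-z
  CIs, logistic and linear regressions with McFadden/Nagelkerke pseudo-R²,
  nested-model likelihood-ratio comparison at α = 0.025, and ROC/AUC with
  Youden-index operating points.
- **Synthetic cohort generator** — a first-class module emulating the
  source trial's structure (n = 107 genotyped patients; 52 weight records of
  which 38 match the panel and 14 survive pruning; HAM-D-17 trajectories with
  baseline ≥ 18; ~18% dropout; ~76% of patients with zero prior adequate
  antidepressant trials), so every downstream stage is testable without
  clinical data.
- **Published-table verification** — the printed stratification summaries of
  the source analysis (rounded PPV/accuracy percentages plus fixed margins)
  are inverted by exhaustive enumeration to the unique underlying integer
  2×2 tables, and the odds-ratio machinery reproduces every printed OR, CI
  and p-value at printed precision.

## Worked example

```python
from psygrs import (SimulationConfig, simulate_cohort, qc_variants,
                    harmonize_weights, prune_ld, compute_grs, decile_report)

genotypes, weights_table, phenotypes = simulate_cohort(SimulationConfig(seed=11))
genotypes = qc_variants(genotypes)
weights = harmonize_weights(weights_table, genotypes)   # 52 records -> 38 on panel
pruned = prune_ld(genotypes, weights)                   # 38 -> 14 independent SNPs
scores = compute_grs(genotypes, pruned)                 # per-allele average GRS
for r in decile_report(scores, phenotypes["nonresponse"].to_numpy(float)):
    print(f"top {r.top_fraction:.0%}: PPV {r.ppv:.1%}  OR {r.odds_ratio:.2f} "
          f"({r.ci_low:.2f}-{r.ci_high:.2f})  p {r.p_value:.4f}")
```

prints

```
top 10%: PPV 80.0%  OR 6.27 (1.25-31.53)  p 0.0260
top 20%: PPV 73.7%  OR 5.13 (1.65-15.98)  p 0.0048
top 30%: PPV 73.1%  OR 6.00 (2.16-16.67)  p 0.0006
top 40%: PPV 60.0%  OR 3.09 (1.27-7.52)  p 0.0131
top 50%: PPV 60.0%  OR 4.23 (1.70-10.51)  p 0.0019
```

Each row reads: among the patients in that top GRS fraction, PPV is the
share who were nonresponders at week 7; the OR compares their odds of
nonresponse with the remaining patients (OR > 1 with p below 0.05 means the
cut-off concentrates nonresponders). In this synthetic cohort the planted
GRS effect (0.8 log-odds per SD) produces the same qualitative pattern the
clinical analysis reported: high PPVs and significant ORs down to the top
40–50%.

The `examples/` directory holds one short narrative script per capability
(simulation, scoring, PCA, stratification, models + ROC, published-table
verification); each prints what it computes and what the numbers mean. A
thin CLI mirrors the stages:

```bash
grs simulate --seed 11 --out cohort/
grs score --vcf cohort/genotypes.vcf --weights cohort/weights.tsv --out cohort/scores.tsv
grs stratify --scores cohort/scores.tsv --pheno cohort/phenotypes.csv --endpoint nonresponse
grs verify-table2
```

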