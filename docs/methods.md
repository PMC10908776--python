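# Methods

## The analysis

The package implements a small-panel genetic risk score (GRS) analysis of
antidepressant treatment outcomes in psychotic depression. A patient's GRS
is the weighted count of risk alleles,

    S_i = Σ_j β_j · d_ij ,

where β_j is the per-allele log-odds effect of variant j taken from external
GWAS summary statistics (treatment-resistant depression, suggestive
significance p < 5×10⁻⁶) and d_ij ∈ {0,1,2} counts the effect allele.
Downstream, patients are ranked by GRS, split at top-fraction cut-offs
(10%…50%), and each split is summarized by predictive values and the
cross-product odds ratio; covariate-adjusted logistic/linear models and ROC
curves quantify what the GRS adds beyond clinical covariates.

Clinical endpoints follow the source trial's definitions: *nonresponse* is a
decrease of less than 50% in the 17-item Hamilton Depression Rating Scale
(HAM-D-17) from baseline to week 7; *nonremission* is a week-7 HAM-D-17
above 7; the *adequate-trial count* is the number of prior antidepressant
trials at sufficient dose for ≥ 4 weeks with an ATHF reliability score ≥ 3.
Since remission (week-7 ≤ 7) implies at least a 50% drop for any baseline
≥ 16, remitters are a subset of responders; equivalently every nonresponder
is a nonremitter.

## Scoring pipeline

**Harmonization.** Weights are matched to the panel by variant id.
If the effect allele equals the panel alt allele the weight is used as-is;
if the effect/other pair is the panel pair in reverse orientation the weight
is sign-flipped and flagged; strand-ambiguous pairs (A/T, C/G) are dropped
because orientation cannot be resolved without strand information; ids
absent from the panel and allele pairs matching neither orientation are
dropped and counted. The report carries all five counters.

**Variant QC** retains variants with minor-allele frequency > 0.05,
call rate > 98%, and a one-degree-of-freedom χ² Hardy–Weinberg p > 10⁻⁶
computed on complete genotypes. The χ² form (rather than an exact test) is
closed-form testable and matches the threshold style of standard GWAS QC
pipelines. QC is idempotent.

**LD pruning** is greedy and windowed: within each sliding window of 50
consecutive variants (per chromosome, advancing by 5), while any retained
pair has squared dosage correlation above 0.5, one member of the worst pair
is removed. The removal rule — drop the variant with the smaller |aligned
weight|, ties broken by larger genomic position — is deterministic and
preserves the most informative weights; it intentionally differs from
MAF-based tool heuristics, which the source tooling does not document
precisely. Sweeps repeat until a full pass makes no removal, so no offending
pair that ever shares a window survives. Pairs whose index distance exceeds
the window are never compared, as with the conventional windowed tools.

**Scoring** defaults to the per-allele average S_i / (2 m), matching the
cited tool's default and the magnitude of the reported score median
(≈ 6.4×10⁻³); the raw sum is first-class. Missing dosages are imputed to
twice the alt-allele frequency by default; with imputation off they drop out
of both numerator and denominator, and an individual with no observed
variant gets a missing score. Both normalizations are exposed because the
source analysis does not state which it used; the reported score range is
consistent with per-allele averaging.

## Stratification statistics

For a cut-off keeping the k = ⌈fraction·n⌉ highest scores (ties resolved by
stable input order), the 2×2 table against an endpoint is a = events in the
top group, b = non-events in the top group, c, d likewise in the reference
group; individuals with missing endpoints are excluded once, identically for
every row. Then PPV = a/(a+b), NPV = d/(c+d), accuracy = (a+d)/n,
OR = ad/bc with SE(ln OR) = √(1/a+1/b+1/c+1/d), 95% CI
exp(ln OR ± 1.96·SE), and a two-sided p from z = ln OR / SE. A table with a
zero cell receives the Haldane–Anscombe correction (+0.5 to every cell)
before all three quantities, with a flag; the policy is configurable.
Stratification p-values are flagged at 0.05, matching the published table's
convention; no multiplicity correction is applied across rows, as none was
in the source.

**Published-row verification.** The published stratification table prints
rounded percentages and the OR/CI/p per row. With the margins fixed (n = 88
analyzed patients; 32 nonresponders, 50 nonremitters), enumerating all
integer tables whose top-group size lies within ±0.03·n of fraction·n and
whose PPV (and, for the nonresponse rows, accuracy) round half-up to the
printed one-decimal values leaves exactly one candidate for eight of the
ten rows; recomputing OR, CI and p on those tables reproduces every printed
value at printed precision. The size window is needed because group
membership was assigned on all 107 scored patients and then tabulated on
the 88 with complete outcomes, so the analyzed group size can deviate from
fraction·88 by a few patients. The two top-10% rows are internally
inconsistent as printed (no integer table matches PPV = 100% with the
printed NPV/accuracy, and the printed ORs 52.37/21.34 match no standard
zero-cell correction on any candidate); they are reported as excluded.
Two further printing artifacts are documented rather than imitated: the
nonremission "NPV" column equals c/(c+d) for every reconstructible row, and
the nonremission accuracy column equals the 56.8% base rate in four rows.
This package always reports the standard definitions.

## Regression models and ROC

Binary endpoints use maximum-likelihood logistic regression (Newton,
gradient tolerance 10⁻⁸; perfect separation and non-convergence raise
diagnostics), the trial count ordinary least squares. Logistic fit quality
is reported as McFadden, McFadden-adjusted and Nagelkerke pseudo-R²; the
source analysis printed an unnamed "adjusted R²" for logistic models, so no
single variant is privileged and the comparison metric is always labelled
(Nagelkerke by default). Negative adjusted R² values are reported as-is.
Nested models are compared by likelihood ratio with the significance flag at
the multiplicity-adjusted α = 0.025. Missing data are handled complete-case
per model. ROC curves place one operating point per distinct predicted
value (ties grouped); the trapezoidal AUC equals the tie-adjusted
Mann–Whitney estimator identically, and the Youden point maximizes
sensitivity + specificity − 1 with ties broken toward sensitivity.
Model-based ROC curves use in-sample predictions, as the source analysis
did; the report says so, since in-sample AUCs are optimistic. Bootstrap AUC
CIs (2,000 seeded resamples) are descriptive conveniences.

## Synthetic cohort generator

The generator's defaults are the study conditions: 107 genotyped
individuals; a 38-variant panel organized in 14 LD blocks (sizes
5,4,4,3,3,3,3,2,2,2,2,2,2,1); 52 weight records of which 14 carry ids absent
from the panel; half-normal per-allele weights at scale 0.025 (oriented to
the risk allele, giving a per-allele-averaged score median near the
reported 6.4×10⁻³); per-endpoint intercepts −0.56 (nonresponse) and −0.75
(conditional nonremission among responders), calibrated to the reported
36.4% / 56.8% completer rates; a GRS liability of 0.8 log-odds per SD,
which yields point-biserial correlations near the reported ±0.3; dropout
rate 0.178 (≈ 19 of 107 missing week-7 endpoints); and adequate-trial count
probabilities (0.757, 0.197, 0.037, 0, 0.009) over 0–4 trials, reproducing
the reported right skew.

**Genotypes.** Each variant is Hardy–Weinberg distributed at its allele
frequency; one ancestral frequency is drawn per LD block from
maf_range = (0.10, 0.5) — LD partners in real data carry near-identical
allele frequencies, and equal frequencies let the copula (below) express
strong genotype correlation. The floor of 0.10 reflects that the weight
SNPs already passed MAF > 0.05 QC in a very large GWAS, so panel QC at
n = 107 retains them. Substructure uses Balding–Nichols subpopulation
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with a single Fst knob. LD is
induced by a Gaussian copula: block-mates share a latent factor and each
latent is thresholded at the HWE genotype quantiles. Thresholding
attenuates correlation, so the declared block r is treated as the *target
genotype correlation*: the genotype covariance of the copula has a closed
form in bivariate-normal orthant probabilities, and the latent correlation
is inverted numerically (Brent's method) to deliver the declared value.
At the default 0.99 the realized genotype r² within blocks is ≈ 0.98, so
greedy pruning at r² = 0.5 keeps exactly one variant per block — the
38 → 14 trajectory.

**Outcomes.** Nonresponse is drawn from a logistic model on the
standardized GRS plus centered covariates (age, sex, combination-treatment
arm, severity; default effects 0.02, −0.2, −0.5, 0.15 — modest, with the
combination arm protective as in the trial). Nonremission is drawn so every
nonresponder is a nonremitter. Week-7 HAM-D-17 integers are then
synthesized to be exactly consistent with both flags (nonresponder:
week-7 > baseline/2; responder non-remitter: 8…⌊baseline/2⌋; remitter:
0…7), baseline being a truncated normal (31.8 ± 5.2, support 18–52)
rounded to integers. Dropouts are generated then masked, with the pre-mask
columns retained (suffix `_complete`) so complete-data oracles remain
possible in tests. Treatment histories contain exactly the drawn number of
adequate trials plus 0–2 inadequate ones, so the ATHF counting rule is
exercised, not assumed.

**What the generator does not emulate:** genuine haplotype structure and
recombination maps, imputation dosages and INFO scores, array intensities,
genotype–covariate correlation, informative (outcome-dependent) dropout,
and secular trends in symptom scores. Tests passing on this generator
certify the pipeline's statistical machinery under its stated model — not
performance of any specific GRS on real patients.

## Numerical choices and edge cases

- Rounding for printed-value comparison is half-up at the printed decimals
  (the convention of the published table), implemented with decimal
  arithmetic, not binary-float `round`.
- Tie handling is deterministic everywhere: stable input order at decile
  boundaries, larger-position removal at equal |weight| in pruning, higher
  sensitivity at equal Youden J, largest-|loading|-positive sign convention
  in PCA.
- The outlier rule (6 SD on 2 components, ≤ 5 iterations, means/SDs
  recomputed on the unflagged set) flags cascades of graded outliers; a
  group of several equally displaced individuals inflates the component SD
  in proportion to the displacement itself and is not flaggable by any
  fixed SD multiple — a structural property of SD rules worth knowing when
  interpreting "n outliers removed" statements.
- Zero denominators in predictive values yield NaN markers, never
  exceptions; degenerate 2×2 tables (two zeros in one margin) yield NaN
  odds ratios with the correction flag set.
- Monte-Carlo test sizes (e.g. 100-replicate coverage checks at n = 2,000,
  500-replicate type-I checks at n = 400) were chosen so each property test
  completes in seconds while keeping the Monte-Carlo SE small relative to
  the asserted tolerance; the tolerances themselves are 3-SE bands around
  the theoretical values.

## Known limitations

- Variant matching is by id only; positional/allele-based matching across
  builds is out of scope, as are multi-allelic variants and imputed
  (non-integer) dosages.
- The windowed pruning contract constrains only pairs that share a window;
  long-range LD beyond the window survives by design.
- In-sample AUCs and unpenalized refitting mean the model-comparison
  numbers describe fit improvement, not validated predictive performance.
- The published top-10% rows cannot be verified from the printed summaries;
  the package reports them as excluded rather than guessing the intended
  counts.
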