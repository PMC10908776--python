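"""Top-decile GRS stratification with predictive values and odds ratios.

Builds the synthetic cohort, scores it, and prints one row per top-fraction
cut-off (10%...50%) for treatment nonresponse: PPV, NPV, accuracy, the
cross-product odds ratio with its Wald 95% CI, and the z-test p-value.
"""

from psygrs import (
    SimulationConfig,
    compute_grs,
    decile_report,
    harmonize_weights,
    prune_ld,
    qc_variants,
    simulate_cohort,
)

genotypes, weights_table, phenotypes = simulate_cohort(SimulationConfig(seed=11))
genotypes = qc_variants(genotypes)
scores = compute_grs(genotypes, prune_ld(genotypes, harmonize_weights(weights_table, genotypes)))

rows = decile_report(scores, phenotypes["nonresponse"].to_numpy(dtype=float))
print("fraction  a/b/c/d       PPV    NPV    acc     OR   95% CI          p")
for r in rows:
    print(
        f"top {r.top_fraction:.0%}   {'/'.join(map(str, r.table.cells)):<12}"
        f" {r.ppv:5.1%} {r.npv:6.1%} {r.accuracy:6.1%}"
        f" {r.odds_ratio:6.2f}  ({r.ci_low:.2f}-{r.ci_high:.2f})  {r.p_value:.4f}"
    )
# A rising PPV toward the top decile with ORs above 1 is the signature of a
# score that concentrates nonresponders among its highest values; individuals
# with missing week-7 outcomes are excluded from every row identically.
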