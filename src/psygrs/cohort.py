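"""Synthetic cohort generator for the treatment-response GRS pipeline.

Emulates the structure of a small randomized clinical trial of psychotic
depression used to evaluate a treatment-resistance genetic risk score:
~107 genotyped inpatients, a handful of GWAS-weighted SNPs (52 reported, 38
available on the panel, 14 after LD pruning), HAM-D-17 depression scores at
baseline (inclusion requires >= 18) and week 7, binary nonresponse
(< 50% HAM-D decrease) and nonremission (week-7 HAM-D > 7) endpoints,
~18% dropout before the week-7 assessment, and a strongly right-skewed count
of prior adequate antidepressant trials (~76% zeros).

Genotypes are Hardy-Weinberg draws at uniform MAFs.  Linkage disequilibrium
is induced by a Gaussian copula: correlated latent normals are thresholded at
the HWE genotype quantiles, so the pairwise latent correlation maps
monotonically to the genotype correlation.  Population substructure uses
Balding-Nichols beta-distributed subpopulation allele frequencies with a
single Fst knob.  Outcomes follow a logistic liability on the standardized
GRS plus clinical covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .scoring import GenotypeMatrix, ScoreVector

__all__ = [
    "SimulationConfig",
    "TreatmentRecord",
    "simulate_genotypes",
    "simulate_weights",
    "simulate_outcomes",
    "simulate_cohort",
    "count_adequate_trials",
    "derive_endpoints",
]

#: Non-ambiguous ref/alt pairs used by default (ambiguous pairs are A/T, C/G).
_SAFE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: Default LD block layout: 14 blocks over 38 variants, mirroring a panel on
#: which greedy pruning at r^2 = 0.5 keeps one variant per block.
_DEFAULT_BLOCKS = [5, 4, 4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1]

_ARMS = ["venlafaxine", "imipramine", "venlafaxine_quetiapine"]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults reproduce the source trial's structure: 107 genotyped
    individuals; a 38-variant panel in 14 high-LD blocks receiving weights
    from 52 summary-statistic records (14 of which do not match the panel);
    a 17.8% dropout rate; adequate-trial count probabilities matching the
    reported 75.7% zero fraction; and a log-odds of nonresponse of 0.8 per
    standard deviation of GRS, which yields a point-biserial correlation with
    response of roughly -0.3.
    """

    n_individuals: int = 107
    n_variants: int = 38
    maf_range: tuple[float, float] = (0.10, 0.5)
    ld_block_sizes: list[int] = field(default_factory=lambda: list(_DEFAULT_BLOCKS))
    ld_within_block_r: float = 0.99
    n_subpops: int = 1
    subpop_fst: float = 0.0
    n_causal: int | None = None  # None = every panel variant carries a weight
    beta_scale: float = 0.025
    n_weights_extra: int = 14  # summary-stat records whose ids miss the panel
    swap_allele_fraction: float = 0.0
    ambiguous_fraction: float = 0.0
    genotype_missing_rate: float = 0.0
    intercepts: dict = field(
        default_factory=lambda: {"nonresponse": -0.56, "nonremission": -0.75}
    )
    beta_grs: float = 0.8
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.02, "sex": -0.2, "treatment_arm": -0.5, "severity": 0.15}
    )
    dropout_rate: float = 0.178
    trial_count_probs: tuple[float, ...] = (0.757, 0.197, 0.037, 0.0, 0.009)
    seed: int = 2026

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0:
            raise ValueError("n_individuals and n_variants must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.ld_within_block_r < 1.0:
            raise ValueError("ld_within_block_r must be in [0, 1)")
        if sum(self.ld_block_sizes) > self.n_variants:
            raise ValueError("ld_block_sizes exceed n_variants")
        if any(s <= 0 for s in self.ld_block_sizes):
            raise ValueError("ld block sizes must be positive")
        if self.n_subpops <= 0:
            raise ValueError("n_subpops must be positive")
        if self.subpop_fst < 0:
            raise ValueError("subpop_fst must be >= 0")
        if self.n_causal is not None and self.n_causal > self.n_variants:
            raise ValueError("n_causal cannot exceed n_variants")
        for frac_name in ("swap_allele_fraction", "ambiguous_fraction", "dropout_rate", "genotype_missing_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be a probability")
        probs = np.asarray(self.trial_count_probs, dtype=float)
        if (probs < 0).any() or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("trial_count_probs must be non-negative and sum to 1")


@dataclass
class TreatmentRecord:
    """One antidepressant trial in a patient's treatment history.

    A trial is *adequate* when the dose was sufficient, it lasted at least
    four weeks, and the ATHF reliability score is at least 3 (moderate
    confidence in the record).
    """

    drug_name: str
    dose_adequate: bool
    duration_weeks: float
    athf_score: int

    def __post_init__(self) -> None:
        if not 0 <= self.athf_score <= 5:
            raise ValueError(f"athf_score must be in 0..5, got {self.athf_score}")
        if self.duration_weeks < 0:
            raise ValueError("duration_weeks must be >= 0")

    @property
    def is_adequate(self) -> bool:
        return bool(self.dose_adequate and self.duration_weeks >= 4 and self.athf_score >= 3)


def count_adequate_trials(history: list[TreatmentRecord]) -> int:
    """Number of adequate antidepressant trials in a treatment history."""
    return sum(1 for rec in history if rec.is_adequate)


def derive_endpoints(baseline: np.ndarray, week7: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derive (nonresponse, nonremission) from HAM-D-17 trajectories.

    Nonresponse: decrease from baseline to week 7 is below 50% of baseline.
    Nonremission: week-7 score above 7.  NaN week-7 scores (dropouts)
    propagate to NaN endpoints.
    """
    baseline = np.asarray(baseline, dtype=float)
    week7 = np.asarray(week7, dtype=float)
    with np.errstate(invalid="ignore"):
        nonresponse = ((baseline - week7) < 0.5 * baseline).astype(float)
        nonremission = (week7 > 7).astype(float)
    nonresponse[np.isnan(week7)] = np.nan
    nonremission[np.isnan(week7)] = np.nan
    return nonresponse, nonremission


def _genotype_correlation(r_latent: float, p: float) -> float:
    """Genotype correlation induced by a latent-normal copula at ``r_latent``.

    Under the copula a genotype is the sum of two threshold indicators of one
    latent normal (thresholds at the HWE quantiles), so the covariance of two
    genotypes decomposes into four bivariate-normal orthant terms; the HWE
    genotype variance is 2p(1-p).
    """
    if r_latent <= 0:
        return max(r_latent, 0.0)
    q0 = (1 - p) ** 2
    q1 = q0 + 2 * p * (1 - p)
    thresholds = stats.norm.ppf([q0, q1])
    cov = 0.0
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, r_latent], [r_latent, 1.0]])
    for bi in thresholds:
        for bj in thresholds:
            upper = 1.0 - stats.norm.cdf(bi) - stats.norm.cdf(bj) + mvn.cdf([bi, bj])
            cov += upper - (1.0 - stats.norm.cdf(bi)) * (1.0 - stats.norm.cdf(bj))
    return cov / (2 * p * (1 - p))


def _latent_correlation_for_target(p: float, target_r: float) -> float:
    """Latent copula correlation delivering genotype correlation ``target_r``."""
    from scipy.optimize import brentq

    if target_r <= 0:
        return 0.0
    hi = 1.0 - 1e-9
    if _genotype_correlation(hi, p) <= target_r:
        return hi
    return float(brentq(lambda rl: _genotype_correlation(rl, p) - target_r, 1e-9, hi, xtol=1e-6))


def _block_layout(config: SimulationConfig) -> list[list[int]]:
    """Contiguous variant-index blocks; unassigned variants are singletons."""
    blocks, i = [], 0
    for size in config.ld_block_sizes:
        blocks.append(list(range(i, i + size)))
        i += size
    while i < config.n_variants:
        blocks.append([i])
        i += 1
    return blocks


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an individuals x variants dosage matrix under the configured model.

    Within each subpopulation every variant is in Hardy-Weinberg equilibrium
    at its (Balding-Nichols perturbed) allele frequency; variants within an LD
    block share correlated copula latents at ``ld_within_block_r``.
    Deterministic for a given config/seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    # one ancestral frequency per LD block: variants in strong LD carry
    # near-identical allele frequencies, and equal copula thresholds let the
    # latent correlation translate into genotype correlation without the
    # attenuation that unequal thresholds would impose
    blocks = _block_layout(config)
    ancestral = np.empty(m)
    for block in blocks:
        ancestral[block] = rng.uniform(lo, hi)

    # Subpopulation allele frequencies (Balding-Nichols)
    fst = config.subpop_fst
    if config.n_subpops > 1 and fst > 0:
        a = ancestral * (1 - fst) / fst
        b = (1 - ancestral) * (1 - fst) / fst
        freqs = rng.beta(a, b, size=(config.n_subpops, m))
        freqs = np.clip(freqs, 1e-4, 1 - 1e-4)
    else:
        freqs = np.tile(ancestral, (config.n_subpops, 1))
    subpop = np.repeat(np.arange(config.n_subpops), math.ceil(n / config.n_subpops))[:n]

    # Correlated latent normals per LD block, thresholded at HWE quantiles.
    # The declared block r is the target *genotype* correlation; thresholding
    # attenuates latent correlation, so the latent value is calibrated per
    # block to deliver the requested genotype correlation at the block MAF.
    z = rng.standard_normal((n, m))
    r = config.ld_within_block_r
    for block in blocks:
        if len(block) > 1 and r > 0:
            r_latent = _latent_correlation_for_target(float(ancestral[block[0]]), r)
            shared = rng.standard_normal(n)
            z[:, block] = math.sqrt(r_latent) * shared[:, None] + math.sqrt(1 - r_latent) * z[:, block]

    p_ind = freqs[subpop, :]  # (n, m) per-individual allele frequency
    q0 = (1 - p_ind) ** 2
    q1 = q0 + 2 * p_ind * (1 - p_ind)
    u = stats.norm.cdf(z)
    dosages = np.where(u < q0, 0.0, np.where(u < q1, 1.0, 2.0))

    if config.genotype_missing_rate > 0:
        mask = rng.random((n, m)) < config.genotype_missing_rate
        dosages[mask] = np.nan

    n_ambig = int(round(config.ambiguous_fraction * m))
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    refs = [_SAFE_PAIRS[k][0] for k in pair_idx]
    alts = [_SAFE_PAIRS[k][1] for k in pair_idx]
    if n_ambig:
        which = rng.choice(m, size=n_ambig, replace=False)
        ap = rng.integers(0, len(_AMBIG_PAIRS), size=n_ambig)
        for j, k in zip(which, ap):
            refs[j], alts[j] = _AMBIG_PAIRS[k]

    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{1000 + j}" for j in range(m)],
            "chrom": ["1"] * m,
            "pos": np.arange(1, m + 1) * 10_000,
            "ref": refs,
            "alt": alts,
        }
    )
    samples = [f"IND{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)
    gm.subpop = subpop  # ancillary truth for structure tests
    return gm


def simulate_weights(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GWAS-style summary statistics table carrying the scoring weights.

    Every panel variant is listed plus ``n_weights_extra`` records with ids
    absent from the panel (unavailable on the genotyping array, as happens
    across imputation panels).  ``n_causal`` variants carry half-normal
    effects at scale ``beta_scale`` oriented to the risk allele; all p-values
    fall below the suggestive-significance cut 5e-6 so the downstream filter
    keeps them.  A ``swap_allele_fraction`` of records is emitted in the
    opposite allele orientation (effect/other swapped, beta negated) to
    exercise harmonization sign-flipping.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    m = genotypes.n_variants
    n_causal = m if config.n_causal is None else config.n_causal
    if n_causal > m:
        raise ValueError("n_causal cannot exceed the panel variant count")
    betas = np.zeros(m)
    causal = rng.choice(m, size=n_causal, replace=False)
    betas[causal] = np.abs(rng.normal(0.0, config.beta_scale, size=n_causal))

    v = genotypes.variants
    rows = []
    swap = rng.random(m) < config.swap_allele_fraction
    for j in range(m):
        ea, oa, b = v.at[j, "alt"], v.at[j, "ref"], betas[j]
        if swap[j]:
            ea, oa, b = oa, ea, -b
        rows.append(
            {
                "variant_id": v.at[j, "variant_id"],
                "chrom": v.at[j, "chrom"],
                "pos": int(v.at[j, "pos"]),
                "effect_allele": ea,
                "other_allele": oa,
                "beta": b,
                "p_value": 10.0 ** rng.uniform(-8, math.log10(5.0e-6)),
            }
        )
    # Records unavailable on this panel (different array / imputation panel)
    for k in range(config.n_weights_extra):
        ref, alt = _SAFE_PAIRS[rng.integers(0, len(_SAFE_PAIRS))]
        rows.append(
            {
                "variant_id": f"rs9{9000 + k}",
                "chrom": "2",
                "pos": int((k + 1) * 10_000),
                "effect_allele": alt,
                "other_allele": ref,
                "beta": float(np.abs(rng.normal(0.0, config.beta_scale))),
                "p_value": 10.0 ** rng.uniform(-8, math.log10(5.0e-6)),
            }
        )
    return pd.DataFrame(rows)


def _simulate_history(rng: np.random.Generator, n_adequate: int) -> list[TreatmentRecord]:
    """Treatment history containing exactly ``n_adequate`` adequate trials."""
    drugs = ["citalopram", "fluoxetine", "paroxetine", "sertraline", "nortriptyline", "mirtazapine"]
    history = []
    for _ in range(n_adequate):
        history.append(
            TreatmentRecord(
                drug_name=drugs[rng.integers(0, len(drugs))],
                dose_adequate=True,
                duration_weeks=float(4 + rng.integers(0, 9)),
                athf_score=int(rng.integers(3, 6)),
            )
        )
    for _ in range(int(rng.integers(0, 3))):  # inadequate attempts
        mode = rng.integers(0, 3)
        history.append(
            TreatmentRecord(
                drug_name=drugs[rng.integers(0, len(drugs))],
                dose_adequate=bool(mode != 0),
                duration_weeks=float(rng.integers(0, 4)) if mode != 2 else float(4 + rng.integers(0, 5)),
                athf_score=int(rng.integers(0, 3)) if mode == 2 else int(rng.integers(0, 6)),
            )
        )
    rng.shuffle(history)
    return history


def simulate_outcomes(
    grs: ScoreVector | np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Covariates, HAM-D-17 trajectories, endpoints and treatment histories.

    Nonresponse is drawn from a logistic model on the standardized GRS plus
    centered covariates; nonremission is drawn so that every nonresponder is
    a nonremitter (remission is the stricter outcome).  Week-7 HAM-D scores
    are synthesized to be exactly consistent with the drawn endpoints, then
    masked for the dropout fraction (the pre-mask scores are kept in
    ``*_complete`` columns so complete-data oracles remain possible).
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    values = grs.values if isinstance(grs, ScoreVector) else np.asarray(grs, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("GRS values must be finite")
    n = values.size
    sd = values.std(ddof=1) if n > 1 else 0.0
    z = (values - values.mean()) / sd if sd > 0 else np.zeros(n)

    age = np.clip(rng.normal(51.0, 10.4, size=n), 18.0, 65.0)
    sex = (rng.random(n) < 0.477).astype(int)  # 1 = female
    arm = rng.choice(_ARMS, size=n)
    severity = rng.choice([4, 5, 6, 7], size=n, p=[0.15, 0.40, 0.30, 0.15])
    a, b = (18 - 31.8) / 5.2, (52 - 31.8) / 5.2
    baseline = np.rint(stats.truncnorm.rvs(a, b, loc=31.8, scale=5.2, size=n, random_state=rng)).astype(int)

    eff = config.covariate_effects
    arm_combo = (arm == "venlafaxine_quetiapine").astype(float)
    cov_lp = (
        eff.get("age", 0.0) * (age - 51.0)
        + eff.get("sex", 0.0) * (sex - 0.477)
        + eff.get("treatment_arm", 0.0) * (arm_combo - 1.0 / 3.0)
        + eff.get("severity", 0.0) * (severity - 5.45)
    )
    lp_nr = config.intercepts["nonresponse"] + config.beta_grs * z + cov_lp
    nonresponse = (rng.random(n) < expit(lp_nr)).astype(int)
    # conditional nonremission among responders; nonresponders are nonremitters
    lp_nm = config.intercepts["nonremission"] + config.beta_grs * z + cov_lp
    extra_nonremit = (rng.random(n) < expit(lp_nm)).astype(int)
    nonremission = np.where(nonresponse == 1, 1, extra_nonremit)

    week7 = np.empty(n, dtype=int)
    for i in range(n):
        half = baseline[i] // 2
        if nonresponse[i]:
            week7[i] = rng.integers(half + 1, min(52, baseline[i] + 4) + 1)
        elif nonremission[i]:
            week7[i] = rng.integers(8, half + 1)  # responded but week-7 score > 7
        else:
            week7[i] = rng.integers(0, 8)  # remission

    dropout = (rng.random(n) < config.dropout_rate).astype(int)
    week7_masked = week7.astype(float)
    week7_masked[dropout == 1] = np.nan
    nr_masked, nm_masked = derive_endpoints(baseline, week7_masked)

    n_adeq = rng.choice(len(config.trial_count_probs), size=n, p=config.trial_count_probs)
    histories = [_simulate_history(rng, int(k)) for k in n_adeq]
    n_trials = np.array([count_adequate_trials(h) for h in histories])

    return pd.DataFrame(
        {
            "individual_id": [f"IND{i:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "treatment_arm": arm,
            "severity": severity,
            "hamd_baseline": baseline,
            "hamd_week7": week7_masked,
            "hamd_week7_complete": week7,
            "dropout": dropout,
            "nonresponse": nr_masked,
            "nonremission": nm_masked,
            "nonresponse_complete": nonresponse,
            "nonremission_complete": nonremission,
            "n_adequate_trials": n_trials,
            "treatment_history": [
                [
                    {
                        "drug_name": r.drug_name,
                        "dose_adequate": r.dose_adequate,
                        "duration_weeks": r.duration_weeks,
                        "athf_score": r.athf_score,
                    }
                    for r in h
                ]
                for h in histories
            ],
        }
    )


def simulate_cohort(config: SimulationConfig):
    """Full synthetic study: genotypes, summary-statistic weights, phenotypes.

    Convenience wrapper seeding the three generators from one root seed.
    Phenotypes are generated from the *oracle* GRS (all panel weights, true
    orientation) so that downstream harmonization choices do not alter the
    generative truth.
    """
    from .scoring import compute_grs, harmonize_weights

    genotypes = simulate_genotypes(config)
    weights_table = simulate_weights(genotypes, config)
    oracle = harmonize_weights(weights_table, genotypes, p_max=5.0e-6)
    if len(oracle) == 0:
        grs_values = np.zeros(config.n_individuals)
    else:
        grs_values = compute_grs(genotypes, oracle, mode="mean_per_allele").values
    phenotypes = simulate_outcomes(grs_values, config)
    return genotypes, weights_table, phenotypes
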