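"""Genetic risk score engine: variant QC, weight harmonization, LD pruning, scoring.

The genetic risk score (GRS) of an individual is the weighted sum of effect-allele
dosages over a set of variants selected from external GWAS summary statistics:

    S_i = sum_j beta_j * dosage_ij

where ``beta_j`` is the per-allele log-odds effect oriented to the allele counted
by the genotype panel.  The panel and the summary statistics were typically
produced on different arrays and imputation panels, so before scoring the
weights must be *harmonized* (allele orientation resolved, strand-ambiguous
variants dropped), the panel *quality-controlled* (minor allele frequency,
call rate, Hardy-Weinberg equilibrium), and the surviving variants *pruned*
for linkage disequilibrium so that the score is built from approximately
independent signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "WeightSet",
    "ScoreVector",
    "EmptyPanelError",
    "hwe_chisq",
    "qc_variants",
    "harmonize_weights",
    "prune_ld",
    "compute_grs",
    "AMBIGUOUS_PAIRS",
]

#: Strand-ambiguous allele pairs: indistinguishable after strand flip.
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

VALID_BASES = frozenset("ACGT")


class EmptyPanelError(ValueError):
    """All variants were removed by a filtering step."""


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    Dosages count copies of the alt allele and live in {0, 1, 2}; missing
    genotypes are ``NaN``.  ``variants`` is a DataFrame with columns
    ``variant_id, chrom, pos, ref, alt`` aligned to the dosage columns.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("sample count does not match dosage rows")
        if m != len(self.variants):
            raise ValueError("variant count does not match dosage columns")
        if self.variants["variant_id"].duplicated().any():
            dups = self.variants.loc[self.variants["variant_id"].duplicated(), "variant_id"]
            raise ValueError(f"duplicate variant ids: {sorted(set(dups))}")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing (NaN)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant, from non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx].copy(),
        )

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(j) != 1:
            raise KeyError(variant_id)
        return self.dosages[:, j[0]]


@dataclass
class WeightSet:
    """Scoring weights aligned to a genotype panel.

    ``table`` columns: ``variant_id, counted_allele, aligned_beta,
    sign_flipped``; the counted allele is always the panel's alt allele so
    panel dosages count it directly.  ``report`` carries the harmonization
    bookkeeping (matched / flipped / ambiguous / unmatched counts).
    """

    table: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])


@dataclass
class ScoreVector:
    """Per-individual genetic risk score.

    ``mode='sum'`` is the raw weighted allele count ``sum_j beta_j d_ij``;
    ``mode='mean_per_allele'`` divides by twice the number of non-missing
    variants (the convention of the standard scoring tool, which makes scores
    comparable across individuals with different missingness).
    """

    values: np.ndarray
    mode: str
    n_variants: int
    n_used: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)

    def __len__(self) -> int:
        return self.values.size

    def standardized(self) -> np.ndarray:
        v = self.values
        sd = np.nanstd(v, ddof=1)
        if sd == 0:
            return np.zeros_like(v)
        return (v - np.nanmean(v)) / sd


def hwe_chisq(dosage: np.ndarray) -> tuple[float, float]:
    """One-degree-of-freedom chi-square Hardy-Weinberg test on one variant.

    Uses complete genotypes only.  Returns ``(chi2, p)``; a monomorphic or
    empty column returns ``(0.0, 1.0)`` (it carries no HWE information and is
    handled by the MAF filter instead).
    """
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    counts = np.array([(d == 0).sum(), (d == 1).sum(), (d == 2).sum()], dtype=float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.98,
    hwe_p_min: float = 1e-6,
    return_summary: bool = False,
):
    """Filter variants on minor-allele frequency, call rate and HWE.

    Retains variants with MAF > ``maf_min``, non-missing fraction >
    ``call_rate_min`` and HWE chi-square p-value > ``hwe_p_min``.  Variant
    order is preserved.  Raises :class:`EmptyPanelError` if nothing survives.
    """
    for name, t in (("maf_min", maf_min), ("call_rate_min", call_rate_min), ("hwe_p_min", hwe_p_min)):
        if not 0.0 < t < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {t}")
    maf = genotypes.maf()
    cr = genotypes.call_rate()
    hwe_p = np.array([hwe_chisq(genotypes.dosages[:, j])[1] for j in range(genotypes.n_variants)])
    with np.errstate(invalid="ignore"):
        keep = (maf > maf_min) & (cr > call_rate_min) & (hwe_p > hwe_p_min)
    keep = np.nan_to_num(keep, nan=False).astype(bool)
    if not keep.any():
        raise EmptyPanelError("no variants pass QC")
    out = genotypes.subset_variants(keep)
    if return_summary:
        summary = {
            "n_input": int(genotypes.n_variants),
            "n_pass": int(keep.sum()),
            "n_fail_maf": int((~np.nan_to_num(maf > maf_min, nan=False)).sum()),
            "n_fail_call_rate": int((cr <= call_rate_min).sum()),
            "n_fail_hwe": int((hwe_p <= hwe_p_min).sum()),
        }
        return out, summary
    return out


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in AMBIGUOUS_PAIRS


def harmonize_weights(
    stats_table: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_max: float = 5.0e-6,
) -> WeightSet:
    """Orient GWAS summary-statistic effects to a genotype panel.

    Records with ``p_value < p_max`` are matched to the panel by variant id.
    If the effect allele equals the panel alt allele the beta is kept; if the
    effect/other pair is the panel ref/alt pair in reverse orientation the
    beta is sign-flipped (and flagged); strand-ambiguous pairs (A/T, C/G) are
    dropped because their orientation cannot be resolved without strand
    information; ids absent from the panel, or allele pairs matching neither
    orientation, are dropped and counted.
    """
    required = {"variant_id", "effect_allele", "other_allele", "beta", "p_value"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    panel = genotypes.variants.set_index("variant_id")
    rows = []
    report = {
        "n_input": int(len(stats_table)),
        "n_p_excluded": 0,
        "n_unmatched_id": 0,
        "n_ambiguous": 0,
        "n_allele_mismatch": 0,
        "n_sign_flipped": 0,
        "n_matched": 0,
    }
    for rec in stats_table.itertuples(index=False):
        if not rec.p_value < p_max:
            report["n_p_excluded"] += 1
            continue
        if rec.variant_id not in panel.index:
            report["n_unmatched_id"] += 1
            continue
        ea, oa = str(rec.effect_allele), str(rec.other_allele)
        if _is_ambiguous(ea, oa):
            report["n_ambiguous"] += 1
            continue
        ref, alt = panel.at[rec.variant_id, "ref"], panel.at[rec.variant_id, "alt"]
        if ea == alt and oa == ref:
            beta, flipped = float(rec.beta), False
        elif ea == ref and oa == alt:
            beta, flipped = -float(rec.beta), True
            report["n_sign_flipped"] += 1
        else:
            report["n_allele_mismatch"] += 1
            continue
        report["n_matched"] += 1
        rows.append(
            {
                "variant_id": rec.variant_id,
                "counted_allele": alt,
                "aligned_beta": beta,
                "sign_flipped": flipped,
            }
        )
    table = pd.DataFrame(rows, columns=["variant_id", "counted_allele", "aligned_beta", "sign_flipped"])
    if len(table):
        order = panel.index.get_indexer(table["variant_id"])
        table = table.iloc[np.argsort(order, kind="stable")].reset_index(drop=True)
    return WeightSet(table=table, report=report)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, complete pairs."""
    df = pd.DataFrame(dosages)
    r = df.corr(min_periods=2).to_numpy()
    return np.nan_to_num(r, nan=0.0) ** 2


def prune_ld(
    genotypes: GenotypeMatrix,
    weights: WeightSet,
    window_variants: int = 50,
    step_variants: int = 5,
    r2_max: float = 0.5,
) -> WeightSet:
    """Greedy windowed LD pruning of a weighted variant set.

    Variants are sorted by (chrom, pos).  Within each sliding window of
    ``window_variants`` consecutive variants (per chromosome, advancing by
    ``step_variants``), while any retained pair has squared dosage correlation
    above ``r2_max``, the member of the worst pair with the smaller
    ``|aligned_beta|`` is removed (ties: the one at the larger position).
    Sweeps repeat until a full pass makes no removal, so every pair that
    shares a window in the survivor set satisfies r^2 <= ``r2_max``.
    """
    if window_variants < 2:
        raise ValueError("window_variants must be >= 2")
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    if step_variants < 1:
        raise ValueError("step_variants must be >= 1")

    panel = genotypes.variants.set_index("variant_id")
    tab = weights.table.copy()
    tab["chrom"] = panel.loc[tab["variant_id"], "chrom"].to_numpy()
    tab["pos"] = panel.loc[tab["variant_id"], "pos"].to_numpy()
    tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    col_index = {vid: j for j, vid in enumerate(genotypes.variants["variant_id"])}
    removed: set[str] = set()

    for chrom, group in tab.groupby("chrom", sort=False):
        ids = list(group["variant_id"])
        betas = dict(zip(group["variant_id"], group["aligned_beta"]))
        poss = dict(zip(group["variant_id"], group["pos"]))
        m = len(ids)
        changed = True
        while changed:
            changed = False
            for start in range(0, max(m - 1, 1), step_variants):
                win = [v for v in ids[start : start + window_variants] if v not in removed]
                while len(win) > 1:
                    cols = genotypes.dosages[:, [col_index[v] for v in win]]
                    r2 = _pairwise_r2(cols)
                    np.fill_diagonal(r2, 0.0)
                    worst = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[worst] <= r2_max:
                        break
                    vi, vj = win[worst[0]], win[worst[1]]
                    bi, bj = abs(betas[vi]), abs(betas[vj])
                    if bi < bj:
                        drop = vi
                    elif bj < bi:
                        drop = vj
                    else:
                        drop = vi if poss[vi] > poss[vj] else vj
                    removed.add(drop)
                    win.remove(drop)
                    changed = True

    kept = weights.table[~weights.table["variant_id"].isin(removed)].reset_index(drop=True)
    report = dict(weights.report)
    report["n_pruned"] = len(removed)
    report["n_after_pruning"] = len(kept)
    return WeightSet(table=kept, report=report)


def compute_grs(
    genotypes: GenotypeMatrix,
    weights: WeightSet,
    mode: str = "mean_per_allele",
    impute_missing: bool = True,
) -> ScoreVector:
    """Weighted genetic risk score per individual.

    ``S_i = sum_j beta_j * dosage_ij`` over the weighted variants; missing
    dosages are imputed to twice the alt-allele frequency when
    ``impute_missing`` is on, otherwise dropped from both numerator and (for
    ``mean_per_allele``) the ``2 * m_nonmissing`` denominator.  An individual
    with every variant missing (imputation off) receives a NaN score.
    """
    if mode not in ("sum", "mean_per_allele"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    if len(weights) == 0:
        raise ValueError("weight set is empty")
    idx = genotypes.variants.set_index("variant_id").index.get_indexer(weights.table["variant_id"])
    if (idx < 0).any():
        bad = [v for v, i in zip(weights.table["variant_id"], idx) if i < 0]
        raise KeyError(f"weights refer to variants absent from panel: {bad}")
    d = genotypes.dosages[:, idx].astype(float)
    betas = weights.table["aligned_beta"].to_numpy(dtype=float)
    missing = np.isnan(d)
    if impute_missing:
        with np.errstate(invalid="ignore"):
            fill = np.nanmean(d, axis=0)  # mean dosage = 2 * alt allele frequency
        d = np.where(missing, fill[None, :], d)
        n_used = np.full(d.shape[0], len(betas), dtype=int)
        s = d @ betas
    else:
        n_used = (~missing).sum(axis=1)
        s = np.where(missing, 0.0, d) @ betas
        s = np.where(n_used == 0, np.nan, s)
    if mode == "sum":
        values = s
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(n_used > 0, s / (2.0 * np.maximum(n_used, 1)), np.nan)
    return ScoreVector(values=values, mode=mode, n_variants=len(betas), n_used=n_used)
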