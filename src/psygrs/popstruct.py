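"""Genotype PCA for population-structure checks and covariate adjustment.

Principal components of the standardized dosage matrix expose population
substructure: each variant column is centered at twice its alt-allele
frequency and scaled by the binomial standard deviation sqrt(2 p (1 - p)),
so components capture correlated allele-frequency shifts rather than
variant-specific variance.  Components are used three ways downstream:
scatter plots for visual heterogeneity checks, iterative SD-based outlier
removal, and inclusion as regression covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scoring import GenotypeMatrix

__all__ = ["PCResult", "compute_pcs", "flag_outliers", "grs_normality"]


@dataclass
class PCResult:
    scores: np.ndarray  # (n, k), zero-mean columns
    explained_variance: np.ndarray  # (k,) fractions, non-increasing
    excluded_variants: np.ndarray  # boolean mask of zero-variance columns
    outlier_flags: np.ndarray | None = None
    outlier_iterations: int = 0

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def compute_pcs(genotypes: GenotypeMatrix, k: int = 10) -> PCResult:
    """Top-k principal components of the standardized genotype matrix.

    Missing dosages are mean-imputed before standardization.  Zero-variance
    (monomorphic) columns are excluded and flagged.  The sign of each
    component is fixed by making its largest-magnitude variant loading
    positive, so results are reproducible across runs and orderings.
    """
    n, m = genotypes.dosages.shape
    if not 1 <= k <= min(n, m):
        raise ValueError(f"k must be in 1..min(n, m) = {min(n, m)}")
    X = genotypes.dosages.astype(float).copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    p_hat = col_mean / 2.0
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    excluded = ~(scale > 0)
    if excluded.all():
        raise ValueError("every variant is monomorphic; PCA undefined")
    Z = (X[:, ~excluded] - 2.0 * p_hat[~excluded]) / scale[~excluded]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    k_eff = min(k, S.size)
    scores = U[:, :k_eff] * S[:k_eff]
    # deterministic sign: largest-|loading| positive per component
    for c in range(k_eff):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
            Vt[c] = -Vt[c]
    explained = (S**2) / (S**2).sum()
    return PCResult(scores=scores, explained_variance=explained[:k_eff], excluded_variants=excluded)


def flag_outliers(
    pcs: PCResult,
    n_components: int = 2,
    sd_multiple: float = 6.0,
    max_iter: int = 5,
) -> PCResult:
    """Iterative SD-rule population-outlier flagging on leading components.

    An individual is flagged when its score on any of the first
    ``n_components`` components lies more than ``sd_multiple`` standard
    deviations from that component's mean; means and SDs are recomputed on
    the unflagged set each round until convergence or ``max_iter`` rounds.
    """
    if n_components > pcs.k:
        raise ValueError("n_components exceeds available components")
    scores = pcs.scores[:, :n_components]
    n = scores.shape[0]
    flags = np.zeros(n, dtype=bool)
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        keep = ~flags
        if not keep.any():
            raise ValueError("all individuals flagged as population outliers")
        mu = scores[keep].mean(axis=0)
        sd = scores[keep].std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, np.inf)
        new_flags = (np.abs(scores - mu) > sd_multiple * sd).any(axis=1)
        if (new_flags == flags).all():
            break
        flags = new_flags
    if flags.all():
        raise ValueError("all individuals flagged as population outliers")
    return PCResult(
        scores=pcs.scores,
        explained_variance=pcs.explained_variance,
        excluded_variants=pcs.excluded_variants,
        outlier_flags=flags,
        outlier_iterations=iterations,
    )


def grs_normality(values: np.ndarray) -> dict:
    """Shapiro-Wilk check of GRS normality, reported descriptively.

    An approximately normal score distribution is the conventional informal
    indication that population stratification is not driving the score; this
    is a descriptive report, never a gate.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    stat, p = stats.shapiro(values)
    return {"statistic": float(stat), "p_value": float(p), "n": int(values.size)}
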