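"""Top-fraction risk stratification: predictive values and odds ratios.

Patients are split at GRS percentile cut-offs (top 10%...50% versus the
rest) and each split is summarized by the 2x2 table

    a = events in the top group        b = non-events in the top group
    c = events in the reference group  d = non-events in the reference group

with PPV = a/(a+b), NPV = d/(c+d), accuracy = (a+d)/n, and the cross-product
odds ratio OR = (a/b)/(c/d) = ad/bc.  The OR significance test is the z-test
on ln(OR) with standard error sqrt(1/a + 1/b + 1/c + 1/d); the 95% CI is
exp(ln OR +/- 1.96 SE).  Tables containing a zero cell receive the
Haldane-Anscombe correction (+0.5 to every cell) by default.

:func:`reconstruct_table` inverts rounded published summaries (PPV,
accuracy, margins) back to the unique integer table, which is how the
package verifies published stratification rows without access to the
underlying cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .scoring import ScoreVector

__all__ = [
    "ContingencyTable",
    "StratumResult",
    "OddsRatioResult",
    "TableReconstructionError",
    "assign_top_group",
    "make_table",
    "predictive_values",
    "odds_ratio",
    "reconstruct_table",
    "decile_report",
    "round_half_up",
]


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # events, top group
    b: int  # non-events, top group
    c: int  # events, reference group
    d: int  # non-events, reference group

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool


@dataclass
class StratumResult:
    top_fraction: float
    k_top: int
    table: ContingencyTable
    ppv: float
    npv: float
    accuracy: float
    sensitivity: float
    specificity: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool


class TableReconstructionError(ValueError):
    """Zero or multiple integer tables match the printed summaries."""

    def __init__(self, message: str, candidates: list[tuple[int, int, int, int]]):
        super().__init__(message)
        self.candidates = candidates


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def assign_top_group(scores: ScoreVector | np.ndarray, fraction: float) -> tuple[np.ndarray, int]:
    """Flag the k = ceil(fraction * n) highest-scoring individuals.

    Ties at the cut score are resolved by stable original order (earlier
    individuals are taken first), making membership deterministic.
    Returns ``(membership_mask, k)``.
    """
    values = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    if values.size == 0:
        raise ValueError("no scores supplied")
    if np.isnan(values).any():
        raise ValueError("scores must be non-missing when assigning groups")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = values.size
    k = math.ceil(fraction * n)
    order = np.argsort(-values, kind="stable")  # descending; ties keep original order
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask, k


def make_table(membership: np.ndarray, events: np.ndarray) -> ContingencyTable:
    """Tabulate top-group membership against event status.

    Individuals with a missing (NaN) event status are excluded before
    tabulation.
    """
    membership = np.asarray(membership, dtype=bool)
    events = np.asarray(events, dtype=float)
    if membership.shape != events.shape:
        raise ValueError("membership and events must have equal length")
    ok = ~np.isnan(events)
    membership, events = membership[ok], events[ok].astype(bool)
    return ContingencyTable(
        a=int((membership & events).sum()),
        b=int((membership & ~events).sum()),
        c=int((~membership & events).sum()),
        d=int((~membership & ~events).sum()),
    )


def predictive_values(table: ContingencyTable) -> dict:
    """PPV, NPV, accuracy, sensitivity, specificity of a 2x2 table.

    A quantity with a zero denominator is reported as NaN (undefined), not
    raised.
    """
    a, b, c, d = table.cells
    n = table.n

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "ppv": ratio(a, a + b),
        "npv": ratio(d, c + d),
        "accuracy": ratio(a + d, n),
        "sensitivity": ratio(a, a + c),
        "specificity": ratio(d, b + d),
    }


def odds_ratio(table: ContingencyTable, zero_cell_policy: str = "haldane") -> OddsRatioResult:
    """Cross-product odds ratio with Wald CI and z-test on ln(OR).

    ``zero_cell_policy='haldane'`` adds 0.5 to every cell when any cell is
    zero before computing the estimate, CI and p-value; ``'none'`` leaves the
    table untouched (a zero cell then yields an infinite or zero OR with NaN
    inference).  A table with two zero cells in the same row or column has no
    defined OR and is reported as NaN with the correction flag set.
    """
    if zero_cell_policy not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell_policy {zero_cell_policy!r}")
    a, b, c, d = (float(x) for x in table.cells)
    degenerate = (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0)
    if degenerate:
        return OddsRatioResult(math.nan, math.nan, math.nan, math.nan, True)
    has_zero = min(a, b, c, d) == 0.0
    corrected = False
    if has_zero and zero_cell_policy == "haldane":
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if min(b, c) == 0.0 or min(a, d) == 0.0:
        or_ = math.inf if min(b, c) == 0.0 else 0.0
        return OddsRatioResult(or_, math.nan, math.nan, math.nan, corrected)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - 1.96 * se)
    ci_high = math.exp(log_or + 1.96 * se)
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return OddsRatioResult(or_, ci_low, ci_high, p, corrected)


def reconstruct_table(
    ppv_printed: float,
    accuracy_printed: float | None,
    *,
    n: int,
    n_events: int,
    fraction: float,
    size_window: float = 0.03,
) -> ContingencyTable:
    """Invert rounded printed summaries to the unique integer 2x2 table.

    Enumerates every table with row margin ``n_events`` / ``n - n_events``
    and top-group size within ``size_window * n`` of ``fraction * n``, and
    keeps those whose PPV (and accuracy, when supplied) round half-up to the
    printed percentages at one decimal.  Raises
    :class:`TableReconstructionError` unless exactly one table survives.
    """
    if not 0 <= n_events <= n:
        raise ValueError("n_events must be within 0..n")
    target = fraction * n
    lo = math.ceil(target - size_window * n)
    hi = math.floor(target + size_window * n)
    survivors: list[tuple[int, int, int, int]] = []
    for s in range(max(lo, 1), hi + 1):
        for a in range(0, min(s, n_events) + 1):
            b = s - a
            c = n_events - a
            d = n - n_events - b
            if c < 0 or d < 0:
                continue
            if round_half_up(100.0 * a / s) != ppv_printed:
                continue
            if accuracy_printed is not None and round_half_up(100.0 * (a + d) / n) != accuracy_printed:
                continue
            survivors.append((a, b, c, d))
    if len(survivors) != 1:
        kind = "no" if not survivors else f"{len(survivors)} distinct"
        raise TableReconstructionError(
            f"{kind} integer tables reproduce PPV={ppv_printed}"
            + (f", accuracy={accuracy_printed}" if accuracy_printed is not None else "")
            + f" at n={n}, events={n_events}, fraction={fraction}",
            survivors,
        )
    return ContingencyTable(*survivors[0])


def decile_report(
    scores: ScoreVector | np.ndarray,
    outcomes: np.ndarray,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5),
    zero_cell_policy: str = "haldane",
) -> list[StratumResult]:
    """One stratification row per top-fraction cut-off.

    Membership is assigned on all scored individuals; individuals with a
    missing outcome are excluded at tabulation, consistently across rows
    (so the analyzed n is identical for every fraction).
    """
    outcomes = np.asarray(outcomes, dtype=float)
    results = []
    for fraction in fractions:
        membership, k = assign_top_group(scores, fraction)
        table = make_table(membership, outcomes)
        pv = predictive_values(table)
        orr = odds_ratio(table, zero_cell_policy=zero_cell_policy)
        results.append(
            StratumResult(
                top_fraction=fraction,
                k_top=k,
                table=table,
                odds_ratio=orr.odds_ratio,
                ci_low=orr.ci_low,
                ci_high=orr.ci_high,
                p_value=orr.p_value,
                correction_applied=orr.correction_applied,
                **pv,
            )
        )
    return results
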