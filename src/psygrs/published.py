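"""Printed reference values from the published clinical stratification analysis.

The psychotic-depression trial analysis this package re-implements printed a
stratification table of PPV / NPV / accuracy / OR / 95% CI / p for treatment
nonresponse and nonremission at the top 10-50% GRS cut-offs (n = 88
outcome-complete patients; 32 nonresponders, 50 nonremitters).  These rounded
summaries, together with the fixed margins, pin down the underlying integer
2x2 tables uniquely for eight of the ten rows, which lets the package's
odds-ratio machinery be verified against the printed numbers exactly.

The two top-10% rows are internally inconsistent as printed: no integer
table with the stated margins reproduces the printed PPV/accuracy pair, and
the printed ORs (52.37, 21.34) match no standard zero-cell correction on any
candidate table.  They are therefore carried with ``reconstructible=False``
and reported as excluded, never silently passed.

Two further printing artifacts are documented rather than imitated: in the
nonremission rows the printed "NPV" equals c/(c+d) (one minus the standard
NPV) for every reconstructible row, and the printed accuracy column equals
the 56.8% event base rate in four rows.  This package always reports the
standard definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PublishedStratumRow", "REFERENCE_MARGINS", "REFERENCE_ROWS", "TOP10_GROUP_SIZE"]


@dataclass(frozen=True)
class PublishedStratumRow:
    endpoint: str
    fraction: float
    ppv: float  # printed percent, one decimal
    npv: float
    accuracy: float
    odds_ratio: float  # printed to 2 decimals
    ci_low: float
    ci_high: float
    p_value: float
    p_decimals: int  # decimals at which the p-value was printed
    reconstructible: bool
    use_accuracy: bool  # accuracy column usable as a reconstruction constraint


#: Analyzed sample and event margins behind every row.
REFERENCE_MARGINS = {
    "nonresponse": {"n": 88, "n_events": 32},
    "nonremission": {"n": 88, "n_events": 50},
}

#: Printed top-10% group size among the 88 outcome-complete patients.
TOP10_GROUP_SIZE = 9

REFERENCE_ROWS: list[PublishedStratumRow] = [
    PublishedStratumRow("nonresponse", 0.10, 100.0, 73.7, 76.4, 52.37, 2.91, 940.75, 0.00072, 5, False, True),
    PublishedStratumRow("nonresponse", 0.20, 66.7, 71.4, 70.5, 5.00, 1.65, 15.15, 0.0044, 4, True, True),
    PublishedStratumRow("nonresponse", 0.30, 60.0, 73.0, 69.3, 4.06, 1.53, 10.76, 0.0048, 4, True, True),
    PublishedStratumRow("nonresponse", 0.40, 57.6, 76.4, 69.3, 4.38, 1.73, 11.10, 0.0018, 4, True, True),
    PublishedStratumRow("nonresponse", 0.50, 45.5, 72.7, 59.1, 2.22, 0.91, 5.41, 0.079, 3, True, True),
    PublishedStratumRow("nonremission", 0.10, 100.0, 51.9, 57.8, 21.34, 1.22, 374.54, 0.036, 3, False, False),
    PublishedStratumRow("nonremission", 0.20, 77.8, 51.4, 56.8, 3.31, 0.99, 11.04, 0.052, 3, True, False),
    PublishedStratumRow("nonremission", 0.30, 76.0, 49.2, 56.8, 3.27, 1.15, 9.27, 0.026, 3, True, False),
    PublishedStratumRow("nonremission", 0.40, 75.8, 45.5, 56.8, 3.75, 1.44, 9.76, 0.0068, 4, True, False),
    PublishedStratumRow("nonremission", 0.50, 63.6, 50.0, 56.8, 1.75, 0.75, 4.10, 0.20, 2, True, False),
]
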