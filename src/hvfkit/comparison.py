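"""Extraction-vs-reference comparison and aggregate error statistics.

Every extracted item is compared with its reference value as text.
Metadata fields admit three outcomes: exact MATCH; FORMAT_INCONSISTENCY
when the two texts differ only in representation (case, whitespace,
date dialect, numeric formatting, units) but canonicalize to the same
value; TRUE_ERROR otherwise.  Plot data points admit only MATCH or
TRUE_ERROR, compared among all non-empty reference points.

Aggregates follow the usual validation-study summary: aggregate error
count and rate (errors / items, as a percentage) with an exact
two-sided Clopper–Pearson binomial confidence interval, and the
median (Q1, Q3) of per-report error counts using median-inclusive
(Tukey hinge) quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .data_model import ABSENT, PlotGrid, canonical_text, normalize_field
from .layout_registry import METADATA_FIELDS

MATCH = "MATCH"
FORMAT_INCONSISTENCY = "FORMAT_INCONSISTENCY"
TRUE_ERROR = "TRUE_ERROR"

#: distinguished text for a missing value
ABSENT_TEXT = ""


@dataclass(frozen=True)
class ComparisonOutcome:
    outcome: str  # MATCH | FORMAT_INCONSISTENCY | TRUE_ERROR
    element: object  # field_id or (plot_id, row, col)
    extracted: str
    reference: str


def _canonical(field_id: str, text: str) -> str:
    """Representation-insensitive canonical form of a field's text."""
    collapsed = " ".join(text.split()).casefold()
    v = normalize_field(field_id, text)
    if v is ABSENT:
        return collapsed
    return canonical_text(field_id, v).casefold()


def compare_field(extracted: str, reference: str, field_id: str) -> ComparisonOutcome:
    """Classify one metadata field comparison.

    Exact text equality is a MATCH; representational differences that
    preserve the information (case, whitespace, date dialect, units,
    trailing zeros) are FORMAT_INCONSISTENCY; everything else — dropped
    signs, wrong characters, values from the wrong field — is a
    TRUE_ERROR.
    """
    if field_id not in METADATA_FIELDS:
        raise KeyError(f"unknown metadata field {field_id!r}")
    if extracted is None or reference is None:
        raise TypeError("use ABSENT_TEXT for missing values, not None")
    if extracted == reference:
        out = MATCH
    elif _canonical(field_id, extracted) == _canonical(field_id, reference):
        out = FORMAT_INCONSISTENCY
    else:
        out = TRUE_ERROR
    return ComparisonOutcome(out, field_id, extracted, reference)


def compare_grid(extracted: PlotGrid, reference: PlotGrid) -> list[ComparisonOutcome]:
    """Per-point comparison over all non-empty reference cells.

    A reference point the extraction left EMPTY is a TRUE_ERROR; points
    empty in the reference are not enumerated (extra extracted ink is
    surfaced by the pipeline as warnings, not counted here).
    """
    if extracted.plot_id != reference.plot_id:
        raise ValueError(
            f"plot_id mismatch: {extracted.plot_id} vs {reference.plot_id}"
        )
    outcomes = []
    for r in range(10):
        for c in range(10):
            ref = reference.cells[r][c]
            if ref.is_empty:
                continue
            ext = extracted.cells[r][c]
            out = MATCH if ext.token() == ref.token() else TRUE_ERROR
            outcomes.append(ComparisonOutcome(
                out, (reference.plot_id, r, c), ext.token(), ref.token()
            ))
    return outcomes


def compare_reports(extracted, reference) -> dict[str, list[ComparisonOutcome]]:
    """All outcomes for one report pair, keyed 'metadata'/'value'/'percentile'."""
    meta = [
        compare_field(
            canonical_text(fid, extracted.metadata.get(fid)),
            canonical_text(fid, reference.metadata.get(fid)),
            fid,
        )
        for fid in METADATA_FIELDS
    ]
    value, percentile = [], []
    for pid, ref_grid in reference.grids().items():
        ext_grid = extracted.grids()[pid]
        (value if pid in ("RAW", "TD_VALUE", "PD_VALUE") else percentile).extend(
            compare_grid(ext_grid, ref_grid)
        )
    return {"metadata": meta, "value": value, "percentile": percentile}


# --- statistics -----------------------------------------------------------


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval, as fractions.

    The bounds invert the binomial tail probabilities; equivalently the
    beta-distribution quantile form used here.  ``low`` is exactly 0
    when x = 0 and ``high`` exactly 1 when x = n.
    """
    if not (0 <= x <= n) or n < 1:
        raise ValueError(f"need 0 <= x <= n, n >= 1; got x={x}, n={n}")
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0, 1); got {level}")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def _tukey_quartiles(values: list[int]) -> tuple[float, float, float]:
    """Median and median-inclusive (Tukey hinge) quartiles."""
    v = sorted(values)
    n = len(v)
    med = float(np.median(v))
    lo = v[: (n + 1) // 2]
    hi = v[n // 2:]
    return float(np.median(lo)), med, float(np.median(hi))


@dataclass(frozen=True)
class ErrorSummary:
    aggregate_errors: int
    total_items: int
    rate: float  # percent
    ci_low: float  # percent
    ci_high: float  # percent
    per_report_errors: tuple
    median: float
    q1: float
    q3: float
    format_inconsistencies: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("rate must lie inside its confidence interval")
        if self.aggregate_errors != sum(self.per_report_errors):
            raise ValueError("aggregate must equal the sum of per-report counts")

    def format_row(self) -> str:
        return (f"{self.aggregate_errors}/{self.total_items} errors, "
                f"{self.rate:.1f}% (95% CI {self.ci_low:.1f}-{self.ci_high:.1f}), "
                f"median {self.median:g} (Q1 {self.q1:g}, Q3 {self.q3:g}) per report")

    def to_dict(self) -> dict:
        return {
            "aggregate_errors": self.aggregate_errors,
            "total_items": self.total_items,
            "rate_percent": round(self.rate, 1),
            "ci95_low_percent": round(self.ci_low, 1),
            "ci95_high_percent": round(self.ci_high, 1),
            "per_report_errors": list(self.per_report_errors),
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "format_inconsistencies": self.format_inconsistencies,
        }


def summarize(outcomes_by_report: list[list[ComparisonOutcome]],
              level: float = 0.95) -> ErrorSummary:
    """Aggregate TRUE_ERROR statistics over a group of reports.

    Only TRUE_ERROR counts toward the error rate; format
    inconsistencies are tallied separately.  Permutation-invariant in
    the report order.
    """
    if not outcomes_by_report:
        raise ValueError("need at least one report group")
    per_report = [sum(o.outcome == TRUE_ERROR for o in rep)
                  for rep in outcomes_by_report]
    errors = sum(per_report)
    total = sum(len(rep) for rep in outcomes_by_report)
    fmt = sum(o.outcome == FORMAT_INCONSISTENCY
              for rep in outcomes_by_report for o in rep)
    if total == 0:
        lo = hi = rate = 0.0
    else:
        lo, hi = clopper_pearson(errors, total, level)
        rate = 100.0 * errors / total
    q1, med, q3 = _tukey_quartiles(per_report)
    return ErrorSummary(
        aggregate_errors=errors,
        total_items=total,
        rate=rate,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        per_report_errors=tuple(per_report),
        median=med,
        q1=q1,
        q3=q3,
        format_inconsistencies=fmt,
    )
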