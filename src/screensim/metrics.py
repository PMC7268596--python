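"""Performance metrics for screening simulations.

Three metrics summarize each simulated approach against the human
baseline:

* **proportion missed** — of the records included in the final report, the
  fraction excluded at the simulated title-and-abstract stage;
* **workload savings** — of the records that would need manual
  title-and-abstract screening (2N for dual independent screening in a
  systematic review, N for the single reviewer of a rapid review), the
  number and fraction that no longer need a human;
* **time savings** — workload savings converted at 0.5 min/record and an
  8-hour working day.

Displayed integers are rounded half-up (7.5 -> 8) and computed with exact
rational arithmetic; days below one are rendered ``"<1"``.  Full-precision
values are kept alongside the display values.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

__all__ = [
    "ConfusionTable",
    "TimeModel",
    "TimeSavings",
    "PerformanceMetrics",
    "SummaryStat",
    "round_half_up",
    "pct_display",
    "baseline_total",
    "proportion_missed",
    "workload_savings",
    "time_savings",
    "aggregate",
    "confusion_table",
    "evaluate_strategy",
]


def round_half_up(value: float | Fraction) -> int:
    """Round to the nearest integer, ties away from zero (for x >= 0)."""
    if value < 0:
        raise ValueError("display rounding is defined for non-negative values")
    if isinstance(value, Fraction):
        return int((2 * value.numerator + value.denominator) // (2 * value.denominator))
    return int((2 * Fraction(value).numerator + Fraction(value).denominator)
               // (2 * Fraction(value).denominator))


def pct_display(numerator: int, denominator: int) -> int:
    """``100 * numerator / denominator`` rounded half-up, exact arithmetic."""
    if denominator <= 0:
        raise ValueError("percentage denominator must be positive")
    return round_half_up(Fraction(100 * numerator, denominator))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 cross-tabulation of a strategy's consensus vs the final report.

    ``tp``: final-report includes retained at title/abstract; ``fn``:
    final-report includes excluded; ``fp``/``tn``: the remaining records
    forwarded / excluded.  ``tp + fn`` equals the review's full-text
    include count.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion table counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class TimeModel:
    """Linear screening-time model: minutes per record and hours per day."""

    minutes_per_record: float = 0.5
    hours_per_day: float = 8.0

    def __post_init__(self) -> None:
        if self.minutes_per_record <= 0 or self.hours_per_day <= 0:
            raise ValueError("time model parameters must be positive")


@dataclass(frozen=True)
class TimeSavings:
    hours_raw: float
    days_raw: float
    hours: int          # displayed, rounded half-up
    days: str           # displayed: "<1" below one day, else rounded half-up

    def __str__(self) -> str:  # e.g. "82 (10)" as printed in report tables
        return f"{self.hours} ({self.days})"


@dataclass(frozen=True)
class SummaryStat:
    """median (range) summary used throughout reporting."""

    median: float
    min: float
    max: float

    def __str__(self) -> str:
        def fmt(x: float) -> str:
            return str(round_half_up(x)) if x >= 0 else str(x)

        return f"{fmt(self.median)} ({fmt(self.min)} to {fmt(self.max)})"


@dataclass(frozen=True)
class PerformanceMetrics:
    """Bundle of the three metrics for one review x strategy."""

    missed_n: int | None
    missed_pct: int | None          # None when the review has no includes
    savings_records: int
    savings_pct: int
    hours: int
    days: str
    baseline_total: int
    manual_screens: int
    hours_raw: float = 0.0
    days_raw: float = 0.0


def baseline_total(review_type: str, n_records: int) -> int:
    """Manual title-and-abstract screens the human baseline consumes.

    Dual independent screening means every record is screened twice in a
    systematic review; a rapid review's single reviewer screens each once.
    """
    if review_type == "systematic":
        return 2 * n_records
    if review_type == "rapid":
        return n_records
    raise ValueError(f"unknown review_type {review_type!r}")


def proportion_missed(table: ConfusionTable) -> tuple[int, int | None]:
    """(missed count, displayed percent) from a 2x2 table.

    Undefined (percent ``None``) when the review has zero final-report
    includes.
    """
    includes = table.tp + table.fn
    if includes == 0:
        return table.fn, None
    return table.fn, pct_display(table.fn, includes)


def workload_savings(manual_screens: int, baseline: int) -> tuple[int, int]:
    """(records saved, displayed percent of the baseline)."""
    if manual_screens > baseline:
        raise ValueError(
            f"manual screens ({manual_screens}) exceed the baseline "
            f"({baseline}): strategy accounting bug"
        )
    records = baseline - manual_screens
    return records, pct_display(records, baseline) if baseline else 0


def time_savings(records: int, time_model: TimeModel = TimeModel()) -> TimeSavings:
    """Convert records saved into hours and working days."""
    if records < 0:
        raise ValueError("records saved must be non-negative")
    # exact when the model parameters are exactly representable (defaults are)
    hours_raw = Fraction(records) * Fraction(time_model.minutes_per_record) / 60
    days_raw = hours_raw / Fraction(time_model.hours_per_day)
    days = "<1" if days_raw < 1 else str(round_half_up(days_raw))
    return TimeSavings(
        hours_raw=float(hours_raw),
        days_raw=float(days_raw),
        hours=round_half_up(hours_raw),
        days=days,
    )


def aggregate(values: Iterable[float]) -> SummaryStat:
    """median (min, max) of per-review values."""
    vals = list(values)
    if not vals:
        raise ValueError("cannot aggregate an empty list")
    return SummaryStat(median=statistics.median(vals), min=min(vals), max=max(vals))


# ---------------------------------------------------------------------------
# From strategy results
# ---------------------------------------------------------------------------

def confusion_table(consensus_includes: set[str], dataset) -> ConfusionTable:
    """Cross-tabulate a strategy's consensus against the final report."""
    ft = dataset.fulltext_includes
    ids = dataset.record_ids
    tp = len(ft & consensus_includes)
    fn = len(ft - consensus_includes)
    fp = len(consensus_includes - ft)
    tn = len(ids) - tp - fn - fp
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def evaluate_strategy(
    result,
    dataset,
    time_model: TimeModel = TimeModel(),
    *,
    nominal_training: int | None = None,
) -> PerformanceMetrics:
    """All three metrics for one strategy result.

    ``nominal_training`` substitutes a nominal training-set size for the
    actually screened one in the savings arithmetic (report-compat mode:
    published tables deduct the nominal 200 even when extra batches were
    screened before predictions became available).
    """
    table = confusion_table(result.consensus_includes, dataset)
    missed_n, missed_pct = proportion_missed(table)
    baseline = baseline_total(dataset.review_type, dataset.workload_N)
    manual = result.manual_screens
    if nominal_training is not None:
        actual_t = result.components.get("training_screens", 0)
        if actual_t:
            manual = manual - actual_t + nominal_training
    records, pct = workload_savings(manual, baseline)
    ts = time_savings(records, time_model)
    return PerformanceMetrics(
        missed_n=missed_n,
        missed_pct=missed_pct,
        savings_records=records,
        savings_pct=pct,
        hours=ts.hours,
        days=ts.days,
        baseline_total=baseline,
        manual_screens=manual,
        hours_raw=ts.hours_raw,
        days_raw=ts.days_raw,
    )
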