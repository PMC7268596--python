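"""Published 17-review screening benchmark: inputs and reference columns.

A published retrospective evaluation of machine-assisted title-and-abstract
screening reports, for 11 systematic and 6 rapid reviews, the per-reviewer
screening workload N, the training-set composition (includes/excludes
screened before the tool produced predictions), and the number of remaining
records the tool predicted relevant, P.  From those counts alone the
workload- and time-savings columns of its results tables are fully
determined; this module carries the counts (inputs) and the printed
savings/time columns (reference values) so the arithmetic can be
recomputed and cross-checked cell by cell.

A handful of printed cells contradict their own inputs (wrong denominator
or a transcription slip); :data:`KNOWN_DISCREPANT_CELLS` lists them.  The
recomputed values are authoritative and comparison helpers flag — never
silently match — these cells.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BenchmarkReview",
    "BENCHMARK_REVIEWS",
    "PrintedCell",
    "PRINTED_WORKLOAD_TIME",
    "KNOWN_DISCREPANT_CELLS",
    "NOMINAL_TRAINING",
]

#: Nominal training-set size; savings columns in the published tables always
#: deduct this, even for the one review that needed 300 screens.
NOMINAL_TRAINING = 200


@dataclass(frozen=True)
class BenchmarkReview:
    """Per-review counts: workload and classifier training/prediction."""

    name: str
    review_type: str            # "systematic" | "rapid"
    workload: int               # per-reviewer screening workload N
    ta_includes: int            # title/abstract-stage includes (consensus)
    ft_includes: int            # final-report (full-text) includes
    train_includes: int         # includes in the screened training set
    train_excludes: int         # excludes in the screened training set
    predicted_relevant: int     # hard-true predictions among the N - T rest

    @property
    def training_size(self) -> int:
        return self.train_includes + self.train_excludes


BENCHMARK_REVIEWS: tuple[BenchmarkReview, ...] = (
    # systematic reviews
    BenchmarkReview("Biomarkers", "systematic", 1812, 209, 45, 14, 186, 503),
    BenchmarkReview("Brain injury", "systematic", 6262, 518, 40, 11, 189, 2126),
    BenchmarkReview("Activity and pregnancy", "systematic", 2928, 236, 98, 10, 190, 319),
    BenchmarkReview("Concussion", "systematic", 1439, 46, 5, 3, 197, 638),
    BenchmarkReview("Antipsychotics", "systematic", 12156, 1177, 127, 15, 185, 2117),
    BenchmarkReview("Digital technologies for pain", "systematic", 2662, 207, 64, 15, 185, 321),
    BenchmarkReview("Treatments for bronchiolitis", "systematic", 5861, 518, 137, 12, 188, 656),
    BenchmarkReview("VBAC", "systematic", 5092, 807, 21, 25, 175, 1490),
    BenchmarkReview("Visual acuity", "systematic", 11229, 224, 1, 4, 296, 3639),
    BenchmarkReview("Experience of bronchiolitis", "systematic", 651, 88, 28, 13, 187, 111),
    BenchmarkReview("Experiences of UTIs", "systematic", 1493, 25, 4, 3, 197, 864),
    # rapid reviews
    BenchmarkReview("Preterm delivery", "rapid", 451, 96, 34, 47, 153, 95),
    BenchmarkReview("Community gardening", "rapid", 1536, 153, 32, 55, 145, 139),
    BenchmarkReview("Depression safety", "rapid", 964, 44, 8, 7, 193, 449),
    BenchmarkReview("Depression treatments", "rapid", 1583, 418, 179, 43, 157, 904),
    BenchmarkReview("Patient education for cancer", "rapid", 2413, 153, 1, 5, 195, 1410),
    BenchmarkReview("Workplace stress", "rapid", 767, 141, 59, 36, 164, 210),
)


@dataclass(frozen=True)
class PrintedCell:
    """One review x strategy row of the published workload/time columns."""

    records: int     # workload savings, records
    pct: int         # workload savings, % of the manual baseline
    hours: int       # time savings, hours
    days: str        # time savings, days ("<1" below one day)


#: (review name, strategy) -> printed workload/time cell.  Strategies use
#: the package's identifiers: single_full_auto / single_semi_auto (all 17
#: reviews) and dual_full_auto / dual_semi_auto (systematic reviews only).
PRINTED_WORKLOAD_TIME: dict[tuple[str, str], PrintedCell] = {
    # single reviewer, fully automated
    ("Biomarkers", "single_full_auto"): PrintedCell(3424, 94, 29, "4"),
    ("Brain injury", "single_full_auto"): PrintedCell(12324, 98, 103, "13"),
    ("Activity and pregnancy", "single_full_auto"): PrintedCell(5656, 97, 47, "6"),
    ("Concussion", "single_full_auto"): PrintedCell(2678, 93, 22, "3"),
    ("Antipsychotics", "single_full_auto"): PrintedCell(24112, 99, 201, "25"),
    ("Digital technologies for pain", "single_full_auto"): PrintedCell(5124, 96, 43, "5"),
    ("Treatments for bronchiolitis", "single_full_auto"): PrintedCell(11522, 98, 96, "12"),
    ("VBAC", "single_full_auto"): PrintedCell(9984, 98, 83, "10"),
    ("Visual acuity", "single_full_auto"): PrintedCell(22258, 99, 185, "23"),
    ("Experience of bronchiolitis", "single_full_auto"): PrintedCell(1102, 85, 9, "1"),
    ("Experiences of UTIs", "single_full_auto"): PrintedCell(2786, 93, 23, "3"),
    ("Preterm delivery", "single_full_auto"): PrintedCell(251, 56, 2, "<1"),
    ("Community gardening", "single_full_auto"): PrintedCell(1336, 87, 11, "1"),
    ("Depression safety", "single_full_auto"): PrintedCell(764, 79, 6, "<1"),
    ("Depression treatments", "single_full_auto"): PrintedCell(1383, 87, 12, "1"),
    ("Patient education for cancer", "single_full_auto"): PrintedCell(2213, 92, 18, "2"),
    ("Workplace stress", "single_full_auto"): PrintedCell(567, 74, 5, "<1"),
    # single reviewer, semi-automated
    ("Biomarkers", "single_semi_auto"): PrintedCell(2921, 85, 24, "3"),
    ("Brain injury", "single_semi_auto"): PrintedCell(10198, 81, 85, "11"),
    ("Activity and pregnancy", "single_semi_auto"): PrintedCell(5337, 91, 44, "6"),
    ("Concussion", "single_semi_auto"): PrintedCell(2040, 71, 17, "2"),
    ("Antipsychotics", "single_semi_auto"): PrintedCell(21995, 90, 183, "23"),
    ("Digital technologies for pain", "single_semi_auto"): PrintedCell(4803, 90, 40, "5"),
    ("Treatments for bronchiolitis", "single_semi_auto"): PrintedCell(10866, 93, 91, "11"),
    ("VBAC", "single_semi_auto"): PrintedCell(8494, 83, 71, "9"),
    ("Visual acuity", "single_semi_auto"): PrintedCell(18619, 83, 155, "19"),
    ("Experience of bronchiolitis", "single_semi_auto"): PrintedCell(991, 76, 8, "1"),
    ("Experiences of UTIs", "single_semi_auto"): PrintedCell(1940, 65, 16, "2"),
    ("Preterm delivery", "single_semi_auto"): PrintedCell(161, 36, 1, "<1"),
    ("Community gardening", "single_semi_auto"): PrintedCell(1197, 78, 10, "1"),
    ("Depression safety", "single_semi_auto"): PrintedCell(315, 41, 3, "<1"),
    ("Depression treatments", "single_semi_auto"): PrintedCell(479, 30, 4, "<1"),
    ("Patient education for cancer", "single_semi_auto"): PrintedCell(803, 33, 7, "<1"),
    ("Workplace stress", "single_semi_auto"): PrintedCell(357, 47, 3, "<1"),
    # dual independent screening, fully automated (systematic reviews)
    ("Biomarkers", "dual_full_auto"): PrintedCell(1612, 47, 13, "2"),
    ("Brain injury", "dual_full_auto"): PrintedCell(6062, 48, 51, "6"),
    ("Activity and pregnancy", "dual_full_auto"): PrintedCell(2728, 47, 23, "3"),
    ("Concussion", "dual_full_auto"): PrintedCell(1239, 43, 10, "1"),
    ("Antipsychotics", "dual_full_auto"): PrintedCell(11956, 49, 100, "12"),
    ("Digital technologies for pain", "dual_full_auto"): PrintedCell(2462, 46, 21, "3"),
    ("Treatments for bronchiolitis", "dual_full_auto"): PrintedCell(5661, 48, 47, "6"),
    ("VBAC", "dual_full_auto"): PrintedCell(4892, 48, 41, "5"),
    ("Visual acuity", "dual_full_auto"): PrintedCell(11029, 49, 92, "11"),
    ("Experience of bronchiolitis", "dual_full_auto"): PrintedCell(451, 35, 4, "<1"),
    ("Experiences of UTIs", "dual_full_auto"): PrintedCell(1293, 43, 11, "1"),
    # dual independent screening, semi-automated (systematic reviews)
    ("Biomarkers", "dual_semi_auto"): PrintedCell(1109, 32, 9, "1"),
    ("Brain injury", "dual_semi_auto"): PrintedCell(3936, 31, 33, "4"),
    ("Activity and pregnancy", "dual_semi_auto"): PrintedCell(2409, 41, 20, "3"),
    ("Concussion", "dual_semi_auto"): PrintedCell(601, 21, 5, "<1"),
    ("Antipsychotics", "dual_semi_auto"): PrintedCell(9839, 40, 82, "10"),
    ("Digital technologies for pain", "dual_semi_auto"): PrintedCell(2141, 40, 18, "2"),
    ("Treatments for bronchiolitis", "dual_semi_auto"): PrintedCell(5005, 43, 42, "5"),
    ("VBAC", "dual_semi_auto"): PrintedCell(3402, 33, 28, "4"),
    ("Visual acuity", "dual_semi_auto"): PrintedCell(7390, 33, 62, "8"),
    ("Experience of bronchiolitis", "dual_semi_auto"): PrintedCell(340, 26, 3, "<1"),
    ("Experiences of UTIs", "dual_semi_auto"): PrintedCell(447, 15, 4, "<1"),
}

#: Printed cells whose values contradict the tables' own count inputs
#: (review name, strategy, field).  The Biomarkers percentages divide by the
#: fully automated savings instead of the 2N baseline; the Depression
#: safety percentage divides by N - 200; the Preterm delivery and
#: Experiences-of-UTIs semi-automated records (and the percentages that
#: follow from them) do not equal baseline - (training + predicted
#: relevant [+ N]).
KNOWN_DISCREPANT_CELLS: frozenset[tuple[str, str, str]] = frozenset(
    {
        ("Biomarkers", "single_semi_auto", "pct"),
        ("Biomarkers", "dual_full_auto", "pct"),
        ("Biomarkers", "dual_semi_auto", "pct"),
        ("Depression safety", "single_semi_auto", "pct"),
        ("Preterm delivery", "single_semi_auto", "records"),
        ("Preterm delivery", "single_semi_auto", "pct"),
        ("Experiences of UTIs", "single_semi_auto", "records"),
        ("Experiences of UTIs", "single_semi_auto", "pct"),
        ("Experiences of UTIs", "dual_semi_auto", "records"),
        ("Experiences of UTIs", "dual_semi_auto", "pct"),
    }
)
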