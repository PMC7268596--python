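"""Citation records, reviewer decisions, and review datasets.

A review dataset bundles the bibliographic records retrieved by a search,
the title-and-abstract screening decisions of one (rapid review) or two
(systematic review) human reviewers, and the set of records that made it
into the final report after full-text assessment.  Screening decisions are
binarized at load time: ``include``/``unsure``/``borderline`` all count as
include, because at the title-and-abstract stage any record a reviewer is
not willing to discard moves forward; the raw label is retained for audit.
"""

from __future__ import annotations

import csv
import hashlib
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ValidationError",
    "CitationRecord",
    "ScreeningDecision",
    "ReviewDataset",
    "normalize_decision",
    "load_review_dataset",
    "write_review_dataset",
    "title_abstract_consensus_human",
    "read_ris",
    "write_ris",
]

SENIOR = "senior"
SECOND = "second"
REVIEWER_ROLES = (SENIOR, SECOND)

INCLUDE = "include"
EXCLUDE = "exclude"

#: Raw screening labels that are treated as "include" at the
#: title-and-abstract stage.
_INCLUDE_SYNONYMS = frozenset({"include", "unsure", "borderline", "relevant"})
_EXCLUDE_SYNONYMS = frozenset({"exclude", "irrelevant"})


class ValidationError(ValueError):
    """A dataset, decision file, or configuration failed validation."""


def normalize_decision(raw_label: str, record_id: str | None = None) -> str:
    """Binarize a raw screening label.

    ``include``, ``unsure`` and ``borderline`` (any case) all map to
    ``include``; ``exclude`` maps to ``exclude``.  Anything else raises
    :class:`ValidationError` naming the offending record.
    """
    label = raw_label.strip().lower()
    if label in _INCLUDE_SYNONYMS:
        return INCLUDE
    if label in _EXCLUDE_SYNONYMS:
        return EXCLUDE
    where = f" for record {record_id!r}" if record_id is not None else ""
    raise ValidationError(f"unrecognized screening label {raw_label!r}{where}")


@dataclass(frozen=True)
class CitationRecord:
    """One bibliographic record as presented to a screener.

    ``truth_ta`` / ``truth_ft`` are optional ground-truth relevance flags at
    the title-and-abstract and full-text stages; they are populated by the
    synthetic corpus generator and absent for real screening data.
    """

    record_id: str
    title: str
    abstract: str = ""
    keywords: tuple[str, ...] = ()
    authors: tuple[str, ...] = ()
    truth_ta: bool | None = None
    truth_ft: bool | None = None

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValidationError("record_id must be a non-empty string")
        if self.truth_ft and not self.truth_ta:
            raise ValidationError(
                f"record {self.record_id!r}: full-text relevant implies "
                "title/abstract relevant"
            )
        object.__setattr__(self, "keywords", tuple(self.keywords))
        object.__setattr__(self, "authors", tuple(self.authors))

    def text_fields(self) -> tuple[str, str, str]:
        """(title, abstract, joined keywords) — the text a screener sees."""
        return self.title, self.abstract, " ".join(self.keywords)


def stable_record_id(title: str, year: str | int = "") -> str:
    """Assign a stable identifier from title (+ optional year) on import."""
    digest = hashlib.blake2s(
        f"{title.strip().lower()}|{year}".encode(), digest_size=8
    ).hexdigest()
    return f"rec-{digest}"


@dataclass(frozen=True)
class ScreeningDecision:
    """A single reviewer's title-and-abstract decision for one record."""

    record_id: str
    reviewer_role: str
    decision: str
    raw_label: str = ""

    def __post_init__(self) -> None:
        if self.reviewer_role not in REVIEWER_ROLES:
            raise ValidationError(
                f"reviewer_role must be one of {REVIEWER_ROLES}, "
                f"got {self.reviewer_role!r}"
            )
        if self.decision not in (INCLUDE, EXCLUDE):
            raise ValidationError(
                f"decision must be {INCLUDE!r} or {EXCLUDE!r}, "
                f"got {self.decision!r} (record {self.record_id!r})"
            )
        if not self.raw_label:
            object.__setattr__(self, "raw_label", self.decision)


@dataclass
class ReviewDataset:
    """A review's records, screening decisions and full-text includes.

    ``review_type`` is ``"systematic"`` (dual independent screening: senior
    and second reviewer both screen every record) or ``"rapid"`` (single
    senior reviewer).  ``fulltext_includes`` is the consensus set of records
    included in the final report.
    """

    name: str
    review_type: str
    records: list[CitationRecord]
    decisions: list[ScreeningDecision]
    fulltext_includes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.review_type not in ("systematic", "rapid"):
            raise ValidationError(
                f"review_type must be 'systematic' or 'rapid', "
                f"got {self.review_type!r}"
            )
        ids = [r.record_id for r in self.records]
        self._ids = set(ids)
        if len(self._ids) != len(ids):
            seen: set[str] = set()
            dupes = sorted({i for i in ids if i in seen or seen.add(i)})
            raise ValidationError(f"duplicate record_id(s): {dupes[:5]}")
        self._decisions: dict[str, dict[str, ScreeningDecision]] = {
            SENIOR: {},
            SECOND: {},
        }
        for d in self.decisions:
            if d.record_id not in self._ids:
                raise ValidationError(
                    f"decision for unknown record_id {d.record_id!r}"
                )
            by_role = self._decisions[d.reviewer_role]
            if d.record_id in by_role:
                raise ValidationError(
                    f"duplicate {d.reviewer_role} decision for record "
                    f"{d.record_id!r}"
                )
            by_role[d.record_id] = d
        if self.review_type == "rapid" and self._decisions[SECOND]:
            raise ValidationError(
                "rapid reviews carry senior decisions only; found "
                f"{len(self._decisions[SECOND])} second-reviewer decisions"
            )
        unknown_ft = self.fulltext_includes - self._ids
        if unknown_ft:
            raise ValidationError(
                f"fulltext_includes reference unknown ids: {sorted(unknown_ft)[:5]}"
            )
        # Full-text candidates came from the human title/abstract stage.
        if self.fulltext_includes:
            if self.review_type == "systematic":
                passed = title_abstract_consensus_human(self)
            else:
                passed = self.includes_of(SENIOR)
            stray = self.fulltext_includes - passed
            if stray:
                raise ValidationError(
                    "fulltext_includes not screened in at title/abstract: "
                    f"{sorted(stray)[:5]}"
                )

    @property
    def workload_N(self) -> int:
        """Per-reviewer title-and-abstract screening workload."""
        return len(self.records)

    @property
    def record_ids(self) -> set[str]:
        return set(self._ids)

    def record(self, record_id: str) -> CitationRecord:
        if not hasattr(self, "_by_id"):
            self._by_id = {r.record_id: r for r in self.records}
        return self._by_id[record_id]

    def decision_of(self, role: str, record_id: str) -> str | None:
        d = self._decisions[role].get(record_id)
        return d.decision if d is not None else None

    def includes_of(self, role: str) -> set[str]:
        """Record ids the given reviewer marked include."""
        return {
            rid
            for rid, d in self._decisions[role].items()
            if d.decision == INCLUDE
        }

    def decided_by(self, role: str) -> set[str]:
        return set(self._decisions[role])

    def summary(self) -> dict[str, int]:
        """Headline counts: workload, title/abstract and full-text includes."""
        if self.review_type == "systematic":
            ta = len(title_abstract_consensus_human(self))
        else:
            ta = len(self.includes_of(SENIOR))
        return {
            "workload_N": self.workload_N,
            "ta_includes": ta,
            "fulltext_includes": len(self.fulltext_includes),
        }


def title_abstract_consensus_human(dataset: ReviewDataset) -> set[str]:
    """Records forwarded to full text under dual independent screening.

    A record advances if *either* reviewer marked it include.  Only defined
    for systematic reviews; rapid reviews have no second reviewer.
    """
    if dataset.review_type != "systematic":
        raise ValidationError(
            "human title/abstract consensus requires a systematic dataset "
            "with a second reviewer"
        )
    return dataset.includes_of(SENIOR) | dataset.includes_of(SECOND)


# ---------------------------------------------------------------------------
# CSV I/O
#
# records CSV: record_id, title, abstract, keywords, authors
#   (keywords/authors are ";"-joined)
# decisions CSV: record_id, senior_decision, second_decision,
#   fulltext_include (0/1); second_decision empty for rapid reviews.
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["record_id", "title", "abstract", "keywords", "authors"]
_DECISION_COLUMNS = [
    "record_id",
    "senior_decision",
    "second_decision",
    "fulltext_include",
]


def _read_records_csv(path: str | os.PathLike) -> list[CitationRecord]:
    import pandas as pd

    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _RECORD_COLUMNS[:2] if c not in frame.columns]
    if missing:
        raise ValidationError(f"records CSV missing column(s): {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            CitationRecord(
                record_id=row.record_id,
                title=getattr(row, "title", ""),
                abstract=getattr(row, "abstract", ""),
                keywords=tuple(
                    k for k in getattr(row, "keywords", "").split(";") if k
                ),
                authors=tuple(
                    a for a in getattr(row, "authors", "").split(";") if a
                ),
            )
        )
    return records


def load_review_dataset(
    records_path: str | os.PathLike,
    decisions_path: str | os.PathLike,
    *,
    fmt: str = "csv",
    name: str = "review",
    review_type: str = "systematic",
) -> ReviewDataset:
    """Load a review dataset from a records file and a decisions CSV.

    ``fmt`` is ``"csv"`` (records as CSV) or ``"ris+csv"`` (records as RIS).
    The decisions CSV schema is fixed: ``record_id, senior_decision,
    second_decision, fulltext_include``; raw labels are binarized via
    :func:`normalize_decision` and retained in the decision's ``raw_label``.
    """
    import pandas as pd

    if fmt not in ("csv", "ris+csv"):
        raise ValidationError(f"unknown format {fmt!r}; use 'csv' or 'ris+csv'")
    if fmt == "ris+csv":
        with open(records_path, encoding="utf-8") as fh:
            records = read_ris(fh)
    else:
        records = _read_records_csv(records_path)

    frame = pd.read_csv(decisions_path, dtype=str, keep_default_na=False)
    missing = [c for c in ("record_id", "senior_decision") if c not in frame.columns]
    if missing:
        raise ValidationError(f"decisions CSV missing column(s): {missing}")
    if review_type == "systematic" and "second_decision" not in frame.columns:
        raise ValidationError(
            "systematic review decisions CSV must carry a second_decision column"
        )

    decisions: list[ScreeningDecision] = []
    fulltext: set[str] = set()
    n_senior = n_second = 0
    for row in frame.itertuples(index=False):
        rid = row.record_id
        raw_senior = row.senior_decision
        if raw_senior:
            decisions.append(
                ScreeningDecision(rid, SENIOR, normalize_decision(raw_senior, rid), raw_senior)
            )
            n_senior += 1
        raw_second = getattr(row, "second_decision", "")
        if raw_second:
            decisions.append(
                ScreeningDecision(rid, SECOND, normalize_decision(raw_second, rid), raw_second)
            )
            n_second += 1
        if str(getattr(row, "fulltext_include", "0")).strip() in ("1", "true", "True"):
            fulltext.add(rid)

    empty_roles = [r for r, n in ((SENIOR, n_senior), (SECOND, n_second)) if n == 0]
    if review_type == "rapid":
        empty_roles = [r for r in empty_roles if r != SECOND]
    if empty_roles:
        raise ValidationError(
            f"decisions file carries zero decisions for reviewer(s): {empty_roles}"
        )

    return ReviewDataset(
        name=name,
        review_type=review_type,
        records=records,
        decisions=decisions,
        fulltext_includes=fulltext,
    )


def write_review_dataset(
    dataset: ReviewDataset,
    records_path: str | os.PathLike,
    decisions_path: str | os.PathLike,
    *,
    fmt: str = "csv",
) -> None:
    """Write a dataset back out in the fixed CSV (or RIS+CSV) schema."""
    if fmt == "ris+csv":
        with open(records_path, "w", encoding="utf-8") as fh:
            write_ris(dataset.records, fh)
    else:
        with open(records_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_RECORD_COLUMNS)
            for r in dataset.records:
                writer.writerow(
                    [r.record_id, r.title, r.abstract, ";".join(r.keywords), ";".join(r.authors)]
                )
    with open(decisions_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DECISION_COLUMNS)
        for r in dataset.records:
            rid = r.record_id
            senior = dataset.decision_of(SENIOR, rid) or ""
            second = dataset.decision_of(SECOND, rid) or ""
            writer.writerow(
                [rid, senior, second, int(rid in dataset.fulltext_includes)]
            )


# ---------------------------------------------------------------------------
# Minimal RIS codec (tags: TY, ID, TI, AU, AB, KW, ER)
# ---------------------------------------------------------------------------

def read_ris(stream: io.TextIOBase | Iterable[str]) -> list[CitationRecord]:
    """Parse RIS-formatted records (the subset of tags screening uses)."""
    records: list[CitationRecord] = []
    current: dict[str, list[str]] = {}

    def flush() -> None:
        if not current:
            return
        rid = current.get("ID", [""])[0]
        title = current.get("TI", current.get("T1", [""]))[0]
        if not rid:
            rid = stable_record_id(title)
        records.append(
            CitationRecord(
                record_id=rid,
                title=title,
                abstract=" ".join(current.get("AB", [])),
                keywords=tuple(current.get("KW", [])),
                authors=tuple(current.get("AU", [])),
            )
        )
        current.clear()

    for line in stream:
        line = line.rstrip("\n")
        if len(line) >= 5 and line[2:5] == "  -" :
            tag, value = line[:2], line[6:].strip() if len(line) > 6 else ""
            if tag == "ER":
                flush()
            elif tag != "TY":
                current.setdefault(tag, []).append(value)
        elif line.strip() and current:
            # RIS continuation line: append to the last seen tag value
            last_tag = next(reversed(current))
            current[last_tag][-1] += " " + line.strip()
    flush()
    return records


def write_ris(records: Sequence[CitationRecord], stream: io.TextIOBase) -> None:
    for r in records:
        stream.write("TY  - JOUR\n")
        stream.write(f"ID  - {r.record_id}\n")
        stream.write(f"TI  - {r.title}\n")
        for a in r.authors:
            stream.write(f"AU  - {a}\n")
        if r.abstract:
            stream.write(f"AB  - {r.abstract}\n")
        for k in r.keywords:
            stream.write(f"KW  - {k}\n")
        stream.write("ER  - \n")
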