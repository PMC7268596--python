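"""Cited-references recovery: can reference-list scanning find missed records?

Comprehensive searches do not stop at bibliographic databases; scanning
the reference lists of the studies a review *did* include often resurfaces
records a screening strategy dropped.  Given the set of records a strategy
missed and a citation graph, a missed record counts as recovered when at
least one retained included study cites it.  Recovery consults only the
strategy-retained includes — a missed record cannot rescue itself via its
own reference list.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import pct_display
from .records import ValidationError
from .simulate import CitationGraph

__all__ = ["RecoveryResult", "recover"]


@dataclass(frozen=True)
class RecoveryResult:
    """Missed records before/after the cited-references search."""

    missed_before: frozenset[str]
    recovered: frozenset[str]
    missed_after: frozenset[str]
    pct_recovered: int | None          # of the missed records; None if none missed
    adjusted_missed_pct: int | None    # of the final-report includes, after recovery


def recover(
    missed: set[str],
    graph: CitationGraph,
    included_found: set[str],
    *,
    n_fulltext_includes: int | None = None,
    known_ids: set[str] | None = None,
) -> RecoveryResult:
    """Determine which missed records a cited-references search would find.

    ``included_found`` are the full-text includes the strategy retained.
    ``n_fulltext_includes`` (total includes in the final report) enables
    the adjusted proportion-missed; ``known_ids`` validates the graph.
    """
    if known_ids is not None:
        unknown = {rid for edge in graph.edges for rid in edge} - known_ids
        if unknown:
            raise ValidationError(
                f"citation graph references unknown ids: {sorted(unknown)[:5]}"
            )
    sources = set(included_found)
    recovered = {m for m in missed if graph.cited_by(m) & sources}
    missed_after = set(missed) - recovered

    pct_recovered = pct_display(len(recovered), len(missed)) if missed else None
    adjusted = None
    if n_fulltext_includes:
        adjusted = pct_display(len(missed_after), n_fulltext_includes)
    return RecoveryResult(
        missed_before=frozenset(missed),
        recovered=frozenset(recovered),
        missed_after=frozenset(missed_after),
        pct_recovered=pct_recovered,
        adjusted_missed_pct=adjusted,
    )
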