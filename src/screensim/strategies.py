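"""The four machine-assisted screening strategies and the human baselines.

Each strategy turns (human decisions, classifier predictions, training set)
into a per-record title-and-abstract consensus — the set of records
forwarded to full-text assessment — plus the number of manual screens the
approach consumes.  Training-set records always carry the senior reviewer's
recorded human decision into the consensus; the classifier speaks only for
the records nobody screened.

Single-reviewer strategies replace the (sole or senior) human pass with
the classifier; dual strategies keep the second reviewer screening
everything, so a record advances if either the second reviewer or the
senior/classifier arm marks it relevant.  The semi-automated variants add
a human verification pass over the classifier's predicted-relevant
records: only those the senior reviewer also marked include advance from
the machine arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .records import (
    SECOND,
    SENIOR,
    ReviewDataset,
    ValidationError,
    title_abstract_consensus_human,
)

__all__ = ["StrategyKind", "StrategyResult", "apply_strategy", "missed_records"]


class StrategyKind(str, Enum):
    """Screening approaches; ``dual_*`` require a systematic dataset."""

    SINGLE_FULL_AUTO = "single_full_auto"
    SINGLE_SEMI_AUTO = "single_semi_auto"
    DUAL_FULL_AUTO = "dual_full_auto"
    DUAL_SEMI_AUTO = "dual_semi_auto"
    BASELINE_SECOND_ONLY = "baseline_second_only"
    BASELINE_HUMAN = "baseline_human"

    @property
    def needs_second_reviewer(self) -> bool:
        return self in (
            StrategyKind.DUAL_FULL_AUTO,
            StrategyKind.DUAL_SEMI_AUTO,
            StrategyKind.BASELINE_SECOND_ONLY,
        )

    @property
    def uses_predictions(self) -> bool:
        return self in (
            StrategyKind.SINGLE_FULL_AUTO,
            StrategyKind.SINGLE_SEMI_AUTO,
            StrategyKind.DUAL_FULL_AUTO,
            StrategyKind.DUAL_SEMI_AUTO,
        )


@dataclass(frozen=True)
class StrategyResult:
    """Consensus and manual-effort accounting for one strategy run."""

    strategy: StrategyKind
    consensus_includes: frozenset[str]
    components: dict[str, int] = field(default_factory=dict)

    @property
    def manual_screens(self) -> int:
        """Total human title-and-abstract screens consumed."""
        return sum(self.components.values())


def apply_strategy(
    dataset: ReviewDataset,
    predictions,
    training_set,
    strategy: StrategyKind | str,
) -> StrategyResult:
    """Apply one screening strategy and account for the manual effort.

    ``predictions`` must cover exactly the records outside ``training_set``
    (both may be ``None`` for the pure-human baselines).
    """
    strategy = StrategyKind(strategy)
    n = dataset.workload_N
    senior_inc = dataset.includes_of(SENIOR)

    if strategy.needs_second_reviewer and dataset.review_type != "systematic":
        raise ValidationError(
            f"{strategy.value} requires a systematic dataset with a second reviewer"
        )

    if strategy is StrategyKind.BASELINE_HUMAN:
        if dataset.review_type == "systematic":
            consensus = title_abstract_consensus_human(dataset)
            components = {"senior_screens": n, "second_reviewer_screens": n}
        else:
            consensus = senior_inc
            components = {"senior_screens": n}
        return StrategyResult(strategy, frozenset(consensus), components)

    if strategy is StrategyKind.BASELINE_SECOND_ONLY:
        return StrategyResult(
            strategy,
            frozenset(dataset.includes_of(SECOND)),
            {"second_reviewer_screens": n},
        )

    # machine-assisted strategies
    if predictions is None or training_set is None:
        raise ValidationError(f"{strategy.value} requires predictions and a training set")
    train_ids = set(training_set.record_ids)
    pred_ids = set(predictions.record_ids)
    if pred_ids & train_ids:
        raise ValidationError("predictions overlap the training set")
    if pred_ids | train_ids != dataset.record_ids:
        raise ValidationError(
            "predictions must cover exactly the unscreened records "
            f"({len(pred_ids | train_ids)} covered of {n})"
        )

    t = len(train_ids)
    hard_true = set(predictions.hard_true_ids())
    p = len(hard_true)
    train_senior_inc = train_ids & senior_inc

    if strategy is StrategyKind.SINGLE_FULL_AUTO:
        consensus = train_senior_inc | hard_true
        components = {"training_screens": t}
    elif strategy is StrategyKind.SINGLE_SEMI_AUTO:
        consensus = train_senior_inc | (hard_true & senior_inc)
        components = {"training_screens": t, "senior_verifications": p}
    elif strategy is StrategyKind.DUAL_FULL_AUTO:
        consensus = dataset.includes_of(SECOND) | train_senior_inc | hard_true
        components = {"training_screens": t, "second_reviewer_screens": n}
    else:  # DUAL_SEMI_AUTO
        consensus = (
            dataset.includes_of(SECOND)
            | train_senior_inc
            | (hard_true & senior_inc)
        )
        components = {
            "training_screens": t,
            "senior_verifications": p,
            "second_reviewer_screens": n,
        }
    return StrategyResult(strategy, frozenset(consensus), components)


def missed_records(result: StrategyResult, dataset: ReviewDataset) -> set[str]:
    """Final-report includes the strategy would have excluded."""
    return set(dataset.fulltext_includes) - set(result.consensus_includes)
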