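"""Screening strategies: consensus rules, effort accounting, nesting."""

from __future__ import annotations

import pytest

from screensim import (
    PredictionSet,
    StrategyKind,
    SyntheticConfig,
    ValidationError,
    apply_strategy,
    draw_training_set,
    generate_corpus,
    missed_records,
)
from screensim.simulate import ReviewerProfile

MACHINE_STRATEGIES = [
    StrategyKind.SINGLE_FULL_AUTO,
    StrategyKind.SINGLE_SEMI_AUTO,
    StrategyKind.DUAL_FULL_AUTO,
    StrategyKind.DUAL_SEMI_AUTO,
]


def _oracle_consensus(dataset, predictions, training_set, strategy):
    """Record-by-record re-derivation of each strategy's forwarding rule."""
    train = set(training_set.record_ids)
    hard = predictions.hard_true_ids()
    out = set()
    for r in dataset.records:
        rid = r.record_id
        senior = dataset.decision_of("senior", rid) == "include"
        second = dataset.decision_of("second", rid) == "include"
        train_keep = rid in train and senior
        machine = rid in hard
        rule = {
            StrategyKind.SINGLE_FULL_AUTO: train_keep or machine,
            StrategyKind.SINGLE_SEMI_AUTO: train_keep or (machine and senior),
            StrategyKind.DUAL_FULL_AUTO: second or train_keep or machine,
            StrategyKind.DUAL_SEMI_AUTO: second or train_keep or (machine and senior),
        }[strategy]
        if rule:
            out.add(rid)
    return out


@pytest.mark.parametrize("strategy", MACHINE_STRATEGIES)
def test_consensus_matches_record_level_oracle(trained_pipeline, strategy):
    ds, ts, preds = trained_pipeline
    result = apply_strategy(ds, preds, ts, strategy)
    assert set(result.consensus_includes) == _oracle_consensus(ds, preds, ts, strategy)


@pytest.mark.parametrize("strategy", MACHINE_STRATEGIES)
def test_manual_screens_match_event_log(trained_pipeline, strategy):
    """Formula-vs-event-log oracle: count individually simulated human
    screening events and compare with the closed-form accounting."""
    ds, ts, preds = trained_pipeline
    events = [("senior", rid, "training") for rid in ts.record_ids]
    if strategy in (StrategyKind.SINGLE_SEMI_AUTO, StrategyKind.DUAL_SEMI_AUTO):
        events += [("senior", rid, "verify") for rid in preds.hard_true_ids()]
    if strategy in (StrategyKind.DUAL_FULL_AUTO, StrategyKind.DUAL_SEMI_AUTO):
        events += [("second", r.record_id, "screen") for r in ds.records]
    result = apply_strategy(ds, preds, ts, strategy)
    assert result.manual_screens == len(events)
    assert result.manual_screens == sum(result.components.values())


def test_strategy_nesting(trained_pipeline):
    """semi ⊆ fully and single ⊆ dual, hence missed counts anti-monotone."""
    ds, ts, preds = trained_pipeline
    consensus = {
        s: set(apply_strategy(ds, preds, ts, s).consensus_includes)
        for s in MACHINE_STRATEGIES
    }
    assert consensus[StrategyKind.SINGLE_SEMI_AUTO] <= consensus[StrategyKind.SINGLE_FULL_AUTO]
    assert consensus[StrategyKind.DUAL_SEMI_AUTO] <= consensus[StrategyKind.DUAL_FULL_AUTO]
    assert consensus[StrategyKind.SINGLE_FULL_AUTO] <= consensus[StrategyKind.DUAL_FULL_AUTO]
    assert consensus[StrategyKind.SINGLE_SEMI_AUTO] <= consensus[StrategyKind.DUAL_SEMI_AUTO]


def test_baseline_human_and_second_only(trained_pipeline):
    ds, _, _ = trained_pipeline
    human = apply_strategy(ds, None, None, StrategyKind.BASELINE_HUMAN)
    assert set(human.consensus_includes) == ds.includes_of("senior") | ds.includes_of("second")
    assert human.manual_screens == 2 * ds.workload_N
    second = apply_strategy(ds, None, None, StrategyKind.BASELINE_SECOND_ONLY)
    assert set(second.consensus_includes) == ds.includes_of("second")
    assert second.manual_screens == ds.workload_N


def test_baseline_human_rapid_counts_single_pass(rapid_dataset):
    result = apply_strategy(rapid_dataset, None, None, StrategyKind.BASELINE_HUMAN)
    assert result.manual_screens == rapid_dataset.workload_N
    assert set(result.consensus_includes) == rapid_dataset.includes_of("senior")


def test_dual_strategies_rejected_on_rapid_dataset(rapid_dataset):
    ts = draw_training_set(rapid_dataset, 50, seed=1)
    rest = tuple(rapid_dataset.record_ids - set(ts.record_ids))
    preds = PredictionSet(rest, tuple(0.9 for _ in rest))
    for s in (StrategyKind.DUAL_FULL_AUTO, StrategyKind.DUAL_SEMI_AUTO,
              StrategyKind.BASELINE_SECOND_ONLY):
        with pytest.raises(ValidationError):
            apply_strategy(rapid_dataset, preds, ts, s)


def test_predictions_overlapping_training_rejected(trained_pipeline):
    ds, ts, preds = trained_pipeline
    bad = PredictionSet(preds.record_ids[:-1] + (ts.record_ids[0],), preds.probabilities)
    with pytest.raises(ValidationError, match="overlap"):
        apply_strategy(ds, bad, ts, StrategyKind.SINGLE_FULL_AUTO)


def test_no_predicted_relevant_keeps_training_includes_only(trained_pipeline):
    ds, ts, preds = trained_pipeline
    none = PredictionSet(preds.record_ids, tuple(0.0 for _ in preds.record_ids))
    result = apply_strategy(ds, none, ts, StrategyKind.SINGLE_FULL_AUTO)
    expected = set(ts.record_ids) & ds.includes_of("senior")
    assert set(result.consensus_includes) == expected
    assert result.manual_screens == ts.size


def test_missed_records_set_difference(trained_pipeline):
    ds, ts, preds = trained_pipeline
    result = apply_strategy(ds, preds, ts, StrategyKind.DUAL_FULL_AUTO)
    missed = missed_records(result, ds)
    assert missed == ds.fulltext_includes - set(result.consensus_includes)


def test_perfect_classifier_and_senior_miss_nothing():
    """hard = truth and an error-free senior reviewer give zero missed
    final-report includes for every strategy."""
    ds = generate_corpus(
        SyntheticConfig(
            n_records=500,
            prevalence_ta=0.12,
            senior_profile=ReviewerProfile(1.0, 1.0),
            seed=21,
        )
    )
    ts = draw_training_set(ds, 100, seed=22)
    rest = [r for r in ds.records if r.record_id not in set(ts.record_ids)]
    preds = PredictionSet(
        tuple(r.record_id for r in rest),
        tuple(1.0 if r.truth_ta else 0.0 for r in rest),
    )
    for strategy in MACHINE_STRATEGIES:
        result = apply_strategy(ds, preds, ts, strategy)
        assert missed_records(result, ds) == set()
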