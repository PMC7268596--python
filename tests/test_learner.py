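"""Relevance learner: training protocol, predictions, dual supervision."""

from __future__ import annotations

import math

import numpy as np
import pytest

from screensim import (
    CitationRecord,
    LearnerConfig,
    PredictionSet,
    ReviewDataset,
    ScreeningDecision,
    SyntheticConfig,
    TermLabel,
    TrainingSet,
    ValidationError,
    draw_training_set,
    extend_training_set,
    fit_classifier,
    generate_corpus,
    grow_training_set,
    predict,
    predictions_available,
)
from screensim.learner import write_predictions_csv


def test_training_draw_is_deterministic_and_senior_labelled(systematic_dataset):
    a = draw_training_set(systematic_dataset, 200, seed=9)
    b = draw_training_set(systematic_dataset, 200, seed=9)
    assert a.record_ids == b.record_ids
    assert a.size == 200
    for rid, label in zip(a.record_ids, a.labels):
        assert label == (systematic_dataset.decision_of("senior", rid) == "include")


def test_training_draw_exhaustive_and_oversized(systematic_dataset):
    n = systematic_dataset.workload_N
    assert draw_training_set(systematic_dataset, n, seed=1).size == n
    with pytest.raises(ValidationError):
        draw_training_set(systematic_dataset, n + 1, seed=1)


@pytest.mark.parametrize(
    ("n_includes", "n_excludes", "min_includes", "expected"),
    [
        (4, 296, 2, True),    # availability reached with few includes
        (2, 198, 2, True),
        (1, 199, 2, False),   # below the include minimum
        (0, 200, 2, False),   # untrainable: one class only
        (5, 0, 2, False),     # no excludes at all
    ],
)
def test_predictions_available_rule(n_includes, n_excludes, min_includes, expected):
    ts = TrainingSet(
        tuple(f"r{i}" for i in range(n_includes + n_excludes)),
        tuple([True] * n_includes + [False] * n_excludes),
    )
    assert predictions_available(ts, min_includes) is expected


def test_extend_appends_a_batch_of_unscreened_records(systematic_dataset):
    ts = draw_training_set(systematic_dataset, 200, seed=4)
    bigger = extend_training_set(systematic_dataset, ts, 100, seed=5)
    assert bigger.size == 300
    assert bigger.record_ids[:200] == ts.record_ids
    assert len(set(bigger.record_ids)) == 300


def test_extend_rejects_zero_batch(systematic_dataset):
    ts = draw_training_set(systematic_dataset, 10, seed=4)
    with pytest.raises(ValidationError):
        extend_training_set(systematic_dataset, ts, 0, seed=5)


def test_growth_exhausts_on_all_irrelevant_corpus():
    """If no include ever appears, the loop must fail loudly, reporting
    the class counts, rather than spin."""
    from screensim.simulate import ReviewerProfile

    ds = generate_corpus(
        SyntheticConfig(
            n_records=50,
            prevalence_ta=0.0,
            senior_profile=ReviewerProfile(1.0, 1.0),
            seed=2,
        )
    )
    with pytest.raises(ValidationError, match="includes=0"):
        grow_training_set(ds, 20, 10, seed=3)


def test_separable_corpus_reaches_perfect_training_accuracy():
    ds = generate_corpus(
        SyntheticConfig(n_records=1000, prevalence_ta=0.1, signal_enrichment=10.0, seed=7)
    )
    ts, _ = grow_training_set(ds, 200, 100, seed=8)
    model = fit_classifier(ds, ts)
    probs = model.score([ds.record(rid) for rid in ts.record_ids])
    assert np.array_equal(probs >= model.threshold, np.array(ts.labels))


def test_no_term_labels_means_zero_offsets(trained_pipeline):
    ds, ts, _ = trained_pipeline
    model = fit_classifier(ds, ts)
    assert not model.term_offsets.any()


def test_relevant_term_label_never_decreases_containing_records(trained_pipeline):
    ds, ts, _ = trained_pipeline
    term = "w00003"  # a signal token present in many records
    plain = fit_classifier(ds, ts)
    tagged = fit_classifier(ds, ts, term_labels=[TermLabel(term, "relevant")])
    rest = [ds.record(r.record_id) for r in ds.records if r.record_id not in set(ts.record_ids)]
    p0, p1 = plain.score(rest), tagged.score(rest)
    has_term = np.array([term in set(r.title.split() + r.abstract.split() + list(r.keywords)) for r in rest])
    assert np.all(p1[has_term] >= p0[has_term])
    np.testing.assert_allclose(p1[~has_term], p0[~has_term])


def test_large_delta_forces_tagged_term_above_threshold(trained_pipeline):
    ds, ts, _ = trained_pipeline
    term = "w00003"
    model = fit_classifier(
        ds, ts,
        term_labels=[TermLabel(term, "relevant")],
        config=LearnerConfig(delta=50.0),
    )
    rest = [ds.record(r.record_id) for r in ds.records if r.record_id not in set(ts.record_ids)]
    probs = model.score(rest)
    for r, p in zip(rest, probs):
        tokens = set(r.title.split()) | set(r.abstract.split()) | set(r.keywords)
        if term in tokens:
            assert p >= model.threshold


def test_predictions_cover_exactly_the_unscreened_records(trained_pipeline):
    ds, ts, preds = trained_pipeline
    assert len(preds.record_ids) == ds.workload_N - ts.size
    assert set(preds.record_ids) == ds.record_ids - set(ts.record_ids)
    # hard predictions are exactly the thresholded probabilities
    assert preds.P == sum(p >= preds.threshold for p in preds.probabilities)
    for p, h in zip(preds.probabilities, preds.hard):
        assert h == (p >= preds.threshold)


def test_prediction_is_reproducible(trained_pipeline):
    ds, ts, preds = trained_pipeline
    again = predict(fit_classifier(ds, ts), ds, ts)
    assert again == preds


def test_featureless_record_scores_the_intercept():
    """A record with no text falls back to the model's base rate."""
    records = [
        CitationRecord(f"r{i}", title="alpha beta" if i % 2 else "gamma delta")
        for i in range(12)
    ] + [CitationRecord("blank", title="")]
    decisions = [
        ScreeningDecision(f"r{i}", "senior", "include" if i % 2 else "exclude")
        for i in range(12)
    ] + [ScreeningDecision("blank", "senior", "exclude")]
    ds = ReviewDataset("tiny", "rapid", records, decisions)
    ts = TrainingSet(tuple(f"r{i}" for i in range(12)), tuple(bool(i % 2) for i in range(12)))
    model = fit_classifier(ds, ts)
    preds = predict(model, ds, ts)
    expected = 1.0 / (1.0 + math.exp(-model.intercept))
    assert preds.probability_of("blank") == pytest.approx(expected)


def test_predictions_csv_round_trips_six_decimals(tmp_path, trained_pipeline):
    _, _, preds = trained_pipeline
    path = tmp_path / "predictions.csv"
    write_predictions_csv(preds, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "record_id,probability,hard"
    assert len(lines) == 1 + len(preds.record_ids)
    rid, prob, hard = lines[1].split(",")
    assert rid == preds.record_ids[0]
    assert prob == f"{preds.probabilities[0]:.6f}"
    assert hard == ("true" if preds.hard[0] else "false")


def test_flagged_fraction_is_recall_first_over_prediction(emulated_suite):
    """Across the emulated benchmark reviews the tool flags more records
    than are truly relevant (recall-first operating point), with the
    median flagged fraction in the band real screening tools show."""
    fracs = []
    for res in emulated_suite:
        preds, truth = res["predictions"], res["truth"]
        n_rest = len(preds.record_ids)
        frac = preds.P / n_rest
        prevalence = sum(truth[rid] for rid in preds.record_ids) / n_rest
        assert frac >= prevalence
        fracs.append(frac)
    assert 0.10 <= float(np.median(fracs)) <= 0.67
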