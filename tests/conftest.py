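"""Shared fixtures: synthetic corpora and one fully trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from screensim import (
    SyntheticConfig,
    fit_classifier,
    generate_corpus,
    grow_training_set,
    predict,
)


@pytest.fixture(scope="session")
def systematic_dataset():
    """Mid-sized systematic review corpus with a clear term signal."""
    return generate_corpus(
        SyntheticConfig(
            n_records=600,
            prevalence_ta=0.12,
            p_ft_given_ta=0.4,
            signal_enrichment=5.0,
            name="sys-fixture",
            seed=101,
        )
    )


@pytest.fixture(scope="session")
def rapid_dataset():
    return generate_corpus(
        SyntheticConfig(
            n_records=500,
            prevalence_ta=0.15,
            p_ft_given_ta=0.3,
            review_type="rapid",
            name="rapid-fixture",
            seed=102,
        )
    )


@pytest.fixture(scope="session")
def trained_pipeline(systematic_dataset):
    """(dataset, training_set, predictions) for strategy-level tests."""
    ts, _ = grow_training_set(systematic_dataset, 120, 60, seed=103)
    model = fit_classifier(systematic_dataset, ts)
    preds = predict(model, systematic_dataset, ts)
    return systematic_dataset, ts, preds


@pytest.fixture(scope="session")
def emulated_suite():
    """Full pipeline over the 17 emulated benchmark reviews.

    Returns a list of dicts with the dataset, training set, predictions,
    and the true-relevance lookup, shared by learner-behaviour and
    acceptance tests.
    """
    from screensim.simulate import emulated_study_configs

    results = []
    for cfg in emulated_study_configs(seed=3):
        ds = generate_corpus(cfg)
        ts, _ = grow_training_set(ds, 200, 100, seed=cfg.seed + 1)
        model = fit_classifier(ds, ts)
        preds = predict(model, ds, ts)
        results.append(
            {
                "config": cfg,
                "dataset": ds,
                "training_set": ts,
                "predictions": preds,
                "truth": {r.record_id: bool(r.truth_ta) for r in ds.records},
            }
        )
    return results
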