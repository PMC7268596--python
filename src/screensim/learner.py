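"""Relevance-prediction engine emulating an Abstrackr-style screening tool.

The workflow mirrors how such tools are used in practice: the senior
reviewer screens a random training set (default 200 records, extended in
batches of 100 until the tool can produce predictions), a classifier is
fitted to the labelled records, and a probability of relevance plus a
binary "hard" prediction (probability >= threshold) is emitted for every
record nobody screened.

The classifier is an L2-regularized logistic regression on token counts of
title + abstract + keywords (title tokens weighted x2; lowercase
alphanumeric tokens of length >= 2, no stemming).  Dual supervision —
reviewer-tagged relevant/irrelevant terms — enters as fixed additive
log-odds offsets (+delta for relevant-tagged, -delta for irrelevant-tagged
terms present in a record) applied at scoring time, so a tagged term shifts
every record containing it monotonically toward or away from relevance.
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .records import INCLUDE, SENIOR, CitationRecord, ReviewDataset, ValidationError

__all__ = [
    "LearnerConfig",
    "TrainingSet",
    "TermLabel",
    "ClassifierModel",
    "PredictionSet",
    "tokenize",
    "record_tokens",
    "draw_training_set",
    "predictions_available",
    "extend_training_set",
    "grow_training_set",
    "fit_classifier",
    "predict",
    "write_predictions_csv",
]

_TOKEN_RE = re.compile(r"[a-z0-9]+")
#: Weight of title tokens relative to abstract/keyword tokens.
TITLE_WEIGHT = 2


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens of length >= 2; no stemming."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= 2]


def record_tokens(record: CitationRecord) -> list[str]:
    """Feature tokens of a record: title (x2) + abstract + keywords."""
    title = tokenize(record.title)
    return (
        title * TITLE_WEIGHT
        + tokenize(record.abstract)
        + [t for kw in record.keywords for t in tokenize(kw)]
    )


@dataclass(frozen=True)
class LearnerConfig:
    """Tunables of the prediction engine.

    ``delta`` is the log-odds offset one tagged term contributes;
    ``threshold`` converts probabilities into hard predictions; ``C`` is the
    inverse L2 regularization strength of the logistic fit;
    ``min_includes`` is the smallest number of include labels (with at
    least one exclude) before predictions become available.
    ``recall_bias`` is the extra weight the relevant class receives in the
    probability calibration: screening tools operate recall-first and flag
    far more records than the prevalence, and this parameter reproduces
    that over-predicting operating point (1.0 = neutral calibration).
    ``calibration_folds`` caps the cross-validation folds used to collect
    out-of-fold margins for Platt calibration.
    """

    delta: float = 2.0
    threshold: float = 0.5
    C: float = 1.0
    min_includes: int = 2
    recall_bias: float = 2.0
    calibration_folds: int = 5


@dataclass(frozen=True)
class TermLabel:
    """A reviewer-tagged term: indicative of relevance or irrelevance."""

    term: str
    polarity: str  # "relevant" | "irrelevant"

    def __post_init__(self) -> None:
        if self.polarity not in ("relevant", "irrelevant"):
            raise ValidationError(
                f"term polarity must be 'relevant' or 'irrelevant', got {self.polarity!r}"
            )


@dataclass(frozen=True)
class TrainingSet:
    """Randomly ordered records screened by the senior reviewer."""

    record_ids: tuple[str, ...]
    labels: tuple[bool, ...]  # True = include

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.labels):
            raise ValidationError("training ids and labels differ in length")
        if len(set(self.record_ids)) != len(self.record_ids):
            raise ValidationError("training set contains duplicate records")

    @property
    def size(self) -> int:
        return len(self.record_ids)

    @property
    def n_includes(self) -> int:
        return int(sum(self.labels))

    @property
    def n_excludes(self) -> int:
        return self.size - self.n_includes


def _senior_label(dataset: ReviewDataset, record_id: str) -> bool:
    decision = dataset.decision_of(SENIOR, record_id)
    if decision is None:
        raise ValidationError(
            f"record {record_id!r} lacks a senior decision to use as a training label"
        )
    return decision == INCLUDE


def draw_training_set(dataset: ReviewDataset, size: int, seed: int) -> TrainingSet:
    """Uniform random training sample, labelled with senior decisions."""
    n = dataset.workload_N
    if size > n:
        raise ValidationError(f"training size {size} exceeds the workload {n}")
    ids = [r.record_id for r in dataset.records]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)[:size]
    chosen = tuple(ids[i] for i in order)
    return TrainingSet(chosen, tuple(_senior_label(dataset, rid) for rid in chosen))


def predictions_available(training_set: TrainingSet, min_includes: int = 2) -> bool:
    """Both classes represented at the configured minimum."""
    return training_set.n_includes >= min_includes and training_set.n_excludes >= 1


def extend_training_set(
    dataset: ReviewDataset,
    training_set: TrainingSet,
    batch: int,
    seed: int,
) -> TrainingSet:
    """Screen a further uniform-random batch of unscreened records."""
    if batch <= 0:
        raise ValidationError("batch must be positive")
    screened = set(training_set.record_ids)
    remaining = [r.record_id for r in dataset.records if r.record_id not in screened]
    if not remaining:
        raise ValidationError(
            "no unscreened records remain and predictions are still unavailable "
            f"(includes={training_set.n_includes}, excludes={training_set.n_excludes})"
        )
    rng = np.random.default_rng(seed)
    take = min(batch, len(remaining))
    order = rng.permutation(len(remaining))[:take]
    extra = tuple(remaining[i] for i in order)
    return TrainingSet(
        training_set.record_ids + extra,
        training_set.labels + tuple(_senior_label(dataset, rid) for rid in extra),
    )


def grow_training_set(
    dataset: ReviewDataset,
    size: int,
    batch: int,
    seed: int,
    min_includes: int = 2,
) -> tuple[TrainingSet, int]:
    """Draw ``size`` records, then extend in batches until predictions are
    available.  Returns the training set and the number of extension batches.
    """
    ts = draw_training_set(dataset, size, seed)
    batches = 0
    while not predictions_available(ts, min_includes):
        ts = extend_training_set(dataset, ts, batch, seed + 1 + batches)
        batches += 1
    return ts, batches


@dataclass
class ClassifierModel:
    """Fitted relevance model: logistic weights plus term-label offsets."""

    vocabulary: dict[str, int]
    weights: np.ndarray
    intercept: float
    term_offsets: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (len(self.weights) == len(self.vocabulary) == len(self.term_offsets)):
            raise ValidationError("weights, vocabulary and term_offsets must align")

    def score(self, records: Sequence[CitationRecord]) -> np.ndarray:
        """Probability of relevance for each record."""
        counts = _count_matrix(records, self.vocabulary)
        margin = counts @ self.weights + self.intercept
        if np.any(self.term_offsets):
            presence = (counts > 0).astype(float)
            margin = margin + presence @ self.term_offsets
        return 1.0 / (1.0 + np.exp(-margin))


@dataclass(frozen=True)
class PredictionSet:
    """Probability and hard prediction for each unscreened record."""

    record_ids: tuple[str, ...]
    probabilities: tuple[float, ...]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if len(self.record_ids) != len(self.probabilities):
            raise ValidationError("prediction ids and probabilities differ in length")

    @property
    def hard(self) -> tuple[bool, ...]:
        return tuple(p >= self.threshold for p in self.probabilities)

    @property
    def P(self) -> int:
        """Count of hard-true (predicted relevant) records."""
        return sum(self.hard)

    def hard_true_ids(self) -> set[str]:
        return {rid for rid, h in zip(self.record_ids, self.hard) if h}

    def probability_of(self, record_id: str) -> float:
        if not hasattr(self, "_index"):
            object.__setattr__(
                self, "_index", {rid: i for i, rid in enumerate(self.record_ids)}
            )
        return self.probabilities[self._index[record_id]]


def _build_vocabulary(records: Iterable[CitationRecord]) -> dict[str, int]:
    vocab: set[str] = set()
    for r in records:
        vocab.update(record_tokens(r))
    return {tok: i for i, tok in enumerate(sorted(vocab))}


def _count_matrix(
    records: Sequence[CitationRecord], vocabulary: Mapping[str, int]
) -> sp.csr_matrix:
    data, indices, indptr = [], [], [0]
    for r in records:
        row: dict[int, int] = {}
        for tok in record_tokens(r):
            j = vocabulary.get(tok)
            if j is not None:
                row[j] = row.get(j, 0) + 1
        for j in sorted(row):
            indices.append(j)
            data.append(row[j])
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.asarray(data, dtype=float), indices, indptr),
        shape=(len(records), len(vocabulary)),
    )


def fit_classifier(
    dataset: ReviewDataset,
    training_set: TrainingSet,
    term_labels: Sequence[TermLabel] = (),
    config: LearnerConfig = LearnerConfig(),
) -> ClassifierModel:
    """Fit the relevance model on the training set's token counts.

    The vocabulary spans the whole uploaded corpus (all records are known
    to the tool before screening starts).  Both screening classes must be
    represented; tagged terms get log-odds offsets +-delta applied at
    scoring time.
    """
    if not predictions_available(training_set, min_includes=1):
        raise ValidationError(
            "cannot fit: training set does not represent both classes"
        )
    seen = {l.term: l.polarity for l in term_labels}
    if len(seen) != len({l.term for l in term_labels}):  # pragma: no cover
        raise ValidationError("a term has at most one polarity")
    vocabulary = _build_vocabulary(dataset.records)
    if not vocabulary:
        raise ValidationError("empty vocabulary: all records are textless")

    train_records = [dataset.record(rid) for rid in training_set.record_ids]
    x = _count_matrix(train_records, vocabulary)
    y = np.asarray(training_set.labels, dtype=int)
    clf = LogisticRegression(
        C=config.C, solver="liblinear", class_weight="balanced", max_iter=1000
    )
    clf.fit(x, y)
    weights = clf.coef_.ravel()
    intercept = float(clf.intercept_[0])

    # Platt-calibrate on out-of-fold margins.  High-dimensional fits on a
    # few hundred records put the apparent decision boundary far from where
    # unseen records actually score; calibrating against out-of-fold
    # margins corrects the shift.  The relevant class gets recall_bias
    # times its balanced weight so the 0.5 hard cut sits at the
    # recall-first operating point screening tools use.
    slope, shift = _platt_calibration(x, y, config)
    weights = slope * weights
    intercept = slope * intercept + shift

    offsets = np.zeros(len(vocabulary))
    for label in term_labels:
        term = label.term.lower()
        j = vocabulary.get(term)
        if j is not None:
            offsets[j] = config.delta if label.polarity == "relevant" else -config.delta
    return ClassifierModel(
        vocabulary=vocabulary,
        weights=weights,
        intercept=intercept,
        term_offsets=offsets,
        threshold=config.threshold,
    )


def _platt_calibration(
    x: sp.csr_matrix, y: np.ndarray, config: LearnerConfig
) -> tuple[float, float]:
    """(slope, shift) mapping raw margins to calibrated log-odds.

    Falls back to the identity when either class is too small for
    cross-validation or the fitted slope is not positive (degenerate fit).
    """
    from sklearn.model_selection import StratifiedKFold

    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    n_splits = min(config.calibration_folds, n_pos, n_neg)
    if n_splits < 2:
        return 1.0, 0.0
    oof = np.zeros(len(y))
    for train_idx, test_idx in StratifiedKFold(n_splits=n_splits).split(x, y):
        fold = LogisticRegression(
            C=config.C, solver="liblinear", class_weight="balanced", max_iter=1000
        )
        fold.fit(x[train_idx], y[train_idx])
        oof[test_idx] = x[test_idx] @ fold.coef_.ravel() + fold.intercept_[0]
    # balanced class weights, with the relevant class upweighted further
    sample_weight = np.where(
        y == 1,
        config.recall_bias * len(y) / (2.0 * n_pos),
        len(y) / (2.0 * n_neg),
    )
    platt = LogisticRegression(max_iter=1000)
    platt.fit(oof.reshape(-1, 1), y, sample_weight=sample_weight)
    slope = float(platt.coef_[0, 0])
    if slope <= 0:
        return 1.0, 0.0
    return slope, float(platt.intercept_[0])


def predict(
    model: ClassifierModel,
    dataset: ReviewDataset,
    training_set: TrainingSet,
) -> PredictionSet:
    """Probabilities and hard predictions for the unscreened records."""
    screened = set(training_set.record_ids)
    rest = [r for r in dataset.records if r.record_id not in screened]
    probs = model.score(rest) if rest else np.empty(0)
    return PredictionSet(
        record_ids=tuple(r.record_id for r in rest),
        probabilities=tuple(float(p) for p in probs),
        threshold=model.threshold,
    )


def write_predictions_csv(predictions: PredictionSet, path: str | os.PathLike) -> None:
    """Mirror of the tool's downloadable predictions file."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "probability", "hard"])
        for rid, prob, hard in zip(
            predictions.record_ids, predictions.probabilities, predictions.hard
        ):
            writer.writerow([rid, f"{prob:.6f}", "true" if hard else "false"])
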