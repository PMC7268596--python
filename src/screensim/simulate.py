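"""Synthetic review corpora with the statistical structure of real screening.

Real screening datasets from evidence-synthesis centres are rarely
deposited, so every downstream stage is exercised on generated corpora that
emulate their published statistical shape: per-reviewer workloads of a few
hundred to ~12,000 records, title-and-abstract inclusion rates of 2-26%,
full-text inclusion below 1-11% of the workload, two imperfect human
reviewers, and a citation graph from included studies to other relevant
records.

The text model is a two-class bag-of-words multinomial: every record draws
``tokens_per_record`` tokens from a shared vocabulary; in truly relevant
records a small set of signal terms has its probability multiplied by
``signal_enrichment`` (then renormalized).  A linear classifier on token
counts sees tunable separability without any natural-language modelling;
``signal_enrichment=1`` is the exact chance-level control.  Reviewer errors
are independent Bernoulli per record and reviewer, parameterized by
sensitivity/specificity profiles.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .benchmark import BENCHMARK_REVIEWS
from .records import (
    SECOND,
    SENIOR,
    CitationRecord,
    ReviewDataset,
    ScreeningDecision,
    ValidationError,
)

__all__ = [
    "ReviewerProfile",
    "SyntheticConfig",
    "CitationGraph",
    "generate_corpus",
    "generate_citation_graph",
    "emulated_study_configs",
    "write_truth_csv",
    "write_edges_csv",
    "read_edges_csv",
]


@dataclass(frozen=True)
class ReviewerProfile:
    """Imperfect human screener.

    ``sensitivity`` = P(include | truly relevant at title/abstract);
    ``specificity`` = P(exclude | truly irrelevant).
    """

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


#: Default reviewer profiles: the senior reviewer is presumed the most
#: accurate screener; the second (junior) reviewer misses more, so that
#: single-second-reviewer miss rates span the 0-43% range seen in practice.
SENIOR_PROFILE = ReviewerProfile(sensitivity=0.95, specificity=0.995)
SECOND_PROFILE = ReviewerProfile(sensitivity=0.85, specificity=0.99)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one generated review corpus.

    Defaults emulate the median systematic review of the published
    benchmark: 2928 records, 8% title/abstract prevalence, and full-text
    inclusion of ~42% of the title/abstract-relevant records.
    """

    n_records: int = 2928
    prevalence_ta: float = 0.08
    p_ft_given_ta: float = 0.42
    vocab_size: int = 500
    n_signal_terms: int = 20
    signal_enrichment: float = 5.0
    tokens_per_record: int = 120
    senior_profile: ReviewerProfile = SENIOR_PROFILE
    second_profile: ReviewerProfile = SECOND_PROFILE
    citation_prob_rho: float = 0.05
    review_type: str = "systematic"
    name: str = "synthetic"
    seed: int = 0
    #: abstracts are blanked with this probability to exercise missing text
    p_empty_abstract: float = 0.05
    title_tokens: int = 8
    keyword_tokens: int = 3

    def __post_init__(self) -> None:
        if self.n_signal_terms >= self.vocab_size:
            raise ValidationError("n_signal_terms must be < vocab_size")
        if not 0.0 <= self.prevalence_ta < 1.0:
            raise ValidationError("prevalence_ta must be in [0, 1)")
        if not 0.0 < self.p_ft_given_ta <= 1.0:
            raise ValidationError("p_ft_given_ta must be in (0, 1]")
        if not 0.0 <= self.citation_prob_rho <= 1.0:
            raise ValidationError("citation_prob_rho must be in [0, 1]")
        if self.signal_enrichment <= 0:
            raise ValidationError("signal_enrichment must be positive")
        if self.review_type not in ("systematic", "rapid"):
            raise ValidationError("review_type must be 'systematic' or 'rapid'")


@dataclass(frozen=True)
class CitationGraph:
    """Directed edges: included study -> cited relevant record."""

    edges: frozenset[tuple[str, str]]

    def cited_by(self, record_id: str) -> set[str]:
        return {s for s, m in self.edges if m == record_id}


def _class_distributions(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    base = np.full(config.vocab_size, 1.0 / config.vocab_size)
    rel = base.copy()
    rel[: config.n_signal_terms] *= config.signal_enrichment
    rel /= rel.sum()
    return base, rel


def _draw_tokens(rng: np.random.Generator, probs: np.ndarray, k: int) -> list[str]:
    idx = rng.choice(len(probs), size=k, p=probs)
    return [f"w{j:05d}" for j in idx]


def generate_corpus(config: SyntheticConfig) -> ReviewDataset:
    """Generate a fully labelled review dataset.

    Truth labels are Bernoulli draws (``prevalence_ta`` for title/abstract
    relevance; ``p_ft_given_ta`` for full-text relevance among the
    relevant); record text comes from the class-conditional multinomial;
    reviewer decisions are drawn per profile, independently per record and
    reviewer.  Full-text includes follow the human flow: a record enters
    the final report only if it is full-text relevant *and* a human arm
    screened it in at title/abstract (either reviewer for systematic
    reviews, the senior for rapid ones).  Identical config+seed gives an
    identical dataset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records
    truth_ta = rng.random(n) < config.prevalence_ta
    truth_ft = truth_ta & (rng.random(n) < config.p_ft_given_ta)
    if config.prevalence_ta > 0 and not truth_ta.any():
        warnings.warn(
            f"{config.name}: zero relevant records drawn at prevalence "
            f"{config.prevalence_ta}; downstream stages will be degenerate",
            stacklevel=2,
        )

    base, rel = _class_distributions(config)
    n_body = max(config.tokens_per_record - config.title_tokens, 0)
    records: list[CitationRecord] = []
    for i in range(n):
        probs = rel if truth_ta[i] else base
        title = " ".join(_draw_tokens(rng, probs, config.title_tokens))
        abstract = " ".join(_draw_tokens(rng, probs, n_body))
        if rng.random() < config.p_empty_abstract:
            abstract = ""
        keywords = tuple(_draw_tokens(rng, probs, config.keyword_tokens))
        records.append(
            CitationRecord(
                record_id=f"{config.name}-{i:06d}",
                title=title,
                abstract=abstract,
                keywords=keywords,
                authors=(),
                truth_ta=bool(truth_ta[i]),
                truth_ft=bool(truth_ft[i]),
            )
        )

    def draw_decisions(profile: ReviewerProfile, role: str) -> list[ScreeningDecision]:
        u = rng.random(n)
        include = np.where(truth_ta, u < profile.sensitivity, u >= profile.specificity)
        return [
            ScreeningDecision(records[i].record_id, role, "include" if include[i] else "exclude")
            for i in range(n)
        ]

    decisions = draw_decisions(config.senior_profile, SENIOR)
    senior_inc = {d.record_id for d in decisions if d.decision == "include"}
    if config.review_type == "systematic":
        second = draw_decisions(config.second_profile, SECOND)
        decisions += second
        human_pass = senior_inc | {d.record_id for d in second if d.decision == "include"}
    else:
        human_pass = senior_inc

    fulltext = {
        records[i].record_id
        for i in range(n)
        if truth_ft[i] and records[i].record_id in human_pass
    }
    return ReviewDataset(
        name=config.name,
        review_type=config.review_type,
        records=records,
        decisions=decisions,
        fulltext_includes=fulltext,
    )


def generate_citation_graph(
    dataset: ReviewDataset, rho: float, seed: int
) -> CitationGraph:
    """Bernoulli citation graph from included studies to relevant records.

    Each (included study, other truly-relevant record) pair receives a
    directed edge independently with probability ``rho``; a record is
    recoverable via reference-list scanning iff it has at least one
    incoming edge from a retained included study.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValidationError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sources = sorted(dataset.fulltext_includes)
    # relevant records may cite each other; only self-citation is excluded
    targets = sorted(r.record_id for r in dataset.records if r.truth_ta)
    edges: set[tuple[str, str]] = set()
    if sources and targets:
        draws = rng.random((len(sources), len(targets))) < rho
        for i, s in enumerate(sources):
            for j, m in enumerate(targets):
                if s != m and draws[i, j]:
                    edges.add((s, m))
    return CitationGraph(frozenset(edges))


def emulated_study_configs(
    seed: int, scale: float = 1.0, signal_enrichment: float = 5.0
) -> list[SyntheticConfig]:
    """One synthetic config per benchmark review.

    Workloads, title/abstract prevalences and full-text rates mirror each
    of the 17 published reviews; ``scale`` shrinks workloads (floor 300
    records) for quick test runs.  Each config gets its own sub-seed.
    """
    configs = []
    for i, b in enumerate(BENCHMARK_REVIEWS):
        n = max(int(round(b.workload * scale)), 300)
        prevalence = b.ta_includes / b.workload
        p_ft = min(b.ft_includes / b.ta_includes, 1.0) if b.ta_includes else 0.5
        configs.append(
            SyntheticConfig(
                n_records=n,
                prevalence_ta=prevalence,
                p_ft_given_ta=max(p_ft, 0.01),
                signal_enrichment=signal_enrichment,
                review_type=b.review_type,
                name=b.name.lower().replace(" ", "-"),
                seed=(seed * 1000 + i) % 2**31,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Plain-text side files
# ---------------------------------------------------------------------------

def write_truth_csv(dataset: ReviewDataset, path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "truth_ta", "truth_ft"])
        for r in dataset.records:
            writer.writerow([r.record_id, int(bool(r.truth_ta)), int(bool(r.truth_ft))])


def write_edges_csv(graph: CitationGraph, path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["citing_id", "cited_id"])
        for citing, cited in sorted(graph.edges):
            writer.writerow([citing, cited])


def read_edges_csv(path: str | os.PathLike) -> CitationGraph:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"citing_id", "cited_id"} - set(reader.fieldnames):
            raise ValidationError("edge list CSV must have citing_id, cited_id columns")
        return CitationGraph(frozenset((row["citing_id"], row["cited_id"]) for row in reader))
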