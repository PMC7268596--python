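"""Data model: decision normalization, consensus, validation, round-trips."""

from __future__ import annotations

import io

import numpy as np
import pytest

from screensim import (
    CitationRecord,
    ReviewDataset,
    ScreeningDecision,
    ValidationError,
    load_review_dataset,
    normalize_decision,
    title_abstract_consensus_human,
    write_review_dataset,
)
from screensim.records import read_ris, write_ris


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        ("unsure", "include"),
        ("include", "include"),
        ("Borderline", "include"),
        ("UNSURE", "include"),
        ("exclude", "exclude"),
        ("Exclude", "exclude"),
        ("  include ", "include"),
    ],
)
def test_normalize_decision_binarizes(raw, expected):
    """Include/unsure/borderline are equivalent at title/abstract stage."""
    assert normalize_decision(raw) == expected


def test_normalize_decision_rejects_unknown_label_naming_record():
    with pytest.raises(ValidationError, match="rec-9"):
        normalize_decision("maybe", record_id="rec-9")


def _tiny_dataset(senior_inc, second_inc, ids=("a", "b", "c", "d"), review_type="systematic"):
    records = [CitationRecord(i, title=f"title {i}") for i in ids]
    decisions = [
        ScreeningDecision(i, "senior", "include" if i in senior_inc else "exclude")
        for i in ids
    ]
    if review_type == "systematic":
        decisions += [
            ScreeningDecision(i, "second", "include" if i in second_inc else "exclude")
            for i in ids
        ]
    return ReviewDataset("tiny", review_type, records, decisions)


def test_consensus_is_union_of_reviewer_includes():
    ds = _tiny_dataset({"a", "b"}, {"b", "c"})
    assert title_abstract_consensus_human(ds) == {"a", "b", "c"}


def test_consensus_empty_when_nobody_includes():
    assert title_abstract_consensus_human(_tiny_dataset(set(), set())) == set()


def test_consensus_matches_per_record_or_oracle(systematic_dataset):
    consensus = title_abstract_consensus_human(systematic_dataset)
    for r in systematic_dataset.records:
        expected = (
            systematic_dataset.decision_of("senior", r.record_id) == "include"
            or systematic_dataset.decision_of("second", r.record_id) == "include"
        )
        assert (r.record_id in consensus) == expected


def test_consensus_requires_second_reviewer():
    ds = _tiny_dataset({"a"}, set(), review_type="rapid")
    with pytest.raises(ValidationError):
        title_abstract_consensus_human(ds)


def test_fulltext_relevance_implies_title_abstract_relevance():
    with pytest.raises(ValidationError):
        CitationRecord("x", title="t", truth_ta=False, truth_ft=True)


def test_duplicate_record_ids_rejected():
    records = [CitationRecord("a", title="t"), CitationRecord("a", title="t2")]
    with pytest.raises(ValidationError, match="duplicate"):
        ReviewDataset("dup", "systematic", records, [])


def test_decision_for_unknown_record_rejected():
    with pytest.raises(ValidationError, match="unknown"):
        ReviewDataset(
            "x",
            "rapid",
            [CitationRecord("a", title="t")],
            [ScreeningDecision("zz", "senior", "include")],
        )


def test_rapid_review_rejects_second_reviewer_decisions():
    with pytest.raises(ValidationError, match="senior decisions only"):
        ReviewDataset(
            "x",
            "rapid",
            [CitationRecord("a", title="t")],
            [ScreeningDecision("a", "second", "include")],
        )


def test_fulltext_includes_must_pass_human_stage():
    records = [CitationRecord(i, title=i) for i in "ab"]
    decisions = [
        ScreeningDecision("a", "senior", "include"),
        ScreeningDecision("b", "senior", "exclude"),
    ]
    with pytest.raises(ValidationError, match="not screened in"):
        ReviewDataset("x", "rapid", records, decisions, fulltext_includes={"b"})


def test_csv_round_trip_preserves_dataset(tmp_path, systematic_dataset):
    rp, dp = tmp_path / "records.csv", tmp_path / "decisions.csv"
    write_review_dataset(systematic_dataset, rp, dp)
    loaded = load_review_dataset(rp, dp, name="sys-fixture", review_type="systematic")
    assert loaded.record_ids == systematic_dataset.record_ids
    assert loaded.fulltext_includes == systematic_dataset.fulltext_includes
    for role in ("senior", "second"):
        assert loaded.includes_of(role) == systematic_dataset.includes_of(role)


def test_ris_round_trip_preserves_text_fields(systematic_dataset):
    buf = io.StringIO()
    write_ris(systematic_dataset.records[:25], buf)
    buf.seek(0)
    back = read_ris(buf)
    assert len(back) == 25
    for orig, rt in zip(systematic_dataset.records[:25], back):
        assert rt.record_id == orig.record_id
        assert rt.title == orig.title
        assert rt.abstract == orig.abstract
        assert rt.keywords == orig.keywords


def test_loader_summary_echoes_review_scale_counts(tmp_path):
    """A 1439-record review with 46 title/abstract and 5 full-text includes."""
    rng = np.random.default_rng(7)
    n = 1439
    ids = [f"r{i:04d}" for i in range(n)]
    senior_inc = set(ids[:40])
    second_inc = set(ids[30:46])  # union of both arms = 46
    ft = set(ids[:5])
    with open(tmp_path / "records.csv", "w") as fh:
        fh.write("record_id,title,abstract,keywords,authors\n")
        for i in ids:
            fh.write(f"{i},study {i},,,\n")
    with open(tmp_path / "decisions.csv", "w") as fh:
        fh.write("record_id,senior_decision,second_decision,fulltext_include\n")
        for i in ids:
            senior = "include" if i in senior_inc else "exclude"
            second = "unsure" if i in second_inc else "exclude"
            fh.write(f"{i},{senior},{second},{int(i in ft)}\n")
    ds = load_review_dataset(
        tmp_path / "records.csv", tmp_path / "decisions.csv",
        name="concussion-like", review_type="systematic",
    )
    assert ds.summary() == {"workload_N": 1439, "ta_includes": 46, "fulltext_includes": 5}


def test_loader_rejects_empty_decisions(tmp_path):
    with open(tmp_path / "records.csv", "w") as fh:
        fh.write("record_id,title,abstract,keywords,authors\na,t,,,\n")
    with open(tmp_path / "decisions.csv", "w") as fh:
        fh.write("record_id,senior_decision,second_decision,fulltext_include\n")
    with pytest.raises(ValidationError, match="zero decisions"):
        load_review_dataset(
            tmp_path / "records.csv", tmp_path / "decisions.csv",
            review_type="systematic",
        )


def test_loader_requires_second_column_for_systematic(tmp_path):
    with open(tmp_path / "records.csv", "w") as fh:
        fh.write("record_id,title,abstract,keywords,authors\na,t,,,\n")
    with open(tmp_path / "decisions.csv", "w") as fh:
        fh.write("record_id,senior_decision\na,include\n")
    with pytest.raises(ValidationError, match="second_decision"):
        load_review_dataset(
            tmp_path / "records.csv", tmp_path / "decisions.csv",
            review_type="systematic",
        )
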