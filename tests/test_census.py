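"""Domain/TM parsing, hydropathy prediction, dedupe and architecture calls."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_tm_runs
from srbkit import fixtures as fx
from srbkit.census import (
    DomainHit,
    SequenceRecord,
    TMSegment,
    census_summary,
    classify_architecture,
    dedupe_identical,
    merge_tm_segments,
    predict_tm_hydropathy,
    read_domain_hits,
    read_tm_table,
)


# ---------------------------------------------------------------------------
# parsers
# ---------------------------------------------------------------------------

def test_read_domain_hits_empty():
    assert read_domain_hits(io.StringIO("# only comments\n")) == []


def test_domtblout_round_trip(mixed_proteome, tmp_path):
    _, records, truths, hits = mixed_proteome
    fx.write_domtblout(hits, records, tmp_path / "hits.domtblout")
    back = read_domain_hits(tmp_path / "hits.domtblout")
    assert [(h.seq_id, h.env_start, h.env_end) for h in back] == [
        (h.seq_id, h.env_start, h.env_end) for h in hits
    ]
    assert all(h.included for h in back)


def test_malformed_row_names_line_number():
    text = "# header\nseqA - 100 CD36 x 350 1e-5 50 0 1 1 1e-5 1e-5 50 0 1 350 5 90 90 5 0.9 d\n"
    with pytest.raises(ValueError, match="line 2"):
        read_domain_hits(io.StringIO(text))


def test_unknown_dialect():
    with pytest.raises(ValueError, match="dialect"):
        read_domain_hits(io.StringIO(""), dialect="csv")


def test_tmhmm_round_trip(mixed_proteome, tmp_path):
    _, _, truths, _ = mixed_proteome
    fx.write_tmhmm(truths, tmp_path / "tm.tmhmm")
    segs = read_tm_table(tmp_path / "tm.tmhmm")
    expected = sorted(
        (sid, s, e) for sid, t in truths.items() for s, e in t.tm_spans
    )
    assert sorted((s.seq_id, s.start, s.end) for s in segs) == expected


# ---------------------------------------------------------------------------
# hydropathy
# ---------------------------------------------------------------------------

def test_hydropathy_poly_ile_flanked_by_asp():
    seq = SequenceRecord("s", "t", "D" * 30 + "I" * 30 + "D" * 30)
    segs = predict_tm_hydropathy(seq)
    assert len(segs) == 1
    (seg,) = segs
    # segment covers the hydrophobic run to within 3 residues each side
    assert abs(seg.start - 31) <= 3 and abs(seg.end - 60) <= 3


def test_hydropathy_hydrophilic_sequence_empty():
    seq = SequenceRecord("s", "t", "D" * 80)
    assert predict_tm_hydropathy(seq) == []


def test_hydropathy_short_sequence_empty():
    assert predict_tm_hydropathy(SequenceRecord("s", "t", "I" * 10)) == []


def test_hydropathy_fixture_srb_two_segments(mixed_proteome):
    _, records, truths, _ = mixed_proteome
    srbs = [r for r in records if truths[r.id].label == "SR-B"]
    for rec in srbs:
        segs = predict_tm_hydropathy(rec)
        spans = truths[rec.id].tm_spans
        assert len(segs) == 2
        for seg, (s, e) in zip(segs, spans):
            assert seg.start <= e and seg.end >= s  # overlaps the true TM


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_hydropathy_agrees_with_brute_force(seed):
    rng = np.random.default_rng(seed)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(rng.choice(list(letters), size=int(rng.integers(19, 200))))
    runs = [
        (s.start, s.end)
        for s in predict_tm_hydropathy(SequenceRecord("s", "t", seq))
    ]
    oracle = []
    for a, b in brute_force_tm_runs(seq):
        if b - a + 1 < 12:
            continue
        oracle.append((a, b))
    # package applies the >40 trim on top of the oracle's raw runs
    for (a, b), (oa, ob) in zip(runs, [r for r in oracle]):
        assert oa <= a <= b <= ob
    assert len(runs) == len(oracle)


# ---------------------------------------------------------------------------
# dedupe
# ---------------------------------------------------------------------------

def test_dedupe_keeps_smallest_id():
    recs = [SequenceRecord("B", "t1", "ACDE"), SequenceRecord("A", "t1", "ACDE")]
    out = dedupe_identical(recs)
    assert [r.id for r in out] == ["A"]


def test_dedupe_cross_taxon_duplicates_retained():
    recs = [SequenceRecord("a", "t1", "ACDE"), SequenceRecord("b", "t2", "ACDE")]
    assert len(dedupe_identical(recs)) == 2


def test_dedupe_unique_untouched(mixed_proteome):
    _, records, _, _ = mixed_proteome
    assert dedupe_identical(records) == list(records)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.sampled_from("abcdef"), st.sampled_from(["t1", "t2"]),
                  st.sampled_from(["ACD", "ACE", "GHK"])),
        max_size=12,
    )
)
def test_dedupe_idempotent(raw):
    recs = [SequenceRecord(f"{i}_{rid}", tax, s) for i, (rid, tax, s) in enumerate(raw)]
    once = dedupe_identical(recs)
    assert dedupe_identical(once) == once


# ---------------------------------------------------------------------------
# architecture classification
# ---------------------------------------------------------------------------

def _classify_all(records, truths, hits):
    hits_by = {}
    for h in hits:
        hits_by.setdefault(h.seq_id, []).append(h)
    tms = [
        TMSegment(sid, s, e)
        for sid, t in truths.items()
        for s, e in t.tm_spans
    ]
    tms_by = {}
    for t in tms:
        tms_by.setdefault(t.seq_id, []).append(t)
    return [
        classify_architecture(r, hits_by.get(r.id, []), tms_by.get(r.id, []))
        for r in records
    ]


def test_classifier_matches_truth_and_spans(mixed_proteome):
    _, records, truths, hits = mixed_proteome
    calls = _classify_all(records, truths, hits)
    for rec, call in zip(records, calls):
        t = truths[rec.id]
        assert call.label == t.label, rec.id
        if call.label == "SR-B":
            assert call.ecto_span == t.ecto_span


def test_cd36_hit_without_tms_is_no_tm():
    seq = SequenceRecord("s", "t", "A" * 200)
    hit = DomainHit("s", "CD36", 20, 180, 100.0, 1e-30, True)
    call = classify_architecture(seq, [hit], [])
    assert call.label == "cd36_no_tm"
    assert call.ecto_span is None


def test_excluded_hit_is_non_cd36():
    seq = SequenceRecord("s", "t", "A" * 200)
    hit = DomainHit("s", "CD36", 20, 180, 10.0, 5.0, False)
    assert classify_architecture(seq, [hit], []).label == "non_cd36"


def test_hit_for_unknown_sequence_raises():
    seq = SequenceRecord("s", "t", "A" * 50)
    hit = DomainHit("other", "CD36", 5, 40, 10.0, 1e-5, True)
    with pytest.raises(ValueError, match="unknown seq_id"):
        classify_architecture(seq, [hit], [])


def test_merge_tm_segments_overlaps():
    segs = [TMSegment("s", 10, 30), TMSegment("s", 25, 45), TMSegment("s", 60, 80)]
    merged = merge_tm_segments(segs)
    assert [(t.start, t.end) for t in merged] == [(10, 45), (60, 80)]


def test_srb_count_never_exceeds_cd36_count(mixed_proteome):
    _, records, truths, hits = mixed_proteome
    calls = _classify_all(records, truths, hits)
    n_srb = sum(c.label == "SR-B" for c in calls)
    n_cd36 = sum(c.label != "non_cd36" for c in calls)
    assert n_srb <= n_cd36


def test_census_summary_counts(mixed_proteome):
    _, records, truths, hits = mixed_proteome
    calls = _classify_all(records, truths, hits)
    taxon_of = {r.id: r.taxon for r in records}
    clade_of = {t: "cladeA" for t in {r.taxon for r in records}}
    table = census_summary(calls, taxon_of, clade_of)
    assert int(table["n_srb"].sum()) == sum(c.label == "SR-B" for c in calls)
    assert int(table["n_cd36_hits"].sum()) == sum(c.label != "non_cd36" for c in calls)


def test_census_summary_unmapped_taxon():
    call = classify_architecture(SequenceRecord("s", "tX", "A" * 50), [], [])
    with pytest.raises(ValueError, match="unmapped taxon"):
        census_summary([call], {"s": "tX"}, {})


def test_census_summary_empty():
    assert census_summary([], {}, {}).empty
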