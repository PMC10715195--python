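"""Alignment coordinate maps, filtering, consensus, identity and bridge calls."""

import io

import numpy as np
import pytest

from oracles import brute_force_mean_identity
from srbkit import fixtures as fx
from srbkit.msa import (
    Alignment,
    conservation,
    conservation_mask,
    consensus,
    detect_expansion_columns,
    gap_filter,
    map_bridge_cysteines,
    mean_pairwise_identity,
    read_alignment,
)


def test_read_alignment_and_column_maps():
    aln = read_alignment(io.StringIO(">r1\nAC-\n>r2\nA-C\n"))
    assert aln.n_cols == 3
    assert aln.col_to_pos("r2", 2) is None
    assert aln.col_to_pos("r1", 2) == 2
    assert aln.pos_to_col("r2", 2) == 3


def test_read_alignment_ragged_and_empty():
    with pytest.raises(ValueError, match="r2"):
        Alignment([("r1", "ACDE"), ("r2", "AC")])
    with pytest.raises(ValueError):
        read_alignment(io.StringIO(""))


def test_column_maps_are_bijective(gold_family):
    _, aln, _ = gold_family
    for rid in aln.ids:
        seq = aln.ungapped(rid)
        for pos in range(1, len(seq) + 1):
            col = aln.pos_to_col(rid, pos)
            assert aln.col_to_pos(rid, col) == pos


def test_gold_alignment_round_trip(gold_family, tmp_path):
    from srbkit.msa import write_alignment

    _, aln, _ = gold_family
    write_alignment(aln, tmp_path / "fam.afa")
    back = read_alignment(tmp_path / "fam.afa")
    assert back.rows == aln.rows


def test_gap_filter_identity_on_ungapped():
    aln = Alignment([("a", "ACDE"), ("b", "ACDF")])
    out, kept = gap_filter(aln)
    assert kept == [1, 2, 3, 4]
    assert out.rows == aln.rows


def test_gap_filter_removes_mostly_gapped_column():
    rows = [(f"r{i}", "A-C" if i else "AAC") for i in range(10)]
    out, kept = gap_filter(Alignment(rows), max_gap_frac=0.8)
    assert kept == [1, 3]  # middle column is gapped in 9/10 rows


def test_gap_filter_drops_lineage_insertion(gold_family):
    config, aln, truth = gold_family
    out, kept = gap_filter(aln, max_gap_frac=0.8)
    start, end = truth.expansion_columns["row3"]
    removed = set(range(start, end + 1))
    assert removed.isdisjoint(kept)
    assert len(kept) == aln.n_cols - 25
    # lift-back: kept columns preserve original coordinates
    for new_c, old_c in enumerate(kept, start=1):
        assert out.row("row0")[new_c - 1] == aln.row("row0")[old_c - 1]


def test_consensus_identical_rows():
    aln = Alignment([(f"r{i}", "ACDEF") for i in range(5)])
    assert consensus(aln) == "ACDEF"


def test_consensus_occupancy_and_mode():
    aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "-")])
    assert consensus(aln) == "A"  # occupancy 0.75, mode A
    sparse = Alignment([("a", "A"), ("b", "A")] + [(f"g{i}", "-") for i in range(8)])
    assert consensus(sparse) == ""  # occupancy 0.2 < 0.5


def test_conservation_values():
    aln = Alignment([("a", "AA-"), ("b", "AC-"), ("c", "AC-"), ("d", "AC-")])
    vals = conservation(aln)
    assert vals[0] == 1.0
    assert vals[1] == 0.75
    assert vals[2] == 0.0


def test_conservation_forty_percent_mask():
    rows = [(f"r{i}", "A") for i in range(4)] + [(f"s{i}", "CDEGHK"[i]) for i in range(6)]
    aln = Alignment([(rid, s[0]) for rid, s in rows])
    assert conservation(aln)[0] == pytest.approx(0.4)
    assert conservation_mask(aln, 0.40)[0]


def test_identity_examples():
    assert mean_pairwise_identity(Alignment([("a", "ACDE"), ("b", "ACDE")])) == 1.0
    assert mean_pairwise_identity(Alignment([("a", "AAAA"), ("b", "AATT")])) == 0.5
    with pytest.raises(ValueError):
        mean_pairwise_identity(Alignment([("a", "AC")]))


def test_identity_matches_brute_force_and_random_expectation():
    rng = np.random.default_rng(0)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    rows = [(f"r{i}", "".join(rng.choice(letters, size=200))) for i in range(20)]
    aln = Alignment(rows)
    ours = mean_pairwise_identity(aln)
    oracle = brute_force_mean_identity([s for _, s in rows])
    assert ours == pytest.approx(oracle, abs=1e-12)
    assert ours == pytest.approx(0.05, abs=0.01)  # binomial expectation 1/20


def test_detect_expansion_columns_planted(gold_family):
    _, aln, truth = gold_family
    found = detect_expansion_columns(aln, "row0", min_run=10)
    start, end = truth.expansion_columns["row3"]
    assert found["row3"].runs == ((start, end, 25),)
    before, after = found["row3"].anchors[0]
    assert (before, after) == (59, 60)  # insertion planted before ancestor position 60
    assert all(not v.runs for rid, v in found.items() if rid != "row3")


def test_detect_expansion_min_run_threshold():
    config = fx.GoldAlignmentConfig(n_rows=4, ancestor_len=60, insertions={2: (30, 8)},
                                    seed=5)
    aln, _ = fx.gen_gold_alignment(config)
    found = detect_expansion_columns(aln, "row0", min_run=10)
    assert all(not v.runs for v in found.values())


def test_detect_expansion_unknown_ref():
    aln = Alignment([("a", "AC"), ("b", "AC")])
    with pytest.raises(ValueError, match="zzz"):
        detect_expansion_columns(aln, "zzz")


# ---------------------------------------------------------------------------
# bridge cysteines
# ---------------------------------------------------------------------------

def test_bridge_pairs_present_in_all_rows(gold_family):
    config, aln, _ = gold_family
    calls = map_bridge_cysteines(aln, "row0", config.cys_pairs)
    assert calls and all(c.status == "present" for c in calls)
    for c in calls:
        qa, qb = c.query_positions
        row_seq = aln.ungapped(c.seq_id)
        assert row_seq[qa - 1] == "C" and row_seq[qb - 1] == "C"


def test_bridge_non_cysteine_reference_raises(gold_family):
    _, aln, _ = gold_family
    with pytest.raises(ValueError, match="not a cysteine"):
        map_bridge_cysteines(aln, "row0", [(1, 2)])


def test_bridge_absent_when_cysteines_missing():
    config = fx.GoldAlignmentConfig(n_rows=4, ancestor_len=80, cys_pairs=((20, 60),),
                                    cys_dropout_rows=(1, 2, 3), seed=6)
    aln, _ = fx.gen_gold_alignment(config)
    calls = map_bridge_cysteines(aln, "row0", [(20, 60)])
    assert all(c.status == "absent" for c in calls)


def test_bridge_expansion_cysteines_excluded_as_false_positive():
    """Cysteines matched inside a lineage-specific insertion are excluded."""
    config = fx.GoldAlignmentConfig(
        n_rows=4, ancestor_len=100,
        insertions={2: (40, 20)},
        insertion_seqs={2: "S" * 18 + "CC"},
        cys_pairs=((40, 41),),
        cys_dropout_rows=(2,),
        seed=7,
    )
    aln, _ = fx.gen_gold_alignment(config)
    expansions = detect_expansion_columns(aln, "row0", min_run=10)
    calls = map_bridge_cysteines(aln, "row0", [(40, 41)], expansions=expansions)
    by_row = {c.seq_id: c.status for c in calls}
    assert by_row["row2"] == "excluded_expansion"
    assert by_row["row1"] == "present"
    assert by_row["row3"] == "present"
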