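"""Kabsch geometry, iterative superposition, binning and expansion segments."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from oracles import horn_superpose
from srbkit import fixtures as fx
from srbkit.structcomp import (
    Residue,
    Structure,
    bin_residue_pairs,
    classify_plddt,
    detect_structural_expansions,
    filter_by_ptm,
    global_rmsd,
    kabsch,
    matching_objective,
    monotone_match,
    read_structure,
    superpose_iterative,
    write_structure,
)


def _rand_points(rng, n):
    return rng.normal(0, 10, (n, 3))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def test_pdb_round_trip_helix(tmp_path):
    spec = fx.StructureSpec(n_strands=0, strand_len=0, apex_helices=((50, (0, 0, 1)),))
    st_, _ = fx.gen_synthetic_structure(spec, structure_id="helix", confidence=75.0,
                                        ptm=0.88)
    path = tmp_path / "helix.pdb"
    write_structure(st_, path)
    back = read_structure(path)
    assert len(back) == 50
    assert back.sequence == st_.sequence
    assert np.abs(back.ca - st_.ca).max() < 2e-3  # PDB has 3 decimals
    assert np.all(back.confidence == 75.0)
    assert back.ptm == pytest.approx(0.88)


def test_read_structure_empty_stream():
    with pytest.raises(ValueError, match="empty"):
        read_structure(io.StringIO(""))


def test_classify_plddt_bounds():
    st_ = Structure("s", [Residue(i, "A", {"CA": np.zeros(3)}) for i in range(1, 4)],
                    confidence=np.array([95.0, 70.0, 10.0]))
    assert classify_plddt(st_) == ["high", "moderate", "low"]
    st_none = Structure("s", [Residue(1, "A", {"CA": np.zeros(3)})], confidence=None)
    with pytest.raises(ValueError, match="confidence"):
        classify_plddt(st_none)


def test_ptm_gate():
    def mk(pid, ptm):
        return Structure(pid, [Residue(1, "A", {"CA": np.zeros(3)})], ptm=ptm)

    kept, skipped = filter_by_ptm([mk("a", 0.9), mk("b", 0.5), mk("c", None)])
    assert [s.id for s in kept] == ["a", "c"]
    assert skipped == ["b"]


# ---------------------------------------------------------------------------
# Kabsch
# ---------------------------------------------------------------------------

def test_kabsch_identity_on_self():
    pts = _rand_points(np.random.default_rng(0), 30)
    rot, trans, rmsd = kabsch(pts, pts)
    assert rmsd < 1e-10
    assert np.allclose(rot, np.eye(3), atol=1e-9)
    assert np.allclose(trans, 0, atol=1e-9)


def test_kabsch_recovers_exact_rigid_motion():
    pts = _rand_points(np.random.default_rng(1), 40)
    r90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = pts @ r90.T + np.array([5.0, -3.0, 12.0])
    rot, trans, rmsd = kabsch(pts, moved)
    assert rmsd < 1e-10
    assert np.allclose(moved @ rot.T + trans, pts, atol=1e-8)


def test_kabsch_agrees_with_quaternion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(10, 201))
        ref, mov = _rand_points(rng, n), _rand_points(rng, n)
        _, _, rmsd = kabsch(ref, mov)
        _, rmsd_horn = horn_superpose(ref, mov)
        assert abs(rmsd - rmsd_horn) < 1e-8


def test_kabsch_rejects_degenerate_inputs():
    line = np.outer(np.arange(10.0), np.array([1.0, 0.0, 0.0]))
    with pytest.raises(ValueError, match="degenerate"):
        kabsch(line, line)
    with pytest.raises(ValueError, match="3 points"):
        kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_kabsch_rmsd_invariant_under_rigid_pretransform(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 50))
    ref, mov = _rand_points(rng, n), _rand_points(rng, n)
    _, _, rmsd = kabsch(ref, mov)
    rot = Rotation.random(random_state=int(rng.integers(0, 2**31))).as_matrix()
    mov2 = mov @ rot.T + rng.normal(0, 5, 3)
    _, _, rmsd2 = kabsch(ref, mov2)
    assert rmsd == pytest.approx(rmsd2, abs=1e-8)


# ---------------------------------------------------------------------------
# monotone matching
# ---------------------------------------------------------------------------

def test_monotone_match_prefers_low_distance():
    dist = np.array([[0.1, 9.0], [9.0, 0.2]])
    assert monotone_match(dist, 5.0) == [(0, 0), (1, 1)]


def test_monotone_match_respects_cutoff():
    dist = np.full((3, 3), 10.0)
    np.fill_diagonal(dist, 1.0)
    dist[2, 2] = 10.0
    assert monotone_match(dist, 5.0) == [(0, 0), (1, 1)]


def test_monotone_match_strictly_increasing():
    rng = np.random.default_rng(3)
    dist = rng.uniform(0, 10, (30, 40))
    pairs = monotone_match(dist, 5.0)
    assert all(a2 > a1 and b2 > b1 for (a1, b1), (a2, b2) in zip(pairs, pairs[1:]))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_repairing_never_worsens_objective(seed):
    """At fixed transform the DP matching is at least as good (count, -sum) as
    any previous matching — here the naive diagonal one."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 30))
    dist = rng.uniform(0, 8, (n, n))
    prev = [(i, i) for i in range(n) if dist[i, i] <= 5.0]
    new = monotone_match(dist, 5.0)
    c_prev, s_prev = matching_objective(dist, prev)
    c_new, s_new = matching_objective(dist, new)
    assert (c_new, -s_new) >= (c_prev, -s_prev)


# ---------------------------------------------------------------------------
# iterative superposition
# ---------------------------------------------------------------------------

def test_superpose_exact_copy_all_paired(structure_pair):
    ref, _, _ = structure_pair
    res = superpose_iterative(ref, ref)
    assert len(res.pairs) == len(ref)
    assert all(d < 1e-6 for _, _, d in res.pairs)
    assert res.unaligned_ref == [] and res.unaligned_query == []
    assert res.rmsd_ca < 1e-6
    assert res.converged


def test_superpose_recovers_truth_pairs_under_rigid_transform():
    spec = fx.StructureSpec()
    ref, query, (s, e) = fx.make_structure_pair(spec, 20, seed=17, query_noise=0.0)
    res = superpose_iterative(ref, query)
    truth_pairs = [(i, i if i < s - 1 else i + (e - s + 1)) for i in range(len(ref))]
    assert [(a, b) for a, b, _ in res.pairs] == truth_pairs
    assert res.rmsd_ca < 1e-6


def test_superpose_detects_planted_insertion(structure_pair):
    ref, query, (s, e) = structure_pair
    res = superpose_iterative(ref, query)
    segs = detect_structural_expansions(res, min_run=10, n_query=len(query))
    assert len(segs) == 1
    seg = segs[0]
    assert abs(seg.start - s) <= 2 and abs(seg.end - e) <= 2
    assert not seg.terminal
    # core pairs fit tightly (sigma*sqrt(3) expectation at sigma = 0.3)
    assert res.rmsd_ca < 0.7
    # rotation stays proper through the iterations
    assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_superpose_unknown_seed_mode(structure_pair):
    ref, query, _ = structure_pair
    with pytest.raises(ValueError, match="seed"):
        superpose_iterative(ref, query, seed="random")


def test_short_insertion_below_min_run_not_reported():
    spec = fx.StructureSpec()
    ref, query, _ = fx.make_structure_pair(spec, 6, seed=19, query_noise=0.1)
    res = superpose_iterative(ref, query)
    assert detect_structural_expansions(res, min_run=10, n_query=len(query)) == []


# ---------------------------------------------------------------------------
# bins and RMSD scopes
# ---------------------------------------------------------------------------

def test_bins_match_resolution_categories():
    assert bin_residue_pairs([0.2, 2.0, 5.0]) == ["high", "medium", "low"]
    # boundary membership: the middle interval is closed
    assert bin_residue_pairs([1.5, 2.7]) == ["medium", "medium"]
    with pytest.raises(ValueError):
        bin_residue_pairs([-0.1])


def test_bin_counts_partition_pairs(structure_pair):
    ref, query, _ = structure_pair
    res = superpose_iterative(ref, query)
    counts = {b: res.bins.count(b) for b in ("high", "medium", "low")}
    assert sum(counts.values()) == len(res.pairs)


def test_global_rmsd_identical_structures(structure_pair):
    ref, _, _ = structure_pair
    res = superpose_iterative(ref, ref)
    assert global_rmsd(res, ref, ref, scope="calpha") < 1e-6
    assert global_rmsd(res, ref, ref, scope="all_atom") < 1e-6


def test_global_rmsd_single_pair_distance():
    from srbkit.structcomp import SuperpositionResult

    r = SuperpositionResult("r", "q", np.eye(3), np.zeros(3),
                            pairs=[(0, 0, 2.0)], rmsd_ca=2.0, bins=["medium"],
                            unaligned_ref=[], unaligned_query=[], converged=True,
                            n_iter=1)
    assert global_rmsd(r, scope="calpha") == pytest.approx(2.0)


def test_noisy_pair_rmsd_follows_sigma_sqrt3():
    """One-sided per-coordinate noise sigma gives cα RMSD ≈ sigma*sqrt(3)."""
    spec = fx.StructureSpec()
    sigma = 0.3
    rmsds = []
    for k in range(50):
        ref, query, _ = fx.make_structure_pair(spec, 15, seed=100 + k,
                                               query_noise=sigma)
        res = superpose_iterative(ref, query)
        rmsds.append(res.rmsd_ca)
    mean = float(np.mean(rmsds))
    assert mean == pytest.approx(sigma * math.sqrt(3), rel=0.2)
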