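"""Synthetic proteomes, gold alignments and idealized structures.

Every downstream stage of the package is testable without external data
because the generators here plant their own ground truth: SR-B-like
sequences with a hydrophilic-by-construction ectodomain between two strongly
hydrophobic TM helices (so architecture labels and the hydropathy predictor
cannot disagree), decoys that each violate exactly one architecture
condition, constructively built alignments with exact insertion and cysteine
columns, and cα-trace structures (ideal helices, cylinder-wall barrel
strands) with planted apex insertions, rigid transforms and Gaussian noise.

Generators are deterministic: identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .census import DomainHit, SequenceRecord, TMSegment
from .msa import Alignment
from .structcomp import Residue, Structure

# Residues used for tails/ectodomains: every Kyte-Doolittle value <= -0.4, so
# no 19-residue window can approach the TM detection cutoff by construction.
HYDROPHILIC_AA = "DEGHKNPQRSTY"
# TM helices come from the strongly hydrophobic set; A is allowed but rare so
# that window means stay far above the cutoff.
TM_AA = "ILVF"
TM_LEN = 21

DECOY_CLASSES = ("no_tm", "single_tm", "fused", "non_cd36")


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for a synthetic CD36-domain proteome."""

    n_taxa: int = 3
    seqs_per_taxon: int = 4
    ecto_len_range: tuple[int, int] = (380, 480)
    expansion_len: int = 0
    expansion_anchor: int = 200  # 1-based ectodomain position
    expansion_fraction: float = 1.0  # fraction of SR-Bs receiving the expansion
    motif_specs: tuple[tuple[str, str, int], ...] = ()  # (motif id, consensus, ecto pos)
    cys_pairs: tuple[tuple[int, int], ...] = ()  # ectodomain positions
    decoy_mix: Mapping[str, float] = field(default_factory=dict)
    fused_tail_len: int = 800
    seed: int = 0

    def __post_init__(self):
        if self.ecto_len_range[0] < 50:
            raise ValueError("ecto_len_range min must be >= 50")
        if self.expansion_len and not (1 <= self.expansion_anchor <= self.ecto_len_range[0]):
            raise ValueError("expansion_anchor must lie inside the ectodomain")
        bad = set(self.decoy_mix) - set(DECOY_CLASSES)
        if bad:
            raise ValueError(f"unknown decoy classes {sorted(bad)}")
        if sum(self.decoy_mix.values()) > 1 + 1e-9:
            raise ValueError("decoy fractions must sum to <= 1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one synthetic entity; spans 1-based inclusive."""

    seq_id: str
    taxon: str
    label: str  # SR-B | cd36_no_tm | cd36_partial_tm | fused_suspect | non_cd36
    ecto_span: tuple[int, int] | None = None
    expansion_span: tuple[int, int] | None = None
    cys_positions: tuple[int, ...] = ()
    motif_positions: tuple[tuple[str, int], ...] = ()
    tm_spans: tuple[tuple[int, int], ...] = ()


def _rand_seq(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _rand_tm(rng: np.random.Generator) -> str:
    # mostly I/L/V/F with a sprinkling of alanine
    letters = list(TM_AA)
    out = [letters[i] for i in rng.integers(0, len(letters), TM_LEN)]
    if rng.random() < 0.5:
        out[int(rng.integers(0, TM_LEN))] = "A"
    return "".join(out)


def _build_ectodomain(
    rng: np.random.Generator, config: FixtureConfig, expanded: bool
) -> tuple[str, dict]:
    """Base ectodomain with planted motifs/cysteines and optional expansion.

    Returns (sequence, info) where info carries ectodomain-local coordinates:
    motif positions, cysteine positions and the expansion span (or None).
    """
    base_len = int(rng.integers(config.ecto_len_range[0], config.ecto_len_range[1] + 1))
    ecto = list(_rand_seq(rng, HYDROPHILIC_AA, base_len))
    for motif_id, consensus, pos in config.motif_specs:
        if pos < 1 or pos + len(consensus) - 1 > base_len:
            raise ValueError(
                f"infeasible planting: motif {motif_id} at {pos} leaves the ectodomain"
            )
        ecto[pos - 1 : pos - 1 + len(consensus)] = list(consensus)
    for p1, p2 in config.cys_pairs:
        for p in (p1, p2):
            if not (1 <= p <= base_len):
                raise ValueError(f"infeasible planting: cysteine at {p} outside ectodomain")
            ecto[p - 1] = "C"
    motif_positions = {m: pos for m, _, pos in config.motif_specs}
    cys_positions = [p for pair in config.cys_pairs for p in pair]
    expansion_span = None
    if expanded and config.expansion_len > 0:
        anchor = config.expansion_anchor
        ins = _rand_seq(rng, HYDROPHILIC_AA, config.expansion_len)
        ecto[anchor - 1 : anchor - 1] = list(ins)
        expansion_span = (anchor, anchor + config.expansion_len - 1)
        motif_positions = {
            m: (p + config.expansion_len if p >= anchor else p)
            for m, p in motif_positions.items()
        }
        cys_positions = [
            p + config.expansion_len if p >= anchor else p for p in cys_positions
        ]
    info = {
        "motifs": motif_positions,
        "cys": cys_positions,
        "expansion": expansion_span,
    }
    return "".join(ecto), info


def _assemble(
    rng: np.random.Generator,
    config: FixtureConfig,
    seq_id: str,
    taxon: str,
    label: str,
) -> tuple[SequenceRecord, TruthRecord]:
    expanded = label in ("SR-B", "fused") and rng.random() < config.expansion_fraction
    ecto, info = _build_ectodomain(rng, config, expanded)
    if label == "fused":
        n_tail = _rand_seq(rng, HYDROPHILIC_AA, config.fused_tail_len)
    else:
        n_tail = _rand_seq(rng, HYDROPHILIC_AA, int(rng.integers(18, 31)))
    c_tail = _rand_seq(rng, HYDROPHILIC_AA, int(rng.integers(10, 26)))
    tm1, tm2 = _rand_tm(rng), _rand_tm(rng)

    if label == "no_tm":
        parts, tm_spans = [n_tail, ecto, c_tail], []
        ecto_start = len(n_tail) + 1
        final_label = "cd36_no_tm"
    elif label == "single_tm":
        parts = [n_tail, tm1, ecto, c_tail]
        tm_spans = [(len(n_tail) + 1, len(n_tail) + TM_LEN)]
        ecto_start = len(n_tail) + TM_LEN + 1
        final_label = "cd36_partial_tm"
    else:  # SR-B, fused, non_cd36 all share the TM-ecto-TM layout
        parts = [n_tail, tm1, ecto, tm2, c_tail]
        tm1_span = (len(n_tail) + 1, len(n_tail) + TM_LEN)
        ecto_start = tm1_span[1] + 1
        tm2_start = ecto_start + len(ecto)
        tm_spans = [tm1_span, (tm2_start, tm2_start + TM_LEN - 1)]
        final_label = {"SR-B": "SR-B", "fused": "fused_suspect", "non_cd36": "non_cd36"}[label]
    seq = "".join(parts)
    ecto_span = (ecto_start, ecto_start + len(ecto) - 1)
    off = ecto_start - 1
    truth = TruthRecord(
        seq_id=seq_id,
        taxon=taxon,
        label=final_label,
        ecto_span=None if label == "no_tm" else ecto_span,
        expansion_span=(
            None
            if info["expansion"] is None
            else (info["expansion"][0] + off, info["expansion"][1] + off)
        ),
        cys_positions=tuple(p + off for p in info["cys"]),
        motif_positions=tuple((m, p + off) for m, p in sorted(info["motifs"].items())),
        tm_spans=tuple(tm_spans),
    )
    # no_tm decoys still have a real CD36 region; record its span separately
    if label == "no_tm":
        truth = TruthRecord(
            seq_id, taxon, final_label, ecto_span, truth.expansion_span,
            truth.cys_positions, truth.motif_positions, (),
        )
    return SequenceRecord(seq_id, taxon, seq), truth


def gen_synthetic_proteome(
    config: FixtureConfig,
) -> tuple[list[SequenceRecord], dict[str, TruthRecord]]:
    """Generate a labelled proteome of SR-B-like sequences and decoys.

    Each decoy violates exactly one architecture condition (its class), so
    census classification has a well-defined truth.  Decoy counts are
    ``round(fraction * total)`` per class, spread across taxa deterministically.
    """
    rng = np.random.default_rng(config.seed)
    total = config.n_taxa * config.seqs_per_taxon
    labels = []
    for cls in DECOY_CLASSES:
        labels.extend([cls] * int(round(config.decoy_mix.get(cls, 0.0) * total)))
    if len(labels) > total:
        raise ValueError("decoy fractions produce more decoys than sequences")
    labels.extend(["SR-B"] * (total - len(labels)))
    order = rng.permutation(total)
    records, truths = [], {}
    k = 0
    for t in range(config.n_taxa):
        taxon = f"taxon{t + 1:02d}"
        for s in range(config.seqs_per_taxon):
            label = labels[order[k]]
            seq_id = f"{taxon}|seq{s + 1:03d}"
            rec, truth = _assemble(rng, config, seq_id, taxon, label)
            records.append(rec)
            truths[seq_id] = truth
            k += 1
    return records, truths


# ---------------------------------------------------------------------------
# Companion tables
# ---------------------------------------------------------------------------

def domain_hits_for(
    records: Sequence[SequenceRecord],
    truths: Mapping[str, TruthRecord],
    inset: int = 3,
) -> list[DomainHit]:
    """CD36 domain hits implied by the truth (omitted for non_cd36 decoys).

    Envelopes are inset a few residues inside the true CD36 region, the way
    domain envelopes rarely reach the domain's structural edges.
    """
    hits = []
    for rec in records:
        truth = truths[rec.id]
        if truth.label == "non_cd36" or truth.ecto_span is None:
            continue
        s, e = truth.ecto_span
        hits.append(DomainHit(rec.id, "CD36", s + inset, e - inset, 250.0, 1e-50, True))
    return hits


def write_domtblout(
    hits: Sequence[DomainHit], records: Sequence[SequenceRecord], path
) -> None:
    """Write hits in the whitespace-delimited per-domain hmmsearch dialect."""
    lengths = {r.id: r.length for r in records}
    with open(path, "w") as fh:
        fh.write("# synthetic per-domain hit table\n")
        fh.write("#" + " " * 20 + "--- full sequence --- --- this domain ---\n")
        for k, h in enumerate(hits, start=1):
            tlen = lengths.get(h.seq_id, h.env_end)
            fh.write(
                f"{h.seq_id} - {tlen} {h.domain_name} PF01130.21 350 "
                f"{h.e_value:.2g} {h.bit_score:.1f} 0.1 1 1 "
                f"{h.e_value:.2g} {h.e_value:.2g} {h.bit_score:.1f} 0.1 "
                f"1 350 {h.env_start} {h.env_end} {h.env_start} {h.env_end} "
                f"0.98 synthetic\n"
            )


def write_tmhmm(truths: Mapping[str, TruthRecord], path) -> None:
    """Write truth TM spans in the TMHMM short-output dialect."""
    with open(path, "w") as fh:
        for sid in sorted(truths):
            for s, e in truths[sid].tm_spans:
                fh.write(f"{sid}\tTMHMM2.0\tTMhelix\t{s}\t{e}\n")


def write_truth_tsv(truths: Mapping[str, TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\ttaxon\tlabel\tecto_start\tecto_end\texp_start\texp_end\t"
            "cys_positions\ttm_spans\n"
        )
        for sid in sorted(truths):
            t = truths[sid]
            es, ee = t.ecto_span if t.ecto_span else ("", "")
            xs, xe = t.expansion_span if t.expansion_span else ("", "")
            cys = ",".join(str(p) for p in t.cys_positions)
            tms = ";".join(f"{a}-{b}" for a, b in t.tm_spans)
            fh.write(f"{sid}\t{t.taxon}\t{t.label}\t{es}\t{ee}\t{xs}\t{xe}\t{cys}\t{tms}\n")


# ---------------------------------------------------------------------------
# Gold alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldAlignmentConfig:
    """A family derived from one ancestor with per-lineage insertions."""

    n_rows: int = 6
    ancestor_len: int = 120
    sub_rate: float = 0.05
    insertions: Mapping[int, tuple[int, int]] = field(default_factory=dict)  # row -> (pos, len)
    insertion_seqs: Mapping[int, str] = field(default_factory=dict)  # row -> explicit residues
    cys_pairs: tuple[tuple[int, int], ...] = ()
    cys_dropout_rows: tuple[int, ...] = ()  # rows whose ancestral cysteines are mutated away
    seed: int = 0


@dataclass(frozen=True)
class GoldAlignmentTruth:
    cys_columns: tuple[int, ...]  # alignment columns of ancestral cysteines (1-based)
    expansion_columns: Mapping[str, tuple[int, int]]  # row id -> (start col, end col)
    ancestor_positions: tuple[int, ...]  # alignment column of each ancestor position


def gen_gold_alignment(config: GoldAlignmentConfig) -> tuple[Alignment, GoldAlignmentTruth]:
    """Build an alignment constructively: ancestor columns + per-lineage gap blocks.

    Row 0 is the unmutated ancestor (a natural reference row).  Substitutions
    never touch cysteine-pair positions (except in dropout rows, where the
    ancestral cysteines become serines) and never create new cysteines.
    """
    rng = np.random.default_rng(config.seed)
    l = config.ancestor_len
    ancestor = list(_rand_seq(rng, HYDROPHILIC_AA, l))
    cys_pos = sorted({p for pair in config.cys_pairs for p in pair})
    for p in cys_pos:
        if not (1 <= p <= l):
            raise ValueError(f"cysteine position {p} outside ancestor")
        ancestor[p - 1] = "C"
    row_ids = [f"row{r}" for r in range(config.n_rows)]
    # ungapped row sequences (pre-insertion)
    base_rows = []
    for r in range(config.n_rows):
        if r == 0:
            base_rows.append(list(ancestor))
            continue
        row = list(ancestor)
        for p in range(1, l + 1):
            if p in cys_pos:
                if r in config.cys_dropout_rows:
                    row[p - 1] = "S"
                continue
            if rng.random() < config.sub_rate:
                choices = [a for a in HYDROPHILIC_AA if a != row[p - 1]]
                row[p - 1] = choices[int(rng.integers(0, len(choices)))]
        base_rows.append(row)
    insertion_payload: dict[int, str] = {}
    for r, (pos, ln) in config.insertions.items():
        if not (1 <= pos <= l + 1):
            raise ValueError(f"insertion position {pos} outside ancestor+1")
        payload = config.insertion_seqs.get(r) or _rand_seq(rng, HYDROPHILIC_AA, ln)
        if len(payload) != ln:
            raise ValueError(f"row {r}: insertion_seqs length != declared length")
        insertion_payload[r] = payload
    # column layout: ancestor positions 1..L with insertion blocks (before pos),
    # blocks ordered by (pos, row)
    events = sorted(config.insertions.items(), key=lambda kv: (kv[1][0], kv[0]))
    gapped = [[] for _ in range(config.n_rows)]
    col = 0
    ancestor_cols = []
    expansion_cols: dict[str, tuple[int, int]] = {}

    def emit_block(row: int, payload: str):
        nonlocal col
        start = col + 1
        for ch in payload:
            col += 1
            for rr in range(config.n_rows):
                gapped[rr].append(ch if rr == row else "-")
        expansion_cols[row_ids[row]] = (start, col)

    ev_idx = 0
    for p in range(1, l + 2):
        while ev_idx < len(events) and events[ev_idx][1][0] == p:
            row, _ = events[ev_idx][0], events[ev_idx][1]
            emit_block(row, insertion_payload[row])
            ev_idx += 1
        if p <= l:
            col += 1
            ancestor_cols.append(col)
            for rr in range(config.n_rows):
                gapped[rr].append(base_rows[rr][p - 1])
    aln = Alignment([(rid, "".join(chars)) for rid, chars in zip(row_ids, gapped)])
    truth = GoldAlignmentTruth(
        cys_columns=tuple(ancestor_cols[p - 1] for p in cys_pos),
        expansion_columns=expansion_cols,
        ancestor_positions=tuple(ancestor_cols),
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Idealized structures
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å
STRAND_RISE = 3.8  # Å per residue along the strand axis


@dataclass(frozen=True)
class StructureSpec:
    """An idealized beta-barrel core with an apex helix bundle."""

    n_strands: int = 6
    strand_len: int = 14
    barrel_radius: float = 8.0
    apex_helices: tuple[tuple[int, tuple[float, float, float]], ...] = (
        (12, (1.0, 0.0, 0.0)),
        (12, (0.0, 1.0, 0.0)),
        (12, (-1.0, 0.2, 0.0)),
    )
    expansion_helix_len: int = 0
    expansion_at: int | None = None  # insert after this residue (1-based)
    noise_sigma: float = 0.0
    rotation: tuple | None = None  # 3x3 proper rotation
    translation: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def ideal_helix(n: int, axis, start, rng_phase: float = 0.0) -> np.ndarray:
    """Ideal α-helix cα trace (rise 1.5 Å, 100°/residue, radius 2.3 Å)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    t = np.arange(n)
    ang = np.deg2rad(HELIX_TWIST * t + rng_phase)
    pts = (
        np.asarray(start)
        + np.outer(HELIX_RISE * t, u)
        + HELIX_RADIUS * (np.outer(np.cos(ang), v) + np.outer(np.sin(ang), w))
    )
    return pts


def _core_coords(spec: StructureSpec) -> np.ndarray:
    coords = []
    top = (spec.strand_len - 1) * STRAND_RISE
    for s in range(spec.n_strands):
        theta = 2 * math.pi * s / spec.n_strands
        x = spec.barrel_radius * math.cos(theta)
        y = spec.barrel_radius * math.sin(theta)
        zs = np.arange(spec.strand_len) * STRAND_RISE
        if s % 2 == 1:
            zs = zs[::-1]  # serpentine direction
        coords.extend([(x, y, z) for z in zs])
    z0 = top + 5.0
    for k, (length, axis) in enumerate(spec.apex_helices):
        start = np.array([-length * HELIX_RISE / 2.0, (k - 1) * 5.0, z0 + 4.5 * k])
        coords.extend(ideal_helix(length, axis, start))
    return np.array(coords)


def gen_synthetic_structure(
    spec: StructureSpec,
    structure_id: str = "synthetic",
    residue_letters: str | None = None,
    confidence: float | np.ndarray | None = 75.0,
    ptm: float | None = None,
) -> tuple[Structure, tuple[int, int] | None]:
    """Generate a cα-trace structure; returns (structure, insertion range or None).

    The optional expansion helix is inserted into the chain after residue
    ``expansion_at`` (default: after the first apex helix) and placed pointing
    radially away from the core centroid, so it has no spatial counterpart in
    an expansion-free reference.  Noise is isotropic per-coordinate Gaussian;
    the rigid transform is applied last.
    """
    rng = np.random.default_rng(spec.seed)
    core = _core_coords(spec)
    n_core = len(core)
    insertion_range = None
    coords = core
    if spec.expansion_helix_len > 0:
        at = spec.expansion_at
        if at is None:
            at = spec.n_strands * spec.strand_len + spec.apex_helices[0][0]
        if not (1 <= at <= n_core):
            raise ValueError("expansion_at outside the core chain")
        centroid = core.mean(axis=0)
        anchor = core[at - 1]
        direction = anchor - centroid
        direction[2] = abs(direction[2]) + 1.0  # bias upward, away from the barrel
        direction /= np.linalg.norm(direction)
        start = anchor + 9.0 * direction
        ins = ideal_helix(spec.expansion_helix_len, direction, start)
        coords = np.vstack([core[:at], ins, core[at:]])
        insertion_range = (at + 1, at + spec.expansion_helix_len)
    n = len(coords)
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, coords.shape)
    if spec.rotation is not None:
        coords = coords @ np.asarray(spec.rotation, dtype=float).T
    if spec.translation is not None:
        coords = coords + np.asarray(spec.translation, dtype=float)
    if residue_letters is None:
        residue_letters = _rand_seq(rng, "ACDEFGHIKLMNPQRSTVWY", n)
    if len(residue_letters) != n:
        raise ValueError("residue_letters length mismatch")
    if confidence is None:
        conf = None
    elif np.isscalar(confidence):
        conf = np.full(n, float(confidence))
    else:
        conf = np.asarray(confidence, dtype=float)
    residues = [
        Residue(i + 1, residue_letters[i], {"CA": coords[i].copy()}) for i in range(n)
    ]
    return Structure(structure_id, residues, confidence=conf, ptm=ptm), insertion_range


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    rot = Rotation.random(random_state=int(rng.integers(0, 2**31 - 1))).as_matrix()
    trans = rng.uniform(-20.0, 20.0, 3)
    return rot, trans


def make_structure_pair(
    spec: StructureSpec,
    insertion_len: int,
    insertion_at: int | None = None,
    query_noise: float = 0.3,
    seed: int = 0,
    transform_query: bool = True,
) -> tuple[Structure, Structure, tuple[int, int]]:
    """An expansion-free reference and a query with a planted apex insertion.

    Core residue letters are shared between the two structures (they are the
    same protein apart from the insertion); the query carries per-coordinate
    Gaussian noise and, optionally, a random rigid transform.  Returns
    (ref, query, true insertion range in query residue ranks).
    """
    rng = np.random.default_rng(seed)
    core_spec = StructureSpec(
        n_strands=spec.n_strands,
        strand_len=spec.strand_len,
        barrel_radius=spec.barrel_radius,
        apex_helices=spec.apex_helices,
        seed=seed,
    )
    n_core = spec.n_strands * spec.strand_len + sum(l for l, _ in spec.apex_helices)
    core_letters = _rand_seq(rng, "ACDEFGHIKLMNPQRSTVWY", n_core)
    ref, _ = gen_synthetic_structure(core_spec, "reference", residue_letters=core_letters)
    if insertion_at is None:
        insertion_at = spec.n_strands * spec.strand_len + spec.apex_helices[0][0]
    ins_letters = _rand_seq(rng, "ACDEFGHIKLMNPQRSTVWY", insertion_len)
    q_letters = core_letters[:insertion_at] + ins_letters + core_letters[insertion_at:]
    rot, trans = random_rigid_transform(rng) if transform_query else (None, None)
    q_spec = StructureSpec(
        n_strands=spec.n_strands,
        strand_len=spec.strand_len,
        barrel_radius=spec.barrel_radius,
        apex_helices=spec.apex_helices,
        expansion_helix_len=insertion_len,
        expansion_at=insertion_at,
        noise_sigma=query_noise,
        rotation=None if rot is None else tuple(map(tuple, rot)),
        translation=None if trans is None else tuple(trans),
        seed=seed + 1,
    )
    query, ins_range = gen_synthetic_structure(q_spec, "query", residue_letters=q_letters)
    return ref, query, ins_range


# ---------------------------------------------------------------------------
# Cavity test shapes
# ---------------------------------------------------------------------------

def _pseudo_structure(structure_id: str, coords: np.ndarray) -> Structure:
    residues = [
        Residue(i + 1, "A", {"CA": np.asarray(c, dtype=float)}) for i, c in enumerate(coords)
    ]
    return Structure(structure_id, residues, confidence=None)


def gen_cavity_shape(
    shape: str,
    inner_radius: float = 6.0,
    wall_radius: float = 4.4,
    length: float = 24.0,
    spacing: float = 1.2,
    vdw: float = 1.70,
    probe_small: float = 0.9,
) -> tuple[Structure, dict]:
    """Pseudo-atom shapes with analytically known void truth.

    rod: solid cylinder, zero internal void.  tube: open hollow cylinder whose
    lumen admits the small probe but not the bulk probe — a tunnel by
    construction.  shell: closed hollow sphere whose probe-accessible interior
    is a ball of ``inner_radius`` (atom centres sit at inner_radius + vdw +
    probe_small), an enclosed cavity of volume 4/3*pi*r^3.
    """
    if shape == "rod":
        pts = []
        radius = wall_radius
        for z in np.arange(0.0, length + 1e-9, spacing):
            for x in np.arange(-radius, radius + 1e-9, spacing):
                for y in np.arange(-radius, radius + 1e-9, spacing):
                    if x * x + y * y <= radius * radius:
                        pts.append((x, y, z))
        truth = {"void_volume": 0.0, "klass": None}
    elif shape == "tube":
        pts = []
        n_circ = max(8, int(math.ceil(2 * math.pi * wall_radius / spacing)))
        for z in np.arange(0.0, length + 1e-9, spacing):
            for k in range(n_circ):
                a = 2 * math.pi * k / n_circ
                pts.append((wall_radius * math.cos(a), wall_radius * math.sin(a), z))
        truth = {"void_volume": None, "klass": "tunnel"}
    elif shape == "shell":
        r_sphere = inner_radius + vdw + probe_small
        n = max(64, int(math.ceil(4 * math.pi * r_sphere**2 / spacing**2)))
        k = np.arange(n)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * k  # Fibonacci lattice
        z = 1.0 - 2.0 * (k + 0.5) / n
        r_xy = np.sqrt(1.0 - z * z)
        pts = np.column_stack(
            [r_sphere * r_xy * np.cos(phi), r_sphere * r_xy * np.sin(phi), r_sphere * z]
        )
        truth = {"void_volume": 4.0 / 3.0 * math.pi * inner_radius**3, "klass": "cavity"}
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return _pseudo_structure(shape, np.asarray(pts, dtype=float)), truth
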