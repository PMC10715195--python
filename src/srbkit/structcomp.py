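"""Structure comparison: superposition, per-residue RMSD-cα, expansions.

Predicted structures (PDB, per-residue confidence in the B-factor column by
predicted-model convention) are superposed onto a reference with an iterative
scheme: rigid Kabsch fit on the current residue pairing, then re-pairing by a
monotone (chain-order preserving) matching of the most spatially adjacent
cα atoms, repeated to a fixed point.  Per-pair cα distances are binned into
the crystallographic-resolution-style categories high (<1.5 Å), medium
(1.5-2.7 Å) and low (>2.7 Å); residues left without a spatial counterpart
are "unaligned", and long unaligned runs mark lineage-specific expansions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist

from .constants import ONE_TO_THREE, THREE_TO_ONE


@dataclass
class Residue:
    seqid: int
    name: str  # one-letter code ('X' for unknown)
    atoms: dict[str, np.ndarray]

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    confidence: np.ndarray | None = None  # per-residue pLDDT in [0, 100]
    ptm: float | None = None

    def __post_init__(self):
        for r in self.residues:
            if "CA" not in r.atoms:
                raise ValueError(f"{self.id}: residue {r.seqid} has no CA atom")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if len(self.confidence) != len(self.residues):
                raise ValueError("confidence length mismatch")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.residues)

    def to_pdb(self, path) -> None:
        write_structure(self, path)


# ---------------------------------------------------------------------------
# PDB I/O (gemmi-backed)
# ---------------------------------------------------------------------------

def read_structure(
    source, structure_id: str | None = None, chain: str | None = None, predicted: bool = True
) -> Structure:
    """Read PDB ATOM records into a :class:`Structure`.

    ``predicted=True`` stores the B-factor column as per-residue pLDDT.  A
    ``REMARK 300 PTM <v>`` line (our writer's convention; standard PDB has no
    pTM field) populates the model-level pTM.  Duplicate atoms keep the first
    occurrence; a residue without a cα is an error.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        default_id = Path(source).stem
    else:
        text = source.read()
        default_id = "structure"
    if not text.strip():
        raise ValueError("empty PDB stream")
    ptm = None
    for line in text.splitlines():
        if line.startswith("REMARK") and " PTM " in line:
            try:
                ptm = float(line.split()[-1])
            except ValueError:
                pass
    st = gemmi.read_pdb_string(text)
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError("no models/chains in PDB stream")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = next((c for c in model if c.name == chain), None)
        if ch is None:
            raise ValueError(f"chain {chain!r} not found")
    residues: list[Residue] = []
    conf: list[float] = []
    for res in ch:
        atoms: dict[str, np.ndarray] = {}
        b = None
        for atom in res:
            if atom.name in atoms:
                continue  # keep first occurrence of duplicate atoms
            atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if atom.name == "CA":
                b = atom.b_iso
        if "CA" not in atoms:
            raise ValueError(f"residue {res.seqid.num} ({res.name}) has no CA atom")
        residues.append(
            Residue(res.seqid.num, THREE_TO_ONE.get(res.name.upper(), "X"), atoms)
        )
        conf.append(b if b is not None else 0.0)
    residues.sort(key=lambda r: r.seqid)
    return Structure(
        structure_id or default_id,
        residues,
        confidence=np.array(conf) if predicted else None,
        ptm=ptm,
    )


def write_structure(struct: Structure, path) -> None:
    """Write a Structure as PDB via gemmi (B-factor column = pLDDT)."""
    st = gemmi.Structure()
    st.name = struct.id
    model = gemmi.Model("1")
    ch = gemmi.Chain("A")
    conf = struct.confidence
    serial = 1
    for k, res in enumerate(struct.residues):
        r = gemmi.Residue()
        r.name = ONE_TO_THREE.get(res.name, "UNK")
        r.seqid = gemmi.SeqId(res.seqid, " ")
        for name, xyz in res.atoms.items():
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(name[0])
            a.pos = gemmi.Position(*xyz)
            a.occ = 1.0
            a.b_iso = float(conf[k]) if conf is not None else 0.0
            a.serial = serial
            serial += 1
            r.add_atom(a)
        ch.add_residue(r)
    model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    pdb_text = st.make_pdb_string()
    with open(path, "w") as fh:
        if struct.ptm is not None:
            fh.write(f"REMARK 300 PTM {struct.ptm:.3f}\n")
        fh.write(pdb_text)


# ---------------------------------------------------------------------------
# Confidence classes
# ---------------------------------------------------------------------------

def classify_plddt(struct: Structure, bounds: tuple[float, float] = (90.0, 70.0)) -> list[str]:
    """Per-residue confidence classes: high (>= hi), moderate ([lo, hi)), low."""
    if struct.confidence is None:
        raise ValueError(f"{struct.id}: no per-residue confidence present")
    hi, lo = bounds
    out = []
    for v in struct.confidence:
        out.append("high" if v >= hi else ("moderate" if v >= lo else "low"))
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mov`` onto ``ref``.

    Returns (rotation, translation, rmsd) with the convention
    ``mov @ rotation.T + translation ~= ref``.  The rotation is proper
    (determinant +1; reflections corrected).  Requires >= 3 non-collinear
    points.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = ref.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    cr, cm = ref.mean(axis=0), mov.mean(axis=0)
    r0, m0 = ref - cr, mov - cm
    sv_r = np.linalg.svd(r0, compute_uv=False)
    sv_m = np.linalg.svd(m0, compute_uv=False)
    scale = max(sv_r[0], sv_m[0], 1.0)
    if sv_r[1] / scale < 1e-9 or sv_m[1] / scale < 1e-9:
        raise ValueError("degenerate (collinear or coincident) point set")
    h = m0.T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    diff = (mov @ rot.T + trans) - ref
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# Monotone spatial pairing
# ---------------------------------------------------------------------------

_PAIR_BONUS = 1.0e7  # dominates any achievable summed distance


def monotone_match(dist: np.ndarray, d_max: float) -> list[tuple[int, int]]:
    """Chain-order preserving matching maximizing pair count, then minimizing
    summed distance, over pairs with distance <= ``d_max``.

    Dynamic programme over the (n_ref+1, n_query+1) prefix grid; returns
    0-based (ref_index, query_index) pairs strictly increasing in both.
    """
    n, m = dist.shape
    score = np.where(dist <= d_max, _PAIR_BONUS - dist, -np.inf)
    best = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        cand = np.maximum(best[i - 1, 1:], best[i - 1, :-1] + score[i - 1])
        best[i, 1:] = np.maximum.accumulate(cand)
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        b = best[i, j]
        if b == best[i - 1, j]:
            i -= 1
        elif b == best[i, j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs


def matching_objective(dist, pairs) -> tuple[int, float]:
    """(pair count, summed distance) of a matching — DP's lexicographic objective."""
    return len(pairs), float(sum(dist[i, j] for i, j in pairs))


# ---------------------------------------------------------------------------
# Iterative superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    ref_id: str
    query_id: str
    rotation: np.ndarray
    translation: np.ndarray
    pairs: list[tuple[int, int, float]]  # (ref residue idx, query residue idx, cα distance)
    rmsd_ca: float
    bins: list[str]
    unaligned_ref: list[int]
    unaligned_query: list[int]
    converged: bool
    n_iter: int

    def to_json(self, path=None) -> str:
        payload = {
            "ref_id": self.ref_id,
            "query_id": self.query_id,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "n_pairs": len(self.pairs),
            "rmsd_ca": self.rmsd_ca,
            "bin_counts": {b: self.bins.count(b) for b in ("high", "medium", "low")},
            "n_unaligned_ref": len(self.unaligned_ref),
            "n_unaligned_query": len(self.unaligned_query),
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _sequence_seed_pairs(ref: Structure, query: Structure) -> list[tuple[int, int]]:
    """Initial residue pairs from a global sequence alignment (BLOSUM62, affine gaps)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(ref.sequence, query.sequence)[0]
    pairs = []
    for (rs, re_), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend((rs + k, qs + k) for k in range(re_ - rs))
    return pairs


def superpose_iterative(
    ref: Structure,
    query: Structure,
    seed: str = "sequence",
    d_pair: float = 5.0,
    max_iter: int = 20,
    bin_edges: tuple[float, float] = (1.5, 2.7),
) -> SuperpositionResult:
    """Iterative rigid superposition with spatial-adjacency re-pairing.

    Starting from a seed pairing ("sequence": global sequence alignment of
    residue types; "identity": equal residue ranks, for same-length inputs),
    alternate a Kabsch fit on the current pairs with a monotone re-pairing
    that keeps every pair within ``d_pair`` Å, until the pair set repeats or
    ``max_iter`` is reached.
    """
    ref_ca, qry_ca = ref.ca, query.ca
    if seed == "sequence":
        pairs = _sequence_seed_pairs(ref, query)
    elif seed == "identity":
        k = min(len(ref), len(query))
        pairs = [(i, i) for i in range(k)]
    else:
        raise ValueError(f"unknown seed mode {seed!r}")
    if len(pairs) < 3:
        raise ValueError("no usable seed pairs found")
    converged = False
    n_iter = 0
    rot = np.eye(3)
    trans = np.zeros(3)
    for n_iter in range(1, max_iter + 1):
        ri = np.array([p[0] for p in pairs])
        qi = np.array([p[1] for p in pairs])
        rot, trans, _ = kabsch(ref_ca[ri], qry_ca[qi])
        moved = qry_ca @ rot.T + trans
        dist = cdist(ref_ca, moved)
        new_pairs = monotone_match(dist, d_pair)
        if len(new_pairs) < 3:
            new_pairs = pairs  # keep the seed rather than collapse
        if new_pairs == pairs:
            converged = True
            break
        pairs = new_pairs
    # final fit and distances on the converged pair set
    ri = np.array([p[0] for p in pairs])
    qi = np.array([p[1] for p in pairs])
    rot, trans, rmsd = kabsch(ref_ca[ri], qry_ca[qi])
    moved = qry_ca @ rot.T + trans
    dists = np.linalg.norm(ref_ca[ri] - moved[qi], axis=1)
    triples = [(int(a), int(b), float(d)) for (a, b), d in zip(pairs, dists)]
    bins = bin_residue_pairs(dists, edges=bin_edges)
    paired_r = set(ri.tolist())
    paired_q = set(qi.tolist())
    return SuperpositionResult(
        ref_id=ref.id,
        query_id=query.id,
        rotation=rot,
        translation=trans,
        pairs=triples,
        rmsd_ca=rmsd,
        bins=bins,
        unaligned_ref=[i for i in range(len(ref)) if i not in paired_r],
        unaligned_query=[i for i in range(len(query)) if i not in paired_q],
        converged=converged,
        n_iter=n_iter,
    )


def bin_residue_pairs(
    distances: Sequence[float], edges: tuple[float, float] = (1.5, 2.7)
) -> list[str]:
    """Bin per-pair cα distances: high (< lo), medium ([lo, hi]), low (> hi)."""
    lo, hi = edges
    out = []
    for d in distances:
        if d < 0:
            raise ValueError("negative distance")
        out.append("high" if d < lo else ("medium" if d <= hi else "low"))
    return out


# ---------------------------------------------------------------------------
# Expansion segments and RMSD scopes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpansionSegment:
    """A run of unaligned query residues flanked by paired reference anchors."""

    start: int  # 1-based query residue rank
    end: int
    ref_anchor_before: int | None  # 1-based ref residue rank of last pair before
    ref_anchor_after: int | None
    terminal: bool

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def detect_structural_expansions(
    result: SuperpositionResult, min_run: int = 10, n_query: int | None = None
) -> list[ExpansionSegment]:
    """Maximal runs of >= ``min_run`` consecutive unaligned query residues.

    Indices in the returned segments are 1-based residue ranks.  Runs at
    chain termini carry a one-sided anchor and are flagged terminal.
    """
    unal = sorted(result.unaligned_query)
    if not unal:
        return []
    q_to_r = {q: r for r, q, _ in result.pairs}
    max_q = max(
        [n_query - 1 if n_query else -1]
        + [q for _, q, _ in result.pairs]
        + unal
    )
    segments = []
    k = 0
    while k < len(unal):
        j = k
        while j + 1 < len(unal) and unal[j + 1] == unal[j] + 1:
            j += 1
        start, end = unal[k], unal[j]
        if end - start + 1 >= min_run:
            before = next((q_to_r[q] for q in range(start - 1, -1, -1) if q in q_to_r), None)
            after = next((q_to_r[q] for q in range(end + 1, max_q + 1) if q in q_to_r), None)
            segments.append(
                ExpansionSegment(
                    start=start + 1,
                    end=end + 1,
                    ref_anchor_before=None if before is None else before + 1,
                    ref_anchor_after=None if after is None else after + 1,
                    terminal=before is None or after is None,
                )
            )
        k = j + 1
    return segments


def global_rmsd(
    result: SuperpositionResult,
    ref: Structure | None = None,
    query: Structure | None = None,
    scope: str = "calpha",
) -> float:
    """Global RMSD over paired residues: cα only, or all same-named atoms."""
    if not result.pairs:
        raise ValueError("empty pairing")
    if scope == "calpha":
        d2 = np.array([d**2 for _, _, d in result.pairs])
        return float(np.sqrt(d2.mean()))
    if scope != "all_atom":
        raise ValueError(f"unknown scope {scope!r}")
    if ref is None or query is None:
        raise ValueError("all_atom scope needs both structures")
    rot, trans = result.rotation, result.translation
    sq = []
    for ri, qi, _ in result.pairs:
        rres, qres = ref.residues[ri], query.residues[qi]
        for name, rxyz in rres.atoms.items():
            if name in qres.atoms:
                moved = rot @ qres.atoms[name] + trans
                sq.append(((moved - rxyz) ** 2).sum())
    if not sq:
        raise ValueError("no shared atom names in paired residues")
    return float(np.sqrt(np.mean(sq)))


def filter_by_ptm(
    structures: Sequence[Structure], min_ptm: float = 0.7
) -> tuple[list[Structure], list[str]]:
    """Quality gate: keep models with pTM > ``min_ptm``; return (kept, skipped ids).

    Structures without a recorded pTM pass the gate (no evidence against them).
    """
    kept, skipped = [], []
    for s in structures:
        if s.ptm is not None and s.ptm <= min_ptm:
            skipped.append(s.id)
        else:
            kept.append(s)
    return kept, skipped
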