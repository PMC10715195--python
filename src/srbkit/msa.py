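"""Alignment analytics for CD36 ectodomain multiple sequence alignments.

Alignment computation itself is upstream (e.g. MAFFT); this module consumes
aligned FASTA and provides coordinate maps, gap-fraction column filtering,
consensus and conservation, mean pairwise identity, lineage-specific
expansion-column detection against a reference row, and disulfide-bridge
cysteine homolog mapping with the expansion false-positive exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

GAP_CHARS = "-."


class Alignment:
    """An MSA with per-row column <-> residue coordinate maps (1-based)."""

    def __init__(self, rows: Sequence[tuple[str, str]]):
        if not rows:
            raise ValueError("empty alignment")
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids")
        n_cols = len(rows[0][1])
        for rid, s in rows:
            if len(s) != n_cols:
                raise ValueError(f"ragged alignment: row {rid!r} has length {len(s)} != {n_cols}")
        self.rows = [(rid, s.upper()) for rid, s in rows]
        self.n_cols = n_cols
        self._index = {rid: i for i, (rid, _) in enumerate(self.rows)}
        self._col_to_pos: dict[str, np.ndarray] = {}
        self._pos_to_col: dict[str, np.ndarray] = {}

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, seq_id: str) -> str:
        return self.rows[self._index[seq_id]][1]

    def ungapped(self, seq_id: str) -> str:
        return "".join(c for c in self.row(seq_id) if c not in GAP_CHARS)

    def _build_maps(self, seq_id: str) -> None:
        s = self.row(seq_id)
        col_to_pos = np.zeros(self.n_cols, dtype=int)  # 0 = gap
        pos_to_col = []
        pos = 0
        for c, ch in enumerate(s, start=1):
            if ch not in GAP_CHARS:
                pos += 1
                col_to_pos[c - 1] = pos
                pos_to_col.append(c)
        self._col_to_pos[seq_id] = col_to_pos
        self._pos_to_col[seq_id] = np.array(pos_to_col, dtype=int)

    def col_to_pos(self, seq_id: str, col: int) -> int | None:
        """Residue index at alignment column ``col`` (1-based), None if gap."""
        if seq_id not in self._col_to_pos:
            self._build_maps(seq_id)
        p = int(self._col_to_pos[seq_id][col - 1])
        return p if p > 0 else None

    def pos_to_col(self, seq_id: str, pos: int) -> int:
        """Alignment column of 1-based residue ``pos`` of row ``seq_id``."""
        if seq_id not in self._pos_to_col:
            self._build_maps(seq_id)
        return int(self._pos_to_col[seq_id][pos - 1])

    def matrix(self) -> np.ndarray:
        """Residue characters as an (n_rows, n_cols) array; gaps normalized to '-'."""
        m = np.array([list(s) for _, s in self.rows])
        m[np.isin(m, list(GAP_CHARS))] = "-"
        return m


def read_alignment(source) -> Alignment:
    """Read an aligned FASTA into an :class:`Alignment`."""
    try:
        aln = AlignIO.read(source, "fasta")
    except ValueError as exc:
        raise ValueError(f"could not read alignment: {exc}") from exc
    return Alignment([(rec.id, str(rec.seq)) for rec in aln])


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, s in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Column statistics
# ---------------------------------------------------------------------------

def gap_filter(aln: Alignment, max_gap_frac: float = 0.8) -> tuple[Alignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_frac``.

    A simple declared stand-in for block-based alignment trimming.  Returns
    the filtered alignment and the surviving original column indices
    (1-based) so downstream coordinates can be lifted back.
    """
    if not (0 < max_gap_frac <= 1):
        raise ValueError("max_gap_frac must be in (0, 1]")
    m = aln.matrix()
    gap_frac = (m == "-").mean(axis=0)
    kept = [c + 1 for c in range(aln.n_cols) if gap_frac[c] <= max_gap_frac]
    rows = [(rid, "".join(s[c - 1] for c in kept)) for rid, s in aln.rows]
    return Alignment(rows), kept


def _column_mode(column: np.ndarray) -> tuple[str, int]:
    """Modal non-gap residue (alphabetical tie-break) and its count."""
    residues = column[column != "-"]
    if residues.size == 0:
        return "", 0
    values, counts = np.unique(residues, return_counts=True)
    top = counts.max()
    winner = min(values[counts == top].tolist())  # alphabetical tie-break
    return str(winner), int(top)


def consensus(aln: Alignment, min_occupancy: float = 0.5) -> str:
    """Modal-residue consensus over columns with occupancy >= ``min_occupancy``."""
    m = aln.matrix()
    out = []
    for c in range(aln.n_cols):
        col = m[:, c]
        occ = (col != "-").mean()
        if occ >= min_occupancy:
            winner, _ = _column_mode(col)
            if winner:
                out.append(winner)
    return "".join(out)


def conservation(aln: Alignment) -> np.ndarray:
    """Per-column conservation: modal non-gap residue count / total rows."""
    m = aln.matrix()
    vals = np.zeros(aln.n_cols)
    for c in range(aln.n_cols):
        _, count = _column_mode(m[:, c])
        vals[c] = count / aln.n_rows
    return vals


def conservation_mask(aln: Alignment, threshold: float = 0.40) -> np.ndarray:
    """Boolean per-column mask of conservation >= threshold (default >=40%)."""
    return conservation(aln) >= threshold


def pairwise_identity_matrix(aln: Alignment) -> pd.DataFrame:
    """Row x row identity over columns where both rows hold residues."""
    m = aln.matrix()
    res = m != "-"
    n = aln.n_rows
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = res[i] & res[j]
            denom = int(both.sum())
            ident = float((m[i][both] == m[j][both]).mean()) if denom else 0.0
            out[i, j] = out[j, i] = ident
    return pd.DataFrame(out, index=aln.ids, columns=aln.ids)


def mean_pairwise_identity(aln: Alignment) -> float:
    """Mean identity over unordered row pairs.

    Identity denominator excludes columns where either row is gapped; pairs
    with no co-occupied columns contribute 0.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least 2 rows")
    mat = pairwise_identity_matrix(aln).to_numpy()
    iu = np.triu_indices(aln.n_rows, k=1)
    return float(mat[iu].mean())


# ---------------------------------------------------------------------------
# Expansion columns and bridge cysteines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpansionColumns:
    """Lineage-specific insertion runs of one row relative to a reference row.

    ``runs`` holds (start_col, end_col, n_residues) per maximal run of focal
    residues sitting in reference-gap columns; ``anchors`` holds, per run, the
    reference residue indices immediately before and after (None at termini).
    """

    seq_id: str
    runs: tuple[tuple[int, int, int], ...]
    anchors: tuple[tuple[int | None, int | None], ...]

    def contains_col(self, col: int) -> bool:
        return any(a <= col <= b for a, b, _ in self.runs)


def detect_expansion_columns(
    aln: Alignment, ref_id: str, min_run: int = 10
) -> dict[str, ExpansionColumns]:
    """Find per-row runs of >= ``min_run`` residues in reference-gap columns."""
    if ref_id not in aln.ids:
        raise ValueError(f"unknown reference id {ref_id!r}")
    ref_row = aln.row(ref_id)
    ref_gap = np.array([c in GAP_CHARS for c in ref_row])
    out: dict[str, ExpansionColumns] = {}
    for rid, s in aln.rows:
        if rid == ref_id:
            continue
        res_cols = [c for c in range(aln.n_cols) if s[c] not in GAP_CHARS]
        runs, anchors = [], []
        k = 0
        while k < len(res_cols):
            if not ref_gap[res_cols[k]]:
                k += 1
                continue
            # extend over consecutive focal residues in ref-gap columns
            j = k
            while j + 1 < len(res_cols) and ref_gap[res_cols[j + 1]]:
                j += 1
            count = j - k + 1
            if count >= min_run:
                start_col, end_col = res_cols[k] + 1, res_cols[j] + 1
                before = aln.col_to_pos(ref_id, start_col - 1) if start_col > 1 else None
                if before is None and start_col > 1:
                    # walk left to the nearest reference residue
                    c = start_col - 1
                    while c >= 1 and aln.col_to_pos(ref_id, c) is None:
                        c -= 1
                    before = aln.col_to_pos(ref_id, c) if c >= 1 else None
                after = None
                c = end_col + 1
                while c <= aln.n_cols and aln.col_to_pos(ref_id, c) is None:
                    c += 1
                if c <= aln.n_cols:
                    after = aln.col_to_pos(ref_id, c)
                runs.append((start_col, end_col, count))
                anchors.append((before, after))
            k = j + 1
        out[rid] = ExpansionColumns(rid, tuple(runs), tuple(anchors))
    return out


@dataclass(frozen=True)
class BridgePairCall:
    """Presence of one reference disulfide-bridge cysteine pair in one row."""

    seq_id: str
    bridge_id: int
    ref_columns: tuple[int, int]
    query_positions: tuple[int | None, int | None]
    status: str  # {present | absent | excluded_expansion}


def _find_cys_near(aln: Alignment, seq_id: str, col: int, tolerance: int):
    """Nearest cysteine of ``seq_id`` within ``col`` +- tolerance columns.

    Offsets are tried nearest-first, left before right on ties.  Returns
    (residue_pos, column) or (None, None).
    """
    row = aln.row(seq_id)
    offsets = sorted(range(-tolerance, tolerance + 1), key=lambda o: (abs(o), o))
    for off in offsets:
        c = col + off
        if 1 <= c <= aln.n_cols and row[c - 1] == "C":
            return aln.col_to_pos(seq_id, c), c
    return None, None


def map_bridge_cysteines(
    aln: Alignment,
    ref_id: str,
    ref_pairs: Sequence[tuple[int, int]],
    tolerance: int = 2,
    expansions: Mapping[str, ExpansionColumns] | None = None,
) -> list[BridgePairCall]:
    """Map reference bridge-cysteine pairs onto every row of the alignment.

    Reference residue positions are lifted to alignment columns and each row
    is scanned at those columns +- ``tolerance`` for cysteines.  Both found =>
    present, unless any matched cysteine falls inside that row's
    lineage-specific expansion run, in which case the pair is excluded as a
    false positive (``excluded_expansion``); otherwise absent.
    """
    if ref_id not in aln.ids:
        raise ValueError(f"unknown reference id {ref_id!r}")
    ref_seq = aln.ungapped(ref_id)
    calls = []
    for bridge_id, (p1, p2) in enumerate(ref_pairs, start=1):
        for p in (p1, p2):
            if not (1 <= p <= len(ref_seq)) or ref_seq[p - 1] != "C":
                raise ValueError(f"reference position {p} is not a cysteine")
        col_a, col_b = aln.pos_to_col(ref_id, p1), aln.pos_to_col(ref_id, p2)
        for rid, _ in aln.rows:
            if rid == ref_id:
                continue
            qa, ca = _find_cys_near(aln, rid, col_a, tolerance)
            qb, cb = _find_cys_near(aln, rid, col_b, tolerance)
            exp = expansions.get(rid) if expansions else None
            in_expansion = exp is not None and any(
                c is not None and exp.contains_col(c) for c in (ca, cb)
            )
            if in_expansion:
                status = "excluded_expansion"
            elif qa is not None and qb is not None:
                status = "present"
            else:
                status = "absent"
            calls.append(BridgePairCall(rid, bridge_id, (col_a, col_b), (qa, qb), status))
    return calls


def bridge_calls_table(calls: Sequence[BridgePairCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [c.seq_id for c in calls],
            "bridge_id": [c.bridge_id for c in calls],
            "col_a": [c.ref_columns[0] for c in calls],
            "col_b": [c.ref_columns[1] for c in calls],
            "pos_a": [c.query_positions[0] for c in calls],
            "pos_b": [c.query_positions[1] for c in calls],
            "status": [c.status for c in calls],
        }
    )
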