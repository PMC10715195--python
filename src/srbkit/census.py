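"""Census of class B scavenger receptors by transmembrane architecture.

A bona fide SR-B is operationally a protein whose CD36 ectodomain is flanked
by two transmembrane (TM) helices: the TM-CD36-TM architecture.  This module
parses domain-hit and TM-topology tables (or predicts TM helices from
hydropathy), removes within-taxon duplicate sequences, and classifies every
CD36-domain protein into one of five architecture labels.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import AA20, KYTE_DOOLITTLE

#: hmmsearch's default per-sequence inclusion threshold (full-sequence E-value).
HMMSEARCH_INCLUSION_EVALUE = 0.01

ARCH_LABELS = ("SR-B", "cd36_no_tm", "cd36_partial_tm", "fused_suspect", "non_cd36")


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with a taxon label; residues over the 20 aa + X."""

    id: str
    taxon: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - set(AA20 + "X")
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    seq_id: str
    domain_name: str
    env_start: int
    env_end: int
    bit_score: float
    e_value: float
    included: bool

    def __post_init__(self):
        if not (1 <= self.env_start <= self.env_end):
            raise ValueError(
                f"{self.seq_id}: invalid envelope {self.env_start}-{self.env_end}"
            )


@dataclass(frozen=True)
class TMSegment:
    seq_id: str
    start: int
    end: int
    source: str = "table"  # {table | hydropathy}

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ArchitectureCall:
    seq_id: str
    label: str
    n_cd36_domains: int
    ecto_span: tuple[int, int] | None
    flanking_tms: tuple[TMSegment, TMSegment] | None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(source, default_taxon: str = "") -> list[SequenceRecord]:
    """Read protein FASTA.  Ids of the form ``taxon|name`` carry their taxon."""
    if isinstance(source, (str, Path)):
        handle = open(source)
    else:
        handle = source
    records = []
    for rec in SeqIO.parse(handle, "fasta"):
        rid = rec.id
        taxon = rid.split("|", 1)[0] if "|" in rid else default_taxon
        records.append(SequenceRecord(id=rid, taxon=taxon, residues=str(rec.seq).upper()))
    if isinstance(source, (str, Path)):
        handle.close()
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.residues
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _as_lines(stream):
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return fh.readlines()
    if isinstance(stream, str):
        return io.StringIO(stream).readlines()
    return list(stream)


def read_domain_hits(stream, dialect: str = "domtblout") -> list[DomainHit]:
    """Parse a per-domain hit table.

    ``domtblout`` is the whitespace-delimited per-domain output dialect of
    hmmsearch ('#' comments); envelope coordinates (columns 20-21) define the
    domain span and the full-sequence E-value against the default inclusion
    threshold sets ``included``.  ``tsv`` expects columns
    seq_id, domain_name, env_start, env_end, bit_score, e_value, included.
    """
    if dialect not in ("domtblout", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    hits = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t") if dialect == "tsv" else line.split()
        try:
            if dialect == "domtblout":
                if len(parts) < 22:
                    raise ValueError("expected >=22 whitespace-separated fields")
                seq_id, domain_name = parts[0], parts[3]
                e_value = float(parts[6])
                bit_score = float(parts[13])
                env_start, env_end = int(parts[19]), int(parts[20])
                included = e_value <= HMMSEARCH_INCLUSION_EVALUE
            else:
                if len(parts) < 7:
                    raise ValueError("expected 7 tab-separated fields")
                seq_id, domain_name = parts[0], parts[1]
                env_start, env_end = int(parts[2]), int(parts[3])
                bit_score, e_value = float(parts[4]), float(parts[5])
                included = parts[6].strip().lower() in ("1", "true", "yes")
            hits.append(
                DomainHit(seq_id, domain_name, env_start, env_end, bit_score, e_value, included)
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed {dialect} row at line {lineno}: {exc}") from exc
    return hits


def read_tm_table(stream, dialect: str = "tmhmm") -> list[TMSegment]:
    """Parse TM-helix annotations.

    ``tmhmm`` accepts the short-output dialect (whitespace rows containing a
    ``TMhelix`` token followed by start and end); other topology rows are
    ignored.  ``tsv`` expects seq_id, start, end.
    """
    if dialect not in ("tmhmm", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    segs = []
    for lineno, line in enumerate(_as_lines(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        try:
            if dialect == "tmhmm":
                if "TMhelix" not in parts:
                    continue
                k = parts.index("TMhelix")
                segs.append(TMSegment(parts[0], int(parts[k + 1]), int(parts[k + 2]), "table"))
            else:
                segs.append(TMSegment(parts[0], int(parts[1]), int(parts[2]), "table"))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed {dialect} row at line {lineno}: {exc}") from exc
    return segs


# ---------------------------------------------------------------------------
# Hydropathy TM prediction
# ---------------------------------------------------------------------------

def predict_tm_hydropathy(
    seq: SequenceRecord, window: int = 19, cutoff: float = 1.6
) -> list[TMSegment]:
    """Predict TM helices from Kyte-Doolittle mean hydropathy.

    A sliding window of odd width is centred on each residue; maximal runs of
    centres with mean hydropathy >= cutoff become candidate segments.  Runs
    shorter than 12 residues are discarded; runs longer than 40 are trimmed to
    the 21-residue window of maximal mean hydropathy.  Unknown residues (X)
    score 0.  Sequences shorter than the window yield no segments.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    n = seq.length
    if n < window:
        return []
    values = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq.residues])
    means = np.convolve(values, np.ones(window) / window, mode="valid")
    half = window // 2
    # means[k] is centred on 1-based residue k + half + 1
    qual = means >= cutoff
    segs: list[TMSegment] = []
    i = 0
    while i < len(qual):
        if not qual[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(qual) and qual[j + 1]:
            j += 1
        start, end = i + half + 1, j + half + 1
        run_len = end - start + 1
        if run_len >= 12:
            if run_len > 40:
                # best 21-residue sub-window of centre means
                sub = np.convolve(means[i : j + 1], np.ones(21) / 21, mode="valid")
                k = int(np.argmax(sub))
                start, end = start + k, start + k + 20
            segs.append(TMSegment(seq.id, start, end, "hydropathy"))
        i = j + 1
    return segs


def merge_tm_segments(segments: Sequence[TMSegment]) -> list[TMSegment]:
    """Sort per-sequence segments and merge overlapping/abutting ones."""
    out: list[TMSegment] = []
    by_seq: dict[str, list[TMSegment]] = {}
    for s in segments:
        by_seq.setdefault(s.seq_id, []).append(s)
    for sid in sorted(by_seq):
        merged: list[list] = []
        for s in sorted(by_seq[sid], key=lambda s: (s.start, s.end)):
            if merged and s.start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], s.end)
            else:
                merged.append([s.start, s.end, s.source])
        out.extend(TMSegment(sid, a, b, src) for a, b, src in merged)
    return out


# ---------------------------------------------------------------------------
# Dedupe and classification
# ---------------------------------------------------------------------------

def dedupe_identical(records: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse exact within-taxon duplicates, keeping the smallest id.

    Cross-taxon duplicates are retained.  Output preserves first-appearance
    order of the surviving sequences.
    """
    keeper: dict[tuple[str, str], SequenceRecord] = {}
    for rec in records:
        key = (rec.taxon, rec.residues)
        prev = keeper.get(key)
        if prev is None or rec.id < prev.id:
            keeper[key] = rec
    kept_ids = {rec.id for rec in keeper.values()}
    return [rec for rec in records if rec.id in kept_ids]


def classify_architecture(
    seq: SequenceRecord,
    hits: Sequence[DomainHit],
    tms: Sequence[TMSegment],
    max_overlap: int = 10,
    max_n_tail: int = 400,
    domain_name: str = "CD36",
) -> ArchitectureCall:
    """Classify one sequence against the TM-CD36-TM architecture rule.

    SR-B requires an included CD36 hit with one TM ending before the first
    domain envelope start (+ max_overlap slack) and one TM starting after its
    envelope end (- max_overlap slack).  A qualifying architecture whose
    N-terminal tail before TM1 exceeds ``max_n_tail`` residues is flagged
    ``fused_suspect`` (long foreign N-terminal regions indicate gene-model
    fusions).  The ectodomain span is the region strictly between the two TMs.
    """
    for h in hits:
        if h.seq_id != seq.id:
            raise ValueError(f"hit for unknown seq_id {h.seq_id!r} (expected {seq.id!r})")
        if h.env_end > seq.length:
            raise ValueError(f"{seq.id}: hit envelope exceeds sequence length")
    cd36 = sorted(
        (h for h in hits if h.included and h.domain_name == domain_name),
        key=lambda h: h.env_start,
    )
    if not cd36:
        return ArchitectureCall(seq.id, "non_cd36", 0, None, None)
    first = cd36[0]
    tms = merge_tm_segments([t for t in tms if t.seq_id == seq.id])
    before = [t for t in tms if t.end < first.env_start + max_overlap]
    after = [t for t in tms if t.start > first.env_end - max_overlap]
    a = max(before, key=lambda t: t.end) if before else None
    b = min(after, key=lambda t: t.start) if after else None
    if a is not None and b is not None and a.end < b.start - 1:
        if a.start - 1 > max_n_tail:
            return ArchitectureCall(seq.id, "fused_suspect", len(cd36), None, (a, b))
        return ArchitectureCall(seq.id, "SR-B", len(cd36), (a.end + 1, b.start - 1), (a, b))
    if a is None and b is None:
        return ArchitectureCall(seq.id, "cd36_no_tm", len(cd36), None, None)
    return ArchitectureCall(seq.id, "cd36_partial_tm", len(cd36), None, None)


def census_summary(
    calls: Sequence[ArchitectureCall],
    taxon_of: Mapping[str, str],
    clade_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-taxon SR-B counts with clade annotation and CD36-hit totals."""
    rows = []
    for call in calls:
        taxon = taxon_of.get(call.seq_id)
        if taxon is None:
            raise ValueError(f"no taxon mapping for sequence {call.seq_id!r}")
        if taxon not in clade_of:
            raise ValueError(f"unmapped taxon {taxon!r}")
        rows.append(
            {
                "taxon": taxon,
                "clade": clade_of[taxon],
                "is_srb": call.label == "SR-B",
                "has_cd36": call.label != "non_cd36",
            }
        )
    if not rows:
        return pd.DataFrame(columns=["clade", "taxon", "n_cd36_hits", "n_srb"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["clade", "taxon"], sort=True)
        .agg(n_cd36_hits=("has_cd36", "sum"), n_srb=("is_srb", "sum"))
        .reset_index()
    )
    return out
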