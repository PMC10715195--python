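"""CD36 ectodomain extraction, sanitization and length analytics.

The ectodomain is the region between the two flanking TM helices.  Ectodomain
length is strongly clade-structured (metazoan ectodomains are compact, many
non-metazoan ones carry large apex insertions); ectodomains longer than a
configurable threshold (default 500 aa) are flagged as candidate
lineage-specific expansions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import AA20
from .census import ArchitectureCall, SequenceRecord

DEFAULT_EXPANSION_FLAG_AA = 500


@dataclass(frozen=True)
class Ectodomain:
    seq_id: str
    span: tuple[int, int]
    sequence: str
    expansion_flag: bool = False

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


def extract_ectodomain(
    seq: SequenceRecord,
    call: ArchitectureCall,
    flag_threshold: int = DEFAULT_EXPANSION_FLAG_AA,
) -> Ectodomain:
    """Trim TM helices and tails; return the first-domain ectodomain.

    Only SR-B calls carry an ectodomain span (for multi-domain sequences the
    span flanking the first CD36 domain is the one stored on the call).
    """
    if call.label != "SR-B" or call.ecto_span is None:
        raise ValueError(f"{seq.id}: cannot extract ectodomain from label {call.label!r}")
    start, end = call.ecto_span
    sub = seq.residues[start - 1 : end]
    return Ectodomain(seq.id, (start, end), sub, expansion_flag=len(sub) > flag_threshold)


def sanitize_sequence(sequence: str) -> tuple[str, int]:
    """Replace undetermined residues (X) with alanine (A).

    Alanine is the conventional non-bulky, non-reactive stand-in used when
    preparing sequences for structure prediction.  Returns the sanitized
    sequence and the replacement count; any character outside the 20 canonical
    residues + X is an error.
    """
    bad = set(sequence) - set(AA20 + "X")
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)}")
    n = sequence.count("X")
    return sequence.replace("X", "A"), n


def length_stats(
    ectodomains: Sequence[Ectodomain],
    clade_of: Mapping[str, str],
    flag_threshold: int = DEFAULT_EXPANSION_FLAG_AA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-clade length summaries and the per-sequence expansion flags.

    Returns (per_clade, per_sequence).  per_clade carries min/max/median and a
    fixed-width histogram; per_sequence carries length and the > threshold
    expansion flag.
    """
    rows = []
    for e in ectodomains:
        if e.seq_id not in clade_of:
            raise ValueError(f"unmapped clade for sequence {e.seq_id!r}")
        rows.append(
            {
                "seq_id": e.seq_id,
                "clade": clade_of[e.seq_id],
                "length": e.length,
                "expansion_flag": e.length > flag_threshold,
            }
        )
    if not rows:
        empty = pd.DataFrame()
        return empty, empty
    per_seq = pd.DataFrame(rows)
    groups = []
    for clade, grp in per_seq.groupby("clade", sort=True):
        lengths = grp["length"].to_numpy()
        hist, _ = np.histogram(lengths, bins=np.arange(0, 2500 + 100, 100))
        groups.append(
            {
                "clade": clade,
                "n": len(lengths),
                "min": int(lengths.min()),
                "max": int(lengths.max()),
                "median": float(np.median(lengths)),
                "n_flagged": int(grp["expansion_flag"].sum()),
                "histogram_100aa": ",".join(str(c) for c in hist),
            }
        )
    return pd.DataFrame(groups), per_seq
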