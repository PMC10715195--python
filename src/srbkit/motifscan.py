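"""PWM motif scanning with sequence scores and 0-100 scaled presence values.

A motif is a position weight matrix (PWM) of log2-odds weights over the 20
residues.  The sequence score of a motif against a protein is the maximum,
over all windows, of the summed per-position weights; scores at or above the
motif's match threshold count as a match.  For presentation, raw scores are
mapped per motif onto a 0-100 scale against the motif's theoretical extrema
(the sums of per-position minimum and maximum weights).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import AA20

NO_HIT_SCORE = -math.inf
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass(frozen=True)
class MotifPWM:
    """A protein motif as per-position log2-odds weights vs a background."""

    motif_id: str
    weights: np.ndarray  # (width, 20), columns ordered by AA20
    background: np.ndarray  # (20,), sums to 1
    match_threshold: float = 0.0
    p_value: float | None = None
    e_value: float | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(AA20) or w.shape[0] < 1:
            raise ValueError("weights must be (width, 20)")
        if bg.shape != (len(AA20),) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background must be 20 frequencies summing to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def max_possible(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_possible(self) -> float:
        return float(self.weights.min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(AA20[i] for i in self.weights.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    motif_id: str
    start: int | None  # 1-based window start; None for the no-hit sentinel
    raw_score: float
    scaled_score: float
    passes: bool


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def probs_to_weights(
    probs: np.ndarray, background: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """log2((p + pc*bg) / ((1 + pc) * bg)) — MEME-style log-odds with pseudocount."""
    probs = np.asarray(probs, dtype=float)
    p = (probs + pseudocount * background) / (1.0 + pseudocount)
    return np.log2(p / background)


def read_meme_motifs(source, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[MotifPWM]:
    """Parse the MEME minimal motif format into PWMs.

    Letter probabilities are converted to log2-odds weights against the
    file's background (uniform if the file declares none).  An optional
    ``MATCH_THRESHOLD <v>`` line after a matrix sets that motif's threshold
    (absent => 0).  Matrix rows must sum to ~1 (+-0.01).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    lines = text.splitlines()
    alphabet = AA20
    background = np.full(len(AA20), 1.0 / len(AA20))
    motifs: list[MotifPWM] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET="):
            alphabet = line.split("=", 1)[1].strip()
            if sorted(alphabet) != sorted(AA20):
                raise ValueError("only the 20-residue protein alphabet is supported")
            i += 1
        elif line.startswith("Background letter frequencies"):
            toks: list[str] = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                toks.extend(lines[i].split())
                i += 1
            freq = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)}
            background = np.array([freq[a] for a in AA20])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            i += 1
            # find the letter-probability header
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id}: missing letter-probability matrix")
            header = lines[i]
            toks = header.replace("=", " = ").split()
            width = int(toks[toks.index("w") + 2]) if "w" in toks else None
            e_value = None
            if "E" in toks:
                e_value = float(toks[toks.index("E") + 2])
            p_value = None
            if "P" in toks:
                p_value = float(toks[toks.index("P") + 2])
            i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or not (s[0].isdigit() or s[0] in ".-"):
                    break
                rows.append([float(x) for x in s.split()])
                i += 1
            probs = np.array(rows)
            if width is not None and probs.shape[0] != width:
                raise ValueError(f"motif {motif_id}: expected {width} rows, got {probs.shape[0]}")
            if probs.shape[1] != len(alphabet):
                raise ValueError(f"motif {motif_id}: expected {len(alphabet)} columns")
            bad = np.abs(probs.sum(axis=1) - 1.0) > 0.01
            if bad.any():
                raise ValueError(
                    f"motif {motif_id}: probability row(s) {np.where(bad)[0] + 1} do not sum to 1"
                )
            # reorder columns to AA20 if the file's alphabet differs
            order = [alphabet.index(a) for a in AA20]
            probs = probs[:, order]
            threshold = 0.0
            if i < len(lines) and lines[i].strip().startswith("MATCH_THRESHOLD"):
                threshold = float(lines[i].split()[1])
                i += 1
            motifs.append(
                MotifPWM(
                    motif_id,
                    probs_to_weights(probs, background, pseudocount),
                    background,
                    match_threshold=threshold,
                    p_value=p_value,
                    e_value=e_value,
                )
            )
        else:
            i += 1
    return motifs


def write_meme_motifs(
    motifs_with_probs: Sequence[tuple[MotifPWM, np.ndarray]], path, background=None
) -> None:
    """Write motifs (with their letter probabilities) in MEME minimal format."""
    if background is None:
        background = motifs_with_probs[0][0].background
    with open(path, "w") as fh:
        fh.write("MEME version 5\n\nALPHABET= " + AA20 + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{a} {background[k]:.6f}" for k, a in enumerate(AA20)) + "\n\n"
        )
        for pwm, probs in motifs_with_probs:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            extra = f" E= {pwm.e_value:g}" if pwm.e_value is not None else ""
            fh.write(
                f"letter-probability matrix: alength= 20 w= {pwm.width} "
                f"nsites= 20{extra}\n"
            )
            for row in probs:
                fh.write(" " + " ".join(f"{p:.17g}" for p in row) + "\n")
            fh.write(f"MATCH_THRESHOLD {pwm.match_threshold:g}\n\n")


def pwm_from_sites(
    sites: Sequence[str],
    motif_id: str = "motif",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    match_threshold: float = 0.0,
) -> tuple[MotifPWM, np.ndarray]:
    """Build a PWM from equal-length ungapped sites; returns (pwm, probabilities)."""
    if not sites:
        raise ValueError("no sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("ragged sites")
    if background is None:
        background = np.full(len(AA20), 1.0 / len(AA20))
    counts = np.zeros((width, len(AA20)))
    idx = {a: k for k, a in enumerate(AA20)}
    for s in sites:
        for j, c in enumerate(s.upper()):
            if c not in idx:
                raise ValueError(f"non-amino-acid character {c!r} in site")
            counts[j, idx[c]] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    pwm = MotifPWM(
        motif_id,
        probs_to_weights(probs, background, pseudocount),
        background,
        match_threshold=match_threshold,
    )
    return pwm, probs


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _weights_with_unknown(pwm: MotifPWM) -> np.ndarray:
    """Weights extended with an X column scoring the background-mean weight."""
    x_col = (pwm.weights * pwm.background).sum(axis=1, keepdims=True)
    return np.hstack([pwm.weights, x_col])


def window_scores(sequence: str, pwm: MotifPWM) -> np.ndarray:
    """Summed PWM weight for every window of the sequence (empty if too short)."""
    n, w = len(sequence), pwm.width
    if n < w:
        return np.array([])
    lut = {a: k for k, a in enumerate(AA20)}
    idx = np.array([lut.get(c, len(AA20)) for c in sequence.upper()])
    ext = _weights_with_unknown(pwm)
    win = np.lib.stride_tricks.sliding_window_view(idx, w)  # (n-w+1, w)
    return ext[np.arange(w), win].sum(axis=1)


def score_sequence(sequence: str, pwm: MotifPWM, seq_id: str = "") -> MotifHit:
    """Best-window sequence score against one motif.

    Sequences shorter than the motif width yield the defined no-hit result
    (raw score -inf, scaled 0, passes False).
    """
    scores = window_scores(sequence, pwm)
    if scores.size == 0:
        return MotifHit(seq_id, pwm.motif_id, None, NO_HIT_SCORE, 0.0, False)
    best = int(np.argmax(scores))
    raw = float(scores[best])
    return MotifHit(
        seq_id,
        pwm.motif_id,
        best + 1,
        raw,
        scale_score(raw, pwm),
        raw >= pwm.match_threshold,
    )


def scale_score(raw: float, pwm: MotifPWM) -> float:
    """Min-max map of a raw score onto [0, 100] against theoretical extrema."""
    lo, hi = pwm.min_possible, pwm.max_possible
    if not math.isfinite(raw):
        return 0.0
    if hi <= lo:
        return 0.0
    return float(np.clip(100.0 * (raw - lo) / (hi - lo), 0.0, 100.0))


def scale_scores(raw_scores: Sequence[float], pwm: MotifPWM) -> np.ndarray:
    """Vectorized :func:`scale_score`; warns on degenerate motifs."""
    import warnings

    if pwm.max_possible <= pwm.min_possible:
        warnings.warn(f"degenerate motif {pwm.motif_id}: zero score range")
        return np.zeros(len(raw_scores))
    return np.array([scale_score(r, pwm) for r in raw_scores])


def motif_presence(
    sequences: Sequence[tuple[str, str]], pwms: Sequence[MotifPWM]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Scaled-score heatmap, pass flags and per-motif pass fractions.

    ``sequences`` is (seq_id, residues) pairs.  Returns (scaled, passes,
    pass_fraction): sequence x motif matrices plus a per-motif Series.
    """
    ids = [sid for sid, _ in sequences]
    motif_ids = [p.motif_id for p in pwms]
    scaled = pd.DataFrame(index=ids, columns=motif_ids, dtype=float)
    passes = pd.DataFrame(index=ids, columns=motif_ids, dtype=bool)
    for sid, seq in sequences:
        for pwm in pwms:
            hit = score_sequence(seq, pwm, seq_id=sid)
            scaled.loc[sid, pwm.motif_id] = hit.scaled_score
            passes.loc[sid, pwm.motif_id] = hit.passes
    frac = passes.mean(axis=0) if ids else pd.Series(dtype=float)
    return scaled, passes, frac
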