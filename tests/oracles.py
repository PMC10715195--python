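"""Independent oracle implementations used to cross-check the package.

These deliberately avoid the code paths they verify: the rigid-superposition
oracle is Horn's closed-form quaternion method (eigen-decomposition, not the
SVD route used by the package) and the scanning oracles are plain
enumeration loops.
"""

from __future__ import annotations

import numpy as np

from srbkit.constants import AA20, KYTE_DOOLITTLE


def horn_superpose(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, float]:
    """Horn (1987) quaternion absolute-orientation solution.

    Returns (rotation, rmsd) with mov @ R.T + t ~= ref; reflections cannot
    occur because the rotation is parameterized as a unit quaternion.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    r0 = ref - ref.mean(axis=0)
    m0 = mov - mov.mean(axis=0)
    s = m0.T @ r0
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    n = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    vals, vecs = np.linalg.eigh(n)
    q = vecs[:, -1]  # eigenvector of the largest eigenvalue
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    diff = m0 @ rot.T - r0
    rmsd = float(np.sqrt((diff**2).sum() / len(ref)))
    return rot, rmsd


def brute_force_tm_runs(sequence: str, window: int = 19, cutoff: float = 1.6):
    """Qualifying-centre runs of mean Kyte-Doolittle hydropathy, by direct loops.

    Returns 1-based (start, end) spans of maximal runs of window centres whose
    window mean is >= cutoff, before any length filtering.
    """
    n = len(sequence)
    half = window // 2
    centers = []
    for c in range(half + 1, n - half + 1):  # 1-based centre positions
        total = 0.0
        for k in range(c - half, c + half + 1):
            total += KYTE_DOOLITTLE.get(sequence[k - 1], 0.0)
        if total / window >= cutoff:
            centers.append(c)
    runs = []
    for c in centers:
        if runs and c == runs[-1][1] + 1:
            runs[-1][1] = c
        else:
            runs.append([c, c])
    return [(a, b) for a, b in runs]


def brute_force_best_window(sequence: str, weights: np.ndarray, background: np.ndarray):
    """Best PWM window by direct enumeration.  Returns (score, 1-based start).

    Unknown residues score the background-expected weight at their position,
    mirroring the scanner's stated convention.
    """
    width = weights.shape[0]
    if len(sequence) < width:
        return None
    idx = {a: k for k, a in enumerate(AA20)}
    best, best_start = -np.inf, None
    for start in range(len(sequence) - width + 1):
        total = 0.0
        for j in range(width):
            c = sequence[start + j]
            if c in idx:
                total += weights[j, idx[c]]
            else:
                total += float((weights[j] * background).sum())
        if total > best:
            best, best_start = total, start + 1
    return best, best_start


def brute_force_mean_identity(rows: list[str]) -> float:
    """Mean pairwise identity by direct pair loops (gap-excluding denominator)."""
    vals = []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            both = ident = 0
            for a, b in zip(rows[i], rows[j]):
                if a not in "-." and b not in "-.":
                    both += 1
                    ident += a == b
            vals.append(ident / both if both else 0.0)
    return float(np.mean(vals))
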