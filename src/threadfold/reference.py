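"""Slow brute-force reference implementations for cross-checking.

These enumerate every monotone alignment or matching explicitly and
share no code with the dynamic-programming kernels they are used to
verify.  They are exponential and only meant for instances with both
lengths ≤ ~7.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np


@lru_cache(maxsize=None)
def enumerate_alignments(la: int, lb: int) -> tuple[tuple[str, ...], ...]:
    """All global alignments of lengths (la, lb) as op tuples.

    Ops: 'M' consumes one position of each sequence, 'X' one of the
    first only (gap in the second), 'Y' one of the second only.
    """
    if la == 0 and lb == 0:
        return ((),)
    out: list[tuple[str, ...]] = []
    if la > 0 and lb > 0:
        out.extend(ops + ("M",) for ops in enumerate_alignments(la - 1, lb - 1))
    if la > 0:
        out.extend(ops + ("X",) for ops in enumerate_alignments(la - 1, lb))
    if lb > 0:
        out.extend(ops + ("Y",) for ops in enumerate_alignments(la, lb - 1))
    return tuple(out)


def score_alignment_ops(
    ops: tuple[str, ...], M: np.ndarray, gap_open: float, gap_extend: float
) -> tuple[float, list[tuple[int, int]]]:
    """Score one op sequence: sum of matched M cells minus affine gap costs."""
    i = j = 0
    total = 0.0
    pairs: list[tuple[int, int]] = []
    prev = "M"
    for op in ops:
        if op == "M":
            total += M[i, j]
            pairs.append((i, j))
            i += 1
            j += 1
        else:
            if op != prev:
                total -= gap_open
            total -= gap_extend
            if op == "X":
                i += 1
            else:
                j += 1
        prev = op
    return total, pairs


def best_alignment_bruteforce(
    M: np.ndarray, gap_open: float, gap_extend: float
) -> float:
    """Optimal global affine-gap alignment score by full enumeration."""
    la, lb = M.shape
    best = -np.inf
    for ops in enumerate_alignments(la, lb):
        s, _ = score_alignment_ops(ops, M, gap_open, gap_extend)
        if s > best:
            best = s
    return float(best)


@lru_cache(maxsize=None)
def _alignment_tables(la: int, lb: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Padded per-alignment index tables for vectorized enumeration scoring.

    Returns (row idx, col idx, pad mask, gap penalty units) over all
    alignments of shape (la, lb); gap units are (n_runs, n_positions)
    pairs so any affine penalty can be applied afterwards.
    """
    aligns = enumerate_alignments(la, lb)
    kmax = min(la, lb)
    n = len(aligns)
    rows = np.zeros((n, kmax), dtype=np.int64)
    cols = np.zeros((n, kmax), dtype=np.int64)
    mask = np.zeros((n, kmax), dtype=bool)
    gap_units = np.zeros((n, 2))
    for a, ops in enumerate(aligns):
        i = j = k = 0
        prev = "M"
        for op in ops:
            if op == "M":
                rows[a, k] = i
                cols[a, k] = j
                mask[a, k] = True
                i += 1
                j += 1
                k += 1
            else:
                if op != prev:
                    gap_units[a, 0] += 1
                gap_units[a, 1] += 1
                if op == "X":
                    i += 1
                else:
                    j += 1
            prev = op
    return rows, cols, mask, gap_units


def best_alignment_bruteforce_fast(
    M: np.ndarray, gap_open: float, gap_extend: float
) -> float:
    """Same optimum as :func:`best_alignment_bruteforce`, vectorized."""
    rows, cols, mask, gap_units = _alignment_tables(*M.shape)
    match = np.where(mask, M[rows, cols], 0.0).sum(axis=1)
    penalty = gap_units[:, 0] * gap_open + gap_units[:, 1] * gap_extend
    return float(np.max(match - penalty))


def best_monotone_matching_bruteforce(S: np.ndarray) -> float:
    """Optimal gap-free-penalty monotone matching score by enumeration.

    Considers every strictly increasing pairing of row indices with
    column indices (including the empty matching, score 0).
    """
    la, lb = S.shape
    best = 0.0
    for k in range(1, min(la, lb) + 1):
        for rows in combinations(range(la), k):
            for cols in combinations(range(lb), k):
                s = sum(S[r, c] for r, c in zip(rows, cols))
                if s > best:
                    best = s
    return float(best)


def tm_score_direct(
    coords_a: np.ndarray, coords_b_superposed: np.ndarray, L_norm: int
) -> float:
    """Direct evaluation of the TM formula on already-superposed coordinates."""
    if L_norm > 15:
        d0 = max(1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    else:
        d0 = 0.5
    d = np.sqrt(np.sum((coords_a - coords_b_superposed) ** 2, axis=1))
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def dm_score_direct(deviations: np.ndarray, epsilon: float = 1e-3) -> float:
    """Term-by-term evaluation of the deviation-matrix score."""
    L = deviations.shape[0]
    total = 0.0
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            d_star = np.log(epsilon + abs(i - j))
            total += 1.0 / (1.0 + (deviations[i, j] / d_star) ** 2)
    return total / (L * (L - 1))
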