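"""Rigid-body superposition, TM-score and sequence-order structural alignment.

The clustering and pathway stages need a structural aligner only as a
black box that is exact on self/rigid cases and well behaved under
noise; a compact iterative Kabsch + dynamic-programming aligner provides
that (full TM-align is deliberately not reimplemented).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .structio import CaTrace

logger = logging.getLogger(__name__)

#: linear gap penalty used when rebuilding a correspondence by DP on the
#: 1/(1+(d/d0)^2) distance-score matrix (TM-align's published magnitude)
DP_GAP = 0.6

MAX_ROUNDS = 20


class AlignmentFailure(RuntimeError):
    """No usable residue correspondence could be found."""


@dataclass
class Superposition:
    """Rigid transform of structure b onto structure a plus bookkeeping.

    ``transform(x) = x @ rotation.T + translation`` maps b-frame
    coordinates into the a frame.  ``correspondence`` holds 1-based
    (i, j) residue index pairs, strictly increasing on both sides.
    """

    rotation: np.ndarray
    translation: np.ndarray
    correspondence: list[tuple[int, int]] = field(default_factory=list)
    rmsd: float = 0.0
    tm_score_by_a: float = 0.0
    tm_score_by_b: float = 0.0

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def as_matrix(self) -> np.ndarray:
        """3×4 matrix [R | t] in text-exportable form."""
        return np.hstack([self.rotation, self.translation[:, None]])


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-RMSD rigid transform of b onto a (Kabsch, via SVD).

    Requires N ≥ 3 points in each set.  The returned rotation is proper
    (determinant +1).
    """
    A = np.asarray(coords_a, dtype=np.float64)
    B = np.asarray(coords_b, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (B - cb).T @ (A - ca)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = B @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - A) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def tm_d0(L_norm: int) -> float:
    """TM-score distance scale d0 = 1.24·(L−15)^⅓ − 1.8, clamped to ≥0.5 Å."""
    if L_norm > 15:
        d0 = 1.24 * (L_norm - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def _tm_from_distances(d: np.ndarray, L_norm: int) -> float:
    d0 = tm_d0(L_norm)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def _tm_optimal_fit(
    A: np.ndarray, B: np.ndarray, L_norm: int
) -> tuple[float, np.ndarray, np.ndarray]:
    """Approximate TM-optimal rigid fit of matched coordinate sets.

    The standard iterative scheme: Kabsch fits on shrinking subsets of
    well-fitting residues, seeded from the full set and from contiguous
    fragments; returns the best (TM, rotation, translation) found.
    """
    n = len(A)
    d0 = tm_d0(L_norm)
    best_tm = -1.0
    best_R = np.eye(3)
    best_t = np.zeros(3)
    seeds: list[np.ndarray] = [np.arange(n)]
    for frag in (n // 2, n // 4):
        if frag >= 3:
            seeds.append(np.arange(frag))
            seeds.append(np.arange(n - frag, n))
            seeds.append(np.arange((n - frag) // 2, (n - frag) // 2 + frag))
    for seed in seeds:
        subset = seed
        d_cut = max(d0, 3.5)
        for _ in range(MAX_ROUNDS):
            if len(subset) < 3:
                break
            sup = kabsch(A[subset], B[subset])
            d = np.linalg.norm(sup.transform(B) - A, axis=1)
            tm = _tm_from_distances(d, L_norm)
            if tm > best_tm:
                best_tm = tm
                best_R, best_t = sup.rotation, sup.translation
            new_subset = np.flatnonzero(d < d_cut)
            if len(new_subset) < 3:
                d_cut += 0.5
                continue
            if len(new_subset) == len(subset) and np.array_equal(new_subset, subset):
                break
            subset = new_subset
    return best_tm, best_R, best_t


def tm_score(
    trace_a: CaTrace,
    trace_b: CaTrace,
    correspondence: list[tuple[int, int]] | np.ndarray,
    normalize_by: str = "a",
) -> float:
    """TM-score of a fixed residue correspondence, optimally superposed.

    TM = (1/L_norm) Σ 1/(1+(d_i/d0)²) with d0 from the normalizing
    length.  The superposition maximizing TM is approximated by
    iterative Kabsch fits on shrinking well-fitting subsets; the best
    TM over all rounds is returned.
    """
    corr = np.asarray(correspondence, dtype=np.int64)
    if corr.size == 0:
        warnings.warn("empty correspondence; TM-score 0")
        return 0.0
    if normalize_by not in ("a", "b"):
        raise ValueError("normalize_by must be 'a' or 'b'")
    L_norm = trace_a.L if normalize_by == "a" else trace_b.L
    A = trace_a.coords[corr[:, 0] - 1]
    B = trace_b.coords[corr[:, 1] - 1]
    if len(corr) < 3:
        # too small for a rigid fit; score the raw coordinates
        d = np.linalg.norm(A - B, axis=1)
        return _tm_from_distances(d, L_norm)
    tm, _, _ = _tm_optimal_fit(A, B, L_norm)
    return tm


def _correspondence_from_superposition(
    A: np.ndarray, B_moved: np.ndarray, d0: float
) -> np.ndarray:
    """Rebuild a sequence-order correspondence by DP on the distance matrix."""
    diff = A[:, None, :] - B_moved[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    S = 1.0 / (1.0 + (dist / d0) ** 2)
    _, pairs = _kernels.nw_linear(S, DP_GAP)
    return pairs


def _gapless_seeds(La: int, Lb: int) -> list[np.ndarray]:
    """Diagonal correspondences at a few offsets (0-based pair arrays)."""
    n = min(La, Lb)
    seeds = []
    offsets = {0, (Lb - La) // 2, Lb - La} if La != Lb else {0}
    span = max(La, Lb) - n
    offsets |= {-span // 2, span // 2}
    for off in sorted(offsets):
        i0 = max(0, -off)
        j0 = max(0, off)
        m = min(La - i0, Lb - j0)
        if m >= 5:
            seeds.append(np.stack([np.arange(i0, i0 + m), np.arange(j0, j0 + m)], axis=1))
    return seeds


def _ss_seed(trace_a: CaTrace, trace_b: CaTrace) -> np.ndarray | None:
    """Seed correspondence from a DP over secondary-structure matches."""
    from .structio import assign_secondary_structure

    ss_a = trace_a.ss or assign_secondary_structure(trace_a)
    ss_b = trace_b.ss or assign_secondary_structure(trace_b)
    a = np.frombuffer(ss_a.encode(), dtype=np.uint8)
    b = np.frombuffer(ss_b.encode(), dtype=np.uint8)
    S = (a[:, None] == b[None, :]).astype(np.float64)
    _, pairs = _kernels.nw_linear(S, 0.5)
    return pairs if len(pairs) >= 5 else None


def structural_align(trace_a: CaTrace, trace_b: CaTrace) -> Superposition:
    """Sequence-order-preserving structural alignment maximizing TM-score.

    Several seed correspondences (gapless diagonals, fragment
    superpositions, a secondary-structure DP) are each refined by
    alternating (Kabsch fit on current pairs) with (correspondence
    rebuild by DP on the transformed distance matrix, cell score
    1/(1+(d/d0)²), linear gap 0.6) until the correspondence is stable or
    20 rounds pass.  The result with the best TM-score normalized by a
    is returned; the stored rotation/translation is the full-
    correspondence Kabsch fit of b onto a.
    """
    if trace_a.L < 5 or trace_b.L < 5:
        raise AlignmentFailure("both structures must have at least 5 residues")
    A, B = trace_a.coords, trace_b.coords
    d0 = tm_d0(trace_a.L)

    seeds = _gapless_seeds(trace_a.L, trace_b.L)
    ss_pairs = _ss_seed(trace_a, trace_b)
    if ss_pairs is not None:
        seeds.append(ss_pairs)

    best_corr: np.ndarray | None = None
    best_tm = -1.0
    for seed in seeds:
        corr = seed
        for _ in range(MAX_ROUNDS):
            if len(corr) < 3:
                break
            sup = kabsch(A[corr[:, 0]], B[corr[:, 1]])
            new_corr = _correspondence_from_superposition(A, sup.transform(B), d0)
            if len(new_corr) == len(corr) and np.array_equal(new_corr, corr):
                break
            corr = new_corr
        if len(corr) < 5:
            continue
        sup = kabsch(A[corr[:, 0]], B[corr[:, 1]])
        d = np.linalg.norm(sup.transform(B[corr[:, 1]]) - A[corr[:, 0]], axis=1)
        tm = float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / trace_a.L)
        if tm > best_tm:
            best_tm = tm
            best_corr = corr
    if best_corr is None or len(best_corr) < 5:
        raise AlignmentFailure(
            f"no correspondence of length ≥5 between {trace_a.id} and {trace_b.id}"
        )
    corr1 = [(int(i) + 1, int(j) + 1) for i, j in best_corr]
    Ac = A[best_corr[:, 0]]
    Bc = B[best_corr[:, 1]]
    # report the TM-optimal transform (fit on the well-matching subset),
    # not the full-correspondence least-squares fit, so divergent regions
    # do not drag the frame away from the conserved core
    tm_a, R, t = _tm_optimal_fit(Ac, Bc, trace_a.L)
    moved = Ac - (Bc @ R.T + t)
    sup = Superposition(
        rotation=R,
        translation=t,
        correspondence=corr1,
        rmsd=float(np.sqrt(np.mean(np.sum(moved**2, axis=1)))),
        tm_score_by_a=tm_a,
        tm_score_by_b=tm_score(trace_a, trace_b, corr1, normalize_by="b"),
    )
    return sup
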