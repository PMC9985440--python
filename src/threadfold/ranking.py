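"""Template quality scoring and final ranking.

The deviation-matrix score (DMScore) summarizes an L×L matrix of
pairwise distance deviations into (0, 1], normalizing each term by the
logarithm of the sequence separation so the score does not inherit a
trivial dependence on protein size.  A deterministic geometric
surrogate stands in for a learned deviation predictor behind a simple
scorer interface, and the final ranking fuses alignment score and
predicted quality:

    rankScore = alignScore² + (1 − alignScore) · pDMScore

so high-confidence alignments dominate their own ranking while weak
alignments defer to the structure-quality estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .profiles import DistanceProfile, peakset_from_profile
from .structio import CaTrace
from .threetrack import AlignmentResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DMScoreParams:
    """epsilon keeps the log separation scale finite at |i−j| = 1."""

    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class RankedTemplate:
    template_id: str
    alignScore: float
    pDMScore: float
    rankScore: float


def dm_score(
    deviations: np.ndarray,
    params: DMScoreParams = DMScoreParams(),
    valid: np.ndarray | None = None,
) -> float:
    """Deviation-matrix quality score in (0, 1].

    score = (1/N) Σ_{i≠j} 1 / (1 + (d_ij / d*)²),  d* = log(ε + |i−j|)

    with N the number of contributing off-diagonal entries (L(L−1) for
    a full matrix; a boolean ``valid`` mask restricts the sum, used
    when some pairs carry no deviation estimate).  Note d* ≈ 0 at
    |i−j| = 1, so adjacent pairs contribute ≈0 unless their deviation
    is exactly 0 — the formula's literal small-separation behaviour.
    """
    D = np.asarray(deviations, dtype=np.float64)
    L = D.shape[0]
    if D.ndim != 2 or D.shape[1] != L:
        raise ValueError("deviation matrix must be square")
    if L < 2:
        raise ValueError("need at least 2 residues")
    if np.any(D < 0):
        raise ValueError("deviations must be nonnegative")
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    off = sep > 0
    if valid is not None:
        off = off & np.asarray(valid, dtype=bool)
        if not np.any(off):
            raise ValueError("no valid off-diagonal entries")
    d_star = np.log(params.epsilon + sep[off])
    terms = 1.0 / (1.0 + (D[off] / d_star) ** 2)
    return float(terms.mean())


def surrogate_pdmscore(
    template: CaTrace,
    alignment: AlignmentResult,
    query_profile: DistanceProfile,
    params: DMScoreParams = DMScoreParams(),
    k_peaks: int = 3,
    p_min: float = 0.05,
) -> float:
    """Deterministic geometric quality estimate in (0, 1).

    For every pair of aligned residues the deviation estimate is the
    absolute difference between the template's Cα distance and the
    nearest query peak distance for the corresponding query pair;
    pairs whose query histogram has no peak are excluded.  The
    deviation matrix, restricted to the aligned positions (consecutive
    indexing), is summarized by :func:`dm_score`.
    """
    if not alignment.pairs:
        warnings.warn("empty alignment; surrogate quality score 0")
        return 0.0
    qp = peakset_from_profile(query_profile, k=k_peaks, p_min=p_min)
    q_idx = np.array([p[0] for p in alignment.pairs]) - 1
    t_idx = np.array([p[1] for p in alignment.pairs]) - 1
    Xt = template.coords[t_idx]
    diff = Xt[:, None, :] - Xt[None, :, :]
    dt = np.sqrt(np.sum(diff * diff, axis=2))
    n = len(q_idx)
    dev = np.zeros((n, n))
    valid = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            kk = int(qp.npk[q_idx[a], q_idx[b]])
            if kk == 0:
                continue
            peaks = qp.dist[q_idx[a], q_idx[b], :kk]
            dev[a, b] = np.min(np.abs(dt[a, b] - peaks))
            valid[a, b] = True
    if not np.any(valid):
        warnings.warn("no scorable aligned pairs; surrogate quality score 0")
        return 0.0
    if n < 2:
        return 0.0
    return dm_score(dev, params, valid=valid)


def rank_score(align_score: float, pdm_score: float) -> float:
    """Fusion of alignment score and predicted quality."""
    return align_score * align_score + (1.0 - align_score) * pdm_score


def rank_templates(
    candidates: Sequence[tuple[str, float, float]],
) -> list[RankedTemplate]:
    """Rank (template_id, alignScore, pDMScore) triples by rankScore.

    Ties break by higher alignScore, then id lexicographic.
    """
    ranked = [
        RankedTemplate(tid, a, p, rank_score(a, p)) for tid, a, p in candidates
    ]
    ranked.sort(key=lambda r: (-r.rankScore, -r.alignScore, r.template_id))
    return ranked


Scorer = Callable[[CaTrace, AlignmentResult, DistanceProfile], float]


def score_and_rank(
    results: Sequence[tuple[str, AlignmentResult]],
    traces: dict[str, CaTrace],
    query_profile: DistanceProfile,
    n_pdm: int = 10,
    scorer: Scorer | None = None,
) -> list[RankedTemplate]:
    """Apply the top-N quality-scoring protocol and rank.

    Only the ``n_pdm`` best templates by alignScore receive a quality
    score (the learned predictor is expensive in the original design);
    the rest keep rankScore = alignScore².  Any callable emitting a
    score in (0, 1) can replace the built-in surrogate.
    """
    scorer = scorer or (
        lambda tr, al, prof: surrogate_pdmscore(tr, al, prof)
    )
    by_align = sorted(results, key=lambda t: (-t[1].alignScore, t[0]))
    triples: list[tuple[str, float, float]] = []
    for rank, (tid, res) in enumerate(by_align):
        if rank < n_pdm:
            pdm = float(scorer(traces[tid], res, query_profile))
        else:
            pdm = 0.0
        triples.append((tid, res.alignScore, pdm))
    return rank_templates(triples)
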