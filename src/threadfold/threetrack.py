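"""Three-track alignment of distance profiles against structure profiles.

The alignment score of a query *a* against a template *b* is

    alignScore(a, b) = (S_align + S_gap) / S_tot

where S_align sums, over aligned residue pairs, the best product of a
query peak probability, a template peak probability, a sequence-
separation weight, a distance-difference weight and a distance cut-off
weight; S_gap penalizes gaps; and S_tot is the same sum evaluated on
the query profile alone (its own top probabilities, cut evaluated on
the query side), so a perfect gap-free self-match scores exactly 1.

The three tracks are realized in one pass: the innermost peak-product
term scores a (query pair, template pair) hypothesis; a second-level
dynamic programme over the contact partners of each residue pair fills
the protein-specific score matrix M; a global affine-gap dynamic
programme over M produces the sequence alignment.  Template search over
a clustered library is two-stage: cluster seeds first (multi-peak
structure profiles), then the members of the best clusters
(single-structure point-mass profiles).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .masterdb import ClusterLibrary
from .profiles import (
    DistanceProfile,
    PeakSet,
    StructureProfile,
    peakset_from_profile,
    profile_from_structure,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentParams:
    """Tunable knobs of the three-track alignment.

    ``lambda_cut`` (Å) discards residue pairs whose selected peaks reach
    that far; ``k_a``/``k_b`` cap how many peaks the query and template
    sides contribute; the gap model is affine.  The piecewise weights
    reward long sequence separations and small query/template distance
    differences.
    """

    lambda_cut: float = 20.0
    k_a: int = 3
    k_b: int = 2
    p_min: float = 0.05
    gap_open: float = 1.0
    gap_extend: float = 0.1
    w_seq_breaks: tuple[float, float] = (12, 24)
    w_seq_values: tuple[float, float, float] = (0.5, 0.75, 1.0)
    w_dist_breaks: tuple[float, float] = (5.0, 8.0)
    w_dist_values: tuple[float, float, float] = (1.0, 0.5, 0.25)
    n_clu: int = 10
    n_pdm: int = 10

    def w_seq(self, sep: int) -> float:
        """Sequence-separation weight (long range counts more)."""
        if sep < self.w_seq_breaks[0]:
            return self.w_seq_values[0]
        if sep < self.w_seq_breaks[1]:
            return self.w_seq_values[1]
        return self.w_seq_values[2]

    def w_dist(self, delta: float) -> float:
        """Distance-difference weight (closer peak distances count more)."""
        if delta <= self.w_dist_breaks[0]:
            return self.w_dist_values[0]
        if delta <= self.w_dist_breaks[1]:
            return self.w_dist_values[1]
        return self.w_dist_values[2]

    def _kernel_args(self) -> tuple:
        return (
            self.lambda_cut,
            self.w_seq_breaks[0], self.w_seq_breaks[1], *self.w_seq_values,
            self.w_dist_breaks[0], self.w_dist_breaks[1], *self.w_dist_values,
        )


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class AlignmentResult:
    """Residue correspondence plus the score decomposition."""

    pairs: list[tuple[int, int]]
    S_align: float
    S_gap: float
    S_tot: float
    alignScore: float
    dp_score: float = 0.0
    n_gap_runs: int = 0
    n_gap_positions: int = 0
    score_matrix: np.ndarray | None = None

    @property
    def coverage(self) -> int:
        return len(self.pairs)


def pair_term(
    query_peaks: list[tuple[float, float]],
    template_peaks: list[tuple[float, float]],
    sep: int,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> float:
    """Best peak-product score of one (query pair, template pair) hypothesis.

    Peaks are (distance Å, probability) tuples.  The cut weight vanishes
    unless the largest selected peak distance on *both* sides is below
    ``lambda_cut``; otherwise the term is the max over peak combinations
    of p·q·w_seq·w_dist.
    """
    if not query_peaks or not template_peaks:
        return 0.0
    Da = max(d for d, _ in query_peaks)
    Db = max(d for d, _ in template_peaks)
    if Da >= params.lambda_cut or Db >= params.lambda_cut:
        return 0.0
    ws = params.w_seq(sep)
    return max(
        p * q * ws * params.w_dist(abs(da - db))
        for da, p in query_peaks
        for db, q in template_peaks
    )


def residue_pair_align(
    query_peaks: PeakSet,
    template_peaks: PeakSet,
    n: int,
    n_t: int,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> float:
    """Score of the hypothesis that query residue n matches template residue n_t.

    A monotone dynamic programme (gaps free) aligns the ordered contact
    partners of n against those of n_t, each cell scored by
    :func:`pair_term`; the optimal total fills the protein-specific
    score matrix at [n, n_t].  Indices are 1-based.
    """
    M = _score_submatrix(query_peaks, template_peaks, params, rows=[n - 1], cols=[n_t - 1])
    return float(M[0, 0])


def _score_submatrix(qp: PeakSet, tp: PeakSet, params, rows=None, cols=None) -> np.ndarray:
    q_ptr, q_idx = _kernels.build_contacts(qp.npk, qp.D, params.lambda_cut)
    t_ptr, t_idx = _kernels.build_contacts(tp.npk, tp.D, params.lambda_cut)
    M = _kernels.score_matrix(
        qp.dist, qp.prob, qp.npk, qp.D, q_ptr, q_idx,
        tp.dist, tp.prob, tp.npk, tp.D, t_ptr, t_idx,
        *params._kernel_args(),
    )
    if rows is not None:
        M = M[np.ix_(rows, cols)]
    return M


def score_matrix(
    query_peaks: PeakSet,
    template_peaks: PeakSet,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> np.ndarray:
    """Full protein-specific score matrix M (L_query × L_template)."""
    return _score_submatrix(query_peaks, template_peaks, params)


def sequence_align(
    M: np.ndarray,
    params: AlignmentParams = DEFAULT_PARAMS,
    query_peaks: PeakSet | None = None,
    template_peaks: PeakSet | None = None,
    keep_matrix: bool = False,
) -> AlignmentResult:
    """Global affine-gap alignment over the score matrix M.

    When the peak sets are supplied, S_align is recomputed over the
    aligned pairs from the peak-product terms, S_tot from the query
    profile alone, and alignScore = (S_align + S_gap)/S_tot.  Without
    peak sets (raw-matrix mode, used for dynamic-programming checks)
    S_align is the sum of M over the aligned pairs and the normalizer
    is 1.
    """
    M = np.asarray(M, dtype=np.float64)
    if not np.all(np.isfinite(M)):
        raise ValueError("score matrix must be finite")
    dp_score, pairs0, n_runs, n_gap = _kernels.nw_affine(
        M, params.gap_open, params.gap_extend
    )
    S_gap = -(params.gap_open * n_runs + params.gap_extend * n_gap)
    if query_peaks is not None and template_peaks is not None:
        S_align = float(
            _kernels.s_align_sum(
                pairs0,
                query_peaks.dist, query_peaks.prob, query_peaks.npk, query_peaks.D,
                template_peaks.dist, template_peaks.prob, template_peaks.npk,
                template_peaks.D,
                *params._kernel_args(),
            )
        )
        S_tot = float(
            _kernels.s_tot_sum(
                query_peaks.pmax, query_peaks.npk, query_peaks.D,
                params.lambda_cut,
                params.w_seq_breaks[0], params.w_seq_breaks[1], *params.w_seq_values,
            )
        )
        if S_align == 0.0 or S_tot <= 0.0:
            return AlignmentResult(
                pairs=[], S_align=0.0, S_gap=0.0, S_tot=max(S_tot, 1.0),
                alignScore=0.0, dp_score=float(dp_score),
                score_matrix=M if keep_matrix else None,
            )
    else:
        S_align = float(M[pairs0[:, 0], pairs0[:, 1]].sum()) if len(pairs0) else 0.0
        S_tot = 1.0
        if S_align == 0.0:
            return AlignmentResult(
                pairs=[], S_align=0.0, S_gap=0.0, S_tot=1.0, alignScore=0.0,
                dp_score=float(dp_score), score_matrix=M if keep_matrix else None,
            )
    align_score = (S_align + S_gap) / S_tot
    return AlignmentResult(
        pairs=[(int(i) + 1, int(j) + 1) for i, j in pairs0],
        S_align=S_align,
        S_gap=S_gap,
        S_tot=S_tot,
        alignScore=align_score,
        dp_score=float(dp_score),
        n_gap_runs=int(n_runs),
        n_gap_positions=int(n_gap),
        score_matrix=M if keep_matrix else None,
    )


def three_track_align(
    query_peaks: PeakSet,
    template_peaks: PeakSet,
    params: AlignmentParams = DEFAULT_PARAMS,
    keep_matrix: bool = False,
) -> AlignmentResult:
    """Full three-track alignment of precomputed peak sets."""
    M = score_matrix(query_peaks, template_peaks, params)
    return sequence_align(
        M, params, query_peaks=query_peaks, template_peaks=template_peaks,
        keep_matrix=keep_matrix,
    )


def query_peakset(profile: DistanceProfile, params: AlignmentParams = DEFAULT_PARAMS) -> PeakSet:
    return peakset_from_profile(profile, k=params.k_a, p_min=params.p_min)


def template_peakset(
    profile: StructureProfile | DistanceProfile,
    params: AlignmentParams = DEFAULT_PARAMS,
    single_peak: bool = False,
) -> PeakSet:
    k = 1 if single_peak else params.k_b
    return peakset_from_profile(profile, k=k, p_min=params.p_min if not single_peak else 0.0)


def search_templates(
    query_profile: DistanceProfile,
    library: ClusterLibrary,
    params: AlignmentParams = DEFAULT_PARAMS,
    member_peak_cache: dict | None = None,
) -> list[tuple[str, AlignmentResult]]:
    """Two-stage template search over a clustered library.

    Stage 1 aligns the query against every cluster seed's multi-peak
    structure profile and keeps the best ``n_clu`` clusters by
    alignScore.  Stage 2 aligns the query against every member of those
    clusters using single-peak point-mass profiles of the member
    structures, and returns all scored members sorted by alignScore
    descending (ties: id).
    """
    if library.n_clusters == 0:
        raise ValueError("empty template library")
    qp = query_peakset(query_profile, params)

    stage1: list[tuple[float, int]] = []
    for k, cluster in enumerate(library.clusters):
        prof = library.profiles.get(cluster.seed_id)
        if prof is None:
            raise ValueError(f"cluster seed {cluster.seed_id} has no structure profile")
        res = three_track_align(qp, template_peakset(prof, params), params)
        stage1.append((res.alignScore, k))
    stage1.sort(key=lambda t: (-t[0], library.clusters[t[1]].seed_id))
    kept = [k for _, k in stage1[: params.n_clu]]

    cache = member_peak_cache if member_peak_cache is not None else {}
    results: list[tuple[str, AlignmentResult]] = []
    for k in kept:
        for mid in library.clusters[k].member_ids:
            tp = cache.get(mid)
            if tp is None:
                prof = profile_from_structure(library.traces[mid], smear_sigma=0.0)
                tp = template_peakset(prof, params, single_peak=True)
                cache[mid] = tp
            res = three_track_align(qp, tp, params)
            results.append((mid, res))
    results.sort(key=lambda t: (-t[1].alignScore, t[0]))
    return results


# ---------------------------------------------------------------------------
# FASTA-like paired-gapped alignment output

def format_alignment(
    result: AlignmentResult,
    query_id: str,
    template_id: str,
    query_len: int,
    template_len: int,
) -> str:
    """Render an alignment as a paired gapped FASTA-like block.

    Residues are written as their 1-based positions where aligned and
    '-' where gapped, in a columnar layout shared by the two records.
    """
    cols: list[tuple[str, str]] = []
    qi, ti = 1, 1
    for q, t in result.pairs:
        while qi < q:
            cols.append((str(qi), "-"))
            qi += 1
        while ti < t:
            cols.append(("-", str(ti)))
            ti += 1
        cols.append((str(q), str(t)))
        qi, ti = q + 1, t + 1
    while qi <= query_len:
        cols.append((str(qi), "-"))
        qi += 1
    while ti <= template_len:
        cols.append(("-", str(ti)))
        ti += 1
    qline = " ".join(c[0] for c in cols)
    tline = " ".join(c[1] for c in cols)
    return (
        f">{query_id} alignScore={result.alignScore:.4f}\n{qline}\n"
        f">{template_id}\n{tline}\n"
    )


def parse_alignment(text: str) -> list[tuple[int, int]]:
    """Parse the paired-gapped format back into 1-based pairs."""
    lines = [l for l in text.strip().splitlines() if l and not l.startswith(">")]
    if len(lines) != 2:
        raise ValueError("expected exactly two gapped position lines")
    qcols = lines[0].split()
    tcols = lines[1].split()
    if len(qcols) != len(tcols):
        raise ValueError("ragged alignment block")
    return [
        (int(q), int(t)) for q, t in zip(qcols, tcols) if q != "-" and t != "-"
    ]
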