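"""Folding-pathway inference from remote-homolog residue frequencies.

The working hypothesis: regions that superpose consistently across many
remote homologs are the evolutionarily conserved structural core, and
such cores tend to form early in folding.  Each target residue gets a
frequency score (ResFscore) from how closely the homologs place it
after global structural superposition; the target is segmented by
secondary structure, segments are ranked by average score, and an
adaptively thresholded subset is proposed as the folding intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structio import CaTrace, assign_secondary_structure
from .superpose import AlignmentFailure, structural_align

logger = logging.getLogger(__name__)

# per-residue contribution as a function of post-superposition deviation
RESF_THRESHOLDS = ((2.0, 1.0), (4.0, 0.75), (5.0, 0.25))


@dataclass(frozen=True)
class PathwayParams:
    """Intermediate-selection knobs.

    ``i_cut`` is the initial segment-average threshold, adapted in
    ``step`` increments until the selected length falls inside
    [``window_lo``·L, ``window_hi``·L]; ``n_t`` caps how many templates
    feed the frequency track.
    """

    i_cut: float = 0.4
    step: float = 0.02
    window_lo: float = 0.25
    window_hi: float = 0.75
    n_t: int = 50
    max_steps: int = 50


@dataclass
class ResidueFrequencyTrack:
    """Per-residue conservation frequencies over a template ensemble."""

    resfscore: np.ndarray
    per_template_scores: np.ndarray  # (N_t, L)

    @property
    def L(self) -> int:
        return self.resfscore.shape[0]

    @property
    def N_t(self) -> int:
        return self.per_template_scores.shape[0]


@dataclass
class Segment:
    start: int  # 1-based inclusive
    end: int
    ss_type: str
    avg: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentTable:
    segments: list[Segment] = field(default_factory=list)

    def __iter__(self):
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def total_length(self, mask: np.ndarray | None = None) -> int:
        segs = self.segments if mask is None else [s for s, m in zip(self.segments, mask) if m]
        return sum(s.length for s in segs)


def residue_score(d: float) -> float:
    """Per-template residue contribution from its deviation after superposition."""
    for cut, val in RESF_THRESHOLDS:
        if d <= cut:
            return val
    return 0.0


def residue_frequency(
    target: CaTrace,
    templates: list[CaTrace],
    params: PathwayParams = PathwayParams(),
) -> ResidueFrequencyTrack:
    """Residue-frequency track of the target over a homolog ensemble.

    Each template is structurally aligned and superposed onto the
    target; a target residue aligned at deviation d contributes 1
    (d ≤ 2 Å), 0.75 (≤4 Å), 0.25 (≤5 Å) or 0, and unaligned residues
    contribute 0.  The track is the per-residue mean over templates
    (templates that fail to align are dropped).
    """
    if not templates:
        raise ValueError("need at least one template")
    use = templates[: params.n_t]
    L = target.L
    rows: list[np.ndarray] = []
    for tmpl in use:
        row = np.zeros(L)
        try:
            sup = structural_align(target, tmpl)
        except AlignmentFailure:
            logger.warning("template %s failed to align; dropped", tmpl.id)
            continue
        moved = sup.transform(tmpl.coords)
        for i, j in sup.correspondence:
            d = float(np.linalg.norm(target.coords[i - 1] - moved[j - 1]))
            row[i - 1] = residue_score(d)
        rows.append(row)
    if not rows:
        raise ValueError("no template could be aligned to the target")
    per_template = np.vstack(rows)
    return ResidueFrequencyTrack(
        resfscore=per_template.mean(axis=0), per_template_scores=per_template
    )


def segment_target(target: CaTrace) -> SegmentTable:
    """Partition the target into secondary-structure segments.

    Maximal runs of one SS type; loop runs of ≤4 residues are merged
    into the preceding helix/sheet segment when one exists (else the
    following), keeping the structured type.
    """
    ss = target.ss or assign_secondary_structure(target)
    runs: list[Segment] = []
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            runs.append(Segment(start=start + 1, end=i, ss_type=ss[start]))
            start = i
    merged: list[Segment] = []
    pending_loop: Segment | None = None
    for seg in runs:
        if seg.ss_type == "C" and seg.length <= 4:
            if merged and merged[-1].ss_type != "C":
                merged[-1] = Segment(
                    start=merged[-1].start, end=seg.end, ss_type=merged[-1].ss_type
                )
            else:
                pending_loop = seg  # merge forward into the next structured segment
            continue
        if pending_loop is not None:
            if seg.ss_type != "C":
                seg = Segment(start=pending_loop.start, end=seg.end, ss_type=seg.ss_type)
            else:
                seg = Segment(start=pending_loop.start, end=seg.end, ss_type="C")
            pending_loop = None
        merged.append(seg)
    if pending_loop is not None:
        # trailing short loop with no structured neighbour after it
        if merged and merged[-1].ss_type != "C":
            merged[-1] = Segment(
                start=merged[-1].start, end=pending_loop.end, ss_type=merged[-1].ss_type
            )
        else:
            merged.append(pending_loop)
    return SegmentTable(segments=merged)


def average_segments(track: ResidueFrequencyTrack, segments: SegmentTable) -> SegmentTable:
    """Fill each segment's average residue-frequency score."""
    out = []
    for seg in segments:
        avg = float(track.resfscore[seg.start - 1 : seg.end].mean())
        out.append(Segment(start=seg.start, end=seg.end, ss_type=seg.ss_type, avg=avg))
    return SegmentTable(segments=out)


@dataclass
class IntermediateSelection:
    mask: np.ndarray  # per segment
    i_cut: float
    feasible: bool
    n_steps: int

    def selected(self, segments: SegmentTable) -> list[Segment]:
        return [s for s, m in zip(segments, self.mask) if m]


def _selection_at(segments: SegmentTable, i_cut: float) -> np.ndarray:
    return np.array([s.avg >= i_cut for s in segments], dtype=bool)


def select_intermediate(
    segments: SegmentTable,
    L: int,
    params: PathwayParams = PathwayParams(),
) -> IntermediateSelection:
    """Adaptive intermediate selection.

    Segments with average score ≥ I_cut are selected.  If the selected
    length leaves the window [window_lo·L, window_hi·L], I_cut walks in
    0.02 steps (up when too long, down when too short — selected length
    is monotone non-increasing in I_cut, so the walk is directed) for at
    most ``max_steps`` steps.  If the walk fails but some threshold does
    yield an in-window selection, the selection changes only at the
    distinct segment averages, so a sweep over those values finds it;
    if no threshold works at all, the best-effort threshold minimizing
    the distance of the selected length to the window is returned with
    ``feasible=False``.
    """
    if len(segments) == 0:
        raise ValueError("empty segment table")
    lo = params.window_lo * L
    hi = params.window_hi * L
    i_cut = params.i_cut
    n_steps = 0
    direction = 0
    for n_steps in range(params.max_steps + 1):
        mask = _selection_at(segments, i_cut)
        total = segments.total_length(mask)
        if lo <= total <= hi:
            return IntermediateSelection(mask=mask, i_cut=i_cut, feasible=True, n_steps=n_steps)
        new_dir = 1 if total > hi else -1
        if direction and new_dir != direction:
            break  # the 0.02 grid stepped over the window
        direction = new_dir
        i_cut += params.step * new_dir
        if i_cut < 0.0 or i_cut > 1.0:
            break
    # exhaustive sweep over the thresholds where the selection changes
    candidates = sorted({s.avg for s in segments} | {0.0, 1.0})
    best = None
    for c in candidates:
        mask = _selection_at(segments, c)
        total = segments.total_length(mask)
        if lo <= total <= hi:
            return IntermediateSelection(mask=mask, i_cut=c, feasible=True, n_steps=n_steps)
        dist = lo - total if total < lo else total - hi
        if best is None or dist < best[0]:
            best = (dist, c, mask)
    assert best is not None
    return IntermediateSelection(mask=best[2], i_cut=best[1], feasible=False, n_steps=n_steps)


@dataclass
class FoldingPathway:
    """Ordered folding report: segments sorted by average conservation."""

    order: list[Segment]  # descending by avg
    intermediate: list[bool]  # aligned with order; True = in the intermediate
    track: ResidueFrequencyTrack
    i_cut: float
    feasible: bool

    def report(self) -> str:
        lines = ["# predicted folding order (earliest first)"]
        for rank, (seg, first) in enumerate(zip(self.order, self.intermediate), 1):
            tag = "intermediate" if first else "late"
            lines.append(
                f"{rank}\t{seg.ss_type}{seg.start}-{seg.end}\t"
                f"avg={seg.avg:.3f}\t{tag}"
            )
        lines.append(f"# I_cut={self.i_cut:.2f} feasible={self.feasible}")
        return "\n".join(lines)


def folding_order(
    segments: SegmentTable, selection: IntermediateSelection, track: ResidueFrequencyTrack
) -> FoldingPathway:
    """Sort segments by average score descending (tie: N-terminal first)."""
    idx = sorted(
        range(len(segments)),
        key=lambda k: (-segments.segments[k].avg, segments.segments[k].start),
    )
    return FoldingPathway(
        order=[segments.segments[k] for k in idx],
        intermediate=[bool(selection.mask[k]) for k in idx],
        track=track,
        i_cut=selection.i_cut,
        feasible=selection.feasible,
    )


def infer_pathway(
    target: CaTrace,
    templates: list[CaTrace],
    params: PathwayParams = PathwayParams(),
) -> tuple[FoldingPathway, SegmentTable]:
    """End-to-end pathway inference for one target."""
    track = residue_frequency(target, templates, params)
    segments = average_segments(track, segment_target(target))
    selection = select_intermediate(segments, target.L, params)
    return folding_order(segments, selection, track), segments
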