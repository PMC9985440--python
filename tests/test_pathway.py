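"""Residue-frequency tracks, segmentation, intermediate selection, ordering."""

import dataclasses

import numpy as np
import pytest

from threadfold.pathway import (
    PathwayParams,
    ResidueFrequencyTrack,
    Segment,
    SegmentTable,
    average_segments,
    folding_order,
    infer_pathway,
    residue_frequency,
    residue_score,
    segment_target,
    select_intermediate,
)
from threadfold.structio import CaTrace
from threadfold.synthgen import SynthSpec, make_family, make_structure


def ss_trace(ss: str) -> CaTrace:
    """Trace with prescribed secondary structure on a straight backbone."""
    L = len(ss)
    coords = np.zeros((L, 3))
    coords[:, 0] = 3.8 * np.arange(L)
    return CaTrace(id="ss", res_names=["GLY"] * L, seq_pos=np.arange(1, L + 1),
                   coords=coords, ss=ss)


def table(avgs, lengths=None, types=None) -> tuple[SegmentTable, int]:
    lengths = lengths or [10] * len(avgs)
    types = types or ["H"] * len(avgs)
    segs, pos = [], 1
    for avg, length, t in zip(avgs, lengths, types):
        segs.append(Segment(start=pos, end=pos + length - 1, ss_type=t, avg=avg))
        pos += length
    return SegmentTable(segments=segs), pos - 1


class TestResidueFrequency:
    @pytest.mark.parametrize(
        "d,score",
        [(0.0, 1.0), (2.0, 1.0), (2.0001, 0.75), (4.0, 0.75), (4.0001, 0.25),
         (5.0, 0.25), (5.0001, 0.0), (12.0, 0.0)],
    )
    def test_deviation_thresholds(self, d, score):
        assert residue_score(d) == score

    def test_exact_copies_score_one_everywhere(self, small_trace):
        copies = [dataclasses.replace(small_trace, id=f"t{k}") for k in range(3)]
        track = residue_frequency(small_trace, copies)
        np.testing.assert_allclose(track.resfscore, 1.0)
        assert track.N_t == 3

    def test_track_is_mean_of_per_template_scores(self, small_trace):
        rng = np.random.default_rng(8)
        templates = [
            dataclasses.replace(
                small_trace, id=f"n{k}",
                coords=small_trace.coords + rng.normal(scale=0.8, size=small_trace.coords.shape),
            )
            for k in range(4)
        ]
        track = residue_frequency(small_trace, templates)
        np.testing.assert_allclose(
            track.resfscore, track.per_template_scores.mean(axis=0), atol=1e-12
        )
        assert set(np.unique(track.per_template_scores)) <= {0.0, 0.25, 0.75, 1.0}

    def test_two_template_average(self):
        per = np.array([[1.0, 0.75], [0.75, 0.25]])
        track = ResidueFrequencyTrack(resfscore=per.mean(axis=0), per_template_scores=per)
        assert track.resfscore[0] == pytest.approx(0.875)


class TestSegmentation:
    def test_short_loop_merges_into_preceding_helix(self):
        t = ss_trace("HHHHHCCEEEE")
        segs = segment_target(t).segments
        assert [(s.ss_type, s.start, s.end) for s in segs] == [("H", 1, 7), ("E", 8, 11)]

    def test_pure_loop_kept(self):
        segs = segment_target(ss_trace("CCCCCC")).segments
        assert [(s.ss_type, s.start, s.end) for s in segs] == [("C", 1, 6)]

    def test_long_loop_retained(self):
        segs = segment_target(ss_trace("HHHHHCCCCCCEEEE")).segments
        assert [(s.ss_type, s.start, s.end) for s in segs] == [
            ("H", 1, 5), ("C", 6, 11), ("E", 12, 15)
        ]

    def test_leading_short_loop_merges_forward(self):
        segs = segment_target(ss_trace("CCHHHHH")).segments
        assert [(s.ss_type, s.start, s.end) for s in segs] == [("H", 1, 7)]

    def test_segments_partition_sequence(self):
        for ss in ("HHHHHCCEEEE", "CCHHHCCCCCEEECC", "EEEECCCCCHHHH"):
            segs = segment_target(ss_trace(ss)).segments
            covered = []
            for s in segs:
                covered.extend(range(s.start, s.end + 1))
            assert covered == list(range(1, len(ss) + 1))


class TestAveraging:
    def test_segment_average_arithmetic(self):
        track = ResidueFrequencyTrack(
            resfscore=np.array([1.0, 1.0, 0.5, 0.5]),
            per_template_scores=np.array([[1.0, 1.0, 0.5, 0.5]]),
        )
        segs, _ = table([np.nan], lengths=[4])
        out = average_segments(track, segs)
        assert out.segments[0].avg == pytest.approx(0.75)

    def test_uniform_track_gives_uniform_averages(self):
        track = ResidueFrequencyTrack(
            resfscore=np.full(20, 0.6), per_template_scores=np.full((1, 20), 0.6)
        )
        segs, _ = table([0, 0], lengths=[12, 8])
        out = average_segments(track, segs)
        assert all(s.avg == pytest.approx(0.6) for s in out)


class TestIntermediateSelection:
    def test_high_core_selected_at_initial_threshold(self):
        segs, L = table([0.9, 0.1], lengths=[10, 10])
        sel = select_intermediate(segs, L)
        assert sel.feasible and sel.i_cut == pytest.approx(0.4)
        assert list(sel.mask) == [True, False]
        assert sel.n_steps == 0

    def test_all_high_walks_up_and_flags_infeasible(self):
        segs, L = table([0.9, 0.9, 0.9])
        sel = select_intermediate(segs, L)
        assert not sel.feasible  # every threshold selects all or nothing

    def test_all_zero_walks_down_and_flags_infeasible(self):
        segs, L = table([0.0, 0.0])
        sel = select_intermediate(segs, L)
        assert not sel.feasible
        assert sel.n_steps <= PathwayParams().max_steps

    def test_selection_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        segs, L = table(list(rng.uniform(size=8)))
        prev = None
        for cut in np.linspace(0, 1, 21):
            mask = np.array([s.avg >= cut for s in segs])
            if prev is not None:
                assert not np.any(mask & ~prev)  # nothing newly selected as cut rises
            prev = mask
        # shrinking property drives the directed walk's termination
        totals = [
            sum(s.length for s in segs if s.avg >= cut) for cut in np.linspace(0, 1, 21)
        ]
        assert totals == sorted(totals, reverse=True)

    def test_grid_skip_falls_back_to_exhaustive(self):
        # the only in-window selection needs a threshold strictly between
        # two averages that the 0.02 walk from 0.4 never lands on
        segs, L = table([0.411, 0.413, 0.9], lengths=[4, 4, 12])
        sel = select_intermediate(segs, L)
        assert sel.feasible
        total = segs.total_length(sel.mask)
        assert 0.25 * L <= total <= 0.75 * L

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_intermediate(SegmentTable(segments=[]), 10)


class TestFoldingOrder:
    def test_sorted_by_average_descending(self):
        segs, L = table([0.9, 0.5, 0.2])
        sel = select_intermediate(segs, L)
        track = ResidueFrequencyTrack(
            resfscore=np.zeros(L), per_template_scores=np.zeros((1, L))
        )
        fp = folding_order(segs, sel, track)
        assert [s.avg for s in fp.order] == [0.9, 0.5, 0.2]
        assert fp.intermediate[0] is True

    def test_tie_prefers_nterminal_segment(self):
        segs, L = table([0.5, 0.5])
        sel = select_intermediate(segs, L)
        track = ResidueFrequencyTrack(
            resfscore=np.zeros(L), per_template_scores=np.zeros((1, L))
        )
        fp = folding_order(segs, sel, track)
        assert fp.order[0].start == 1

    def test_single_segment_is_first(self):
        segs, L = table([0.4], lengths=[10])
        sel = select_intermediate(segs, L)
        track = ResidueFrequencyTrack(
            resfscore=np.zeros(L), per_template_scores=np.zeros((1, L))
        )
        fp = folding_order(segs, sel, track)
        assert len(fp.order) == 1
        report = fp.report()
        assert "H1-10" in report


class TestPlantedCore:
    def test_conserved_core_recovered(self):
        spec = SynthSpec(
            seed=99,
            topology=(("H", 14), ("C", 3), ("H", 14), ("C", 3), ("H", 14),
                      ("C", 6), ("E", 9), ("C", 6), ("E", 9)),
            coordinate_noise=0.5,
            n_members=10,
            peripheral_divergence=30 / 78,
        )
        members, core_mask = make_family(spec)
        target = make_structure(spec, trace_id="target")
        fp, segments = infer_pathway(target, members)
        picked = np.zeros(target.L, dtype=bool)
        for seg, chosen in zip(fp.order, fp.intermediate):
            if chosen:
                picked[seg.start - 1 : seg.end] = True
        assert picked[core_mask].all()
        assert not picked[~core_mask].any()
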