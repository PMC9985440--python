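"""Three-track alignment: pair scoring, both DP levels, library search."""

import dataclasses

import numpy as np
import pytest

from threadfold import reference
from threadfold.masterdb import greedy_cluster
from threadfold.profiles import DistanceProfile, profile_from_structure
from threadfold.synthgen import make_fold_library, make_profile
from threadfold.threetrack import (
    DEFAULT_PARAMS,
    format_alignment,
    pair_term,
    parse_alignment,
    query_peakset,
    residue_pair_align,
    score_matrix,
    search_templates,
    sequence_align,
    template_peakset,
    three_track_align,
)


class TestPairTerm:
    def test_perfect_match_long_range(self):
        assert pair_term([(7.25, 1.0)], [(7.25, 1.0)], sep=30) == pytest.approx(1.0)

    def test_short_separation_halves(self):
        assert pair_term([(7.25, 1.0)], [(7.25, 1.0)], sep=5) == pytest.approx(0.5)

    @pytest.mark.parametrize("sep,w", [(11, 0.5), (12, 0.75), (23, 0.75), (24, 1.0)])
    def test_separation_weight_boundaries(self, sep, w):
        assert pair_term([(7.25, 1.0)], [(7.25, 1.0)], sep=sep) == pytest.approx(w)

    def test_distance_difference_weight(self):
        # peaks 7 Å apart fall in the middle weight branch
        assert pair_term([(7.25, 1.0)], [(14.25, 1.0)], sep=30) == pytest.approx(0.5)

    @pytest.mark.parametrize("delta,w", [(5.0, 1.0), (5.5, 0.5), (8.0, 0.5), (8.5, 0.25)])
    def test_distance_weight_boundaries(self, delta, w):
        assert pair_term([(10.25, 1.0)], [(10.25 + delta, 1.0)], sep=30) == pytest.approx(w)

    def test_cutoff_kills_far_top_peak(self):
        # a selected peak at 21 Å exceeds the 20 Å information cut-off
        assert pair_term([(21.0, 1.0)], [(7.25, 1.0)], sep=30) == 0.0
        assert pair_term([(7.25, 0.5), (21.0, 0.5)], [(7.25, 1.0)], sep=30) == 0.0

    def test_empty_peaks_score_zero(self):
        assert pair_term([], [(7.25, 1.0)], sep=30) == 0.0

    def test_max_over_peak_combinations(self):
        q = [(6.25, 0.6), (12.25, 0.4)]
        t = [(12.25, 1.0)]
        # combination (12.25, 0.4)·1·1·1 beats (6.25, 0.6)·1·0.5
        assert pair_term(q, t, sep=30) == pytest.approx(0.4)


class TestResiduePairAlign:
    def test_empty_contact_list_scores_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(25, 60, size=(5, 3))  # everything ≥20 Å apart is possible
        coords[0] = [0.0, 0.0, 0.0]
        from threadfold.structio import CaTrace

        t = CaTrace(id="far", res_names=["GLY"] * 5, seq_pos=np.arange(1, 6), coords=coords)
        prof = profile_from_structure(t, smear_sigma=0.0)
        qp = query_peakset(prof)
        if qp.npk[0].sum() == 0:  # residue 1 has no in-range contacts
            assert residue_pair_align(qp, qp, 1, 1) == 0.0

    def test_toy_matches_exhaustive_matching(self):
        # three partners each with hand-set peak products: the DP total must
        # equal the brute-force max over all ≤20 monotone matchings
        rng = np.random.default_rng(1)
        from threadfold.structio import CaTrace

        for trial in range(10):
            coords = rng.uniform(-8, 8, size=(5, 3))
            t = CaTrace(id="toy", res_names=["GLY"] * 5, seq_pos=np.arange(1, 6), coords=coords)
            qp = query_peakset(profile_from_structure(t, smear_sigma=0.0))
            coords2 = rng.uniform(-8, 8, size=(5, 3))
            t2 = CaTrace(id="toy2", res_names=["GLY"] * 5, seq_pos=np.arange(1, 6), coords=coords2)
            tp = template_peakset(profile_from_structure(t2, smear_sigma=0.0), single_peak=True)
            n, n2 = 2, 3
            q_contacts = [m for m in range(5) if m != n and qp.npk[n, m] > 0]
            t_contacts = [m for m in range(5) if m != n2 and tp.npk[n2, m] > 0]
            S = np.array(
                [[pair_term(qp.peaks(n + 1, m + 1), tp.peaks(n2 + 1, m2 + 1), abs(n - m))
                  for m2 in t_contacts] for m in q_contacts]
            ).reshape(len(q_contacts), len(t_contacts))
            oracle = reference.best_monotone_matching_bruteforce(S) if S.size else 0.0
            assert residue_pair_align(qp, tp, n + 1, n2 + 1) == pytest.approx(oracle, abs=1e-9)

    def test_self_consistency_diagonal_dominates(self, small_trace):
        prof = profile_from_structure(small_trace, smear_sigma=0.0)
        qp = query_peakset(prof)
        tp = template_peakset(prof, single_peak=True)
        M = score_matrix(qp, tp)
        diag_dominates = M.diagonal() >= M.max(axis=1) - 1e-12
        assert diag_dominates.mean() >= 0.95


class TestSequenceAlign:
    def test_diagonal_dominant_matrix_aligns_diagonally(self):
        M = np.eye(4)
        res = sequence_align(M)
        assert res.pairs == [(1, 1), (2, 2), (3, 3), (4, 4)]
        assert res.n_gap_positions == 0

    def test_matches_bruteforce_on_hand_matrix(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            M = rng.uniform(-0.5, 1.0, size=(5, 5))
            res = sequence_align(M)
            oracle = reference.best_alignment_bruteforce(
                M, DEFAULT_PARAMS.gap_open, DEFAULT_PARAMS.gap_extend
            )
            assert res.dp_score == pytest.approx(oracle, abs=1e-9)

    def test_ideal_self_alignment_scores_one(self, small_trace):
        prof = profile_from_structure(small_trace, smear_sigma=0.0)
        qp = query_peakset(prof)
        tp = template_peakset(prof, single_peak=True)
        res = three_track_align(qp, tp)
        assert res.alignScore == pytest.approx(1.0, abs=1e-6)
        assert res.S_gap == 0.0
        assert res.S_align == pytest.approx(res.S_tot)

    def test_score_identity_and_bounds(self, small_trace, mixed_trace):
        qprof = profile_from_structure(small_trace, smear_sigma=0.3)
        tprof = profile_from_structure(mixed_trace, smear_sigma=0.0)
        res = three_track_align(query_peakset(qprof), template_peakset(tprof, single_peak=True))
        assert res.alignScore == pytest.approx((res.S_align + res.S_gap) / res.S_tot, abs=1e-9)
        assert res.alignScore <= 1.0
        assert res.S_gap <= 0.0
        assert res.S_align >= 0.0
        qpos = [p[0] for p in res.pairs]
        tpos = [p[1] for p in res.pairs]
        assert qpos == sorted(qpos) and len(set(qpos)) == len(qpos)
        assert tpos == sorted(tpos) and len(set(tpos)) == len(tpos)

    def test_all_zero_matrix_gives_empty_alignment(self):
        res = sequence_align(np.zeros((6, 4)))
        assert res.pairs == []
        assert res.alignScore == 0.0

    def test_smear_never_increases_self_score(self, small_trace):
        tprof = profile_from_structure(small_trace, smear_sigma=0.0)
        tp = template_peakset(tprof, single_peak=True)
        scores = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            qprof = profile_from_structure(small_trace, smear_sigma=sigma)
            scores.append(three_track_align(query_peakset(qprof), tp).alignScore)
        assert all(a >= b - 1e-9 for a, b in zip(scores, scores[1:]))


@pytest.fixture(scope="module")
def tiny_library():
    traces, labels, specs = make_fold_library(
        seed=303, n_folds=3, members_per_fold=3, length=48, coordinate_noise=0.4
    )
    return greedy_cluster(traces), traces, labels, specs


class TestSearch:
    def test_planted_member_ranked_first(self, tiny_library):
        library, traces, _, specs = tiny_library
        cache = {}
        for member in (traces[0], traces[4]):
            spec = dataclasses.replace(specs[member.id], smear_sigma=0.5)
            qprof = make_profile(member, spec)
            ranked = search_templates(qprof, library, member_peak_cache=cache)
            assert ranked[0][0] == member.id

    def test_full_nclu_equals_exhaustive(self, tiny_library):
        library, traces, _, specs = tiny_library
        qprof = make_profile(traces[1], dataclasses.replace(specs[traces[1].id], smear_sigma=0.5))
        wide = dataclasses.replace(DEFAULT_PARAMS, n_clu=library.n_clusters)
        narrow = dataclasses.replace(DEFAULT_PARAMS, n_clu=library.n_clusters + 5)
        r1 = search_templates(qprof, library, wide)
        r2 = search_templates(qprof, library, narrow)
        assert [t for t, _ in r1] == [t for t, _ in r2]

    def test_all_overflow_query_scores_zero(self, tiny_library):
        library, traces, _, _ = tiny_library
        L = traces[0].L
        P = np.zeros((L, L, 37))
        P[:, :, 36] = 1.0
        qprof = DistanceProfile(L=L, P=P)
        results = search_templates(qprof, library)
        assert all(res.alignScore == 0.0 for _, res in results)

    def test_empty_library_rejected(self, tiny_library):
        from threadfold.masterdb import ClusterLibrary

        _, traces, _, specs = tiny_library
        qprof = make_profile(traces[0], specs[traces[0].id])
        with pytest.raises(ValueError):
            search_templates(qprof, ClusterLibrary())


class TestAlignmentFormat:
    def test_round_trip(self, small_trace):
        prof = profile_from_structure(small_trace, smear_sigma=0.0)
        res = three_track_align(query_peakset(prof), template_peakset(prof, single_peak=True))
        text = format_alignment(res, "query", "tmpl", small_trace.L, small_trace.L)
        assert parse_alignment(text) == res.pairs
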