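"""Segment post-processing, silhouette selection, and the candidate loop."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kerndom.contacts import build_contact_graph
from kerndom.partition import (
    DomainAssignment,
    CandidateClustering,
    InfeasiblePartition,
    Params,
    Segment,
    SegmentList,
    SilhouetteUndefined,
    candidate_loop,
    merge_segment,
    merge_split_helices,
    remove_short_segments,
    segment_distance,
    select_assignment,
    silhouette_score,
    to_segments,
)
from kerndom.synth import FixtureSpec, make_chain

from conftest import toy_chain


def chain_with_ss(ss: str):
    coords = np.arange(len(ss))[:, None] * [3.8, 0, 0]
    return toy_chain(coords, ss=list(ss))


class TestMergeSplitHelices:
    def test_majority_relabelling(self):
        chain = chain_with_ss("H" * 10)
        labels = np.array([1, 1, 1, 1, 1, 1, 1, 2, 2, 2])
        out = merge_split_helices(labels, chain, mhs=30)
        assert (out == 1).all()

    def test_long_helix_untouched(self):
        chain = chain_with_ss("H" * 40)
        labels = np.array([1] * 20 + [2] * 20)
        out = merge_split_helices(labels, chain, mhs=30)
        np.testing.assert_array_equal(out, labels)

    def test_undivided_helix_is_noop(self):
        chain = chain_with_ss("--HHHH--")
        labels = np.array([1, 1, 1, 1, 1, 1, 2, 2])
        np.testing.assert_array_equal(
            merge_split_helices(labels, chain, mhs=30), labels
        )

    def test_tie_takes_first_residue_label(self):
        chain = chain_with_ss("HHHH")
        labels = np.array([2, 2, 1, 1])
        assert (merge_split_helices(labels, chain, mhs=30) == 2).all()


class TestToSegments:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, 2, 2, 2, 1], [(1, 2, 1), (3, 5, 2), (6, 6, 1)]),
            ([3, 3, 3], [(1, 3, 3)]),
            ([1, 2, 1, 2], [(1, 1, 1), (2, 2, 2), (3, 3, 1), (4, 4, 2)]),
        ],
    )
    def test_run_length_encoding(self, labels, expected):
        segs = to_segments(np.array(labels)).segments
        assert [(s.b, s.e, s.label) for s in segs] == expected
        to_segments(np.array(labels)).validate()


class TestSegmentationProperties:
    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=60))
    def test_round_trip_and_segment_count_bound(self, labels):
        """Run-length encoding inverts exactly; t >= number of distinct labels."""
        arr = np.array(labels)
        seglist = to_segments(arr)
        seglist.validate()
        np.testing.assert_array_equal(seglist.labels(), arr)
        assert seglist.t >= len(seglist.distinct_labels())
        assert seglist.n == len(arr)


class TestSegmentDistance:
    def test_single_residue_segments(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        assert segment_distance(Segment(1, 1, 1), Segment(2, 2, 2), D) == 3.0

    def test_constant_distance(self):
        D = np.full((6, 6), 2.5)
        assert segment_distance(Segment(1, 3, 1), Segment(4, 6, 2), D) == 2.5

    def test_four_term_average(self):
        rng = np.random.default_rng(0)
        D = rng.random((4, 4))
        D = (D + D.T) / 2
        got = segment_distance(Segment(1, 2, 1), Segment(3, 4, 2), D)
        assert got == pytest.approx((D[0, 2] + D[0, 3] + D[1, 2] + D[1, 3]) / 4)


class TestMergeSegment:
    def test_same_labelled_neighbours_coalesce(self):
        S = to_segments(np.array([1, 1, 2, 2, 1, 1]))
        out = merge_segment(S, 1, np.zeros((6, 6)))
        assert [(s.b, s.e, s.label) for s in out.segments] == [(1, 6, 1)]

    def test_nearer_neighbour_wins(self):
        # segments <1,2,3>: distances engineered so segment 1 is nearer
        labels = np.array([1, 1, 2, 2, 3, 3])
        n = 6
        D = np.full((n, n), 10.0)
        np.fill_diagonal(D, 0.0)
        D[0:2, 2:4] = D[2:4, 0:2] = 1.0  # seg1 <-> seg2 close
        D[2:4, 4:6] = D[4:6, 2:4] = 9.0  # seg2 <-> seg3 far
        out = merge_segment(to_segments(labels), 1, D)
        assert [(s.b, s.e, s.label) for s in out.segments] == [(1, 4, 1), (5, 6, 3)]

    def test_first_segment_merges_rightward(self):
        S = to_segments(np.array([1, 2, 2, 3]))
        out = merge_segment(S, 0, np.zeros((4, 4)))
        assert [(s.b, s.e, s.label) for s in out.segments] == [(1, 3, 2), (4, 4, 3)]

    def test_single_segment_rejected(self):
        with pytest.raises(InfeasiblePartition):
            merge_segment(to_segments(np.array([1, 1])), 0, np.zeros((2, 2)))


class TestRemoveShortSegments:
    def test_short_middle_collapses(self):
        labels = np.array([1] * 30 + [2] * 5 + [1] * 30)
        D = np.zeros((65, 65))
        with pytest.raises(InfeasiblePartition):
            # merging the short middle eliminates label 2 -> below m=2
            remove_short_segments(to_segments(labels), D, mss=27, sdr=1.5, m=2)
        out = remove_short_segments(to_segments(labels), D, mss=27, sdr=1.5, m=1)
        assert [(s.b, s.e, s.label) for s in out.segments] == [(1, 65, 1)]

    def test_noop_when_constraints_met(self):
        labels = np.array([1] * 30 + [2] * 30)
        out = remove_short_segments(to_segments(labels), np.zeros((60, 60)),
                                    mss=27, sdr=1.5, m=2)
        assert [(s.b, s.e, s.label) for s in out.segments] == [(1, 30, 1), (31, 60, 2)]

    def test_sdr_enforcement_reduces_segment_count(self):
        # 5 segments over m=2 with SDR 1.5 -> must end with t <= 3
        rng = np.random.default_rng(1)
        labels = np.repeat([1, 2, 1, 2, 1], 30)
        n = len(labels)
        D = rng.random((n, n))
        D = (D + D.T) / 2
        out = remove_short_segments(to_segments(labels), D, mss=27, sdr=1.5, m=2)
        assert out.t <= 3
        assert out.t / 2 <= 1.5
        assert set(out.distinct_labels()) == {1, 2}

    def test_contract_properties_on_random_sequences(self):
        """Residue conservation, MSS, and SDR (or signalled infeasibility)."""
        rng = np.random.default_rng(99)
        mss, sdr = 8, 1.5
        for _ in range(300):
            n = int(rng.integers(30, 120))
            m = int(rng.integers(2, 5))
            labels = rng.integers(1, m + 1, size=n)
            labels[rng.choice(n, size=m, replace=False)] = np.arange(1, m + 1)
            D = rng.random((n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            S = to_segments(labels)
            try:
                out = remove_short_segments(S, D, mss=mss, sdr=sdr, m=m)
            except InfeasiblePartition:
                continue
            out.validate()
            assert out.n == n  # residues conserved
            assert min(s.size for s in out.segments) >= mss
            assert out.t / m <= sdr
            assert len(out.distinct_labels()) >= m


class TestSilhouette:
    def test_two_tight_far_groups(self):
        n = 20
        labels = np.array([1] * 10 + [2] * 10)
        D = np.where(labels[:, None] == labels[None, :], 0.1, 10.0)
        np.fill_diagonal(D, 0.0)
        mask = np.ones(n, dtype=bool)
        score = silhouette_score(labels, D, mask)
        assert score > 0.9
        # matches a direct evaluation of the definition
        a = 0.1 * 9 / 9
        b = 10.0
        assert score == pytest.approx((b - a) / b)

    def test_constant_distance_scores_zero(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        D = np.full((6, 6), 4.0)
        np.fill_diagonal(D, 0.0)
        # a(i) and b(i) both 4 -> silhouette 0
        assert silhouette_score(labels, D, np.ones(6, bool)) == pytest.approx(0.0)

    def test_degenerate_mask_signalled(self):
        labels = np.array([1, 2])
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(SilhouetteUndefined):
            silhouette_score(labels, D, np.ones(2, bool))

    def test_mask_restricts_the_average(self):
        labels = np.array([1] * 6 + [2] * 6)
        rng = np.random.default_rng(2)
        D = rng.random((12, 12)) + np.where(
            labels[:, None] == labels[None, :], 0.0, 5.0
        )
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        full = silhouette_score(labels, D, np.ones(12, bool))
        half = silhouette_score(labels, D, np.tile([True, True, True, False, False, False], 2))
        assert full != pytest.approx(half)


class TestCandidateLoop:
    def test_two_blob_candidates_and_bound(self, two_blob, two_blob_graph):
        chain, planted = two_blob
        cands = candidate_loop(chain, two_blob_graph, seed=1)
        assert cands, "expected at least the m=2 candidate"
        ms = [c.m_requested for c in cands]
        assert ms[0] == 2
        assert max(ms) <= chain.n // 27  # hard upper bound floor(n/MDS)

    def test_short_chain_yields_empty_list(self):
        chain, _ = make_chain(
            FixtureSpec(n_domains=1, residues_per_domain=[40], seed=0)
        )
        graph = build_contact_graph(chain)
        assert candidate_loop(chain, graph, seed=0) == []

    def test_m_bounds_restrict_attempts(self, two_blob, two_blob_graph):
        chain, _ = two_blob
        from kerndom.partition import LoopReportEntry

        report: list[LoopReportEntry] = []
        candidate_loop(chain, two_blob_graph, seed=1, m_bounds=(3, 3), report=report)
        assert [e.m for e in report] == [3]

    def test_accepted_candidates_respect_all_constraints(self, two_blob, two_blob_graph):
        chain, _ = two_blob
        params = Params()
        cands = candidate_loop(chain, two_blob_graph, seed=1, params=params)
        for cand in cands:
            labels = cand.labels
            sizes = np.bincount(labels)[1:]
            sizes = sizes[sizes > 0]
            assert sizes.min() >= params.min_domain_size
            cand.segments.validate()
            assert min(s.size for s in cand.segments.segments) >= params.min_segment_size
            # no short helix split across domains
            ss = chain.ss_string()
            i = 0
            while i < len(ss):
                if ss[i] == "H":
                    j = i
                    while j + 1 < len(ss) and ss[j + 1] == "H":
                        j += 1
                    if j - i + 1 <= params.max_helix_merge:
                        assert len(set(labels[i:j + 1])) == 1
                    i = j + 1
                else:
                    i += 1


class TestSelectAssignment:
    def _cand(self, m, sil, n=100):
        sizes = [n // m] * (m - 1) + [n - (n // m) * (m - 1)]
        labels = np.repeat(np.arange(1, m + 1), sizes)
        return CandidateClustering(
            labels=labels, m_requested=m, m_effective=m, silhouette=sil,
            segments=to_segments(labels),
        )

    def test_argmax_silhouette(self):
        out = select_assignment([self._cand(2, 0.71), self._cand(3, 0.54)], "multi", 100)
        assert out.n_domains == 2
        assert out.silhouette == 0.71

    def test_tie_prefers_smaller_m(self):
        out = select_assignment([self._cand(2, 0.5), self._cand(3, 0.5)], "multi", 100)
        assert out.n_domains == 2

    def test_empty_candidates_fall_back_to_single(self):
        out = select_assignment([], "multi", 77)
        assert out.n_domains == 1
        assert out.source == "clustering"
        assert out.to_range_string() == "1-77"

    def test_single_verdict(self):
        out = select_assignment([self._cand(2, 0.9)], "single", 50)
        assert out.n_domains == 1
        assert out.source == "classifier-single"

    def test_forced_m(self):
        cands = [self._cand(2, 0.7), self._cand(3, 0.6)]
        assert select_assignment(cands, "forced", 100, forced_m=3).n_domains == 3
        with pytest.raises(InfeasiblePartition):
            select_assignment(cands, "forced", 100, forced_m=5)


class TestRangeString:
    def test_round_trip_with_discontinuous_domain(self):
        text = "1-87,200-210|88-151|152-199"
        a = DomainAssignment.from_range_string(text)
        assert a.n_domains == 3
        assert a.to_range_string() == text
        labels = a.labels()
        assert labels[0] == labels[199] == labels[86]
        assert len(labels) == 210
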