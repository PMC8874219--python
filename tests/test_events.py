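"""Splice-event metrics, filtering and ranking."""

import math
import random

import pytest

from mrsd import (
    SpliceEvent,
    SpliceJunction,
    TranscriptModel,
    apply_thresholds,
    compute_fold_change,
    compute_nrc,
    filter_events,
    rank_events,
)
from mrsd.events import adjoining_canonical


def _j(start, end, strand="+"):
    return SpliceJunction("chr1", start, end, strand)


@pytest.fixture()
def gene_model():
    # canonical junctions at (101,199), (301,399), (501,599)
    return TranscriptModel(
        "g", "t", "MANE", (_j(101, 199), _j(301, 399), _j(501, 599))
    )


class TestAdjoining:
    def test_shared_donor_preferred(self, gene_model):
        novel = _j(301, 450)  # shares donor with (301,399)
        adj = adjoining_canonical(novel, gene_model)
        assert adj == [_j(301, 399)]

    def test_shared_acceptor(self, gene_model):
        novel = _j(250, 399)
        assert adjoining_canonical(novel, gene_model) == [_j(301, 399)]

    def test_flanking_fallback(self, gene_model):
        novel = _j(220, 280)  # shares no splice site
        adj = set(adjoining_canonical(novel, gene_model))
        assert adj == {_j(101, 199), _j(301, 399)}

    def test_event_never_adjoins_itself(self, gene_model):
        canonical = gene_model.junctions[1]
        assert canonical not in adjoining_canonical(canonical, gene_model)


class TestNrc:
    def test_ratio_to_highest_adjoining(self, gene_model):
        novel = _j(220, 280)
        counts = {novel: 10, _j(101, 199): 40, _j(301, 399): 25}
        assert compute_nrc(novel, counts, gene_model) == pytest.approx(0.25)

    def test_ratio_identity(self, gene_model):
        novel = _j(301, 450)
        counts = {novel: 30, _j(301, 399): 30}
        assert compute_nrc(novel, counts, gene_model) == pytest.approx(1.0)

    def test_nrc_above_one_is_legal(self, gene_model):
        novel = _j(301, 450)
        counts = {novel: 90, _j(301, 399): 30}
        assert compute_nrc(novel, counts, gene_model) == pytest.approx(3.0)

    def test_silent_canonical_background_flags(self, gene_model):
        novel = _j(301, 450)
        with pytest.raises(ValueError, match="NRC undefined"):
            compute_nrc(novel, {novel: 5}, gene_model)


class TestFoldChange:
    def test_ratio_to_best_control(self):
        assert compute_fold_change(0.5, [0.1, 0.05]) == pytest.approx(5.0)

    def test_singleton_when_no_control_carries(self):
        assert compute_fold_change(0.5, []) is None
        assert compute_fold_change(0.5, [0.0, 0.0]) is None

    def test_equality_gives_one(self):
        assert compute_fold_change(0.3, [0.3]) == pytest.approx(1.0)


def _event(reads, nrc, n_samples, max_ctrl=None, fc=None, start=1000):
    return SpliceEvent(
        junction=_j(start, start + 100),
        sample_id="case",
        gene_id="g",
        read_count=reads,
        nrc=nrc,
        nrc_fold_change=fc,
        n_samples=n_samples,
        max_control_nrc=max_ctrl,
    )


class TestFilter:
    def test_singleton_retained_regardless_of_reads(self):
        assert filter_events([_event(1, 0.05, 1)]) != []

    def test_strictly_above_controls_retained(self):
        assert filter_events([_event(5, 0.3, 4, max_ctrl=0.25, fc=1.2)]) != []

    def test_equal_to_control_max_dropped(self):
        assert filter_events([_event(5, 0.25, 4, max_ctrl=0.25, fc=1.0)]) == []

    def test_flagged_event_dropped(self):
        ev = SpliceEvent(
            junction=_j(1, 10), sample_id="s", gene_id="g", read_count=5,
            nrc=math.nan, nrc_fold_change=None, n_samples=1, flagged=True,
        )
        assert filter_events([ev]) == []


class TestThresholds:
    def test_single_read_singleton_dropped_at_min_reads_2(self):
        assert apply_thresholds([_event(1, 1.0, 1)], min_reads=2) == []

    def test_nrc_just_above_threshold_retained(self):
        evs = [_event(5, 0.26, 3, max_ctrl=0.1, fc=2.6)]
        assert apply_thresholds(evs, min_reads=2, min_nrc=0.25) == evs

    def test_nrc_exactly_at_threshold_dropped(self):
        evs = [_event(5, 0.25, 3, max_ctrl=0.1, fc=2.5)]
        assert apply_thresholds(evs, min_reads=2, min_nrc=0.25) == []

    def test_singleton_spared_from_nrc_threshold(self):
        evs = [_event(5, 0.05, 1)]
        assert apply_thresholds(evs, min_reads=2, min_nrc=0.25) == evs

    def test_monotone_in_both_thresholds(self):
        evs = [
            _event(r, nrc, ns, max_ctrl=0.01 if ns > 1 else None,
                   fc=nrc / 0.01 if ns > 1 else None, start=1000 + 10 * k)
            for k, (r, nrc, ns) in enumerate(
                [(1, 0.1, 1), (3, 0.3, 2), (8, 0.2, 1), (2, 0.9, 5), (20, 0.26, 3)]
            )
        ]
        base = set(id(e) for e in apply_thresholds(evs, 2, 0.25))
        for mr, mn in [(3, 0.25), (2, 0.5), (5, 0.9)]:
            tighter = set(id(e) for e in apply_thresholds(evs, mr, mn))
            assert tighter <= base


class TestRanking:
    def test_singleton_outranks_huge_fold_change(self):
        s = _event(3, 1.0, 1, start=100)
        ns = _event(50, 2.0, 4, max_ctrl=0.005, fc=400.0, start=200)
        ranked = rank_events([ns, s])
        assert ranked[0].junction == s.junction and ranked[0].rank == 1

    def test_singletons_by_read_count(self):
        a, b = _event(10, 1.0, 1, start=100), _event(4, 1.0, 1, start=200)
        ranked = rank_events([b, a])
        assert [e.read_count for e in ranked] == [10, 4]
        assert [e.rank for e in ranked] == [1, 2]

    def test_fold_change_then_read_tiebreak(self):
        e1 = _event(2, 0.5, 3, max_ctrl=0.06, fc=8.2, start=100)
        e2 = _event(7, 0.5, 3, max_ctrl=0.1, fc=5.0, start=200)
        e3 = _event(3, 0.5, 3, max_ctrl=0.1, fc=5.0, start=300)
        ranked = rank_events([e3, e2, e1])
        assert [e.nrc_fold_change for e in ranked] == [8.2, 5.0, 5.0]
        assert [e.read_count for e in ranked] == [2, 7, 3]

    def test_rank_invariant_to_input_order(self):
        events = [
            _event(r, 0.5, ns, max_ctrl=None if ns == 1 else 0.1,
                   fc=None if ns == 1 else r / 2, start=100 * r)
            for r, ns in [(2, 1), (9, 3), (5, 1), (7, 4), (3, 2)]
        ]
        expected = [e.junction for e in rank_events(events)]
        rng = random.Random(0)
        for _ in range(10):
            shuffled = events[:]
            rng.shuffle(shuffled)
            assert [e.junction for e in rank_events(shuffled)] == expected

    def test_ranks_are_one_based_and_dense(self):
        events = [_event(i + 1, 1.0, 1, start=10 * i) for i in range(5)]
        ranked = rank_events(events)
        assert sorted(e.rank for e in ranked) == [1, 2, 3, 4, 5]


class TestScorerPipeline:
    def test_injected_events_scored_end_to_end(self, small_synth):
        import numpy as np

        from mrsd import (
            ReferenceSet,
            SpliceEventScorer,
            inject_aberrant_event,
        )

        ref = small_synth.reference_set
        case = ref.sample_counts(ref.samples[0].sample_id)
        controls = ReferenceSet(
            list(ref.samples[1:]), list(ref.junctions), ref.counts[1:], "c"
        )
        case, _, rec_s = inject_aberrant_event(
            case, small_synth.models[0], target_nrc=0.5, reads=10, singleton=True
        )
        case, controls, rec_ns = inject_aberrant_event(
            case, small_synth.models[1], target_nrc=0.4, reads=8,
            singleton=False, controls=controls, rng=np.random.default_rng(1),
        )
        res = SpliceEventScorer(controls, small_synth.models).fit(
            case, min_reads=2, min_nrc=0.0
        )
        by_junction = {e.junction: e for e in res.ranked}
        assert rec_s.junction in by_junction
        assert by_junction[rec_s.junction].is_singleton
        assert by_junction[rec_s.junction].nrc == pytest.approx(rec_s.attained_nrc)
        ns_ev = by_junction[rec_ns.junction]
        assert not ns_ev.is_singleton
        assert ns_ev.n_samples == 1 + len(rec_ns.control_ids)
        assert ns_ev.nrc_fold_change == pytest.approx(
            rec_ns.attained_nrc / rec_ns.max_control_nrc
        )
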