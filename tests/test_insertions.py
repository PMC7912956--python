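"""Poisson background, anchor-window scan, and insertion calling."""

import math

import numpy as np
import pytest

from mobsv.classify import AlignedMate, PairClass, ReadPairRecord
from mobsv.genome import TruthEvent, generate_genome, plant_events
from mobsv.insertions import (
    AnchorCluster,
    call_insertions,
    poisson_upper_tail,
    scan_anchor_windows,
)

from .conftest import classify_sam, simulate_to_sam


def direct_pmf_tail(k, lam):
    """Independent oracle: P(K >= k) by direct pmf summation."""
    total = sum(
        math.exp(-lam) * lam**j / math.factorial(j) for j in range(k)
    )
    return 1.0 - total


class TestPoissonUpperTail:
    def test_zero_count_is_certain(self):
        assert poisson_upper_tail(0, 0.0) == 1.0
        assert poisson_upper_tail(0, 17.3) == 1.0

    def test_one_count_log_two(self):
        assert poisson_upper_tail(1, math.log(2)) == pytest.approx(0.5, abs=1e-12)

    def test_against_pmf_summation(self):
        assert poisson_upper_tail(5, 2.0) == pytest.approx(
            direct_pmf_tail(5, 2.0), abs=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            poisson_upper_tail(-1, 2.0)
        with pytest.raises(ValueError):
            poisson_upper_tail(3, -0.1)


def _anchored_record(i, pos, strand, target=None):
    anchored = AlignedMate(f"p{i}", "chr", pos, pos + 100, strand, True, 60,
                           False, 100)
    if target is None:
        other = AlignedMate(f"p{i}", None, 0, 0, "+", False, 0, False)
    else:
        other = AlignedMate(f"p{i}", target, 10, 110, "+", True, 60, True, 100)
    return ReadPairRecord(f"p{i}", anchored, other)


def _classified(records_by_class):
    out = {c: [] for c in PairClass}
    out.update(records_by_class)
    return out


class TestScanAnchorWindows:
    def test_empty_input(self):
        clusters = scan_anchor_windows(_classified({}), {"chr": 20_000})
        assert clusters == []

    def test_dense_window_is_significant(self):
        recs = [
            _anchored_record(i, 5_000 + (i % 5) * 10, "+", "IS1088")
            for i in range(30)
        ]
        clusters = scan_anchor_windows(
            _classified({PairClass.IS_ANCHORED: recs}), {"chr": 20_000}
        )
        assert len(clusters) == 1
        c = clusters[0]
        assert c.side == "left"
        assert c.support == 30
        # 30 anchored ends in one window against a small background
        assert c.p_value <= 1e-30
        assert c.mate_targets == {"IS1088": 30}
        assert c.start <= 5_100 <= c.end

    def test_mate_unmapped_counts_without_target(self):
        recs = [_anchored_record(i, 8_000, "-") for i in range(25)]
        clusters = scan_anchor_windows(
            _classified({PairClass.MATE_UNMAPPED: recs}), {"chr": 20_000}
        )
        assert len(clusters) == 1
        assert clusters[0].side == "right"
        assert clusters[0].mate_targets == {}

    def test_sparse_background_not_significant(self):
        rng = np.random.default_rng(0)
        recs = [
            _anchored_record(i, int(p), "+")
            for i, p in enumerate(rng.uniform(0, 95_000, size=20))
        ]
        clusters = scan_anchor_windows(
            _classified({PairClass.MATE_UNMAPPED: recs}), {"chr": 100_000}
        )
        assert clusters == []


def _cluster(side, start, end, support, hist, rep="chr", p=1e-40):
    return AnchorCluster(rep, start, end, side, support, dict(hist), p)


class TestCallInsertions:
    def test_empty(self):
        assert call_insertions([]) == []

    def test_flank_pairing_and_element(self):
        clusters = [
            _cluster("left", 4_800, 5_000, 20, {"IS1088": 18}),
            _cluster("right", 5_050, 5_250, 22, {"IS1088": 20}),
        ]
        (call,) = call_insertions(clusters)
        assert (call.bp_start, call.bp_end) == (5_000, 5_050)
        assert call.element == "IS1088"
        assert (call.support_left, call.support_right) == (20, 22)

    def test_tied_histogram_is_ambiguous(self):
        clusters = [
            _cluster("left", 4_800, 5_000, 18, {"IS1088": 9}),
            _cluster("right", 5_050, 5_250, 18, {"ISRme5": 9}),
        ]
        (call,) = call_insertions(clusters)
        assert call.element == "ambiguous"

    def test_overlapping_flanks_clamp_to_one_base(self):
        clusters = [
            _cluster("left", 4_800, 5_100, 20, {}),
            _cluster("right", 4_950, 5_250, 20, {}),
        ]
        (call,) = call_insertions(clusters)
        assert call.bp_end - call.bp_start == 1

    def test_single_sided_needs_double_support(self):
        lone = [_cluster("left", 4_800, 5_000, 7, {"IS1088": 7})]
        assert call_insertions(lone, min_support=4) == []
        lone = [_cluster("left", 4_800, 5_000, 8, {"IS1088": 8})]
        (call,) = call_insertions(lone, min_support=4)
        assert call.support_right == 0

    def test_distant_flanks_not_paired(self):
        clusters = [
            _cluster("left", 1_000, 1_200, 20, {"IS1088": 20}),
            _cluster("right", 9_000, 9_200, 20, {"IS1088": 20}),
        ]
        calls = call_insertions(clusters, max_gap=390, min_support=4)
        assert all(c.support_left == 0 or c.support_right == 0 for c in calls)

    def test_min_support_monotonicity(self):
        clusters = [
            _cluster("left", 4_800, 5_000, 3, {"IS1088": 3}),
            _cluster("right", 5_050, 5_250, 3, {"IS1088": 3}),
            _cluster("left", 8_000, 8_200, 30, {"ISRme5": 30}),
            _cluster("right", 8_250, 8_450, 30, {"ISRme5": 28}),
        ]
        previous = None
        for ms in (1, 4, 8, 40, 100):
            n = len(call_insertions(clusters, min_support=ms))
            if previous is not None:
                assert n <= previous
            previous = n


class TestPlantedInsertionRecovery:
    def test_single_insertion_recovered(self, catalog, catalog_names, tmp_path):
        """A planted IS transposition at 50x yields one two-sided call
        within the library insert size of the true breakpoint."""
        genome = generate_genome(1, [40_000], 0.61, seed=31, names=["chr"])
        events = [TruthEvent("insertion", "chr", 17_000, element="ISRme5")]
        from mobsv.simulate import SimConfig

        sam = tmp_path / "ins.sam"
        simulate_to_sam(genome, events, catalog, SimConfig(seed=13), sam)
        _, _, classified = classify_sam(sam, catalog_names)
        clusters = scan_anchor_windows(classified, {"chr": 40_000})
        sides = {c.side for c in clusters}
        assert sides == {"left", "right"}
        calls = call_insertions(clusters)
        assert len(calls) == 1
        call = calls[0]
        assert abs((call.bp_start + call.bp_end) / 2 - 17_000) < 300
        assert call.element == "ISRme5"
        assert call.support_left + call.support_right >= 15
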