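"""Point-process binarization, frame labeling and event extraction,
checked against independent brute-force references."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avalanchekit as ak
from avalanchekit.detection import AVALANCHE, EXCLUDED, QUIESCENCE

from _reference import (brute_force_binarize, brute_force_events,
                        brute_force_labels)
from conftest import make_cluster_stack


def _stack_from_series(series):
    return np.asarray(series, dtype=float)[:, None, None]


class TestBinarize:
    @pytest.mark.parametrize("series,expected", [
        ([0, 4, 4, 2, 4], [0, 1, 0, 0, 1]),
        ([0, 0, 0, 0, 0], [0, 0, 0, 0, 0]),
        ([5, 5, 5, 5, 5], [0, 0, 0, 0, 0]),   # never crossed from below
        ([0, 3, 2.9, 3, 0], [0, 1, 0, 1, 0]),  # threshold is inclusive
    ])
    def test_crossing_examples(self, series, expected):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # raw series are not z-scored
            pp = ak.binarize_transitions(_stack_from_series(series))
        assert pp.flags[:, 0, 0].tolist() == expected

    def test_warns_when_input_not_zscored(self):
        data = np.full((10, 2, 2), 5.0)
        with pytest.warns(UserWarning, match="z-scored"):
            ak.binarize_transitions(data)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-5, max_value=8, allow_nan=False),
                    min_size=5, max_size=40))
    def test_matches_scan_oracle(self, series):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pp = ak.binarize_transitions(_stack_from_series(series))
        assert pp.flags[:, 0, 0].tolist() == brute_force_binarize(series)


class TestLabelFrames:
    def test_middle_of_five_cluster_frames_is_avalanche(self):
        flags = make_cluster_stack(5, (20, 20), range(5), cluster_px=12)
        labeling = ak.label_frames(ak.PointProcessStack(flags))
        assert labeling.labels[2] == AVALANCHE
        assert labeling.labels[0] == EXCLUDED  # boundary context

    def test_empty_stack_context_rule(self):
        labeling = ak.label_frames(
            ak.PointProcessStack(np.zeros((10, 8, 8), dtype=np.uint8)))
        assert labeling.labels[:2].tolist() == [EXCLUDED, EXCLUDED]
        assert labeling.labels[2:8].tolist() == [QUIESCENCE] * 6
        assert labeling.labels[8:].tolist() == [EXCLUDED, EXCLUDED]

    def test_insufficient_context_excluded(self):
        # qualifying frame flanked by only one qualifying frame each side
        flags = make_cluster_stack(9, (20, 20), [3, 4, 5], cluster_px=12)
        labeling = ak.label_frames(ak.PointProcessStack(flags))
        assert labeling.labels[4] == EXCLUDED
        assert AVALANCHE not in labeling.labels

    def test_subthreshold_clusters_do_not_break_quiescence(self):
        flags = make_cluster_stack(10, (20, 20), range(10), cluster_px=5)
        labeling = ak.label_frames(ak.PointProcessStack(flags))
        assert np.all(labeling.labels[2:8] == QUIESCENCE)


class TestExtractAvalanches:
    def test_minimal_event_is_50px_100ms(self):
        """Five consecutive 10-pixel clusters: the smallest legal avalanche."""
        flags = make_cluster_stack(9, (20, 20), range(2, 7), cluster_px=10)
        pp = ak.PointProcessStack(flags, frame_interval_ms=20.0)
        labeling = ak.label_frames(pp)
        events = ak.extract_avalanches(pp, labeling)
        assert len(events) == 1
        assert events[0].size == 50
        assert events[0].duration_ms == 100.0

    def test_no_qualifying_frames_gives_empty_list(self):
        pp = ak.PointProcessStack(np.zeros((10, 8, 8), dtype=np.uint8))
        assert ak.extract_avalanches(pp, ak.label_frames(pp)) == []

    def test_runs_split_by_gap_give_two_events(self):
        frames = list(range(2, 7)) + list(range(8, 13))
        flags = make_cluster_stack(15, (20, 20), frames, cluster_px=12)
        pp = ak.PointProcessStack(flags)
        events = ak.extract_avalanches(pp, ak.label_frames(pp))
        assert [(e.start, e.end) for e in events] == [(2, 7), (8, 13)]

    def test_events_table_schema(self, detected):
        _, _, _, events = detected
        table = ak.events_to_dataframe(events)
        assert len(table) == len(events)
        assert (table["size_px"] >= 50).all()
        assert (table["duration_ms"] >= 100).all()


def _random_stacks(n_stacks, rng):
    """Random binary stacks mixing sparse noise with planted clusters."""
    stacks = []
    for _ in range(n_stacks):
        flags = (rng.random((50, 30, 30)) < rng.uniform(0.002, 0.02)).astype(np.uint8)
        for _ in range(rng.integers(0, 4)):
            t0 = rng.integers(0, 44)
            length = rng.integers(3, 8)
            r0, c0 = rng.integers(2, 22, size=2)
            side = rng.integers(3, 5)
            flags[t0:t0 + length, r0:r0 + side, c0:c0 + side] = 1
        stacks.append(flags)
    return stacks


class TestOracleEquivalence:
    def test_labels_and_events_match_brute_force(self):
        """Exact agreement with the BFS reference on 200 random stacks."""
        rng = np.random.default_rng(2024)
        for flags in _random_stacks(200, rng):
            pp = ak.PointProcessStack(flags)
            labeling = ak.label_frames(pp)
            ref_qual, ref_labels = brute_force_labels(flags)
            assert labeling.qualifying.tolist() == ref_qual
            assert labeling.labels.tolist() == ref_labels
            events = ak.extract_avalanches(pp, labeling)
            assert [(e.start, e.end, e.size) for e in events] == \
                brute_force_events(flags)

    def test_extracted_events_respect_minima(self):
        rng = np.random.default_rng(7)
        for flags in _random_stacks(30, rng):
            pp = ak.PointProcessStack(flags, frame_interval_ms=20.0)
            for event in ak.extract_avalanches(pp, ak.label_frames(pp)):
                assert event.size >= 50
                assert event.duration_ms >= 100.0
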