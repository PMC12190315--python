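import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_segment
from conftest import random_lick_train
from lickstruct.bout_segmentation import SegmentationParams, label_licks, segment
from lickstruct.errors import InternalConsistencyError, ValidationError
from lickstruct.event_io import NONBOUT
from lickstruct.lick_processing import Lick


class TestSegment:
    def test_empty_session(self, seg_params):
        bouts, nonbout = segment([], seg_params)
        assert bouts == [] and nonbout == set()

    def test_documented_trace_with_extension(self, seg_params):
        # triple at 0.0/0.4/0.8 initiates; 2.0 joins (gap 1.2 <= 3);
        # 6.0 is non-bout (gap 4.0 > 3)
        bouts, nonbout = segment([0.0, 0.4, 0.8, 2.0, 6.0], seg_params)
        assert len(bouts) == 1
        assert bouts[0].lick_indices == [0, 1, 2, 3]
        assert bouts[0].start == 0.0 and bouts[0].end == 2.0
        assert nonbout == {4}

    def test_sparse_train_has_no_bouts(self, seg_params):
        bouts, nonbout = segment([0.0, 2.0, 4.0], seg_params)
        assert bouts == [] and nonbout == {0, 1, 2}

    def test_preceding_pair_does_not_retro_join(self, seg_params):
        bouts, nonbout = segment([0.0, 0.5, 2.0, 2.4, 2.8, 3.0], seg_params)
        assert len(bouts) == 1
        assert bouts[0].lick_indices == [2, 3, 4, 5]
        assert nonbout == {0, 1}

    def test_boundaries_inclusive(self, seg_params):
        # ILI exactly 1.0 initiates; gap exactly 3.0 continues
        bouts, _ = segment([0.0, 1.0, 2.0, 5.0], seg_params)
        assert len(bouts) == 1
        assert bouts[0].lick_indices == [0, 1, 2, 3]
        # gap just above 3.0 terminates
        bouts, nonbout = segment([0.0, 1.0, 2.0, 5.001], seg_params)
        assert bouts[0].lick_indices == [0, 1, 2]
        assert nonbout == {3}

    def test_unsorted_input_rejected(self, seg_params):
        with pytest.raises(ValidationError):
            segment([0.0, 2.0, 1.0], seg_params)
        with pytest.raises(ValidationError):
            segment([0.0, 0.0, 1.0], seg_params)

    def test_two_bouts_separated_by_gap(self, seg_params):
        onsets = [0.0, 0.3, 0.6, 10.0, 10.3, 10.6]
        bouts, nonbout = segment(onsets, seg_params)
        assert [b.lick_indices for b in bouts] == [[0, 1, 2], [3, 4, 5]]
        assert nonbout == set()


class TestOracleEquivalence:
    """segment() must agree bit-identically with the brute-force reference."""

    def test_1000_random_trains(self, seg_params):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            onsets = random_lick_train(rng)
            bouts, nonbout = segment(onsets, seg_params)
            ref_bouts, ref_nonbout = brute_force_segment(
                onsets, seg_params.init_n, seg_params.init_ili_max,
                seg_params.term_gap,
            )
            assert [b.lick_indices for b in bouts] == ref_bouts
            assert sorted(nonbout) == ref_nonbout

    def test_oracle_equivalence_with_varied_params(self):
        rng = np.random.default_rng(7)
        for init_n, ili, gap in [(2, 0.5, 2.0), (4, 1.0, 3.0), (3, 0.3, 0.3)]:
            params = SegmentationParams(init_n, ili, gap)
            for _ in range(100):
                onsets = random_lick_train(rng, n_max=30)
                bouts, nonbout = segment(onsets, params)
                ref_bouts, ref_nonbout = brute_force_segment(
                    onsets, init_n, ili, gap
                )
                assert [b.lick_indices for b in bouts] == ref_bouts
                assert sorted(nonbout) == ref_nonbout


class TestProperties:
    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_partition(self, seed):
        onsets = random_lick_train(np.random.default_rng(seed))
        bouts, nonbout = segment(onsets, SegmentationParams())
        covered = sorted(
            [i for b in bouts for i in b.lick_indices] + sorted(nonbout)
        )
        assert covered == list(range(len(onsets)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_bout_internal_invariants(self, seed):
        params = SegmentationParams()
        onsets = random_lick_train(np.random.default_rng(seed))
        bouts, _ = segment(onsets, params)
        for a, b in zip(bouts, bouts[1:]):
            assert b.start - onsets[a.lick_indices[-1]] > params.term_gap
        for bout in bouts:
            assert bout.n_licks >= params.init_n
            idx = bout.lick_indices
            assert idx == list(range(idx[0], idx[-1] + 1))
            ilis = np.diff(onsets[idx])
            assert np.all(ilis <= params.term_gap)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_raising_term_gap_never_shrinks_bouts(self, seed):
        onsets = random_lick_train(np.random.default_rng(seed))
        lo, _ = segment(onsets, SegmentationParams(term_gap=3.0))
        hi, _ = segment(onsets, SegmentationParams(term_gap=6.0))
        # every bout in the low-gap segmentation is contained in one high-gap bout
        for bout in lo:
            containing = [
                h for h in hi
                if set(bout.lick_indices) <= set(h.lick_indices)
            ]
            assert len(containing) == 1

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_raising_ili_max_never_reduces_bout_count(self, seed):
        onsets = random_lick_train(np.random.default_rng(seed))
        n_tight = len(segment(onsets, SegmentationParams(init_ili_max=0.5))[0])
        n_loose = len(segment(onsets, SegmentationParams(init_ili_max=1.0))[0])
        assert n_loose >= n_tight


class TestLabelLicks:
    def test_labels_match_documented_trace(self, seg_params):
        onsets = [0.0, 0.4, 0.8, 2.0, 6.0]
        licks = [Lick(t, 0.05) for t in onsets]
        bouts, _ = segment(onsets, seg_params)
        labels = label_licks(licks, bouts)
        assert labels == ["b0", "b0", "b0", "b0", NONBOUT]
        assert bouts[0].total_lick_duration == pytest.approx(0.20)

    def test_no_bouts_all_none(self):
        licks = [Lick(0.0, 0.05), Lick(5.0, 0.05)]
        assert label_licks(licks, []) == [NONBOUT, NONBOUT]

    def test_all_licks_in_one_bout(self, seg_params):
        onsets = [0.0, 0.3, 0.6, 0.9]
        licks = [Lick(t, 0.05) for t in onsets]
        bouts, _ = segment(onsets, seg_params)
        labels = label_licks(licks, bouts)
        assert NONBOUT not in labels

    def test_out_of_range_index_is_internal_error(self):
        from lickstruct.bout_segmentation import Bout

        with pytest.raises(InternalConsistencyError):
            label_licks([Lick(0.0, 0.05)], [Bout(0, 0.0, 1.0, [0, 1])])


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(init_n=1),
        dict(init_ili_max=0.0),
        dict(init_ili_max=4.0, term_gap=3.0),
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValidationError):
        SegmentationParams(**kwargs)
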