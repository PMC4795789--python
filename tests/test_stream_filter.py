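"""Output-stream features, threshold calibration, and the two-of-three vote."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nestnet.stream_filter import (
    DIGGING,
    NON_DIGGING,
    CalibrationError,
    FilterThresholds,
    OutputStream,
    calibrate_bounds,
    calibrate_tau,
    calibrate_thresholds,
    classify_segment,
    feature_mp,
    feature_mpt,
    feature_np,
)

streams = st.lists(
    st.floats(-1, 1, allow_nan=False, width=32), min_size=1, max_size=20
).map(lambda v: OutputStream(np.asarray(v, dtype=float)))


class TestFeatures:
    def test_np_counts_strictly_positive(self):
        assert feature_np(OutputStream([-0.3, 0.2, 0.5, -0.1])) == 2
        assert feature_np(OutputStream([-1, -0.5])) == 0
        assert feature_np(OutputStream([0.1] * 10)) == 10
        assert feature_np(OutputStream([0.0, -0.2])) == 0  # zero is not positive

    def test_mp_examples(self):
        s = OutputStream([0.5, 0.3] + [-0.1] * 8)
        assert feature_mp(s) == pytest.approx(0.08)
        assert feature_mp(OutputStream([-0.5] * 4)) == 0.0
        assert feature_mp(OutputStream([1.0] * 10)) == pytest.approx(1.0)

    def test_mpt_example_with_calibrated_tau(self):
        s = OutputStream([0.5, 0.3, 0.1] + [-0.2] * 7)
        assert feature_mpt(s, 0.2) == pytest.approx(0.08)
        assert feature_mpt(OutputStream([0.1, 0.2]), 0.2) == 0.0

    def test_mpt_requires_positive_tau(self):
        with pytest.raises(ValueError):
            feature_mpt(OutputStream([0.5]), 0.0)

    def test_empty_stream_errors(self):
        empty = OutputStream(np.array([]))
        for f in (feature_np, feature_mp):
            with pytest.raises(ValueError):
                f(empty)

    @given(streams, st.floats(0.01, 1.0))
    @settings(max_examples=100, derandomize=True)
    def test_feature_ordering_invariant(self, s, tau):
        assert 0 <= feature_mpt(s, tau) <= feature_mp(s) <= 1

    @given(streams, st.floats(0.01, 0.99), st.floats(0.01, 0.5))
    @settings(max_examples=100, derandomize=True)
    def test_mpt_non_increasing_in_tau(self, s, tau, bump):
        assert feature_mpt(s, tau + bump) <= feature_mpt(s, tau)

    def test_mpt_approaches_mp_as_tau_vanishes(self):
        s = OutputStream([0.4, -0.2, 0.9, 0.05])
        assert feature_mpt(s, 1e-12) == pytest.approx(feature_mp(s))


class TestCalibration:
    def test_tau_is_pooled_positive_mean(self):
        a = OutputStream([0.1, -0.5])
        b = OutputStream([0.3, -1.0])
        assert calibrate_tau([a, b]) == pytest.approx(0.2)
        assert calibrate_tau([OutputStream([0.4, -0.4])]) == pytest.approx(0.4)

    def test_tau_without_positives_errors(self):
        with pytest.raises(CalibrationError):
            calibrate_tau([OutputStream([-0.1, -0.9])])

    @pytest.mark.parametrize(
        "neg, pos, expected",
        [([0.05, 0.10], [0.30, 0.40], 0.20), ([0.0], [1.0], 0.5)],
    )
    def test_gap_midpoint(self, neg, pos, expected):
        assert calibrate_bounds(pos, neg) == pytest.approx(expected)

    def test_overlap_matches_bruteforce_scan(self, rng):
        for _ in range(20):
            pos = rng.uniform(0.1, 0.6, 12)
            neg = rng.uniform(0.0, 0.45, 12)
            bound = calibrate_bounds(pos, neg)
            # oracle: dense scan over a fine grid of candidate cuts
            grid = np.linspace(-0.05, 0.7, 4001)
            accs = [
                (np.sum(pos > c) + np.sum(neg <= c)) / (len(pos) + len(neg))
                for c in grid
            ]
            best = max(accs)
            got = (np.sum(pos > bound) + np.sum(neg <= bound)) / (len(pos) + len(neg))
            assert got == pytest.approx(best)

    def test_gap_bound_separates_validation_perfectly(self, rng):
        pos = rng.uniform(0.5, 0.9, 15)
        neg = rng.uniform(0.0, 0.3, 15)
        bound = calibrate_bounds(pos, neg)
        assert np.all(pos > bound) and np.all(neg <= bound)

    def test_empty_group_errors(self):
        with pytest.raises(CalibrationError):
            calibrate_bounds([], [0.1])

    def test_full_threshold_calibration(self):
        pos = [OutputStream([0.8, 0.6] + [-1.0] * 8)] * 3
        neg = [OutputStream([0.1] + [-1.0] * 9)] * 3
        th = calibrate_thresholds(pos, neg)
        assert th.tau == pytest.approx(np.mean([0.8, 0.6] * 3 + [0.1] * 3))
        assert th.np_bound == 2
        assert classify_segment(pos[0], th) == DIGGING
        assert classify_segment(neg[0], th) == NON_DIGGING


class TestVote:
    def make_thresholds(self):
        return FilterThresholds(tau=0.2, mp_bound=0.15, mpt_bound=0.10, np_bound=2)

    def test_exhaustive_two_of_three_table(self):
        """All 8 (NP, MP, MPT) vote combinations: fix one stream and pick
        bounds on either side of its feature values to force each pattern."""
        s = OutputStream([0.5, 0.3] + [-0.2] * 8)  # NP=2, MP=0.08, MPT(0.35)=0.05
        tau = 0.35
        assert feature_np(s) == 2
        assert feature_mp(s) == pytest.approx(0.08)
        assert feature_mpt(s, tau) == pytest.approx(0.05)
        for np_vote, mp_vote, mpt_vote in itertools.product([True, False], repeat=3):
            th = FilterThresholds(
                tau=tau,
                np_bound=2 if np_vote else 3,
                mp_bound=0.04 if mp_vote else 0.09,
                mpt_bound=0.01 if mpt_vote else 0.06,
            )
            expected = DIGGING if np_vote + mp_vote + mpt_vote >= 2 else NON_DIGGING
            assert classify_segment(s, th) == expected

    def test_vote_thresholds_direct(self):
        """Two-of-three rule checked against hand-built vote combinations."""
        th = self.make_thresholds()
        # three votes positive
        assert classify_segment(OutputStream([1.0] * 3 + [-1.0] * 7), th) == DIGGING
        # exactly two votes (NP + MPT, MP at 0.15 not above): 10*0.15/...
        s = OutputStream([0.75, 0.75] + [-1.0] * 8)
        assert feature_np(s) == 2 and feature_mp(s) == pytest.approx(0.15)
        assert feature_mpt(s, th.tau) == pytest.approx(0.15) and 0.15 > th.mpt_bound
        assert classify_segment(s, th) == DIGGING  # NP and MPT vote, MP does not
        # one vote (NP only)
        s = OutputStream([0.05, 0.05] + [-1.0] * 8)
        assert classify_segment(s, th) == NON_DIGGING
        # zero votes
        assert classify_segment(OutputStream([-0.5] * 10), th) == NON_DIGGING

    @given(streams)
    @settings(max_examples=100, derandomize=True)
    def test_raising_a_value_never_flips_to_negative(self, s):
        th = self.make_thresholds()
        before = classify_segment(s, th)
        v = s.values.copy()
        idx = int(np.argmin(v))
        v[idx] = min(1.0, v[idx] + 0.5)
        after = classify_segment(OutputStream(v), th)
        if before == DIGGING:
            assert after == DIGGING
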