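import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locotrace.binseries import BinSeries
from locotrace.errors import ValidationError
from locotrace.metrics import (bin_distances, segment_activity, summarize,
                               timecourse)
from locotrace.profiles import SessionSpec
from locotrace.simulate import Trajectory, simulate_trajectory


def traj_from_positions(positions, fps=25.0, stage="6dpf", arena=(1000.0, 1000.0)):
    return Trajectory(animal_id="t", strain_name="X", stage=stage, fps=fps,
                      positions=np.asarray(positions, dtype=float), arena=arena)


def straight_trajectory(step_mm, n_steps, fps=25.0):
    xs = np.arange(n_steps + 1) * step_mm
    return traj_from_positions(np.column_stack([xs, np.zeros_like(xs)]), fps=fps)


class TestSegmentActivity:
    def test_stationary_trajectory_all_inactive(self):
        t = traj_from_positions(np.zeros((100, 2)) + 5.0)
        mask = segment_activity(t)
        assert not mask.interval.any()
        assert mask.active_time == 0.0

    def test_constant_motion_above_threshold_all_active(self):
        t = straight_trajectory(1.0, 99)
        mask = segment_activity(t, move_threshold=0.05)
        assert mask.interval.all()

    def test_too_short_trajectory_rejected(self):
        t = traj_from_positions([[0.0, 0.0]])
        with pytest.raises(ValidationError):
            segment_activity(t)

    def test_first_frame_inherits_first_interval(self):
        t = straight_trajectory(1.0, 10)
        mask = segment_activity(t, move_threshold=0.05)
        assert len(mask.frame) == t.length
        assert mask.frame[0] == mask.interval[0]

    def test_raising_threshold_never_increases_swim_time(self, larval_profile):
        session = SessionSpec(duration=60, integration_period=60, stage="6dpf")
        t = simulate_trajectory(larval_profile, session, 8)
        times = [segment_activity(t, thr).active_time
                 for thr in (0.0005, 0.002, 0.01, 0.05, 0.5)]
        assert all(a >= b for a, b in zip(times, times[1:]))


class TestBinDistances:
    def test_stationary_gives_zero_bins(self):
        t = traj_from_positions(np.zeros((251, 2)) + 5.0)
        bins = bin_distances(t, segment_activity(t), 5.0)
        assert np.all(bins.distance == 0)
        assert np.all(bins.active_time == 0)

    def test_uniform_motion_fills_bins_evenly(self):
        v = 2.0  # mm per frame
        t = straight_trajectory(v, 250, fps=25.0)
        bins = bin_distances(t, segment_activity(t), 2.0)
        assert bins.n_bins == 5
        assert bins.distance == pytest.approx(np.full(5, v * 2.0 * 25.0))
        assert bins.active_time == pytest.approx(np.full(5, 2.0))

    def test_bin_sums_equal_brute_force_path_length(self, larval_profile):
        session = SessionSpec(duration=120, integration_period=60, stage="6dpf")
        t = simulate_trajectory(larval_profile, session, 4)
        bins = bin_distances(t, segment_activity(t), 60.0)
        brute = sum(
            float(np.hypot(*(t.positions[i + 1] - t.positions[i])))
            for i in range(t.length - 1))
        assert bins.distance.sum() == pytest.approx(brute, rel=1e-12)

    def test_binning_at_any_divisor_conserves_total(self, larval_profile):
        session = SessionSpec(duration=120, integration_period=60, stage="6dpf")
        t = simulate_trajectory(larval_profile, session, 4)
        mask = segment_activity(t)
        totals = {period: bin_distances(t, mask, period).distance.sum()
                  for period in (1.0, 5.0, 30.0, 60.0, 120.0)}
        ref = totals[60.0]
        for total in totals.values():
            assert total == pytest.approx(ref, rel=1e-12)

    def test_non_divisible_period_rejected(self, larval_profile):
        session = SessionSpec(duration=60, integration_period=60, stage="6dpf")
        t = simulate_trajectory(larval_profile, session, 4)
        with pytest.raises(ValidationError):
            bin_distances(t, segment_activity(t), 7.0)


class TestSummarize:
    def test_printed_reference_triple(self):
        """distance 881 cm over 2435 s of swimming -> 0.36 cm/s at 2 d.p."""
        session = SessionSpec(duration=3600, integration_period=60, stage="6dpf")
        bins = BinSeries("ab", 60.0, np.arange(60) * 60.0,
                         np.full(60, 8810.0 / 60.0),
                         np.full(60, 2435.0 / 60.0))
        s = summarize(bins, session)
        assert s.total_distance_cm == pytest.approx(881.0)
        assert s.swim_time_s == pytest.approx(2435.0)
        assert round(s.mean_speed_cm_s, 2) == 0.36

    def test_arithmetic_example(self):
        session = SessionSpec(duration=3600, integration_period=60, stage="6dpf")
        bins = BinSeries("a", 60.0, np.arange(60) * 60.0,
                         np.full(60, 10.0), np.full(60, 40.0))
        s = summarize(bins, session)
        assert s.total_distance_cm == pytest.approx(60.0)
        assert s.swim_time_s == pytest.approx(2400.0)
        assert s.rest_time_s == pytest.approx(1200.0)
        assert s.mean_speed_cm_s == pytest.approx(0.025)
        assert not s.zero_activity

    def test_zero_activity_flagged_not_dropped(self):
        session = SessionSpec(duration=120, integration_period=60, stage="6dpf")
        bins = BinSeries("a", 60.0, [0.0, 60.0], [0.0, 0.0], [0.0, 0.0])
        s = summarize(bins, session)
        assert s.mean_speed_cm_s == 0.0
        assert s.zero_activity

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data(),
           n_bins=st.integers(min_value=1, max_value=40),
           period=st.sampled_from([3.0, 60.0, 300.0]))
    def test_conservation_and_speed_consistency_fuzzed(self, data, n_bins, period):
        """swim + rest = duration exactly; speed x swim reproduces distance."""
        dist = data.draw(st.lists(
            st.floats(0, 1e4, allow_nan=False), min_size=n_bins, max_size=n_bins))
        active = data.draw(st.lists(
            st.floats(0, period, allow_nan=False), min_size=n_bins, max_size=n_bins))
        bins = BinSeries("f", period, np.arange(n_bins) * period,
                         np.asarray(dist), np.asarray(active))
        session = SessionSpec(duration=n_bins * period, integration_period=period,
                              stage="6dpf")
        s = summarize(bins, session)
        assert s.swim_time_s + s.rest_time_s == session.duration
        if s.swim_time_s > 0:
            assert s.mean_speed_cm_s * s.swim_time_s == pytest.approx(
                s.total_distance_cm, rel=1e-6, abs=1e-12)


class TestTimecourse:
    def _series(self, dists, animal="a"):
        n = len(dists)
        return BinSeries(animal, 60.0, np.arange(n) * 60.0,
                         np.asarray(dists, dtype=float), np.zeros(n))

    def test_identical_animals_have_zero_sem(self):
        tc = timecourse([self._series([5, 5], "a"), self._series([5, 5], "b")])
        assert np.all(tc["sem"] == 0)
        assert np.all(tc["mean"] == 5.0)

    def test_symmetric_pair(self):
        tc = timecourse([self._series([0, 2], "a"), self._series([2, 0], "b")])
        assert tc["mean"].tolist() == [1.0, 1.0]
        assert tc["sem"].tolist() == pytest.approx([np.sqrt(2) / np.sqrt(2)] * 2)

    def test_ragged_grids_rejected(self):
        with pytest.raises(ValidationError):
            timecourse([self._series([1, 2], "a"), self._series([1, 2, 3], "b")])

    def test_needs_two_animals(self):
        with pytest.raises(ValidationError):
            timecourse([self._series([1, 2], "a")])
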