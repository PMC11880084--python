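"""Peak-to-peak CPTT estimation: windowing, discretization, imputation, NCPTT."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cptt import (
    BolusParams,
    TimeActivityCurve,
    bin_to_frames,
    compute_cptt,
    discretization_support,
    isolate_first_pass,
    make_frame_schedule,
    peak_time,
    simulate_first_pass,
)
from cptt.errors import NoPeakError, ParameterError, PeakOrderError


def _tac(values, midpoints=None):
    values = np.asarray(values, dtype=float)
    if midpoints is None:
        midpoints = np.arange(len(values), dtype=float) + 0.5
    return TimeActivityCurve(np.asarray(midpoints, float), values)


class TestIsolateFirstPass:
    def test_clean_peak_window_has_single_local_max(self, schedule):
        rv_c, _ = simulate_first_pass(BolusParams())
        tac = bin_to_frames(rv_c, schedule)
        lo, hi = isolate_first_pass(tac)
        w = tac.values[lo : hi + 1]
        interior_maxima = sum(
            1 for i in range(1, len(w) - 1) if w[i] > w[i - 1] and w[i] >= w[i + 1]
        )
        assert interior_maxima == 1
        assert lo <= int(np.argmax(tac.values)) <= hi

    def test_recirculation_bump_excluded(self):
        # first pass peaks at index 3, local min at 6, recirculation bump at 8
        tac = _tac([0, 1, 5, 9, 4, 2, 1, 3, 4, 2])
        lo, hi = isolate_first_pass(tac)
        assert hi == 6
        assert np.argmax(tac.values[lo : hi + 1]) + lo == 3

    def test_onset_threshold(self):
        tac = _tac([0.0, 0.5, 0.9, 6.0, 10.0, 4.0, 1.0, 0.5, 0.4, 0.3])
        lo, _ = isolate_first_pass(tac, onset_fraction=0.1)
        assert lo == 3  # first frame above 10% of the max (1.0)

    @pytest.mark.parametrize(
        "values",
        [
            np.zeros(6),                      # all-zero
            np.arange(6.0),                   # monotone rising
            np.arange(6.0)[::-1],             # monotone falling
            [0.0, 1.0, 2.0, 3.0, 4.0, 9.0],   # max at last frame
        ],
    )
    def test_no_peak_errors(self, values):
        with pytest.raises(NoPeakError):
            isolate_first_pass(_tac(values))

    def test_too_few_frames(self):
        with pytest.raises(NoPeakError):
            isolate_first_pass(_tac([0.0, 1.0]))


class TestPeakTime:
    def test_third_frame_of_clinical_schedule_is_26s(self, schedule):
        values = np.zeros(17)
        values[[1, 2, 3]] = [2.0, 9.0, 3.0]
        tac = TimeActivityCurve(schedule.midpoints, values)
        est = peak_time(tac, isolate_first_pass(tac))
        assert est.time_s == 26.0  # frame [21, 31) midpoint
        assert not est.ambiguous

    def test_tie_resolves_to_earliest_frame_and_flags(self, schedule):
        values = np.zeros(17)
        values[[1, 2, 3, 4]] = [2.0, 9.0, 9.0, 3.0]
        tac = TimeActivityCurve(schedule.midpoints, values)
        est = peak_time(tac, isolate_first_pass(tac))
        assert est.time_s == 26.0
        assert est.ambiguous

    def test_fine_frames_locate_simulated_peak(self):
        """1 s frames: estimated peak within half a frame of the analytic mode at 30 s."""
        p = BolusParams(t0=22.5, alpha=3.0, beta=2.5)  # mode at 30 s
        s = make_frame_schedule([(60, 1.0)], delay=0.0)
        rv_c, _ = simulate_first_pass(p)
        tac = bin_to_frames(rv_c, s)
        est = peak_time(tac, isolate_first_pass(tac))
        assert est.time_s == pytest.approx(30.0, abs=0.5)

    def test_centroid_mode(self):
        tac = _tac([0, 2, 6, 2, 0, 0])
        est = peak_time(tac, (1, 3), mode="centroid")
        assert est.time_s == pytest.approx((1.5 * 2 + 2.5 * 6 + 3.5 * 2) / 10)

    def test_invalid_window(self):
        with pytest.raises(ParameterError):
            peak_time(_tac([0, 1, 0]), (2, 5))


class TestComputeCPTT:
    def _pair(self, schedule, rv_frame, lv_frame):
        rv = np.zeros(17)
        lv = np.zeros(17)
        rv[rv_frame] = 9.0
        rv[rv_frame - 1] = 1.0
        lv[lv_frame] = 8.0
        lv[lv_frame - 1] = 1.0
        return (TimeActivityCurve(schedule.midpoints, rv),
                TimeActivityCurve(schedule.midpoints, lv))

    def test_adjacent_frames_give_10s(self, schedule):
        rv, lv = self._pair(schedule, 2, 3)  # peaks at 16 s and 26 s
        res = compute_cptt(rv, lv, heart_rate_bpm=60.0)
        assert res.cptt == 10.0
        assert not res.imputed
        assert res.ncptt == pytest.approx(10.0)  # RR = 1 s

    def test_same_frame_imputes_2p5s(self, schedule):
        rv, lv = self._pair(schedule, 3, 3)
        res = compute_cptt(rv, lv, heart_rate_bpm=70.0)
        assert res.cptt == 2.5
        assert res.imputed
        assert res.raw_cptt == 0.0
        assert res.ncptt == pytest.approx(2.5 / (60.0 / 70.0))

    def test_ncptt_formula_at_cohort_means(self, schedule):
        """CPTT 9.2 s at HR 70.1 bpm gives NCPTT 10.75 cardiac cycles."""
        rv, lv = self._pair(schedule, 2, 3)
        res = compute_cptt(rv, lv, heart_rate_bpm=70.1)
        # direct formula on the result's own cptt
        assert res.ncptt == pytest.approx(res.cptt * 70.1 / 60.0)
        assert 9.2 * 70.1 / 60.0 == pytest.approx(10.75, abs=0.005)

    def test_lv_before_rv_is_an_error(self, schedule):
        rv, lv = self._pair(schedule, 4, 3)
        with pytest.raises(PeakOrderError, match="VOI"):
            compute_cptt(rv, lv, heart_rate_bpm=60.0)

    def test_bad_heart_rate(self, schedule):
        rv, lv = self._pair(schedule, 2, 3)
        with pytest.raises(ParameterError):
            compute_cptt(rv, lv, heart_rate_bpm=0.0)

    def test_mismatched_schedules_rejected(self, schedule):
        rv, lv = self._pair(schedule, 2, 3)
        other = TimeActivityCurve(lv.midpoints + 1.0, lv.values)
        with pytest.raises(ParameterError):
            compute_cptt(rv, other, heart_rate_bpm=60.0)

    @given(hr=st.floats(40.0, 120.0))
    def test_ncptt_scales_linearly_with_heart_rate(self, hr):
        schedule = make_frame_schedule()
        rv, lv = self._pair(schedule, 2, 3)
        res = compute_cptt(rv, lv, heart_rate_bpm=hr)
        res2 = compute_cptt(rv, lv, heart_rate_bpm=2 * hr)
        assert res2.ncptt == pytest.approx(2 * res.ncptt)
        assert res.ncptt == pytest.approx(res.cptt / res.rr_interval)


class TestDiscretization:
    def test_5s_frames_support(self):
        """Exhaustive sweep on 5 s frames yields raw values {0, 5, 10}."""
        s = make_frame_schedule([(24, 5.0)], delay=1.0)
        vals = discretization_support(
            s, transits=np.arange(0.5, 10.0, 0.5), onsets=np.arange(12.0, 30.5, 2.0)
        )
        assert set(vals.tolist()) == {0.0, 5.0, 10.0}

    def test_fine_frames_resolve_true_transit(self):
        """1 s frames recover a 7 s transit to within one frame."""
        s = make_frame_schedule([(120, 1.0)], delay=0.0)
        vals = discretization_support(
            s, transits=np.array([7.0]), onsets=np.arange(12.0, 30.5, 3.0)
        )
        assert np.all(np.abs(vals - 7.0) <= 1.0)

    def test_raw_values_are_multiples_of_frame_width(self, rng):
        """On uniform 10 s frames every raw peak-to-peak value is a multiple of 10."""
        s = make_frame_schedule([(14, 10.0)], delay=1.0)
        for _ in range(25):
            p = BolusParams(
                t0=float(rng.uniform(8, 35)),
                transit_delay=float(rng.uniform(0, 25)),
                alpha=float(rng.uniform(2, 5)),
                beta=float(rng.uniform(1.5, 3.5)),
            )
            rv_c, lv_c = simulate_first_pass(p)
            res = compute_cptt(bin_to_frames(rv_c, s), bin_to_frames(lv_c, s), 60.0)
            assert res.raw_cptt % 10.0 == pytest.approx(0.0, abs=1e-9)

    def test_estimator_consistency_on_1s_frames(self, rng):
        """|estimate - truth| <= one frame width for dispersion-free bolus draws."""
        s = make_frame_schedule([(90, 1.0)], delay=0.0)
        for _ in range(40):
            d = float(rng.uniform(1.0, 15.0))
            p = BolusParams(
                t0=float(rng.uniform(10, 30)),
                transit_delay=d,
                alpha=float(rng.uniform(2, 5)),
                beta=float(rng.uniform(1.5, 3.5)),
            )
            rv_c, lv_c = simulate_first_pass(p)
            res = compute_cptt(bin_to_frames(rv_c, s), bin_to_frames(lv_c, s), 60.0)
            assert abs(res.cptt - d) <= 1.0

    def test_imputed_iff_raw_zero(self, rng):
        """The 2.5 s imputation fires exactly when the raw difference is zero."""
        s = make_frame_schedule()
        for _ in range(20):
            p = BolusParams(
                t0=float(rng.uniform(5, 25)), transit_delay=float(rng.uniform(0, 18))
            )
            rv_c, lv_c = simulate_first_pass(p)
            res = compute_cptt(bin_to_frames(rv_c, s), bin_to_frames(lv_c, s), 60.0)
            assert res.imputed == (res.raw_cptt == 0.0)
            assert res.cptt > 0.0
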