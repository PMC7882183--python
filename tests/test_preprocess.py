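"""Cycle extraction, censoring, discard, resampling, smoothing, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvrpipe import (
    AcquisitionRecording,
    CensorMask,
    CycleSeries,
    SmoothedSeries,
    apply_discard_rule,
    average_bouts,
    censor_cycles,
    extract_cycles,
    resample_to_2hz,
    smooth_3s_9s,
)


def make_recording(v, fs=100.0, onsets=None):
    n = len(v)
    dur = n / fs
    if onsets is None:
        onsets = np.arange(0.0, dur, 1.0)
    return AcquisitionRecording(
        subject_id="T", sample_rate=fs, duration=dur,
        mcav={"stroke_affected": np.asarray(v, dtype=float),
              "non_affected": np.asarray(v, dtype=float)},
        map_mmhg=np.zeros(n), petco2_mmhg=np.zeros(n),
        beat_onsets=np.asarray(onsets, dtype=float))


def make_cycles(peaks, rr=1.0, means=None):
    peaks = np.asarray(peaks, dtype=float)
    n = len(peaks)
    means = peaks - 5.0 if means is None else np.asarray(means, dtype=float)
    return CycleSeries(onset=np.arange(n) * rr, rr=np.full(n, rr),
                       mean_v=means, peak_v=peaks)


class TestExtractCycles:
    def test_constant_signal(self):
        rec = make_recording(np.full(1000, 50.0))
        cyc = extract_cycles(rec, "stroke_affected")
        np.testing.assert_allclose(cyc.mean_v, 50.0)
        np.testing.assert_allclose(cyc.peak_v, 50.0)

    def test_rr_from_onsets(self):
        rec = make_recording(np.full(300, 50.0), onsets=[0.0, 1.0, 2.0])
        cyc = extract_cycles(rec, "stroke_affected")
        np.testing.assert_allclose(cyc.rr, [1.0, 1.0])
        assert len(cyc) == 2

    def test_sawtooth_mean_matches_quadrature(self):
        # triangular wave over each 1 s cycle: analytic time-average = 25
        fs = 1000.0
        t = np.arange(0, 4.0, 1 / fs)
        phase = t % 1.0
        v = 50.0 * np.where(phase < 0.5, phase, 1.0 - phase)
        rec = make_recording(v, fs=fs, onsets=[0.0, 1.0, 2.0, 3.0])
        cyc = extract_cycles(rec, "stroke_affected")
        np.testing.assert_allclose(cyc.mean_v, 12.5, atol=0.05)
        np.testing.assert_allclose(cyc.peak_v, 25.0, atol=0.1)

    def test_fewer_than_two_onsets_rejected(self):
        rec = make_recording(np.full(100, 50.0), onsets=[0.0])
        with pytest.raises(ValueError):
            extract_cycles(rec, "stroke_affected")

    def test_peak_never_below_mean(self, clean_recording):
        cyc = extract_cycles(clean_recording, "non_affected")
        assert np.all(cyc.peak_v >= cyc.mean_v)


class TestCensorRules:
    def test_implausible_rr_censored(self):
        cyc = make_cycles([60.0] * 5)
        cyc.rr[2] = 0.15  # 6.67 Hz instantaneous cardiac frequency
        mask = censor_cycles(cyc)
        assert mask.censored.tolist() == [False, False, True, False, False]
        assert mask.reasons[2] == "rr_implausible"

    def test_peak_jump_censors_second_cycle(self):
        mask = censor_cycles(make_cycles([60.0, 72.0, 60.0]))
        assert mask.censored.tolist() == [False, True, False]
        assert mask.reasons[1] == "velocity_jump"

    def test_jump_of_exactly_ten_not_censored(self):
        mask = censor_cycles(make_cycles([60.0, 70.0, 60.0]))
        assert not mask.censored.any()

    def test_single_spike_censors_exactly_one_cycle(self):
        mask = censor_cycles(make_cycles([60.0, 60.0, 72.0, 60.0, 60.0]))
        assert mask.censored.tolist() == [False, False, True, False, False]

    def test_first_cycle_exempt_from_jump(self):
        mask = censor_cycles(make_cycles([100.0, 60.0, 60.0]))
        # cycle 0 has no predecessor and anchors the reference peak; later
        # cycles are judged against the last accepted peak
        assert not mask.censored[0]
        assert mask.censored[1]

    def test_adding_artifact_preserves_existing_censures(self):
        base = make_cycles([60.0, 60.0, 75.0, 60.0, 60.0, 60.0])
        m0 = censor_cycles(base)
        spiked = make_cycles([60.0, 60.0, 75.0, 60.0, 60.0, 75.0])
        m1 = censor_cycles(spiked)
        assert np.all(m1.censored[m0.censored])


class TestDiscardRule:
    @pytest.mark.parametrize("n_censored,expected", [(16, True), (15, False), (0, False)])
    def test_fifteen_percent_boundary(self, n_censored, expected):
        mask = CensorMask(censored=np.arange(100) < n_censored,
                          reasons=["velocity_jump"] * n_censored + [None] * (100 - n_censored),
                          censored_fraction=n_censored / 100,
                          discard=n_censored / 100 > 0.15)
        assert apply_discard_rule(mask) is expected

    @given(st.lists(st.booleans(), min_size=1, max_size=300))
    def test_depends_only_on_censored_fraction(self, flags):
        arr = np.array(flags)
        mask = CensorMask(censored=arr, reasons=[None] * len(arr),
                          censored_fraction=float(arr.mean()),
                          discard=arr.mean() > 0.15)
        assert apply_discard_rule(mask) == (arr.mean() > 0.15)


class TestResample:
    def test_constant_series(self):
        cyc = make_cycles([55.0] * 20, means=[50.0] * 20)
        series = resample_to_2hz(cyc, censor_cycles(cyc), duration=20.0)
        inside = ~np.isnan(series.value)
        assert np.allclose(series.value[inside], 50.0)
        assert np.allclose(np.diff(series.time), 0.5)

    def test_linear_ramp_interpolates_exactly(self):
        means = 40.0 + 0.5 * np.arange(30)  # linear in cycle midpoint time
        cyc = make_cycles(means + 5.0, means=means)
        series = resample_to_2hz(cyc, censor_cycles(cyc), duration=30.0)
        mid = cyc.onset + 0.5
        expected = 40.0 + 0.5 * (series.time - mid[0])
        inside = (series.time >= mid[0]) & (series.time <= mid[-1])
        np.testing.assert_allclose(series.value[inside], expected[inside], atol=1e-12)
        assert np.isnan(series.value[~inside]).all()

    def test_censored_gap_bridged_linearly(self):
        means = np.array([50.0, 50.0, 50.0, 60.0, 70.0, 70.0, 70.0])
        cyc = make_cycles(means + 5.0, means=means)
        cyc.rr[3] = 0.15  # implausible RR censors the interior cycle
        mask = censor_cycles(cyc, jump_max=1000.0)
        assert mask.censored[3] and mask.censored.sum() == 1
        series = resample_to_2hz(cyc, mask, duration=7.0)
        # between midpoints 2.5 and 4.5 the series is the two-point line
        sel = (series.time >= 2.5) & (series.time <= 4.5)
        np.testing.assert_allclose(series.value[sel],
                                   50.0 + 10.0 * (series.time[sel] - 2.5), atol=1e-12)

    def test_all_censored_rejected(self):
        cyc = make_cycles([60.0] * 4)
        cyc.rr[:] = 0.1
        mask = censor_cycles(cyc)
        with pytest.raises(ValueError):
            resample_to_2hz(cyc, mask, duration=4.0)


class TestSmoothing:
    def test_constant_preserved(self):
        s = SmoothedSeries(time=np.arange(0, 30, 0.5), value=np.full(60, 42.0))
        out = smooth_3s_9s(s)
        np.testing.assert_allclose(out.value, 42.0)

    def test_three_block_hand_computation(self):
        # blocks of constant value 10, 20, 30 -> smoothed 15, 20, 25
        v = np.repeat([10.0, 20.0, 30.0], 6)
        s = SmoothedSeries(time=np.arange(0, 9, 0.5), value=v)
        out = smooth_3s_9s(s)
        np.testing.assert_allclose(out.value, [15.0, 20.0, 25.0])
        np.testing.assert_allclose(out.time, [1.5, 4.5, 7.5])

    def test_single_sample_spike_deflection(self):
        # +6 on one sample -> +1 on its block -> +1/3 after 3-block smoothing
        v = np.zeros(60)
        v[30] = 6.0
        s = SmoothedSeries(time=np.arange(0, 30, 0.5), value=v)
        out = smooth_3s_9s(s)
        assert out.value.max() == pytest.approx(1.0 / 3.0)

    def test_partial_final_block_dropped(self):
        s = SmoothedSeries(time=np.arange(0, 8, 0.5), value=np.ones(16))
        assert len(smooth_3s_9s(s).value) == 2

    def test_too_short_rejected(self):
        s = SmoothedSeries(time=np.array([0.0, 0.5]), value=np.ones(2))
        with pytest.raises(ValueError):
            smooth_3s_9s(s)

    @given(st.floats(-5, 5), st.floats(-100, 100), st.integers(0, 6))
    def test_commutes_with_affine_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(50, 10, 48)
        t = np.arange(0, 24, 0.5)
        f_v = smooth_3s_9s(SmoothedSeries(time=t, value=v)).value
        f_av = smooth_3s_9s(SmoothedSeries(time=t, value=a * v + b)).value
        np.testing.assert_allclose(f_av, a * f_v + b, atol=1e-9)


class TestAverageBouts:
    def _block(self, v):
        v = np.asarray(v, dtype=float)
        s = SmoothedSeries(time=np.arange(0, len(v) * 3, 0.5)[: len(v) * 6],
                           value=np.repeat(v, 6))
        return smooth_3s_9s(s)

    def test_identical_bouts_idempotent(self):
        b = self._block([10, 20, 30])
        out = average_bouts([b, b])
        np.testing.assert_allclose(out.value, b.value)

    def test_symmetric_bouts_average_to_constant(self):
        b1 = self._block([10, 20, 30])
        b2 = self._block([30, 20, 10])
        np.testing.assert_allclose(average_bouts([b1, b2]).value, 20.0)

    def test_discarded_bout_excluded(self):
        b = self._block([10, 20, 30])
        out = average_bouts([b])  # the other bout never made it here
        np.testing.assert_allclose(out.value, b.value)
        assert out.provenance == b.provenance

    def test_no_surviving_bouts_rejected(self):
        with pytest.raises(ValueError):
            average_bouts([])

    def test_nan_excluded_pairwise(self):
        b1, b2 = self._block([10, 20, 30]), self._block([30, 20, 10])
        b1.value[0] = np.nan
        out = average_bouts([b1, b2])
        assert out.value[0] == pytest.approx(b2.value[0])
        assert out.value[1] == pytest.approx((b1.value[1] + b2.value[1]) / 2)
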