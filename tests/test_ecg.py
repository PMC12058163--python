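"""ECG filtering, delineation, interval averaging and QT correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from cardioqt.ecg import (
    ECGRecord,
    average_intervals,
    delineate_record,
    detect_r_peaks,
    highpass_baseline,
    qtc_bazett_human,
    qtc_hodges,
    qtc_mitchell_mouse,
    t_wave_metrics,
)
from cardioqt.simulate import ECGSpec, gen_ecg


class TestHighpass:
    def test_removes_dc(self):
        rec = ECGRecord(np.ones(4000), 1000.0)
        out = highpass_baseline(rec, 0.5)
        trim = 1000  # one settling length off each edge
        assert np.max(np.abs(out.samples[trim:-trim])) < 1e-6

    def test_preserves_in_band_amplitude(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        rec = ECGRecord(np.sin(2 * np.pi * 10.0 * t), fs)
        out = highpass_baseline(rec, 0.5)
        # analytic zero-phase magnitude response of the forward-backward filter
        sos = sps.butter(2, 0.5, btype="highpass", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10.0], fs=fs)
        expected = np.abs(h[0]) ** 2
        measured = np.max(np.abs(out.samples[2000:-2000]))
        assert measured == pytest.approx(expected, rel=0.01)
        assert measured == pytest.approx(1.0, rel=0.01)

    def test_attenuates_baseline_wander(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        wander = 0.5 * np.sin(2 * np.pi * 0.2 * t)
        out = highpass_baseline(ECGRecord(wander, fs), 0.5)
        assert np.max(np.abs(out.samples[5000:-5000])) < 0.05

    def test_same_length_and_validation(self):
        rec = ECGRecord(np.random.default_rng(0).normal(size=1000), 1000.0)
        assert highpass_baseline(rec, 0.5).n == rec.n
        with pytest.raises(ValueError):
            highpass_baseline(rec, 600.0)  # beyond Nyquist
        with pytest.raises(ValueError):
            ECGRecord(np.array([1.0, np.nan]), 1000.0)


class TestRPeaks:
    def test_counts_and_accuracy(self, mouse_ecg):
        spec, record, truth, filtered, _ = mouse_ecg
        peaks = detect_r_peaks(filtered)
        assert len(peaks) == spec.n_beats
        err_ms = np.abs(peaks - np.array([t.r_peak for t in truth])) * 1000 / record.sampling_rate
        assert np.max(err_ms) <= 2.0

    def test_flat_signal_empty_with_warning(self):
        rec = ECGRecord(np.zeros(1000), 1000.0)
        with pytest.warns(UserWarning):
            assert detect_r_peaks(rec).size == 0

    def test_noise_robustness(self):
        base = ECGSpec(noise_sd_mV=0.0, wander_mV=0.0, qt_sd_ms=0.0, n_beats=20)
        noisy = ECGSpec(noise_sd_mV=0.05, wander_mV=0.0, qt_sd_ms=0.0, n_beats=20)
        n0 = len(detect_r_peaks(highpass_baseline(gen_ecg(base)[0], 0.5)))
        n1 = len(detect_r_peaks(highpass_baseline(gen_ecg(noisy)[0], 0.5)))
        assert n0 == n1 == 20


class TestDelineation:
    def test_intervals_match_generator_truth(self, mouse_ecg):
        spec, record, truth, filtered, beats = mouse_ecg
        iv = average_intervals(beats, filtered)
        fs = record.sampling_rate
        truth_qt = np.mean([t.interval_ms(fs, "q_onset", "t_end90") for t in truth])
        assert iv.QT_ms == pytest.approx(truth_qt, abs=2.0)
        assert iv.PR_ms == pytest.approx(spec.pr_ms, abs=2.0)
        assert iv.QRS_ms == pytest.approx(spec.qrs_ms, abs=2.0)
        assert iv.RR_ms == pytest.approx(spec.rr_ms, abs=2.0)
        assert iv.HR_bpm == pytest.approx(60000.0 / iv.RR_ms)

    def test_human_record_roundtrip(self):
        # the 0.5-Hz bidirectional high-pass slightly distorts the broad
        # human T wave, biasing the shallow 90%-decline crossing by a few ms
        # (~1% of QT); tolerances reflect that measurement physics
        spec = ECGSpec.human(n_beats=12, qt_sd_ms=0.0)
        record, truth = gen_ecg(spec)
        filtered = highpass_baseline(record, 0.5)
        beats = delineate_record(filtered)
        iv = average_intervals(beats, filtered)
        assert iv.QT_ms == pytest.approx(spec.qt_ms, abs=6.0)
        assert iv.PR_ms == pytest.approx(spec.pr_ms, abs=4.0)
        assert iv.QRS_ms == pytest.approx(spec.qrs_ms, abs=4.0)
        assert iv.RR_ms == pytest.approx(spec.rr_ms, rel=0.01)

    def test_rr_accuracy_across_mouse_rate_range(self):
        for hr in (300.0, 500.0, 700.0):
            spec = ECGSpec(hr_bpm=hr, pr_ms=30.0, qrs_ms=8.0, qt_ms=35.0,
                           n_beats=20, qt_sd_ms=0.0)
            record, _ = gen_ecg(spec)
            filtered = highpass_baseline(record, 0.5)
            peaks = detect_r_peaks(filtered, min_rr_ms=0.5 * spec.rr_ms)
            rr = np.mean(np.diff(peaks)) * 1000 / record.sampling_rate
            assert rr == pytest.approx(60000.0 / hr, rel=0.01)

    def test_order_invariance_of_averaging(self, mouse_ecg):
        _, _, _, filtered, beats = mouse_ecg
        shuffled = list(beats)
        np.random.default_rng(0).shuffle(shuffled)
        a = average_intervals(beats, filtered)
        b = average_intervals(shuffled, filtered)
        assert a.QT_ms == pytest.approx(b.QT_ms)
        assert a.RR_ms == pytest.approx(b.RR_ms)

    def test_zero_beats_error(self, mouse_ecg):
        _, _, _, filtered, _ = mouse_ecg
        with pytest.raises(ValueError):
            average_intervals([], filtered)


class TestQTc:
    @pytest.mark.parametrize(
        "qt,hr,expected",
        [(480, 65, 499), (440, 52, 409), (400, 60, 400)],
    )
    def test_bazett_integer_reporting(self, qt, hr, expected):
        assert qtc_bazett_human(qt, hr).reported("integer") == expected

    @pytest.mark.parametrize("qt,hr,expected", [(400, 95, 461), (440, 52, 426)])
    def test_hodges_integer_reporting(self, qt, hr, expected):
        assert qtc_hodges(qt, hr).reported("integer") == expected

    @pytest.mark.parametrize(
        "qt,rr,expected", [(50.0, 100.0, 50.0), (60.0, 400.0, 30.0), (45.3, 121.0, 41.18)]
    )
    def test_mitchell_mouse(self, qt, rr, expected):
        assert qtc_mitchell_mouse(qt, rr).qtc_ms == pytest.approx(expected, abs=0.005)

    @given(st.floats(min_value=100, max_value=600))
    @settings(max_examples=50, deadline=None)
    def test_identity_points(self, q):
        assert qtc_bazett_human(q, 60.0).qtc_ms == pytest.approx(q, rel=1e-12)
        assert qtc_hodges(q, 60.0).qtc_ms == pytest.approx(q, rel=1e-12)
        assert qtc_mitchell_mouse(q, 100.0).qtc_ms == pytest.approx(q, rel=1e-12)

    @given(
        st.floats(min_value=100, max_value=600),
        st.floats(min_value=100, max_value=600),
        st.floats(min_value=30, max_value=200),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_qt(self, q1, q2, hr):
        if q1 == q2:
            return
        lo, hi = sorted((q1, q2))
        assert qtc_bazett_human(lo, hr).qtc_ms < qtc_bazett_human(hi, hr).qtc_ms
        assert qtc_hodges(lo, hr).qtc_ms < qtc_hodges(hi, hr).qtc_ms
        assert qtc_mitchell_mouse(lo, 60000.0 / hr).qtc_ms < qtc_mitchell_mouse(hi, 60000.0 / hr).qtc_ms

    def test_formula_recorded(self):
        assert qtc_bazett_human(400, 60).formula == "bazett_human"
        assert qtc_hodges(400, 60).formula == "hodges"
        assert qtc_mitchell_mouse(50, 100).formula == "mitchell_mouse"


class TestTWave:
    def test_amplitude_matches_generator(self, mouse_ecg):
        spec, _, _, filtered, beats = mouse_ecg
        tw = t_wave_metrics(filtered, beats)
        assert tw.amplitude_mV == pytest.approx(spec.t_amplitude_mV, abs=0.01)
        assert tw.n_beats_area == 5
        assert not tw.area_from_fewer_than_5

    def test_rectangular_t_wave_area(self):
        # a synthetic beat whose T wave is a flat-top rectangle of known area
        fs = 4000.0
        n = int(0.4 * fs)
        v = np.zeros(n)
        t = np.arange(n) / fs * 1000.0
        v[(t >= 100.0) & (t < 101.0)] = 1.0  # R spike
        h, w = 0.3, 20.0
        v[(t >= 140.0) & (t < 140.0 + w)] = h
        from cardioqt.ecg import BeatFiducials

        beat = BeatFiducials(
            r_peak=100.0 * fs / 1000, isoelectric_level=0.0,
            q_onset=98.0 * fs / 1000, s_end=104.0 * fs / 1000,
            t_peak=150.0 * fs / 1000, t_end90=161.0 * fs / 1000,
        )
        rec = ECGRecord(v, fs)
        tw = t_wave_metrics(rec, [beat])
        # area from QRS end to T end90: rectangle portion within [104, 161] ms
        assert tw.area_mV_ms == pytest.approx(h * w, rel=0.05)
        assert tw.area_from_fewer_than_5

    def test_no_t_wave_raises(self):
        from cardioqt.ecg import BeatFiducials

        rec = ECGRecord(np.zeros(1000), 1000.0)
        beat = BeatFiducials(r_peak=100.0, isoelectric_level=0.0)
        with pytest.raises(ValueError):
            t_wave_metrics(rec, [beat])
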