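"""Heart rate, respiration, adaptation subtraction and LDF metrics."""

import numpy as np
import pytest

from synckit import physio
from synckit.session import LaserEvent, TimeSeries


class TestHeartRate:
    def test_impulse_train_400_bpm(self, fixtures):
        hr = physio.heart_rate(fixtures["ecg_impulses"])
        assert np.median(hr.bpm.slice(5.0, 55.0)) == pytest.approx(400.0, abs=1.0)

    def test_normalized_baseline_is_one(self, fixtures):
        laser = LaserEvent(onset=40.0, duration=10.0, pulse_frequency=20)
        hr = physio.heart_rate(fixtures["ecg_impulses"], [laser])
        base = hr.normalized[0].slice(10.0, 40.0)
        assert base.mean() == pytest.approx(1.0, abs=1e-6)

    def test_amplitude_rescaling_invariant(self, fixtures):
        ecg = fixtures["ecg_impulses"]
        scaled = TimeSeries(ecg.values * 37.0, ecg.sample_rate)
        a = physio.heart_rate(ecg).r_peak_times
        b = physio.heart_rate(scaled).r_peak_times
        np.testing.assert_array_equal(a, b)

    def test_programmed_bradycardia_recovered(self, small_session):
        cfg, session, truth = small_session
        laser = session.lasers[0]
        hr = physio.heart_rate(session.streams["ecg"], [laser])
        stim_min = hr.normalized[0].slice(laser.onset, laser.end).min()
        assert stim_min < 0.2  # asystole drives the rate towards zero
        longest = np.diff(hr.r_peak_times).max()
        assert longest > cfg.asystole_duration * 0.8


class TestRespiration:
    def test_three_hz_sinusoid(self):
        fs = 250.0
        t = np.arange(int(60 * fs)) / fs
        rr = physio.respiration_rate(TimeSeries(np.sin(2 * np.pi * 3 * t), fs))
        assert np.median(rr.bpm.slice(5.0, 55.0)) == pytest.approx(180.0, abs=2.0)

    def test_flat_signal_undefined(self):
        with pytest.warns(UserWarning):
            out = physio.respiration_rate(TimeSeries(np.ones(5000), 250.0))
        assert out is None


class TestAdaptationSubtract:
    def test_periodic_trace_cancels(self):
        fs = 100.0
        t = np.arange(int(40 * fs)) / fs
        ts = TimeSeries(np.sin(2 * np.pi * t / 10.0), fs)  # period = 10 s
        out = physio.adaptation_subtract(ts, shift=10.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_constant_trace_zero(self):
        out = physio.adaptation_subtract(TimeSeries(np.full(1000, 2.0), 100.0), 1.0)
        np.testing.assert_allclose(out.values, 0.0)

    def test_linearity(self, rng):
        fs = 100.0
        a = rng.standard_normal(2000)
        b = rng.standard_normal(2000)
        out_ab = physio.adaptation_subtract(TimeSeries(a + b, fs), 2.0)
        out_a = physio.adaptation_subtract(TimeSeries(a, fs), 2.0)
        out_b = physio.adaptation_subtract(TimeSeries(b, fs), 2.0)
        np.testing.assert_allclose(out_ab.values, out_a.values + out_b.values,
                                   atol=1e-12)

    def test_transient_isolated_from_periodic_dips(self):
        fs, shift = 50.0, 10.0
        t = np.arange(int(60 * fs)) / fs
        periodic = 0.3 * np.sin(2 * np.pi * t / shift)
        transient = np.exp(-0.5 * ((t - 30.0) / 1.5) ** 2)
        out = physio.adaptation_subtract(TimeSeries(periodic + transient, fs),
                                         shift)
        expect = (np.exp(-0.5 * ((t - 30.0) / 1.5) ** 2)
                  - np.exp(-0.5 * ((t - 40.0) / 1.5) ** 2))
        sel = slice(int(shift * fs), None)
        np.testing.assert_allclose(out.values, expect[sel], atol=1e-9)

    def test_shift_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            physio.adaptation_subtract(TimeSeries(np.zeros(100), 100.0), 2.0)


def _triangle(desc=0.1, asc=0.1, fs=20.0):
    """Baseline 1 with a V dip starting at 30 s: down at ``desc``/s to 0.5
    depth, up at ``asc``/s."""
    t = np.arange(int(200 * fs)) / fs
    v = np.ones(t.size)
    t_down = 0.5 / desc
    t_up = 0.5 / asc
    for i, ti in enumerate(t):
        if 30 <= ti < 30 + t_down:
            v[i] = 1 - desc * (ti - 30)
        elif 30 + t_down <= ti < 30 + t_down + t_up:
            v[i] = 0.5 + asc * (ti - 30 - t_down)
    return TimeSeries(v, fs)


class TestLDFMetrics:
    LASER = LaserEvent(onset=30.0, duration=30.0, pulse_frequency=20)

    def test_symmetric_triangle(self):
        m = physio.ldf_metrics(_triangle(), self.LASER, median_window=0.0)
        assert m.rate_coefficient == pytest.approx(1.0, abs=1e-9)
        assert m.fwhm_transit == pytest.approx(5.0, abs=0.1)
        assert m.min_during_stim == pytest.approx(0.5, abs=1e-9)
        assert m.latency_50 is None  # touches 0.5, never crosses below

    def test_asymmetric_slopes(self):
        m = physio.ldf_metrics(_triangle(desc=0.2, asc=0.1), self.LASER,
                               median_window=0.0)
        assert m.rate_coefficient == pytest.approx(0.5, abs=0.01)

    def test_time_reversed_dip_reciprocal(self):
        a = physio.ldf_metrics(_triangle(desc=0.2, asc=0.1), self.LASER,
                               median_window=0.0)
        b = physio.ldf_metrics(_triangle(desc=0.1, asc=0.2), self.LASER,
                               median_window=0.0)
        assert a.rate_coefficient * b.rate_coefficient == pytest.approx(1.0,
                                                                        abs=0.01)

    def test_flat_trace(self):
        ts = TimeSeries(np.ones(int(200 * 20.0)), 20.0)
        m = physio.ldf_metrics(ts, self.LASER, median_window=0.0)
        assert m.min_during_stim == 1.0
        assert m.latency_50 is None and m.fwhm_transit is None
        assert m.late_mean == pytest.approx(1.0)

    def test_raw_scale_invariance(self):
        ts = _triangle()
        scaled = TimeSeries(ts.values * 413.0, ts.sample_rate)
        a = physio.ldf_metrics(ts, self.LASER, median_window=0.0)
        b = physio.ldf_metrics(scaled, self.LASER, median_window=0.0)
        assert a.min_during_stim == pytest.approx(b.min_during_stim)
        assert a.rate_coefficient == pytest.approx(b.rate_coefficient)

    def test_deeper_dip_at_higher_pulse_rate(self, small_session):
        """Generator programs a deeper LDF dip for 20-Hz than lower rates."""
        from synckit import synth
        cfg = synth.GeneratorConfig(
            duration=400.0, seed=21,
            laser_plan=((10, 60.0, 30.0), (20, 250.0, 30.0)),
            regions={"SSp": 2}, n_components=4, latent_dim=2)
        session, _ = synth.generate_session(cfg)
        mins = []
        for ev in session.lasers:
            m = physio.ldf_metrics(session.streams["ldf"], ev,
                                   trial_end=ev.onset + 100.0)
            mins.append(m.min_during_stim)
        assert mins[1] < mins[0]


class TestAlignment:
    def test_single_trial_identity(self):
        fs = 50.0
        ts = TimeSeries(np.sin(np.arange(int(60 * fs)) / fs), fs)
        grid, mean, mat = physio.align_to_syncope([ts], [30.0], pre=5.0, post=10.0)
        np.testing.assert_allclose(mean, mat[0])
        np.testing.assert_allclose(
            mean, np.interp(grid + 30.0, ts.times(), ts.values))

    def test_identical_trials_different_offsets_zero_variance(self):
        fs = 50.0
        t = np.arange(int(120 * fs)) / fs
        v = np.exp(-0.5 * ((t - 40.0) / 2.0) ** 2)
        ts1 = TimeSeries(v, fs)
        v2 = np.exp(-0.5 * ((t - 70.0) / 2.0) ** 2)
        ts2 = TimeSeries(v2, fs)
        grid, mean, mat = physio.align_to_syncope([ts1, ts2], [40.0, 70.0],
                                                  pre=5.0, post=5.0)
        np.testing.assert_allclose(mat.std(axis=0), 0.0, atol=1e-9)

    def test_no_events_logs_and_returns_empty(self):
        with pytest.warns(UserWarning):
            grid, mean, mat = physio.align_to_syncope([], [])
        assert mean is None

    def test_event_sequence_ordering_recovered(self, small_session):
        """Programmed ordering: heart-rate min, then LDF min, then power drop."""
        from synckit import spectral
        from synckit.session import AnalysisWindow
        cfg, session, truth = small_session
        laser = session.lasers[0]
        hr = physio.heart_rate(session.streams["ecg"], [laser])
        spec = spectral.wavelet_power(
            session.streams["lfp"],
            AnalysisWindow(laser.onset - 30, laser.onset), time_downsample=10)
        sync = spectral.detect_syncope(spec, laser)
        df = physio.event_sequence_table([laser], hr.normalized,
                                         session.streams["ldf"], [sync])
        row = df.iloc[0]
        assert row.hr_min_latency < row.ldf_min_latency < row.power_drop_latency
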