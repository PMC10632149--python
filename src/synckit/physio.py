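"""Cardiovascular, respiratory and cerebral-blood-flow signal metrics.

ECG R-peak detection and instantaneous heart rate with per-stimulation
baseline normalization, respiration rate from the chest piezo, the stated
quantification windows, shifted-subtraction isolation of drug transients,
the six laser-Doppler flowmetry (LDF) metrics, and syncope-aligned trial
averaging with the event-sequence table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .session import LaserEvent, SyncopeEvent, TimeSeries

__all__ = ["HeartRateTrace", "LDFMetrics", "heart_rate", "respiration_rate",
           "stim_window_stats", "adaptation_subtract", "ldf_metrics",
           "align_to_syncope", "event_sequence_table"]


@dataclass
class HeartRateTrace:
    """Instantaneous smoothed rate with per-laser normalized copies."""

    bpm: TimeSeries
    r_peak_times: np.ndarray
    normalized: list[TimeSeries]          # one per laser event
    baselines: list[float]                # bpm baseline per laser


@dataclass
class LDFMetrics:
    """The six LDF summary metrics of one stimulation trial (baseline = 1)."""

    latency_50: float | None       # s to fall below 50% of baseline
    min_during_stim: float         # fraction of baseline
    fwhm_transit: float | None     # s below halfway between baseline and minimum
    late_mean: float | None        # mean over the final 100 s of the trial
    recovery_duration: float | None  # s after stimulus end to regain baseline
    rate_coefficient: float | None   # ascent slope / |descent slope|


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 3
              ) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _rate_from_events(event_times: np.ndarray, series: TimeSeries,
                      smooth_window: float) -> TimeSeries:
    """Events/min interpolated onto the sample grid, 1-s moving mean."""
    t = series.times()
    intervals = np.diff(event_times)
    mids = event_times[:-1] + intervals / 2
    inst = 60.0 / intervals
    rate = np.interp(t, mids, inst)
    w = max(int(round(smooth_window * series.sample_rate)), 1)
    rate = ndimage.uniform_filter1d(rate, size=w, mode="nearest")
    return TimeSeries(rate, series.sample_rate, series.t0, series.label + "_rate")


def _normalize_per_event(rate: TimeSeries, lasers: list[LaserEvent],
                         baseline: float) -> tuple[list[TimeSeries], list[float]]:
    normalized, baselines = [], []
    for ev in lasers:
        base = rate.slice(ev.onset - baseline, ev.onset)
        if base.size == 0 or base.mean() <= 0:
            raise ValueError(f"no usable baseline before laser at {ev.onset:.1f} s")
        b = float(base.mean())
        normalized.append(TimeSeries(rate.values / b, rate.sample_rate,
                                     rate.t0, rate.label + "_norm"))
        baselines.append(b)
    return normalized, baselines


def heart_rate(ecg: TimeSeries, lasers: list[LaserEvent] | None = None,
               band: tuple[float, float] = (10.0, 50.0),
               smooth_window: float = 1.0, baseline: float = 30.0,
               prominence_mads: float = 4.0, min_rr: float = 0.07) -> HeartRateTrace:
    """ECG to instantaneous bpm via 10-50 Hz bandpass and R-peak detection.

    Positive peaks are found with an adaptive prominence (4x the median
    absolute deviation of the filtered trace); bpm = 60/RR interpolated to
    the sample grid and smoothed with a 1-s sliding window.  Per laser, a
    normalized copy (pre-laser 30-s baseline mean = 1) is returned.
    """
    if ecg.sample_rate < 200:
        raise ValueError("ECG sample rate must be >= 200 Hz for R-peak timing")
    filt = _bandpass(ecg.values, ecg.sample_rate, band)
    mad = np.median(np.abs(filt - np.median(filt)))
    dist = int(min_rr * ecg.sample_rate)
    peaks, _ = signal.find_peaks(filt, prominence=prominence_mads * mad,
                                 distance=dist)
    if peaks.size < 3:
        raise ValueError("too few R peaks detected")
    # second pass: R peaks tower over band-limited inter-beat ripple, so gate
    # at half the typical height of the taller candidates
    h = filt[peaks]
    thr = 0.5 * np.median(h[h >= np.median(h)])
    peaks, _ = signal.find_peaks(filt, height=thr,
                                 prominence=prominence_mads * mad, distance=dist)
    if peaks.size < 3:
        raise ValueError("too few R peaks detected")
    peak_times = ecg.t0 + peaks / ecg.sample_rate
    rate = _rate_from_events(peak_times, ecg, smooth_window)
    normalized, baselines = _normalize_per_event(rate, lasers or [], baseline)
    return HeartRateTrace(bpm=rate, r_peak_times=peak_times,
                          normalized=normalized, baselines=baselines)


def respiration_rate(piezo: TimeSeries, lasers: list[LaserEvent] | None = None,
                     band: tuple[float, float] = (1.0, 10.0),
                     smooth_window: float = 1.0, baseline: float = 30.0,
                     min_interval: float = 0.15):
    """Breaths/min from the chest piezo; smoothing and normalization as for
    heart rate.  Returns ``(HeartRateTrace-like, None)`` semantics: a trace
    object, or None values when no breath events are detectable."""
    if np.ptp(piezo.values) < 1e-12:
        warnings.warn("flat piezo signal: respiration rate undefined")
        return None
    filt = _bandpass(piezo.values, piezo.sample_rate, band)
    mad = np.median(np.abs(filt - np.median(filt)))
    if mad == 0:
        warnings.warn("flat piezo signal: respiration rate undefined")
        return None
    peaks, _ = signal.find_peaks(filt, prominence=2.0 * mad,
                                 distance=int(min_interval * piezo.sample_rate))
    if peaks.size < 3:
        warnings.warn("too few breaths detected: respiration rate undefined")
        return None
    breath_times = piezo.t0 + peaks / piezo.sample_rate
    rate = _rate_from_events(breath_times, piezo, smooth_window)
    normalized, baselines = _normalize_per_event(rate, lasers or [], baseline)
    return HeartRateTrace(bpm=rate, r_peak_times=breath_times,
                          normalized=normalized, baselines=baselines)


def stim_window_stats(norm_trace: TimeSeries, laser: LaserEvent,
                      stim_window: tuple[float, float] = (6.0, 24.0),
                      post_window: tuple[float, float] = (30.0, 60.0)) -> dict:
    """Mean of a normalized rate trace over the stated stimulation and
    post-stimulation windows (seconds relative to laser onset)."""
    out = {"stim_window": stim_window, "post_window": post_window}
    seg = norm_trace.slice(laser.onset + stim_window[0], laser.onset + stim_window[1])
    out["stim_change"] = float(seg.mean()) if seg.size else None
    seg = norm_trace.slice(laser.onset + post_window[0], laser.onset + post_window[1])
    n_expected = int((post_window[1] - post_window[0]) * norm_trace.sample_rate)
    out["post_change"] = float(seg.mean()) if seg.size >= n_expected else None
    if out["post_change"] is None:
        warnings.warn("trace shorter than the post window; post change missing")
    return out


def adaptation_subtract(trace: TimeSeries, shift: float) -> TimeSeries:
    """Shifted self-subtraction isolating drug transients.

    output(t) = trace(t) - trace(t - shift), defined for t >= shift; a
    stimulus-locked component with period equal to the shift cancels.
    """
    if shift <= 0:
        raise ValueError("shift must be > 0")
    m = int(round(shift * trace.sample_rate))
    if m >= trace.values.size:
        raise ValueError("shift exceeds the trace duration")
    out = trace.values[m:] - trace.values[:-m]
    return TimeSeries(out, trace.sample_rate, trace.t0 + shift,
                      trace.label + "_adapt")


def _first_crossing(values: np.ndarray, times: np.ndarray, level: float,
                    below: bool) -> float | None:
    hit = np.where(values < level if below else values >= level)[0]
    return float(times[hit[0]]) if hit.size else None


def ldf_metrics(ldf: TimeSeries, laser: LaserEvent, baseline: float = 30.0,
                median_window: float = 0.5, stim_duration: float = 30.0,
                late_window: float = 100.0,
                trial_end: float | None = None) -> LDFMetrics:
    """The six LDF metrics of one stimulation trial.

    The trace is normalized to the 30-s pre-stimulation baseline and median
    filtered over 500 ms.  Latency-50 is the first post-onset time below
    0.5; the transit time is the width of the contiguous stretch below the
    half-minimum level (1 + min)/2 around the trial minimum; recovery is
    the first time at or above baseline after the 30-s stimulus window; the
    rate coefficient is the ratio of the ascending to |descending|
    least-squares slopes within the stimulation window.
    """
    base = ldf.slice(laser.onset - baseline, laser.onset)
    if base.size == 0 or base.mean() == 0:
        raise ValueError("no usable LDF baseline before stimulation")
    norm = ldf.values / base.mean()
    k = int(round(median_window * ldf.sample_rate))
    if k > 1:
        norm = ndimage.median_filter(norm, size=k + (k % 2 == 0), mode="nearest")
    t = ldf.times()
    end = trial_end if trial_end is not None else t[-1]

    stim = (t >= laser.onset) & (t < laser.onset + stim_duration)
    if not stim.any():
        raise ValueError("trial does not contain the stimulation window")
    v_stim, t_stim = norm[stim], t[stim]
    min_during_stim = float(v_stim.min())

    post = (t >= laser.onset) & (t <= end)
    lat = _first_crossing(norm[post], t[post], 0.5, below=True)
    latency_50 = (lat - laser.onset) if lat is not None else None

    # transit time: contiguous stretch below the half-minimum level
    fwhm = None
    trial = (t >= laser.onset) & (t <= end)
    v_tr, t_tr = norm[trial], t[trial]
    i_min = int(np.argmin(v_tr))
    level = (1.0 + v_tr[i_min]) / 2.0
    below = v_tr < level
    if below[i_min]:
        i0 = i_min
        while i0 > 0 and below[i0 - 1]:
            i0 -= 1
        i1 = i_min
        while i1 < below.size - 1 and below[i1 + 1]:
            i1 += 1
        fwhm = float(t_tr[i1] - t_tr[i0] + 1.0 / ldf.sample_rate)

    late = (t >= end - late_window) & (t <= end)
    late_mean = float(norm[late].mean()) if late.any() else None

    after = (t >= laser.onset + stim_duration) & (t <= end)
    rec = _first_crossing(norm[after], t[after], 1.0, below=False)
    recovery = (rec - (laser.onset + stim_duration)) if rec is not None else None

    # slopes on the dip limbs only: descent from the last at-baseline sample
    # before the minimum, ascent until the first at-baseline sample after it
    rate_coefficient = None
    i_sm = int(np.argmin(v_stim))
    if 1 <= i_sm < v_stim.size - 1:
        at_base = v_stim >= 1.0
        pre = np.where(at_base[:i_sm])[0]
        i0 = int(pre[-1]) if pre.size else 0
        post = np.where(at_base[i_sm:])[0]
        i1 = i_sm + int(post[0]) if post.size else v_stim.size - 1
        if i0 < i_sm < i1:
            down = np.polyfit(t_stim[i0:i_sm + 1], v_stim[i0:i_sm + 1], 1)[0]
            up = np.polyfit(t_stim[i_sm:i1 + 1], v_stim[i_sm:i1 + 1], 1)[0]
            if down < 0 and up > 0:
                rate_coefficient = float(up / abs(down))

    return LDFMetrics(latency_50=latency_50, min_during_stim=min_during_stim,
                      fwhm_transit=fwhm, late_mean=late_mean,
                      recovery_duration=recovery, rate_coefficient=rate_coefficient)


def align_to_syncope(trials: list[TimeSeries], syncope_onsets: list[float],
                     pre: float = 10.0, post: float = 30.0,
                     grid_rate: float | None = None):
    """Re-reference trial traces to syncope onset and average.

    Returns ``(rel_times, mean_trace, aligned_matrix)``; empty inputs yield
    ``(grid, None, None)`` with a log note.
    """
    if not trials or not syncope_onsets:
        warnings.warn("no syncope events: nothing to align")
        return np.array([]), None, None
    fs = grid_rate or trials[0].sample_rate
    grid = np.arange(-pre, post, 1.0 / fs)
    rows = []
    for ts, onset in zip(trials, syncope_onsets):
        rows.append(np.interp(grid + onset, ts.times(), ts.values))
    aligned = np.vstack(rows)
    return grid, aligned.mean(axis=0), aligned


def event_sequence_table(lasers: list[LaserEvent],
                         hr_norm: list[TimeSeries],
                         ldf: TimeSeries | None,
                         syncope: list[SyncopeEvent | None],
                         eyeroll_latencies: list[float] | None = None,
                         search: float = 30.0) -> pd.DataFrame:
    """Per-trial latencies (s from laser onset) of the syncope event sequence:
    heart-rate minimum, LDF minimum, 50% power drop, and the optional
    manually annotated eye-roll."""
    rows = []
    for i, ev in enumerate(lasers):
        row = {"laser_onset": ev.onset, "pulse_hz": ev.pulse_frequency}
        if i < len(hr_norm) and hr_norm[i] is not None:
            tr = hr_norm[i]
            seg = tr.slice(ev.onset, ev.onset + search)
            row["hr_min_latency"] = float(np.argmin(seg) / tr.sample_rate) if seg.size else np.nan
        if ldf is not None:
            seg = ldf.slice(ev.onset, ev.onset + search)
            row["ldf_min_latency"] = float(np.argmin(seg) / ldf.sample_rate) if seg.size else np.nan
        sync = syncope[i] if i < len(syncope) else None
        row["power_drop_latency"] = (sync.onset - ev.onset) if sync is not None else np.nan
        if eyeroll_latencies is not None and i < len(eyeroll_latencies):
            row["eyeroll_latency"] = eyeroll_latencies[i]
        rows.append(row)
    return pd.DataFrame(rows)
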