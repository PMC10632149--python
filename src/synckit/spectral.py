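"""Wavelet and FFT power analysis of EEG/LFP.

Implements the analytic generalized Morse wavelet spectrogram (80
log-spaced frequencies, 0.5-120 Hz) with per-frequency baseline
normalization, syncope onset/offset detection from the smoothed 8-100 Hz
band-average power (50% drop / 80% recovery), the Monte-Carlo cluster
permutation test on time x frequency maps, and 2-s segment FFT band power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .session import AnalysisWindow, LaserEvent, SyncopeEvent, TimeSeries

__all__ = [
    "WaveletSpectrogram", "ClusterTestResult", "notch_filter", "morse_freqs",
    "wavelet_power", "detect_syncope", "light_contrast_map",
    "cluster_permutation_test", "band_power_fft", "EEG_BANDS",
]

EEG_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0), "low_gamma": (30.0, 59.0), "high_gamma": (61.0, 120.0),
}


@dataclass
class WaveletSpectrogram:
    """Frequency x time power map with baseline-normalization metadata."""

    freqs: np.ndarray          # Hz, strictly increasing, 0.5..120, 80 values
    times: np.ndarray          # s, session clock
    power: np.ndarray          # (n_freqs, n_times), non-negative
    baseline_window: AnalysisWindow | None = None
    normalized: bool = False

    def band_mean(self, band: tuple[float, float]) -> np.ndarray:
        """Average power over frequency rows inside ``band`` (inclusive)."""
        lo, hi = band
        rows = (self.freqs >= lo) & (self.freqs <= hi)
        if not rows.any():
            raise ValueError(f"band {band} outside spectrogram frequencies")
        return self.power[rows].mean(axis=0)


@dataclass
class ClusterTestResult:
    """Significant time x frequency clusters from the permutation test."""

    clusters: pd.DataFrame     # freq_lo, freq_hi, t_lo, t_hi, area, sign, p_value
    n_permutations: int
    alpha_per_tail: float = 0.025
    diff_map: np.ndarray | None = None
    label_map: np.ndarray | None = field(default=None, repr=False)


def notch_filter(series: TimeSeries, band: tuple[float, float] = (59.0, 61.0)) -> TimeSeries:
    """Remove line noise with a zero-phase notch centred in ``band``.

    The 60-Hz component is attenuated by >= 20 dB while frequencies below 55
    and above 65 Hz pass within 1 dB.
    """
    f0 = 0.5 * (band[0] + band[1])
    if series.sample_rate <= 2 * band[1]:
        raise ValueError(
            f"sample rate {series.sample_rate} Hz too low for a {band} Hz notch")
    bw = band[1] - band[0]
    b, a = signal.iirnotch(f0, Q=f0 / bw, fs=series.sample_rate)
    out = signal.filtfilt(b, a, series.values)
    return TimeSeries(out, series.sample_rate, series.t0, series.label)


def morse_freqs(n: int = 80, fmin: float = 0.5, fmax: float = 120.0) -> np.ndarray:
    """The log-spaced analysis frequencies (first exactly fmin, last fmax)."""
    f = np.logspace(np.log10(fmin), np.log10(fmax), n)
    f[0], f[-1] = fmin, fmax  # pin the endpoints against logspace round-off
    return f


def _morse_filterbank(n_samples: int, sample_rate: float, freqs: np.ndarray,
                      gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain analytic Morse wavelets, peak-normalized to 2.

    The generalized Morse wavelet has spectrum a * w^beta * exp(-w^gamma) on
    w > 0 with peak frequency w_p = (beta/gamma)^(1/gamma); each filter is
    scaled so its peak sits at the requested analysis frequency.
    """
    w = 2 * np.pi * np.fft.fftfreq(n_samples, d=1.0 / sample_rate)
    wp = (beta / gamma) ** (1.0 / gamma)
    H = np.zeros((freqs.size, n_samples))
    pos = w > 0
    lw = np.log(w[pos])
    for i, f in enumerate(freqs):
        s = wp / (2 * np.pi * f)
        # log-domain for numerical stability at beta ~ 20
        logH = beta * (np.log(s) + lw - np.log(wp)) - (s * w[pos]) ** gamma + wp ** gamma
        H[i, pos] = 2.0 * np.exp(logH)
    return H


def wavelet_power(series: TimeSeries, baseline: AnalysisWindow | None,
                  n_wavelets: int = 80, fmin: float = 0.5, fmax: float = 120.0,
                  gamma: float = 3.0, beta: float = 20.0,
                  time_downsample: int = 1) -> WaveletSpectrogram:
    """Morse-wavelet power map, normalized to the pre-stimulus baseline.

    Power at each frequency is divided by its mean over the baseline window
    so every baseline row mean is 1.  With ``baseline=None`` the raw
    (unnormalized) spectrogram is returned.  ``time_downsample`` block-averages
    the time axis by that factor before normalization.
    """
    x = np.asarray(series.values, dtype=float)
    freqs = morse_freqs(n_wavelets, fmin, fmax)
    if series.duration < 3.0 / fmin:
        warnings.warn("series shorter than a few cycles of the lowest frequency; "
                      "low-frequency rows are edge-dominated")
    H = _morse_filterbank(x.size, series.sample_rate, freqs, gamma, beta)
    X = np.fft.fft(x)
    power = np.empty((freqs.size, x.size))
    for i in range(freqs.size):
        power[i] = np.abs(np.fft.ifft(X * H[i])) ** 2

    times = series.times()
    if time_downsample > 1:
        n = (x.size // time_downsample) * time_downsample
        power = power[:, :n].reshape(freqs.size, -1, time_downsample).mean(axis=2)
        times = times[:n].reshape(-1, time_downsample).mean(axis=1)

    spec = WaveletSpectrogram(freqs=freqs, times=times, power=power,
                              baseline_window=baseline, normalized=False)
    if baseline is not None:
        _normalize_inplace(spec, baseline)
    return spec


def _normalize_inplace(spec: WaveletSpectrogram, baseline: AnalysisWindow) -> None:
    sel = (spec.times >= baseline.start) & (spec.times < baseline.end)
    if not sel.any():
        raise ValueError("baseline window contains no spectrogram samples")
    base = spec.power[:, sel].mean(axis=1)
    zero = np.where(base <= 0)[0]
    if zero.size:
        raise FloatingPointError(
            f"zero baseline power at {spec.freqs[zero[0]]:.3g} Hz; cannot normalize")
    spec.power = spec.power / base[:, None]
    spec.baseline_window = baseline
    spec.normalized = True


def detect_syncope(spec: WaveletSpectrogram, laser: LaserEvent | float,
                   band: tuple[float, float] = (8.0, 100.0),
                   onset_frac: float = 0.5, offset_frac: float = 0.8,
                   smooth_window: float = 1.0, source: str = "") -> SyncopeEvent | None:
    """Locate a syncope bout after a laser onset from band-average power.

    The 8-100 Hz average of the normalized spectrogram is smoothed with a
    centred moving mean; onset is the first post-laser time it falls below
    ``onset_frac`` and offset the first subsequent time it exceeds
    ``offset_frac``.  Returns ``None`` when power never crosses the onset
    threshold.
    """
    if not spec.normalized:
        raise ValueError("detect_syncope requires a baseline-normalized spectrogram")
    laser_onset = laser.onset if hasattr(laser, "onset") else float(laser)
    trace = spec.band_mean(band)
    dt = float(np.median(np.diff(spec.times)))
    w = max(int(round(smooth_window / dt)), 1)
    smoothed = ndimage.uniform_filter1d(trace, size=w, mode="nearest")

    after = spec.times >= laser_onset
    idx = np.where(after & (smoothed < onset_frac))[0]
    if idx.size == 0:
        return None
    onset_i = idx[0]
    rec = np.where((np.arange(spec.times.size) > onset_i) & (smoothed > offset_frac))[0]
    offset = float(spec.times[rec[0]]) if rec.size else None
    return SyncopeEvent(onset=float(spec.times[onset_i]), offset=offset,
                        band=band, source=source, laser_onset=laser_onset)


def light_contrast_map(on_trials: list[WaveletSpectrogram] | np.ndarray,
                       off_trials: list[WaveletSpectrogram] | np.ndarray) -> np.ndarray:
    """Mean power of light-off trials subtracted from light-on trials."""
    on = _trial_stack(on_trials)
    off = _trial_stack(off_trials)
    if on.shape[1:] != off.shape[1:]:
        raise ValueError("on/off trials are on different freq x time grids")
    return on.mean(axis=0) - off.mean(axis=0)


def _trial_stack(trials) -> np.ndarray:
    if isinstance(trials, np.ndarray):
        arr = np.asarray(trials, dtype=float)
        if arr.ndim != 3:
            raise ValueError("trial array must be (n_trials, n_freqs, n_times)")
        return arr
    if len(trials) == 0:
        raise ValueError("need at least one trial per condition")
    grids = {(t.power.shape, t.freqs[0], t.freqs[-1]) for t in trials}
    if len(grids) > 1:
        raise ValueError("trials are on different freq x time grids")
    return np.stack([t.power for t in trials])


def _cluster_stats(excess: np.ndarray, mask: np.ndarray):
    """Per-cluster (label_map, areas, stats) for one sign's exceedance mask.

    The cluster statistic is its pixel area, with a continuous sub-unit
    tie-break from the cluster's exceedance mass (mass/(1+mass) in [0, 1)):
    equal-area clusters rank by effect size and the permutation null of the
    maximum becomes effectively continuous, avoiding the heavy atoms a pure
    integer area statistic would put in the tail.
    """
    if not mask.any():
        return None, np.array([], dtype=int), np.array([])
    lab, n = ndimage.label(mask)
    areas = np.bincount(lab.ravel())[1:]
    mass = ndimage.sum_labels(excess, lab, index=np.arange(1, n + 1))
    stats = areas + mass / (1.0 + mass)
    return lab, areas, stats


def _max_cluster_stat(excess_pos, mask_pos, excess_neg, mask_neg):
    _, _, sp = _cluster_stats(excess_pos, mask_pos)
    _, _, sn = _cluster_stats(excess_neg, mask_neg)
    return (sp.max() if sp.size else 0.0), (sn.max() if sn.size else 0.0)


def cluster_permutation_test(on_trials, off_trials, n_perm: int = 1000,
                             alpha_per_tail: float = 0.025,
                             cluster_forming_p: float = 0.05,
                             rng: np.random.Generator | int | None = None,
                             freqs: np.ndarray | None = None,
                             times: np.ndarray | None = None) -> ClusterTestResult:
    """Monte-Carlo cluster test on light-on vs light-off power maps.

    Condition labels are shuffled ``n_perm`` times.  The per-pixel
    permutation distribution of mean differences sets the (two-sided)
    cluster-forming threshold; pixels beyond it are grouped into 4-connected
    clusters whose areas (pixel counts) are compared to the null
    distribution of the maximum cluster area of matching sign.  A cluster is
    significant when its empirical p-value is <= ``alpha_per_tail``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    on = _trial_stack(on_trials)
    off = _trial_stack(off_trials)
    if on.shape[1:] != off.shape[1:]:
        raise ValueError("on/off trials are on different freq x time grids")
    if min(len(on), len(off)) < 3:
        warnings.warn("fewer than 3 trials per condition; permutation null is coarse")
    rng = np.random.default_rng(rng)

    n_on = on.shape[0]
    F, T = on.shape[1:]
    X = np.concatenate([on, off]).reshape(n_on + off.shape[0], -1)
    n_tot = X.shape[0]
    observed = X[:n_on].mean(axis=0) - X[n_on:].mean(axis=0)

    if np.allclose(X.max(axis=0), X.min(axis=0)):
        warnings.warn("all trials identical: degenerate null, no clusters")
        empty = pd.DataFrame(columns=["freq_lo", "freq_hi", "t_lo", "t_hi",
                                      "area", "sign", "p_value"])
        return ClusterTestResult(empty, n_perm, alpha_per_tail,
                                 observed.reshape(F, T))

    perm_diffs = np.empty((n_perm, X.shape[1]))
    for p in range(n_perm):
        order = rng.permutation(n_tot)
        perm_diffs[p] = X[order[:n_on]].mean(axis=0) - X[order[n_on:]].mean(axis=0)

    lo = np.quantile(perm_diffs, cluster_forming_p / 2, axis=0)
    hi = np.quantile(perm_diffs, 1 - cluster_forming_p / 2, axis=0)

    null_max_pos = np.empty(n_perm)
    null_max_neg = np.empty(n_perm)
    hi2, lo2 = hi.reshape(F, T), lo.reshape(F, T)
    for p in range(n_perm):
        d = perm_diffs[p].reshape(F, T)
        null_max_pos[p], null_max_neg[p] = _max_cluster_stat(
            d - hi2, d > hi2, lo2 - d, d < lo2)

    obs_map = observed.reshape(F, T)
    rows = []
    label_map = np.zeros((F, T), dtype=int)
    next_label = 1
    for sign, excess, mask, null_max in (
            (1, obs_map - hi2, obs_map > hi2, null_max_pos),
            (-1, lo2 - obs_map, obs_map < lo2, null_max_neg)):
        lab, areas, cl_stats = _cluster_stats(excess, mask)
        if lab is None:
            continue
        for c in range(areas.size):
            sel = lab == c + 1
            p_val = (1 + int((null_max >= cl_stats[c]).sum())) / (n_perm + 1)
            fi, ti = np.where(sel)
            rows.append({
                "freq_lo": float(freqs[fi.min()]) if freqs is not None else int(fi.min()),
                "freq_hi": float(freqs[fi.max()]) if freqs is not None else int(fi.max()),
                "t_lo": float(times[ti.min()]) if times is not None else int(ti.min()),
                "t_hi": float(times[ti.max()]) if times is not None else int(ti.max()),
                "area": int(areas[c]), "sign": sign, "p_value": p_val,
            })
            if p_val <= alpha_per_tail:
                label_map[sel] = next_label * sign
                next_label += 1
    clusters = pd.DataFrame(rows, columns=["freq_lo", "freq_hi", "t_lo", "t_hi",
                                           "area", "sign", "p_value"])
    clusters = clusters[clusters.p_value <= alpha_per_tail].reset_index(drop=True)
    return ClusterTestResult(clusters, n_perm, alpha_per_tail, obs_map, label_map)


def band_power_fft(series: TimeSeries, segment: float = 2.0,
                   bands: dict[str, tuple[float, float]] = EEG_BANDS,
                   taper: str | None = None) -> pd.DataFrame:
    """Per-segment FFT power averaged into the six standard EEG bands.

    Non-overlapping 2-s segments; a trailing partial segment is dropped.
    Band membership is ``lo <= f < hi`` except the last band which includes
    its upper edge.  Returns a segments x bands DataFrame with a
    ``t_start`` column.
    """
    n_seg = int(round(segment * series.sample_rate))
    if series.values.size < n_seg:
        raise ValueError(f"series shorter than one {segment}-s segment")
    n = (series.values.size // n_seg) * n_seg
    segs = series.values[:n].reshape(-1, n_seg)
    if taper == "hann":
        segs = segs * np.hanning(n_seg)
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    freqs = np.fft.rfftfreq(n_seg, d=1.0 / series.sample_rate)
    spectra = np.abs(np.fft.rfft(segs, axis=1)) ** 2
    names = list(bands)
    out = {}
    for i, name in enumerate(names):
        lo, hi = bands[name]
        sel = (freqs >= lo) & ((freqs <= hi) if i == len(names) - 1 else (freqs < hi))
        out[name] = spectra[:, sel].sum(axis=1)
    df = pd.DataFrame(out)
    df.insert(0, "t_start", series.t0 + np.arange(len(df)) * segment)
    return df
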