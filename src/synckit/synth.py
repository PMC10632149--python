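"""Synthetic session generator with ground truth.

Emulates the statistical structure the analysis stages assume: slow latent
behaviour factors driving face-SVD streams and population firing,
inhomogeneous-Poisson spikes, 20-Hz laser trains followed after a
programmed delay by a syncope state (broadband 8-100 Hz LFP/EEG power drop
plus spiking suppression of a designated unit subset), laser-locked unit
responses with programmed latencies, ECG with bradycardia/asystole, a
stimulus-locked LDF dip, pupil keypoints with dilation and blinks, and a
respiration trace.  Every programmed quantity is returned in a
:class:`GroundTruth` record so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .session import BehaviorStreams, LaserEvent, Session, SpikeTrain, TimeSeries

__all__ = ["GeneratorConfig", "GroundTruth", "generate_session",
           "generate_worked_fixtures", "simulate_step_unit", "pink_noise"]


@dataclass
class GeneratorConfig:
    """All generator knobs; ``seed`` fixes every random draw end-to-end."""

    duration: float = 660.0
    seed: int = 0
    # sampling rates (Hz)
    lfp_rate: float = 500.0
    ecg_rate: float = 1000.0
    resp_rate: float = 250.0
    ldf_rate: float = 100.0
    video_rate: float = 30.0
    # units: region -> count.  Base rates span moderately active awake units;
    # the published silence criterion is only informative in this regime.
    regions: dict = field(default_factory=lambda: {"SSp": 8, "HPC": 8, "MBmot": 8, "PVZ": 6})
    rate_range: tuple[float, float] = (5.0, 25.0)
    suppressed_fraction: float = 0.8
    protected_regions: tuple[str, ...] = ("PVZ",)   # stay active through syncope
    responsive_fraction: float = 0.5
    response_latencies: tuple[float, ...] = (0.01, 0.05, 0.2)
    response_burst_rate: float = 400.0   # Hz, onset burst of evoked responses
    response_burst_duration: float = 0.03
    response_step_rate: float = 50.0     # Hz sustained during the train
    rate_suppression: float = 1.0        # fraction of rate removed at syncope
    # behaviour
    latent_dim: int = 4
    latent_cutoff: float = 0.5           # Hz low-pass on latent factors
    n_components: int = 250
    coupling_noise: float = 0.05         # multiplicative rate noise s.d.
    behavior_noise: float = 0.02
    # laser schedule: (pulse_hz, onset_s, duration_s)
    laser_plan: tuple = ((5, 150.0, 30.0), (10, 240.0, 30.0),
                         (20, 330.0, 30.0), (20, 420.0, 30.0))
    syncope_delay: tuple[float, float] = (4.0, 8.0)
    syncope_duration: tuple[float, float] = (10.0, 18.0)
    lfp_suppression_depth: float = 0.7   # amplitude drop in 8-100 Hz (power x0.09)
    # physiology
    hr_baseline_bpm: float = 600.0
    asystole_duration: float = 4.7
    ldf_min_frac: float = 0.35
    pupil_baseline_px: float = 8.0
    pupil_dilation: float = 1.5
    blink_rate: float = 0.05             # Hz
    blink_duration: float = 0.2          # s

    def __post_init__(self) -> None:
        if not 0 <= self.rate_suppression <= 1:
            raise ValueError("rate_suppression must lie in [0, 1]")
        if not 0 <= self.lfp_suppression_depth <= 1:
            raise ValueError("lfp_suppression_depth must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator programmed, for recovery scoring."""

    syncope_onsets: list[float]
    syncope_offsets: list[float]
    unit_latencies: dict[str, float]        # laser-responsive units only
    responsive_units: list[str]
    inactive_units: list[str]               # suppressed at syncope
    unit_base_rates: dict[str, float]
    latents: np.ndarray                     # (L, n_frames) behaviour factors
    unit_gain: np.ndarray                   # units x latent mixing
    hr_profile: tuple[np.ndarray, np.ndarray]   # (times, bpm)
    ldf_profile: tuple[np.ndarray, np.ndarray]  # (times, fraction of baseline)
    hr_min_times: list[float]
    ldf_min_times: list[float]
    pupil_gain: float
    blink_frames: np.ndarray
    laser_plan: tuple


def pink_noise(n: int, sample_rate: float, rng: np.random.Generator,
               f_floor: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f-power noise (flat below ``f_floor``)."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    X *= 1.0 / np.sqrt(np.maximum(f, f_floor))
    x = np.fft.irfft(X, n)
    return x / x.std()


def _lowpass_latents(rng: np.random.Generator, dim: int, n: int,
                     rate: float, cutoff: float) -> np.ndarray:
    z = rng.standard_normal((dim, n))
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    z = signal.sosfiltfilt(sos, z, axis=1)
    return z / z.std(axis=1, keepdims=True)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def _spike_times_from_rate(rate_hz: np.ndarray, dt: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson via fine-bin Bernoulli thinning."""
    p = np.clip(rate_hz * dt, 0.0, 0.95)
    hits = np.where(rng.random(p.size) < p)[0]
    return (hits + rng.random(hits.size)) * dt


def simulate_step_unit(base_rate: float, response_latency: float,
                       laser_onsets: np.ndarray, duration: float,
                       rng: np.random.Generator,
                       burst_rate: float = 400.0, burst_duration: float = 0.03,
                       step_rate: float = 50.0, step_duration: float = 30.0,
                       dt: float = 0.001) -> SpikeTrain:
    """A stationary unit with a programmed laser-locked onset response.

    After each laser onset plus the latency, the rate jumps by an onset
    burst (``burst_rate`` for ``burst_duration``) and a sustained step
    (``step_rate``) lasting ``step_duration``.
    """
    n = int(round(duration / dt))
    t = (np.arange(n) + 0.5) * dt
    rate = np.full(n, base_rate)
    for onset in np.atleast_1d(laser_onsets):
        s = onset + response_latency
        rate[(t >= s) & (t < s + burst_duration)] += burst_rate
        rate[(t >= s) & (t < s + step_duration)] += step_rate
    times = _spike_times_from_rate(rate, dt, rng)
    return SpikeTrain(unit_id="sim", region="SSp", spike_times=times,
                      baseline_rate=base_rate)


def _apply_band_suppression(x: np.ndarray, fs: float, spans: list[tuple[float, float]],
                            depth: float, band=(8.0, 100.0), ramp: float = 0.2
                            ) -> np.ndarray:
    """Multiplicative amplitude drop of the band component inside spans."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    mid = signal.sosfiltfilt(sos, x)
    env = np.ones(x.size)
    t = np.arange(x.size) / fs
    for s, e in spans:
        env[(t >= s) & (t < e)] = 1.0 - depth
    if ramp > 0:
        env = signal.sosfiltfilt(
            signal.butter(2, 1.0 / ramp, btype="lowpass", fs=fs, output="sos"), env)
        env = np.clip(env, 1.0 - depth, 1.0)
    return (x - mid) + mid * env


def _hr_profile(cfg: GeneratorConfig, lasers: list[LaserEvent]):
    """Programmed bpm curve and its per-laser minimum times."""
    dt = 0.01
    t = np.arange(0, cfg.duration, dt)
    bpm = np.full(t.size, cfg.hr_baseline_bpm)
    mins = []
    for ev in lasers:
        if ev.pulse_frequency >= 20:
            # early asystole so the R-R-gap midpoint (the detected heart-rate
            # minimum) precedes the LDF minimum for every syncope delay
            a0 = ev.onset + 0.2                       # decline start
            a1 = ev.onset + 0.6                       # asystole start
            a2 = a1 + cfg.asystole_duration
            a3 = a2 + 8.0                             # recovery complete
            bpm = np.where((t >= a0) & (t < a1),
                           cfg.hr_baseline_bpm * (1 - (t - a0) / (a1 - a0)), bpm)
            bpm = np.where((t >= a1) & (t < a2), 0.0, bpm)
            bpm = np.where((t >= a2) & (t < a3),
                           cfg.hr_baseline_bpm * (t - a2) / (a3 - a2), bpm)
            mins.append((a1 + a2) / 2)
        else:
            dip = 0.75 if ev.pulse_frequency >= 10 else 0.85
            c, w = ev.onset + 3.0, 3.0
            g = np.exp(-0.5 * ((t - c) / w) ** 2)
            bpm = bpm * (1 - (1 - dip) * np.where(
                (t >= ev.onset) & (t < ev.end + 10), g, 0.0))
            mins.append(c)
    return t, bpm, mins


def _ldf_profile(cfg: GeneratorConfig, lasers: list[LaserEvent],
                 syncope_delays: dict[float, float]):
    """Programmed flow curve (fraction of baseline) and minimum times."""
    dt = 1.0 / cfg.ldf_rate
    t = np.arange(0, cfg.duration, dt)
    v = np.ones(t.size)
    mins = []
    for ev in lasers:
        if ev.pulse_frequency >= 20:
            t_min = ev.onset + syncope_delays[ev.onset] - 0.4
            knots_t = [ev.onset + 0.2, t_min, ev.end, ev.end + 25.0]
            knots_v = [1.0, cfg.ldf_min_frac, 0.8, 1.0]
        else:
            depth = 0.75 if ev.pulse_frequency >= 10 else 0.85
            t_min = ev.onset + 2.0
            knots_t = [ev.onset + 0.5, t_min, ev.onset + 3.5]
            knots_v = [1.0, depth, 1.0]
        sel = (t >= knots_t[0]) & (t <= knots_t[-1])
        v[sel] = np.interp(t[sel], knots_t, knots_v)
        mins.append(t_min)
    return t, v, mins


def generate_session(cfg: GeneratorConfig) -> tuple[Session, GroundTruth]:
    """One complete synthetic session plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    lasers = [LaserEvent(onset=o, duration=d, pulse_frequency=f)
              for f, o, d in cfg.laser_plan]
    n_frames = int(round(cfg.duration * cfg.video_rate))
    frame_t = np.arange(n_frames) / cfg.video_rate

    # --- syncope schedule (one bout per 20-Hz laser) ----------------------
    syncope_onsets, syncope_offsets, delays = [], [], {}
    for ev in lasers:
        if ev.pulse_frequency >= 20:
            d = rng.uniform(*cfg.syncope_delay)
            dur = rng.uniform(*cfg.syncope_duration)
            delays[ev.onset] = d
            syncope_onsets.append(ev.onset + d)
            syncope_offsets.append(min(ev.onset + d + dur, cfg.duration - 1.0))

    # --- behaviour latents and face-SVD streams ---------------------------
    z = _lowpass_latents(rng, cfg.latent_dim, n_frames, cfg.video_rate,
                         cfg.latent_cutoff)
    A_movie = rng.normal(0, 1, (cfg.n_components, cfg.latent_dim))
    A_motion = rng.normal(0, 1, (cfg.n_components, cfg.latent_dim))
    c_movie = rng.normal(0, 0.5, (cfg.n_components, 1))
    c_motion = rng.normal(0, 0.5, (cfg.n_components, 1))
    X_movie = np.maximum(A_movie @ z + c_movie, 0.0)
    X_motion = np.maximum(A_motion @ z + c_motion, 0.0)
    if cfg.behavior_noise > 0:
        X_movie = X_movie + rng.normal(0, cfg.behavior_noise, X_movie.shape)
        X_motion = X_motion + rng.normal(0, cfg.behavior_noise, X_motion.shape)

    # whisking drive: one latent plus a laser-onset bump, dropped at syncope
    whisk = np.abs(z[0]) + 0.2
    for ev in lasers:
        whisk = whisk + 1.5 * np.exp(-0.5 * ((frame_t - ev.onset - 1.0) / 1.0) ** 2)
    for s, e in zip(syncope_onsets, syncope_offsets):
        whisk = whisk * np.where((frame_t >= s) & (frame_t < e), 0.2, 1.0)
    w_dir = rng.normal(0, 1, (10, 1))
    whisker_svd = w_dir * whisk[None, :] + rng.normal(0, 0.02, (10, n_frames))

    # --- units ------------------------------------------------------------
    dt = 0.001
    n_ms = int(round(cfg.duration / dt))
    tt = (np.arange(n_ms) + 0.5) * dt
    units: list[SpikeTrain] = []
    unit_gain_rows, unit_ids = [], []
    base_rates: dict[str, float] = {}
    unit_latencies: dict[str, float] = {}
    responsive, inactive = [], []
    syncope_mask = np.zeros(n_ms, dtype=bool)
    for s, e in zip(syncope_onsets, syncope_offsets):
        syncope_mask |= (tt >= s) & (tt < e)

    for region, n_u in cfg.regions.items():
        protected = region in cfg.protected_regions
        n_sup = 0 if protected else int(round(cfg.suppressed_fraction * n_u))
        sup_ids = set(range(n_sup))
        n_resp = n_u if protected else int(round(cfg.responsive_fraction * n_u))
        resp_ids = set(range(n_u - n_resp, n_u))
        for j in range(n_u):
            uid = f"{region}_{j:02d}"
            lam = rng.uniform(*cfg.rate_range)
            g = rng.normal(0, 1, cfg.latent_dim)
            mod = _softplus(g @ z)
            mod = mod / mod.mean()
            rate_f = lam * mod
            if cfg.coupling_noise > 0:
                rate_f = rate_f * np.exp(rng.normal(0, cfg.coupling_noise, n_frames))
            rate = np.interp(tt, frame_t, rate_f)
            if j in resp_ids:
                L = cfg.response_latencies[
                    rng.integers(0, len(cfg.response_latencies))]
                for ev in lasers:
                    s = ev.onset + L
                    rate[(tt >= s) & (tt < s + cfg.response_burst_duration)] += \
                        cfg.response_burst_rate
                    step = (tt >= s) & (tt < ev.end)
                    if not protected:
                        # only protected regions (PVZ-like) stay laser-driven
                        # through the syncope state
                        step &= ~syncope_mask
                    rate[step] += cfg.response_step_rate
                unit_latencies[uid] = L
                responsive.append(uid)
            if j in sup_ids:
                for s, e in zip(syncope_onsets, syncope_offsets):
                    rate[(tt >= s) & (tt < e)] *= 1.0 - cfg.rate_suppression
                inactive.append(uid)
            times = _spike_times_from_rate(rate, dt, rng)
            units.append(SpikeTrain(unit_id=uid, region=region,
                                    spike_times=times, baseline_rate=lam))
            unit_gain_rows.append(g)
            unit_ids.append(uid)
            base_rates[uid] = lam

    # --- LFP / EEG --------------------------------------------------------
    spans = list(zip(syncope_onsets, syncope_offsets))
    streams: dict[str, TimeSeries] = {}
    for name in ("lfp", "eeg"):
        x = pink_noise(int(round(cfg.duration * cfg.lfp_rate)), cfg.lfp_rate, rng)
        x = _apply_band_suppression(x, cfg.lfp_rate, spans,
                                    cfg.lfp_suppression_depth)
        streams[name] = TimeSeries(x, cfg.lfp_rate, 0.0, name)

    # --- ECG --------------------------------------------------------------
    hr_t, hr_bpm, hr_mins = _hr_profile(cfg, lasers)
    phase = np.cumsum(hr_bpm / 60.0) * (hr_t[1] - hr_t[0])
    beat_idx = np.where(np.diff(np.floor(phase)) > 0)[0]
    peak_times = hr_t[beat_idx]
    n_ecg = int(round(cfg.duration * cfg.ecg_rate))
    ecg = rng.normal(0, 0.01, n_ecg)
    sig = 0.004
    half = int(4 * sig * cfg.ecg_rate)
    kernel_t = np.arange(-half, half + 1) / cfg.ecg_rate
    kernel = np.exp(-0.5 * (kernel_t / sig) ** 2)
    for tp in peak_times:
        i = int(round(tp * cfg.ecg_rate))
        lo, hi = max(i - half, 0), min(i + half + 1, n_ecg)
        ecg[lo:hi] += kernel[half - (i - lo): half + (hi - i)]
    streams["ecg"] = TimeSeries(ecg, cfg.ecg_rate, 0.0, "ecg")

    # --- respiration ------------------------------------------------------
    n_rsp = int(round(cfg.duration * cfg.resp_rate))
    rt = np.arange(n_rsp) / cfg.resp_rate
    freq = np.full(n_rsp, 3.0)
    for ev in lasers:
        low = 1.2 if ev.pulse_frequency >= 20 else 2.2
        sel = (rt >= ev.onset + 1.0) & (rt < ev.end + 5.0)
        freq[sel] = low
    freq = signal.sosfiltfilt(
        signal.butter(2, 0.3, btype="lowpass", fs=cfg.resp_rate, output="sos"), freq)
    resp = np.sin(2 * np.pi * np.cumsum(freq) / cfg.resp_rate)
    streams["resp"] = TimeSeries(resp + rng.normal(0, 0.02, n_rsp),
                                 cfg.resp_rate, 0.0, "resp")

    # --- LDF --------------------------------------------------------------
    ldf_t, ldf_v, ldf_mins = _ldf_profile(cfg, lasers, delays)
    ldf = 250.0 * ldf_v + rng.normal(0, 0.5, ldf_v.size)
    streams["ldf"] = TimeSeries(ldf, cfg.ldf_rate, 0.0, "ldf")

    # --- pupil ------------------------------------------------------------
    radius = np.full(n_frames, cfg.pupil_baseline_px)
    for ev in lasers:
        if ev.pulse_frequency >= 20:
            ramp = np.clip((frame_t - ev.onset) / 2.0, 0, 1)
            decay = np.clip(1 - (frame_t - ev.end - 10) / 10.0, 0, 1)
            radius = radius * (1 + (cfg.pupil_dilation - 1) * ramp * decay)
    cx, cy = 50.0, 50.0
    kp = np.empty((4, 2, n_frames))
    kp[0] = [cx + 0 * radius, cy + radius]      # top
    kp[1] = [cx + 0 * radius, cy - radius]      # bottom
    kp[2] = [cx - radius, cy + 0 * radius]      # left
    kp[3] = [cx + radius, cy + 0 * radius]      # right
    kp += rng.normal(0, 0.03, kp.shape)
    conf = rng.uniform(0.9, 1.0, (4, n_frames))
    eye_dark = np.pi * radius ** 2 + rng.normal(0, 2.0, n_frames)
    n_blinks = rng.poisson(cfg.blink_rate * cfg.duration)
    blink_frames = []
    blink_len = max(int(round(cfg.blink_duration * cfg.video_rate)), 1)
    for s in rng.uniform(5, cfg.duration - 5, n_blinks):
        f0 = int(s * cfg.video_rate)
        fr = np.arange(f0, min(f0 + blink_len, n_frames))
        blink_frames.append(fr)
        eye_dark[fr] = 5.0
        conf[:, fr] = 0.3
    blink_frames = (np.unique(np.concatenate(blink_frames))
                    if blink_frames else np.array([], dtype=int))

    behavior = BehaviorStreams(movie_svd=X_movie, motion_svd=X_motion,
                               whisker_motion_svd=whisker_svd,
                               keypoints=kp, confidence=conf,
                               eye_dark_pixel_count=eye_dark,
                               sample_rate=cfg.video_rate)

    session = Session(id=f"synthetic_{cfg.seed:04d}", streams=streams,
                      units=units, behavior=behavior, lasers=lasers,
                      metadata={"generator_seed": cfg.seed,
                                "n_units": len(units)})
    truth = GroundTruth(
        syncope_onsets=syncope_onsets, syncope_offsets=syncope_offsets,
        unit_latencies=unit_latencies, responsive_units=responsive,
        inactive_units=inactive, unit_base_rates=base_rates,
        latents=z, unit_gain=np.array(unit_gain_rows),
        hr_profile=(hr_t, hr_bpm), ldf_profile=(ldf_t, ldf_v),
        hr_min_times=hr_mins, ldf_min_times=ldf_mins,
        pupil_gain=cfg.pupil_dilation, blink_frames=blink_frames,
        laser_plan=cfg.laser_plan)
    return session, truth


# ---------------------------------------------------------------------------
# Deterministic worked fixtures
# ---------------------------------------------------------------------------

def generate_worked_fixtures(out_dir: str | Path | None = None) -> dict:
    """Small deterministic fixtures with closed-form expected values.

    Returns a dict; with ``out_dir`` the array fixtures are also written as
    plain CSV files.
    """
    rng = np.random.default_rng(1234)
    fx: dict = {}

    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    fx["sinusoid_40hz"] = TimeSeries(np.sin(2 * np.pi * 40.0 * t), fs, 0.0, "sin40")

    # triangle LDF: baseline 1, V dip -0.1/s for 5 s then +0.1/s, onset 30 s
    fs_ldf = 20.0
    tl = np.arange(int(200 * fs_ldf)) / fs_ldf
    v = np.ones(tl.size)
    sel = (tl >= 30) & (tl <= 40)
    v[sel] = 1.0 - 0.1 * (5.0 - np.abs(tl[sel] - 35.0))
    fx["triangle_ldf"] = TimeSeries(v, fs_ldf, 0.0, "ldf")
    fx["triangle_laser"] = LaserEvent(onset=30.0, duration=30.0, pulse_frequency=20)

    # ECG impulse train: R peaks every 150 ms -> 400 bpm
    fs_ecg = 1000.0
    te = np.arange(int(60 * fs_ecg)) / fs_ecg
    ecg = np.zeros(te.size)
    for tp in np.arange(0.15, 60, 0.15):
        ecg += np.exp(-0.5 * ((te - tp) / 0.004) ** 2)
    fx["ecg_impulses"] = TimeSeries(ecg, fs_ecg, 0.0, "ecg")

    # pupil unit circle: keypoints at (0, +-1) and (+-1, 0)
    T = 100
    kp = np.zeros((4, 2, T))
    kp[0, 1] = 1.0
    kp[1, 1] = -1.0
    kp[2, 0] = -1.0
    kp[3, 0] = 1.0
    fx["pupil_circle"] = (kp, np.full((4, T), 0.99))

    # step-power LFP: white noise, amplitude x0.3 during [10, 20] s
    n = int(30 * fs)
    x = rng.standard_normal(n)
    ts = np.arange(n) / fs
    x[(ts >= 10) & (ts < 20)] *= 0.3
    fx["step_lfp"] = TimeSeries(x, fs, 0.0, "step_lfp")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("sinusoid_40hz", "triangle_ldf", "ecg_impulses", "step_lfp"):
            ts_obj = fx[name]
            pd.DataFrame({"t": ts_obj.times(), "value": ts_obj.values}).to_csv(
                out / f"{name}.csv", index=False)
        kp, conf = fx["pupil_circle"]
        rows = []
        for f in range(kp.shape[2]):
            for p, pname in enumerate(("top", "bottom", "left", "right")):
                rows.append({"frame": f, "point": pname, "x": kp[p, 0, f],
                             "y": kp[p, 1, f], "confidence": conf[p, f]})
        pd.DataFrame(rows).to_csv(out / "pupil_circle.csv", index=False)
    return fx
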