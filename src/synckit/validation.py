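"""Ground-truth recovery and calibration experiments.

Each function runs one end-to-end check of the pipeline against the
synthetic generator's programmed truth (or against closed-form fixture
identities) and returns a dict of measured quantities.  The same
experiments back the validation suite, the acceptance tests and the
acceptance script; problem sizes are chosen for single-CPU desk scale.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import behavior, physio, spectral, spikes, synth
from .session import AnalysisWindow, LaserEvent, SpikeTrain, SyncopeEvent
from .spikes import LatencyParams, PoissonInactivityParams

__all__ = [
    "syncope_recovery_experiment", "cluster_calibration_experiment",
    "latency_recovery_experiment", "inactivity_experiment",
    "encoding_triad_experiment", "fixture_identities", "curation_experiment",
]


def _detect_session_syncope(session, truth, time_downsample=10):
    """Run the spectral stage on a session's LFP for each 20-Hz laser."""
    lfp = session.streams["lfp"]
    events = []
    for ev in session.lasers_at(20):
        base = AnalysisWindow(ev.onset - 30.0, ev.onset, role="baseline")
        spec = spectral.wavelet_power(lfp, base, time_downsample=time_downsample)
        events.append(spectral.detect_syncope(spec, ev, source="lfp"))
    return events


def syncope_recovery_experiment(n_sessions: int = 20, seed: int = 0,
                                tol_onset: float = 0.5, tol_offset: float = 1.0) -> dict:
    """Detect programmed syncope bouts in short single-laser sessions.

    One 20-Hz laser per 150-s session; onset is scored against the
    programmed (laser onset + delay) and offset against the programmed
    bout end.
    """
    onset_err, offset_err = [], []
    for i in range(n_sessions):
        cfg = synth.GeneratorConfig(
            duration=150.0, seed=seed * 1000 + i,
            laser_plan=((20, 60.0, 30.0),),
            regions={"SSp": 2}, n_components=4, latent_dim=2)
        session, truth = synth.generate_session(cfg)
        for det, t_on, t_off in zip(_detect_session_syncope(session, truth),
                                    truth.syncope_onsets, truth.syncope_offsets):
            if det is None:
                onset_err.append(np.inf)
                offset_err.append(np.inf)
                continue
            onset_err.append(abs(det.onset - t_on))
            offset_err.append(abs(det.offset - t_off) if det.offset is not None
                              else np.inf)
    onset_err = np.array(onset_err)
    offset_err = np.array(offset_err)
    ok = (onset_err <= tol_onset) & (offset_err <= tol_offset)
    return {
        "n_events": onset_err.size,
        "recovered_frac": float(ok.mean()),
        "onset_mae": float(np.median(onset_err[np.isfinite(onset_err)])),
        "offset_mae": float(np.median(offset_err[np.isfinite(offset_err)])),
    }


def cluster_calibration_experiment(n_reps: int = 200, n_perm: int = 500,
                                   n_trials: int = 6, shape=(16, 40),
                                   seed: int = 0) -> dict:
    """Type-I error of the cluster permutation test under the null.

    On/off trials drawn from the same distribution; the family-wise rate of
    reporting any significant cluster should be ~5% (0.025 per tail).
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        on = rng.standard_normal((n_trials, *shape))
        off = rng.standard_normal((n_trials, *shape))
        res = spectral.cluster_permutation_test(on, off, n_perm=n_perm, rng=rng)
        hits += int(len(res.clusters) > 0)
    rate = hits / n_reps
    half = 2.576 * np.sqrt(0.05 * 0.95 / n_reps)
    return {"n_reps": n_reps, "false_positive_rate": float(rate),
            "ci99_lo": 0.05 - half, "ci99_hi": 0.05 + half}


def cluster_effect_experiment(seed: int = 0, n_perm: int = 500,
                              n_trials: int = 8) -> dict:
    """Injected 50% power drop recovers one significant negative cluster."""
    rng = np.random.default_rng(seed)
    F, T = 20, 60
    on = 1.0 + 0.15 * rng.standard_normal((n_trials, F, T))
    off = 1.0 + 0.15 * rng.standard_normal((n_trials, F, T))
    on[:, 4:16, 20:45] -= 0.5
    res = spectral.cluster_permutation_test(on, off, n_perm=n_perm, rng=rng)
    neg = res.clusters[res.clusters.sign < 0]
    overlap = False
    if res.label_map is not None and (res.label_map < 0).any():
        inj = np.zeros((F, T), dtype=bool)
        inj[4:16, 20:45] = True
        overlap = bool((inj & (res.label_map < 0)).sum() > 0.5 * inj.sum())
    return {"n_negative_clusters": int(len(neg)), "overlaps_injection": overlap}


def latency_recovery_experiment(n_seeds: int = 100,
                                latencies=(0.01, 0.05, 0.2),
                                base_rate: float = 5.0, seed: int = 0) -> dict:
    """Recovery of programmed response latencies and null specificity.

    Responsive units carry the generator's default onset burst + sustained
    step; null units are stationary.  Reports the median absolute latency
    error per programmed value and the fraction of null units without a
    (fast) spurious latency.
    """
    params = LatencyParams()
    onsets = np.array([1.0, 3.0, 5.0, 7.0])
    errors = {L: [] for L in latencies}
    rng = np.random.default_rng(seed)
    for L in latencies:
        for _ in range(n_seeds):
            u = synth.simulate_step_unit(base_rate, L, onsets, duration=9.0,
                                         rng=rng, step_duration=1.5)
            est = spikes.laser_latency(u, onsets, params)
            errors[L].append(abs(est - L) if est is not None else np.inf)
    null_ok = 0
    for _ in range(n_seeds):
        t = np.cumsum(rng.exponential(1.0 / base_rate, size=200))
        t = t[t < 9.0]
        u = SpikeTrain("null", "SSp", t, baseline_rate=base_rate)
        est = spikes.laser_latency(u, onsets, params)
        null_ok += int(est is None or est > params.activation_latency_max)
    all_err = np.concatenate([errors[L] for L in latencies])
    return {
        "median_abs_error_ms": float(np.median(all_err) * 1000),
        "per_latency_ms": {L: float(np.median(errors[L]) * 1000) for L in latencies},
        "null_specificity": null_ok / n_seeds,
    }


def inactivity_formula_check(dts=(0.001,), seed: int = 0) -> dict:
    """Silence-bin formula against an independent Poisson-pmf search.

    The required k is the smallest bin count whose zero-spike probability
    (scipy's Poisson pmf, an independent implementation of exp(-mu)) drops
    to p0 or below; agreement is also checked at the probability level.
    """
    params = PoissonInactivityParams()
    lams = np.concatenate([np.linspace(0.3, 2, 8), np.linspace(2.5, 60, 20)])
    max_prob_gap = 0.0
    mismatches = 0
    for lam in lams:
        k = spikes.inactivity_bins_required(lam, params)
        k_raw = np.ceil(-np.log(params.p0) / (lam * params.dt))
        # oracle: bracket the threshold with scipy's pmf
        p_at = stats.poisson.pmf(0, lam * k_raw * params.dt)
        p_before = stats.poisson.pmf(0, lam * (k_raw - 1) * params.dt)
        if not (p_at <= params.p0 + 1e-10 < p_before + 1e-10):
            mismatches += 1
        expected = int(min(k_raw, params.k_max))
        if k != expected:
            mismatches += 1
        max_prob_gap = max(max_prob_gap,
                           abs(np.exp(-lam * k_raw * params.dt) - p_at))
    return {"n_lambdas": lams.size, "mismatches": mismatches,
            "max_prob_discrepancy": float(max_prob_gap)}


def inactivity_experiment(n_units: int = 50, seed: int = 0) -> dict:
    """Sensitivity on suppressed units, false-flag rate on stationary ones.

    Suppressed units fire at their base rate then fall silent at the
    syncope onset for 20 s; null units are stationary with rates >= 2 Hz.
    """
    rng = np.random.default_rng(seed)
    params = PoissonInactivityParams()
    onset, offset, dur = 60.0, 80.0, 120.0
    sync = SyncopeEvent(onset=onset, offset=offset)
    hits = 0
    for _ in range(n_units):
        lam = rng.uniform(5.0, 25.0)
        pre = np.cumsum(rng.exponential(1 / lam, int(3 * lam * onset)))
        pre = pre[pre < onset]
        post = offset + np.cumsum(rng.exponential(1 / lam, int(3 * lam * (dur - offset))))
        post = post[post < dur]
        u = SpikeTrain("u", "SSp", np.concatenate([pre, post]), baseline_rate=lam)
        flag, time_off = spikes.inactive_at_syncope(u, sync, params)
        hits += int(flag)
    false = 0
    for _ in range(n_units):
        lam = rng.uniform(2.0, 20.0)
        t = np.cumsum(rng.exponential(1 / lam, int(3 * lam * dur)))
        t = t[t < dur]
        u = SpikeTrain("u", "SSp", t, baseline_rate=lam)
        flag, _ = spikes.inactive_at_syncope(u, sync, params)
        false += int(flag)
    return {"sensitivity": hits / n_units, "false_flag_rate": false / n_units}


# ---------------------------------------------------------------------------
# Encoding-model triad
# ---------------------------------------------------------------------------

def _encoding_session_config(seed: int) -> synth.GeneratorConfig:
    """Desk-scale session for the encoding experiments: fewer SVD components
    and units than a real recording, same temporal design.  The duration
    keeps ~8 training segments so the 50-neighbour latent average operates
    with the small neighbourhood radius it needs to stay unbiased."""
    return synth.GeneratorConfig(
        duration=960.0, seed=seed,
        laser_plan=((5, 150.0, 30.0), (10, 240.0, 30.0),
                    (20, 330.0, 30.0), (20, 420.0, 30.0)),
        regions={"SSp": 6, "HPC": 6, "PVZ": 4},
        n_components=20, latent_dim=3)


def run_encoding_pipeline(cfg: synth.GeneratorConfig, net_kwargs: dict | None = None):
    """Generate a session, fit the encoder, and return residual summaries."""
    from . import encoding

    session, truth = synth.generate_session(cfg)
    duration = cfg.duration
    split = encoding.make_split(duration, session.lasers, seed=cfg.seed)
    rates = spikes.bin_rates(session.units, duration)
    X = np.vstack([session.behavior.movie_svd, session.behavior.motion_svd])
    kw = dict(hidden=64, conv_channels=32, latent_dim=8,
              max_epochs=150, patience=10, seed=cfg.seed)
    kw.update(net_kwargs or {})
    model = encoding.train_encoder(X, rates, split, **kw)
    result = encoding.compute_residuals(X, rates, split, model)
    return session, truth, split, rates, model, result


def encoding_triad_experiment(n_seeds: int = 10, seed: int = 0) -> dict:
    """The residual triad and the nearest-neighbour-vs-direct comparison.

    Per seed: mean residual across non-protected units ~0 pre-laser
    (|mean| under 10% of the mean rate), positive in the 0.8-s laser-onset
    window, negative in the 2 s after syncope onset; and median control VE
    of the nearest-neighbour prediction exceeds the direct prediction.
    """
    from . import encoding

    triad_pass, nn_wins, pre_ratios = [], [], []
    for i in range(n_seeds):
        cfg = _encoding_session_config(seed * 100 + i)
        session, truth, split, rates, model, result = run_encoding_pipeline(cfg)
        protected = [r in cfg.protected_regions for r in rates.regions]
        unprot = ~np.array(protected)

        pre_w = [AnalysisWindow(ev.onset - 0.8, ev.onset, "pre_laser")
                 for ev in session.lasers]
        on_w = [AnalysisWindow(ev.onset, ev.onset + 0.8, "laser_onset")
                for ev in session.lasers]
        sync_w = [AnalysisWindow(t, t + 2.0, "syncope_onset")
                  for t in truth.syncope_onsets]
        pre = encoding.residual_window_means(result, pre_w).mean(axis=0)
        on = encoding.residual_window_means(result, on_w).mean(axis=0)
        sy = encoding.residual_window_means(result, sync_w).mean(axis=0)
        mean_rate = rates.rates.mean()
        pre_ok = abs(pre[unprot].mean()) < 0.1 * mean_rate
        on_ok = on[unprot].mean() > 0
        sy_ok = sy[unprot].mean() < 0
        triad_pass.append(pre_ok and on_ok and sy_ok)
        pre_ratios.append(abs(pre[unprot].mean()) / mean_rate)

        metrics = encoding.model_metrics(result, split)
        nn_wins.append(float(metrics.ve_nn_control.median())
                       > float(metrics.ve_direct_control.median()))
    return {
        "triad_frac": float(np.mean(triad_pass)),
        "nn_beats_direct_frac": float(np.mean(nn_wins)),
        "median_pre_residual_ratio": float(np.median(pre_ratios)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# Deterministic fixture identities
# ---------------------------------------------------------------------------

def fixture_identities() -> dict:
    """Closed-form fixture values computed through the pipeline operations."""
    fx = synth.generate_worked_fixtures()

    # the fixture is noise-free, so the 500-ms median filter is disabled and
    # the triangle geometry comes out exactly
    m = physio.ldf_metrics(fx["triangle_ldf"], fx["triangle_laser"],
                           median_window=0.0)
    ecg = physio.heart_rate(fx["ecg_impulses"])
    interior = ecg.bpm.slice(5.0, 55.0)

    kp, conf = fx["pupil_circle"]
    area = behavior.pupil_area(kp, conf).area[10]

    whisk = behavior.whisking_trace(
        np.array([[3.0], [4.0]] + [[0.0]] * 8))[0]

    sin40 = fx["sinusoid_40hz"]
    spec = spectral.wavelet_power(sin40, baseline=None, time_downsample=5)
    sl = (spec.times > 1.0) & (spec.times < sin40.duration - 1.0)
    peak_rows = spec.freqs[np.argmax(spec.power[:, sl], axis=0)]
    nearest = spec.freqs[np.argmin(np.abs(spec.freqs - 40.0))]

    return {
        "ldf_rate_coefficient": m.rate_coefficient,
        "ldf_fwhm_s": m.fwhm_transit,
        "ldf_min_during_stim": m.min_during_stim,
        "ecg_bpm": float(np.median(interior)),
        "pupil_area_px2": float(area),
        "whisking_345_norm": float(whisk),
        "wavelet_peak_hz": float(np.median(peak_rows)),
        "wavelet_nearest_bin_hz": float(nearest),
    }


def curation_experiment(n_units: int = 100, duration: float = 600.0,
                        rate: float = 5.0, seed: int = 0) -> dict:
    """Drift-flag specificity on stationary units and the 0.25-Hz boundary."""
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_units):
        t = np.cumsum(rng.exponential(1 / rate, int(3 * rate * duration)))
        t = t[t < duration]
        units.append(SpikeTrain(f"u{i}", "SSp", t))
    flags = spikes.flag_drifting_units(units, duration)

    half = np.cumsum(rng.exponential(1 / 10.0, 6000))
    half = half[half < duration / 2]
    drifting = SpikeTrain("drift", "SSp", half)
    drift_flag = spikes.flag_drifting_units([drifting], duration)[0]

    at = SpikeTrain("b150", "SSp", np.linspace(1, duration - 1, 150))
    below = SpikeTrain("b149", "SSp", np.linspace(1, duration - 1, 149))
    low = spikes.flag_low_rate_units([at, below], duration)
    return {
        "stationary_flag_rate": float(flags.mean()),
        "part_silent_flagged": bool(drift_flag),
        "boundary_at_kept": bool(~low[0]),
        "boundary_below_flagged": bool(low[1]),
    }
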