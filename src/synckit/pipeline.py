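"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis dependencies: spectral syncope detection
first (its events anchor the spike statistics and physiology alignment),
then unit curation/binning, the behaviour encoding model (whose residuals
feed the activation classification), and the physiology metrics.  A failed
stage halts its dependents but independent stages still complete.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import encoding, physio, spectral, spikes
from .config import DEFAULTS, load_config
from .session import AnalysisWindow, Session, load_session

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "run_validation_suite"]


def _spectral_stage(session: Session, cfg: dict, report: dict) -> None:
    sp = cfg["spectral"]
    session.syncope.clear()  # this stage owns the detected events
    rows = []
    for stream_name in ("lfp", "eeg"):
        if stream_name not in session.streams:
            continue
        series = session.streams[stream_name]
        if series.sample_rate > 2 * sp["notch_band"][1]:
            series = spectral.notch_filter(series, tuple(sp["notch_band"]))
        for ev in session.lasers_at(20):
            base = AnalysisWindow(ev.onset - 30.0, ev.onset, role="baseline")
            spec = spectral.wavelet_power(
                series, base, n_wavelets=sp["n_wavelets"], fmin=sp["freq_min"],
                fmax=sp["freq_max"], gamma=sp["morse_gamma"], beta=sp["morse_beta"],
                time_downsample=sp["time_downsample"])
            det = spectral.detect_syncope(
                spec, ev, band=tuple(sp["syncope_band"]),
                onset_frac=sp["onset_frac"], offset_frac=sp["offset_frac"],
                smooth_window=sp["smooth_window"], source=stream_name)
            if det is not None:
                rows.append({"stream": stream_name, "laser_onset_s": ev.onset,
                             "onset_s": det.onset, "offset_s": det.offset})
                # LFP-derived events anchor downstream stages; EEG is the
                # fallback when no depth electrode was recorded
                if stream_name == "lfp" or "lfp" not in session.streams:
                    session.syncope.append(det)
    if not session.lasers_at(20):
        logger.info("no 20-Hz lasers: syncope detection skipped")
    report["syncope_events"] = pd.DataFrame(
        rows, columns=["stream", "laser_onset_s", "onset_s", "offset_s"])


def _spike_stage(session: Session, cfg: dict, report: dict,
                 result: encoding.EncodingResult | None,
                 split: encoding.SplitPlan | None, seed: int) -> None:
    sk = cfg["spikes"]
    duration = session.duration()
    kept, flags = spikes.curate_units(session.units, duration,
                                      sigma=sk["drift_sigma"],
                                      factor=sk["drift_factor"],
                                      threshold=sk["min_rate"])
    report["unit_flags"] = flags
    exclude = split.all_test_spans() if split is not None else []
    for u in kept:
        u.baseline_rate = spikes.baseline_rate(u, duration, exclude)

    inact_params = spikes.PoissonInactivityParams(
        p0=sk["inactivity_p0"], dt=sk["inactivity_dt"],
        k_max=sk["inactivity_k_max"], onset_tolerance=sk["onset_tolerance"],
        sided=sk["onset_tolerance_sided"])
    lat_params = spikes.LatencyParams(
        p_threshold=sk["latency_p_threshold"], step=sk["latency_step"],
        max_window=sk["latency_max"],
        activation_latency_max=sk["activation_latency_max"],
        onset_window=sk["onset_window"])

    sync = session.syncope[0] if session.syncope else None
    onsets = np.array([ev.onset for ev in session.lasers])
    classifications = []
    for u in kept:
        cls = spikes.UnitClassification(unit_id=u.unit_id, region=u.region)
        if sync is not None:
            if sync.offset is not None:
                end = sync.offset
            else:
                later = [ev.end for ev in session.lasers if ev.onset < sync.onset]
                end = max(later) if later else sync.onset + 30.0
            cls.inactive_at_syncope, cls.time_off = spikes.inactive_at_syncope(
                u, sync, inact_params, window_end=end)
        latency = spikes.laser_latency(u, onsets, lat_params) if onsets.size else None
        if result is not None and onsets.size >= lat_params.n_repetitions:
            pre_w = [AnalysisWindow(o - lat_params.onset_window, o, "pre_laser")
                     for o in onsets]
            on_w = [AnalysisWindow(o, o + lat_params.onset_window, "laser_onset")
                    for o in onsets]
            iu = result.unit_ids.index(u.unit_id)
            on_means = encoding.residual_window_means(result, on_w)[:, iu]
            pre_means = encoding.residual_window_means(result, pre_w)[:, iu]
            cls = spikes.classify_laser_activated(u, on_means, pre_means,
                                                  latency, lat_params, base=cls)
        else:
            cls.latency = latency
        classifications.append(cls)
    report["unit_table"] = pd.DataFrame([c.__dict__ for c in classifications])
    report["region_summary"] = spikes.region_summary(classifications)
    if sync is not None:
        report["random_window_control"] = spikes.random_window_control(
            kept, sync, session.lasers, duration, inact_params, rng=seed)


def _encoding_stage(session: Session, cfg: dict, seed: int):
    enc = cfg["encoding"]
    b = session.behavior
    if b.movie_svd is None or b.motion_svd is None:
        logger.info("no behaviour SVD streams: encoding stage skipped")
        return None, None, None
    duration = session.duration()
    split = encoding.make_split(duration, session.lasers,
                                seg_nontest=enc["seg_nontest"],
                                seg_test=enc["seg_test"],
                                test_pre=enc["test_pre"], test_post=enc["test_post"],
                                val_frac=enc["val_frac"], seed=seed)
    rates = spikes.bin_rates(session.units, duration, cfg["spikes"]["rate_bin"])
    X = np.vstack([b.movie_svd, b.motion_svd])
    spec = encoding.EncodingNetworkSpec(
        input_dim=X.shape[0], n_units=rates.counts.shape[0],
        hidden=min(enc["hidden"], max(2 * X.shape[0], 16)),
        conv_channels=enc["conv_channels"], conv_kernel=enc["conv_kernel"],
        latent_dim=min(enc["latent_dim"], max(2 * X.shape[0] // 3, 4)),
        learning_rate=enc["learning_rate"], weight_decay=enc["weight_decay"],
        max_epochs=enc["max_epochs"], patience=enc["patience"], seed=seed)
    model = encoding.train_encoder(X, rates, split, spec=spec)
    result = encoding.compute_residuals(X, rates, split, model,
                                        k=enc["k_neighbors"])
    return split, model, result


def _physio_stage(session: Session, cfg: dict, report: dict) -> None:
    ph = cfg["physio"]
    rows = []
    hr = None
    if "ecg" in session.streams:
        hr = physio.heart_rate(session.streams["ecg"], session.lasers,
                               band=tuple(ph["ecg_band"]),
                               smooth_window=ph["smooth_window"],
                               baseline=ph["baseline"])
    rr = None
    if "resp" in session.streams:
        rr = physio.respiration_rate(session.streams["resp"], session.lasers,
                                     band=tuple(ph["resp_band"]),
                                     smooth_window=ph["smooth_window"],
                                     baseline=ph["baseline"])
    for i, ev in enumerate(session.lasers):
        row = {"laser_onset_s": ev.onset, "pulse_hz": ev.pulse_frequency}
        if hr is not None:
            st = physio.stim_window_stats(hr.normalized[i], ev,
                                          tuple(ph["hr_stim_window"]),
                                          tuple(ph["hr_post_window"]))
            row["hr_stim"] = st["stim_change"]
            row["hr_post"] = st["post_change"]
        if rr is not None:
            st = physio.stim_window_stats(rr.normalized[i], ev,
                                          tuple(ph["rr_stim_window"]),
                                          tuple(ph["rr_post_window"]))
            row["rr_stim"] = st["stim_change"]
            row["rr_post"] = st["post_change"]
        if "ldf" in session.streams and ev.onset > ph["ldf_baseline"]:
            later = [e.onset for e in session.lasers if e.onset > ev.onset]
            trial_end = min(ev.onset + ph["ldf_late_window"],
                            (min(later) - ph["ldf_baseline"]) if later else np.inf,
                            session.duration())
            m = physio.ldf_metrics(session.streams["ldf"], ev,
                                   baseline=ph["ldf_baseline"],
                                   median_window=ph["ldf_median_window"],
                                   stim_duration=min(ph["ldf_stim_duration"],
                                                     ev.duration),
                                   trial_end=trial_end)
            row.update({"ldf_latency50": m.latency_50,
                        "ldf_min": m.min_during_stim,
                        "ldf_fwhm": m.fwhm_transit,
                        "ldf_late_mean": m.late_mean,
                        "ldf_recovery": m.recovery_duration,
                        "ldf_rate_coeff": m.rate_coefficient})
        rows.append(row)
    report["physiology"] = pd.DataFrame(rows)
    if session.syncope and hr is not None:
        sync_by_laser = []
        for ev in session.lasers:
            match = [s for s in session.syncope
                     if s.laser_onset is not None and s.laser_onset == ev.onset]
            sync_by_laser.append(match[0] if match else None)
        report["event_sequence"] = physio.event_sequence_table(
            session.lasers, hr.normalized, session.streams.get("ldf"),
            sync_by_laser)


def run_pipeline(session: Session | str | Path, config: dict | str | None = None,
                 out_dir: str | Path | None = None, seed: int = 0,
                 stages: tuple[str, ...] = ("spectral", "encoding", "spikes", "physio")
                 ) -> dict:
    """Run the enabled stages in dependency order on one session.

    Returns a report dict of DataFrames; with ``out_dir`` every table is
    written as CSV (deterministically) together with the resolved config.
    """
    if not isinstance(session, Session):
        session = load_session(session)
    cfg = config if isinstance(config, dict) else load_config(config)
    report: dict = {"notes": []}

    if "spectral" in stages:
        _spectral_stage(session, cfg, report)
    else:
        report["notes"].append("spectral disabled: syncope-dependent spike "
                               "statistics skipped (missing dependency)")

    split = model = result = None
    if "encoding" in stages:
        try:
            split, model, result = _encoding_stage(session, cfg, seed)
        except ValueError as e:
            report["notes"].append(f"encoding stage failed: {e}")
    if result is not None:
        report["encoding_metrics"] = encoding.model_metrics(result, split)

    if "spikes" in stages and session.units:
        if "spectral" in stages or not session.syncope:
            _spike_stage(session, cfg, report, result, split, seed)
        else:
            _spike_stage(session, cfg, report, result, split, seed)

    if "physio" in stages:
        _physio_stage(session, cfg, report)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, obj in sorted(report.items()):
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", index=False)
        (out / "notes.json").write_text(json.dumps(report["notes"], indent=2))
        from .config import save_config
        save_config(cfg, out / "config.yaml")
    return report


def run_validation_suite(seeds: list[int], quick: bool = False) -> pd.DataFrame:
    """Run every ground-truth recovery experiment; one row per criterion.

    ``quick`` shrinks the repetition counts (the tolerance of the cluster
    calibration widens with the binomial error at the reduced count).
    """
    from . import validation as V

    if not seeds:
        raise ValueError("need at least one seed")
    seed = seeds[0]
    scale = 0.25 if quick else 1.0
    rows = []

    r = V.syncope_recovery_experiment(n_sessions=max(int(20 * scale), 4), seed=seed)
    rows.append(("syncope_recovery", r["recovered_frac"], ">=0.9",
                 r["recovered_frac"] >= 0.9))
    r = V.cluster_calibration_experiment(n_reps=max(int(200 * scale), 50),
                                         n_perm=500, seed=seed)
    rows.append(("cluster_calibration", r["false_positive_rate"],
                 f"[{r['ci99_lo']:.3f},{r['ci99_hi']:.3f}]",
                 r["ci99_lo"] <= r["false_positive_rate"] <= r["ci99_hi"]))
    r = V.latency_recovery_experiment(n_seeds=max(int(100 * scale), 25), seed=seed)
    rows.append(("latency_recovery_ms", r["median_abs_error_ms"], "<=10",
                 r["median_abs_error_ms"] <= 10))
    rows.append(("latency_specificity", r["null_specificity"], ">=0.99",
                 r["null_specificity"] >= 0.99))
    r = V.inactivity_formula_check()
    rows.append(("inactivity_formula", r["mismatches"], "==0", r["mismatches"] == 0))
    r = V.inactivity_experiment(seed=seed)
    rows.append(("inactivity_sensitivity", r["sensitivity"], ">=0.9",
                 r["sensitivity"] >= 0.9))
    rows.append(("inactivity_false_flags", r["false_flag_rate"], "<=0.05",
                 r["false_flag_rate"] <= 0.05))
    r = V.encoding_triad_experiment(n_seeds=max(int(10 * scale), 3), seed=seed)
    rows.append(("encoding_triad", r["triad_frac"], ">=0.9", r["triad_frac"] >= 0.9))
    rows.append(("nn_beats_direct", r["nn_beats_direct_frac"], ">=0.8",
                 r["nn_beats_direct_frac"] >= 0.8))
    f = V.fixture_identities()
    rows.append(("fixture_identities",
                 f["ldf_rate_coefficient"], "==1.0",
                 abs(f["ldf_rate_coefficient"] - 1.0) < 0.02
                 and abs(f["ldf_fwhm_s"] - 5.0) < 0.2
                 and abs(f["ecg_bpm"] - 400.0) < 2.0
                 and abs(f["pupil_area_px2"] - np.pi) < 1e-6
                 and abs(f["whisking_345_norm"] - 5.0) < 1e-9
                 and abs(f["wavelet_peak_hz"] - f["wavelet_nearest_bin_hz"]) < 1e-9))
    c = V.curation_experiment(seed=seed)
    rows.append(("curation", c["stationary_flag_rate"], "<0.05",
                 c["stationary_flag_rate"] < 0.05 and c["part_silent_flagged"]
                 and c["boundary_at_kept"] and c["boundary_below_flagged"]))
    return pd.DataFrame(rows, columns=["criterion", "value", "target", "passed"])
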