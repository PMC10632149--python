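"""Pipeline configuration: one YAML with per-stage parameter blocks.

Every numeric constant used by the analysis stages has a default here;
:func:`load_config` deep-merges a user YAML over the defaults.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "spectral": {
        "n_wavelets": 80,
        "freq_min": 0.5,
        "freq_max": 120.0,
        "morse_gamma": 3.0,
        "morse_beta": 20.0,          # time-bandwidth gamma*beta = 60
        "notch_band": [59.0, 61.0],
        "syncope_band": [8.0, 100.0],
        "onset_frac": 0.5,
        "offset_frac": 0.8,
        "smooth_window": 1.0,        # s, moving mean on band-average power
        "time_downsample": 10,       # spectrogram time decimation factor
        "n_permutations": 1000,
        "alpha_per_tail": 0.025,
        "cluster_forming_p": 0.05,
        "fft_segment": 2.0,          # s
        "fft_taper": None,           # or "hann"
        "bands": {"delta": [1, 4], "theta": [4, 8], "alpha": [8, 13],
                  "beta": [13, 30], "low_gamma": [30, 59], "high_gamma": [61, 120]},
    },
    "spikes": {
        "drift_bin": 0.1,            # s
        "drift_sigma": 30.0,         # s, Gaussian smoothing width (sigma)
        "drift_factor": 5.0,
        "drift_rate_floor": 1e-3,    # Hz; silence makes the ratio blow up
        "min_rate": 0.25,            # Hz
        "rate_bin": 0.1,             # s (10 Hz)
        "inactivity_p0": 0.01,
        "inactivity_dt": 0.001,      # s
        "inactivity_k_max": 4000,    # bins (4 s)
        "onset_tolerance": 0.25,     # s, two-sided by default
        "onset_tolerance_sided": "pre",
        "latency_p_threshold": 1e-6,
        "latency_step": 0.001,       # s
        "latency_max": 1.0,          # s, search cap
        "activation_latency_max": 0.25,  # s
        "onset_window": 0.8,         # s, laser-onset and pre-laser windows
    },
    "behavior": {
        "n_components": 250,
        "segment_length": 1000,      # frames per SVD chunk
        "whisk_components": 10,
        "median_window": 5,          # frames
        "conf_threshold": 0.75,
        "blink_area_threshold": 50.0,  # dark pixels; same value across animals
        "laser_baseline": 30.0,      # s before laser onset
        "syncope_baseline": [-6.0, -4.0],  # s relative to syncope onset
        "laser_summary": 5.0,        # s post laser
        "syncope_summary": 2.0,      # s post syncope
    },
    "encoding": {
        "seg_nontest": 50.0,         # s
        "seg_test": 63.0,            # s
        "test_pre": 3.0,             # s before laser onset
        "test_post": 60.0,           # s after laser onset
        "val_frac": 0.2,
        "hidden": 200,
        "conv_channels": 100,
        "conv_kernel": 15,           # frames (~0.5 s at 30 Hz)
        "latent_dim": 32,
        "learning_rate": 1e-3,
        "weight_decay": 1e-4,
        "max_epochs": 300,
        "patience": 10,
        "k_neighbors": 50,
    },
    "physio": {
        "ecg_band": [10.0, 50.0],    # Hz
        "resp_band": [1.0, 10.0],    # Hz
        "smooth_window": 1.0,        # s
        "baseline": 30.0,            # s before laser onset
        "hr_stim_window": [6.0, 24.0],
        "hr_post_window": [30.0, 60.0],
        "rr_stim_window": [6.0, 15.0],
        "rr_post_window": [36.0, 45.0],
        "prominence_mads": 4.0,
        "ldf_baseline": 30.0,
        "ldf_median_window": 0.5,    # s
        "ldf_stim_duration": 30.0,
        "ldf_late_window": 100.0,
    },
}


def _deep_merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file of per-stage blocks."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ValueError("config YAML must be a mapping of stage blocks")
    return _deep_merge(DEFAULTS, user)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
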