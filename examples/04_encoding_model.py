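"""Predict firing from face behaviour and isolate laser/syncope residuals.

A small network (linear -> temporal conv -> ReLU -> latent -> linear) maps
the 30-Hz movie/motion SVDs to 100-ms binned rates; test-segment
predictions average the recorded activity at the 50 nearest training
latents.  Residuals (recorded - prediction) should hover near zero before
the laser, turn positive at laser onset (direct drive beyond behaviour)
and negative at syncope (suppression not explained by stillness).
"""

import numpy as np

from synckit import encoding
from synckit.session import AnalysisWindow
from synckit.validation import _encoding_session_config, run_encoding_pipeline

cfg = _encoding_session_config(seed=0)
session, truth, split, rates, model, result = run_encoding_pipeline(cfg)

unprot = ~np.array([r in cfg.protected_regions for r in rates.regions])
pre = encoding.residual_window_means(
    result, [AnalysisWindow(ev.onset - 0.8, ev.onset) for ev in session.lasers])
on = encoding.residual_window_means(
    result, [AnalysisWindow(ev.onset, ev.onset + 0.8) for ev in session.lasers])
sy = encoding.residual_window_means(
    result, [AnalysisWindow(t, t + 2.0) for t in truth.syncope_onsets])

print(f"mean rate {rates.rates.mean():.1f} Hz over {len(rates.unit_ids)} units")
print(f"mean residual, non-PVZ units:  pre-laser {pre.mean(0)[unprot].mean():+6.2f} Hz"
      f"   laser onset {on.mean(0)[unprot].mean():+6.2f} Hz"
      f"   syncope {sy.mean(0)[unprot].mean():+6.2f} Hz")
print(f"mean residual, PVZ units at syncope: {sy.mean(0)[~unprot].mean():+6.2f} Hz"
      "  (stays positive: laser-driven through the bout)")

m = encoding.model_metrics(result, split)
print(f"median control-segment VE: nearest-neighbour {m.ve_nn_control.median():.2f}"
      f" vs direct network {m.ve_direct_control.median():.2f}")
print(f"median 1-s correlation: control {m.r_control_1s.median():.2f}, "
      f"during 20-Hz laser {m.r_laser_1s.median():.2f}")
# The nn prediction outperforming the direct read-out, and the control
# correlation exceeding the laser-period correlation, mirror the published
# qualitative pattern.
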