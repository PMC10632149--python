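"""Detect a syncope bout from the LFP wavelet spectrogram.

Power is computed with 80 log-spaced Morse wavelets (0.5-120 Hz), each
frequency normalized to its pre-laser baseline mean; syncope onset is the
first post-laser time the smoothed 8-100 Hz average falls below 50% and
offset the first later time it recovers above 80%.
"""

from synckit.session import AnalysisWindow
from synckit.spectral import detect_syncope, wavelet_power
from synckit.synth import GeneratorConfig, generate_session

cfg = GeneratorConfig(duration=150.0, seed=7, laser_plan=((20, 60.0, 30.0),),
                      regions={"SSp": 2}, n_components=4, latent_dim=2)
session, truth = generate_session(cfg)
laser = session.lasers[0]

baseline = AnalysisWindow(laser.onset - 30.0, laser.onset, role="baseline")
spec = wavelet_power(session.streams["lfp"], baseline, time_downsample=10)
event = detect_syncope(spec, laser, source="lfp")

print(f"laser onset              {laser.onset:7.2f} s (20 Hz, 30 s)")
print(f"programmed syncope onset {truth.syncope_onsets[0]:7.2f} s, "
      f"offset {truth.syncope_offsets[0]:7.2f} s")
print(f"detected  syncope onset  {event.onset:7.2f} s, "
      f"offset {event.offset:7.2f} s")
print(f"onset error {abs(event.onset - truth.syncope_onsets[0])*1e3:.0f} ms, "
      f"offset error {abs(event.offset - truth.syncope_offsets[0])*1e3:.0f} ms")
# Errors of a few hundred ms reflect the 1-s smoothing of the band power.
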