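"""Poisson spike statistics: response latency and inactivity at syncope.

The latency statistic grows a window in 1-ms steps after each laser onset
and reports the first window where the pooled spike count is implausible
(P < 1e-6) under the unit's baseline rate.  The inactivity statistic asks
for a silent run long enough that its chance probability is below 1%
(exp(-lambda k dt) <= 0.01, k capped at 4000 ms), beginning within 250 ms
of syncope onset.
"""

import numpy as np

from synckit.session import SpikeTrain, SyncopeEvent
from synckit.spikes import (LatencyParams, PoissonInactivityParams,
                            inactive_at_syncope, inactivity_bins_required,
                            laser_latency)
from synckit.synth import simulate_step_unit

rng = np.random.default_rng(0)
onsets = np.array([10.0, 40.0, 70.0, 100.0])

unit = simulate_step_unit(base_rate=5.0, response_latency=0.05,
                          laser_onsets=onsets, duration=130.0, rng=rng,
                          step_duration=20.0)
lat = laser_latency(unit, onsets, LatencyParams())
print(f"programmed latency 50 ms -> estimated {lat*1e3:.0f} ms")

params = PoissonInactivityParams()
print(f"silent bins required: lambda=2 Hz -> k={inactivity_bins_required(2.0, params)}"
      f" (2.303 s); lambda=0.5 Hz -> k={inactivity_bins_required(0.5, params)} (capped)")

# a 10-Hz unit that falls silent at syncope onset (60 s) for 15 s
pre = np.arange(0.5, 60.0, 0.1)
post = np.arange(75.0, 90.0, 0.1)
silenced = SpikeTrain("u", "SSp", np.concatenate([pre, post]), baseline_rate=10.0)
flag, time_off = inactive_at_syncope(silenced, SyncopeEvent(60.0, 75.0), params)
print(f"suppressed unit flagged inactive: {flag}, time off = {time_off:.1%} "
      "of the syncope window")
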