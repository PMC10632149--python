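"""Poisson spike statistics, curation, binning and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synckit import spikes
from synckit.session import SpikeTrain, SyncopeEvent
from synckit.spikes import LatencyParams, PoissonInactivityParams


def _poisson_sf_oracle(n, mu):
    """Independent direct-summation implementation of 1 - sum_{m<n} pmf."""
    from math import exp, lgamma, log
    if n == 0:
        return 1.0
    total = 0.0
    for m in range(n):
        total += exp(m * log(mu) - mu - lgamma(m + 1)) if mu > 0 else (m == 0)
    return 1.0 - total


class TestInactivityBins:
    def test_formula_examples(self):
        p = PoissonInactivityParams()
        assert spikes.inactivity_bins_required(2.0, p) == 2303
        assert spikes.inactivity_bins_required(0.5, p) == 4000  # capped
        p1 = PoissonInactivityParams(p0=1.0)
        assert spikes.inactivity_bins_required(7.0, p1) == 0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            spikes.inactivity_bins_required(0.0, PoissonInactivityParams())

    @given(st.floats(min_value=0.1, max_value=100.0),
           st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing_in_rate_and_capped(self, lam1, lam2):
        p = PoissonInactivityParams()
        lo, hi = sorted((lam1, lam2))
        k_lo = spikes.inactivity_bins_required(lo, p)
        k_hi = spikes.inactivity_bins_required(hi, p)
        assert k_lo >= k_hi and k_lo <= p.k_max


class TestResponseProbability:
    def test_empty_sum_is_one(self):
        assert spikes.response_probability(0, 5.0, 4, 0.1) == 1.0

    def test_worked_example(self):
        p = spikes.response_probability(8, 5.0, 4, 0.1)  # N lam t = 2
        assert abs(p - 1.09e-3) < 0.02e-3

    def test_large_rate_asymptote(self):
        assert abs(spikes.response_probability(1, 125.0, 4, 1.0) - 1.0) < 1e-12

    @pytest.mark.parametrize("n,mu", [(1, 0.5), (3, 2.0), (10, 2.0),
                                      (5, 20.0), (40, 20.0)])
    def test_matches_direct_summation_oracle(self, n, mu):
        lam, N, t = mu / 4.0, 4, 1.0
        assert abs(spikes.response_probability(n, lam, N, t)
                   - _poisson_sf_oracle(n, mu)) < 1e-10

    @given(st.integers(min_value=0, max_value=30),
           st.floats(min_value=0.01, max_value=2.0),
           st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=60, deadline=None)
    def test_monotonicity(self, n, t, lam):
        p = spikes.response_probability(n, lam, 4, t)
        assert 0.0 <= p <= 1.0
        assert spikes.response_probability(n + 1, lam, 4, t) <= p
        assert spikes.response_probability(n, lam, 4, t * 1.5) >= p
        assert spikes.response_probability(n, lam * 1.5, 4, t) >= p


class TestBinning:
    def test_half_open_convention(self):
        u = SpikeTrain("u", "SSp", np.array([0.05, 0.1, 0.15]))
        br = spikes.bin_rates([u], duration=0.4)
        # 0.1 falls in the second bin, not the first
        np.testing.assert_array_equal(br.counts[0], [1, 2, 0, 0])

    def test_counts_sum_preserved(self, rng):
        t = np.sort(rng.uniform(0, 50, 400))
        t = np.unique(t)
        u = SpikeTrain("u", "SSp", t)
        br = spikes.bin_rates([u], duration=50.0)
        assert br.counts.sum() == t.size

    def test_mean_rate_recovered(self, rng):
        t = np.cumsum(rng.exponential(1 / 20.0, 30000))
        t = t[t < 600]
        u = SpikeTrain("u", "SSp", t)
        br = spikes.bin_rates([u], duration=600.0)
        assert abs(br.counts[0].mean() - 2.0) < 0.1


class TestCuration:
    def test_part_silent_unit_flagged(self, rng):
        t = np.cumsum(rng.exponential(0.1, 4000))
        t = t[t < 300]  # silent second half of a 600-s recording
        flags = spikes.flag_drifting_units([SpikeTrain("u", "SSp", t)], 600.0)
        assert flags[0]

    def test_stationary_unit_not_flagged(self, rng):
        t = np.cumsum(rng.exponential(0.2, 5000))
        t = t[t < 600]
        flags = spikes.flag_drifting_units([SpikeTrain("u", "SSp", t)], 600.0)
        assert not flags[0]

    def test_empty_train_not_drift_flagged(self):
        u = SpikeTrain("u", "SSp", np.array([]))
        assert not spikes.flag_drifting_units([u], 600.0)[0]
        assert spikes.flag_low_rate_units([u], 600.0)[0]

    def test_low_rate_boundary_strictly_less_than(self):
        at = SpikeTrain("a", "SSp", np.linspace(1, 599, 150))      # 0.25 Hz
        below = SpikeTrain("b", "SSp", np.linspace(1, 599, 149))
        flags = spikes.flag_low_rate_units([at, below], 600.0)
        assert not flags[0] and flags[1]

    def test_baseline_rate_excludes_segments(self):
        u = SpikeTrain("u", "SSp", np.arange(0.5, 100.0, 1.0))  # 1 Hz
        lam = spikes.baseline_rate(u, 100.0, exclude=[(0.0, 50.0)])
        assert abs(lam - 1.0) < 0.03


class TestInactiveAtSyncope:
    def test_silence_from_onset_flags(self):
        p = PoissonInactivityParams()
        pre = np.arange(0.5, 60.0, 0.1)  # 10 Hz up to onset
        post = np.arange(75.0, 90.0, 0.1)
        u = SpikeTrain("u", "SSp", np.concatenate([pre, post]), baseline_rate=10.0)
        flag, time_off = spikes.inactive_at_syncope(
            u, SyncopeEvent(onset=60.0, offset=75.0), p)
        assert flag and time_off > 0.9

    def test_regular_firing_not_flagged(self):
        p = PoissonInactivityParams()
        u = SpikeTrain("u", "SSp", np.arange(0.05, 120.0, 0.1), baseline_rate=10.0)
        flag, time_off = spikes.inactive_at_syncope(
            u, SyncopeEvent(onset=60.0, offset=75.0), p)
        assert not flag and time_off is None

    def test_silence_starting_too_early_not_flagged(self):
        """A run that begins well before the onset window does not count."""
        p = PoissonInactivityParams()
        pre = np.arange(0.5, 58.0, 0.1)  # last spike 2 s before onset
        u = SpikeTrain("u", "SSp", np.concatenate([pre, [90.0]]),
                       baseline_rate=10.0)
        flag, _ = spikes.inactive_at_syncope(
            u, SyncopeEvent(onset=60.0, offset=75.0), p)
        assert not flag


class TestLaserLatency:
    def test_no_spikes_is_undefined(self):
        u = SpikeTrain("u", "SSp", np.array([0.1]), baseline_rate=5.0)
        assert spikes.laser_latency(u, np.array([10.0, 20.0, 30.0, 40.0]),
                                    LatencyParams()) is None

    def test_stronger_response_not_slower(self, rng):
        from synckit.synth import simulate_step_unit
        onsets = np.array([1.0, 3.0, 5.0, 7.0])
        lat = {}
        for burst in (200.0, 800.0):
            r = np.random.default_rng(77)
            u = simulate_step_unit(5.0, 0.05, onsets, 9.0, r, burst_rate=burst,
                                   step_duration=1.5)
            lat[burst] = spikes.laser_latency(u, onsets, LatencyParams())
        assert lat[800.0] <= lat[200.0]


class TestClassification:
    def _unit(self):
        return SpikeTrain("u", "SSp", np.array([1.0]), baseline_rate=5.0)

    def test_zero_residual_fails_strict_positivity(self):
        cls = spikes.classify_laser_activated(
            self._unit(), np.zeros(4), np.zeros(4), latency=0.05,
            params=LatencyParams())
        assert not cls.laser_activated and not cls.criterion_positive_residual

    def test_constructed_activation(self):
        cls = spikes.classify_laser_activated(
            self._unit(), np.ones(4), np.zeros(4), latency=0.05,
            params=LatencyParams())
        assert cls.laser_activated
        assert cls.criterion_positive_residual and cls.criterion_exceeds_pre
        assert cls.criterion_fast_latency

    def test_slow_latency_fails_third_criterion(self):
        cls = spikes.classify_laser_activated(
            self._unit(), np.ones(4), np.zeros(4), latency=0.4,
            params=LatencyParams())
        assert not cls.laser_activated and not cls.criterion_fast_latency

    def test_too_few_lasers_rejected(self):
        with pytest.raises(ValueError):
            spikes.classify_laser_activated(self._unit(), np.ones(2),
                                            np.zeros(2), 0.05, LatencyParams())


class TestRegionSummary:
    def _cls(self, uid, region, latency=None, activated=False, inactive=False,
             time_off=None):
        c = spikes.UnitClassification(unit_id=uid, region=region)
        c.latency = latency
        c.laser_activated = activated
        c.inactive_at_syncope = inactive
        c.time_off = time_off
        return c

    def test_median_latency(self):
        cls = [self._cls(f"u{i}", "SSp", latency=l, activated=True)
               for i, l in enumerate((0.01, 0.02, 0.03))]
        df = spikes.region_summary(cls)
        assert df.loc[0, "median_latency"] == pytest.approx(0.02)

    def test_all_inactive_is_100_percent(self):
        cls = [self._cls(f"u{i}", "HPC", inactive=True, time_off=0.9)
               for i in range(3)]
        df = spikes.region_summary(cls)
        assert df.loc[0, "pct_inactive"] == 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            spikes.region_summary([])
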