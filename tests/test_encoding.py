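"""Split plan, encoding network, nearest-neighbour prediction, residuals."""

import numpy as np
import pytest

from synckit import encoding, spikes
from synckit.session import LaserEvent, SpikeTrain


def _lasers(onsets, freq=20):
    return [LaserEvent(onset=o, duration=30.0, pulse_frequency=freq)
            for o in onsets]


class TestMakeSplit:
    def test_stated_arithmetic_600s_four_lasers(self):
        """600-s session, four contiguous laser windows: 5 test segments
        (315 s) and five 50-s non-test segments split 4/1."""
        split = encoding.make_split(600.0, _lasers([150.0, 213.0, 276.0, 339.0]),
                                    seed=0)
        assert len(split.test) == 5
        assert sum(w.duration for w in split.test) == pytest.approx(315.0)
        assert len(split.train) + len(split.validation) == 5
        assert len(split.validation) == 1
        for w in split.train + split.validation:
            assert w.duration == pytest.approx(50.0)

    def test_no_lasers_control_only(self):
        split = encoding.make_split(300.0, [], seed=0)
        assert [w.role for w in split.test] == ["control"]

    def test_test_segments_independent_of_seed(self):
        a = encoding.make_split(600.0, _lasers([150.0, 240.0]), seed=1)
        b = encoding.make_split(600.0, _lasers([150.0, 240.0]), seed=2)
        assert [(w.start, w.end) for w in a.test] == [(w.start, w.end) for w in b.test]
        assert ([w.start for w in a.train] != [w.start for w in b.train]
                or [w.start for w in a.validation] != [w.start for w in b.validation])

    def test_segments_disjoint_and_lasers_only_in_test(self):
        lasers = _lasers([150.0, 240.0, 330.0, 420.0])
        split = encoding.make_split(660.0, lasers, seed=3)
        spans = ([(w.start, w.end) for w in split.train + split.validation
                  + split.test])
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2 + 1e-9
        for ev in lasers:
            for w in split.train + split.validation:
                assert ev.end <= w.start or ev.onset >= w.end

    def test_insufficient_duration_raises(self):
        with pytest.raises(ValueError):
            encoding.make_split(120.0, _lasers([60.0]), seed=0)


class TestNearestNeighbour:
    def test_duplicated_training_latent_exact(self, rng):
        lat = np.tile(rng.standard_normal((1, 3)), (60, 1))
        rates = np.tile(np.array([[2.0, 7.0]]), (60, 1))
        pred = encoding.nn_latent_predict(lat, rates, lat[:1], k=50)
        np.testing.assert_allclose(pred, [[2.0, 7.0]])

    def test_k_equals_all_gives_training_mean(self, rng):
        lat = rng.standard_normal((40, 3))
        rates = rng.standard_normal((40, 5))
        pred = encoding.nn_latent_predict(lat, rates, rng.standard_normal((7, 3)),
                                          k=40)
        np.testing.assert_allclose(pred, np.tile(rates.mean(0), (7, 1)))

    def test_k_clipped_with_warning(self, rng):
        lat = rng.standard_normal((10, 2))
        with pytest.warns(UserWarning, match="clipped"):
            encoding.nn_latent_predict(lat, rng.standard_normal((10, 3)),
                                       lat, k=50)

    def test_ties_break_to_earlier_time(self):
        lat = np.zeros((5, 2))
        rates = np.arange(5.0)[:, None]
        pred = encoding.nn_latent_predict(lat, rates, np.zeros((1, 2)), k=2)
        # equidistant: earliest two training points win
        np.testing.assert_allclose(pred, [[0.5]])


def _toy_setup(rng, duration=300.0, n_units=4, d=6, linear=True, seed=0):
    """Behaviour-driven rates with a known linear read-out, no lasers."""
    fps, bw = 30.0, 0.1
    n_frames = int(duration * fps)
    from scipy import signal
    z = signal.sosfiltfilt(
        signal.butter(2, 0.5, fs=fps, output="sos"),
        rng.standard_normal((d, n_frames)), axis=1)
    z = z / z.std(axis=1, keepdims=True)
    W = rng.standard_normal((n_units, d))
    n_bins = int(duration / bw)
    frame_of_bin = (np.arange(n_bins) * 3 + 1).astype(int)
    R = (W @ z[:, frame_of_bin]).T + 5.0
    rates = spikes.BinnedRates(counts=R.T * bw, bin_width=bw, t0=0.0,
                               unit_ids=[f"u{i}" for i in range(n_units)],
                               regions=["SSp"] * n_units)
    split = encoding.make_split(duration, [], seed=seed)
    return z, rates, split


class TestTraining:
    def test_zero_rates_predict_zero(self, rng):
        z, rates, split = _toy_setup(rng)
        rates.counts[:] = 0.0
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=300, patience=50, seed=0)
        val_bins = encoding._bins_in_windows(split.validation, 0.1,
                                             rates.counts.shape[1])
        pred = model.predict(z, val_bins)
        assert np.mean(pred ** 2) < 1e-4

    def test_linear_readout_recovered(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=32,
                                       conv_channels=16, latent_dim=8,
                                       max_epochs=250, patience=25, seed=0)
        result = encoding.compute_residuals(z, rates, split, model, k=30)
        m = encoding.model_metrics(result, split)
        assert m.ve_direct_control.median() > 0.9

    def test_intact_behaviour_beats_shuffled(self, rng):
        z, rates, split = _toy_setup(rng)
        kw = dict(hidden=16, conv_channels=8, latent_dim=4, max_epochs=60,
                  patience=10, seed=0)
        m_good = encoding.train_encoder(z, rates, split, **kw)
        perm = rng.permutation(z.shape[1])
        m_bad = encoding.train_encoder(z[:, perm], rates, split, **kw)
        assert min(m_good.val_history) < min(m_bad.val_history)

    def test_no_leakage_from_test_segments(self, rng):
        """Zeroing all test-segment neural data leaves weights bitwise equal."""
        z, rates, split = _toy_setup(rng)
        test_bins = encoding._bins_in_windows(split.test, 0.1,
                                              rates.counts.shape[1])
        kw = dict(hidden=16, conv_channels=8, latent_dim=4, max_epochs=30,
                  patience=10, seed=0)
        m1 = encoding.train_encoder(z, rates, split, **kw)
        rates.counts[:, test_bins] = 0.0
        m2 = encoding.train_encoder(z, rates, split, **kw)
        for p1, p2 in zip(m1._params(), m2._params()):
            np.testing.assert_array_equal(p1, p2)


class TestResiduals:
    def test_exact_identity(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=20, patience=5, seed=0)
        res = encoding.compute_residuals(z, rates, split, model, k=10)
        # identity to numerical precision: (a - b) + b round-trips at ~1 ulp
        np.testing.assert_allclose(res.residual + res.nn, res.recorded,
                                   rtol=1e-12, atol=1e-12)

    def test_injected_offset_appears_in_window_mean(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=20, patience=5, seed=0)
        res = encoding.compute_residuals(z, rates, split, model, k=10)
        ctrl = split.test_segments("control")[0]
        from synckit.session import AnalysisWindow
        win = AnalysisWindow(ctrl.start + 10, ctrl.start + 20, "laser_onset")
        before = encoding.residual_window_means(res, [win])[0]
        res.residual += 0.0  # identity preserved
        times = res.bin_times()
        sel = (times >= win.start - 1e-9) & (times + 0.1 <= win.end + 1e-9)
        res.recorded[sel] += 2.0
        res.residual = res.recorded - res.nn
        after = encoding.residual_window_means(res, [win])[0]
        np.testing.assert_allclose(after - before, 2.0, atol=1e-9)

    def test_window_outside_test_rejected(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=5, patience=5, seed=0)
        res = encoding.compute_residuals(z, rates, split, model, k=10)
        from synckit.session import AnalysisWindow
        train_w = split.train[0]
        with pytest.raises(ValueError, match="test"):
            encoding.residual_window_means(
                res, [AnalysisWindow(train_w.start, train_w.start + 1)])


class TestMetrics:
    def test_perfect_prediction(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=5, patience=5, seed=0)
        res = encoding.compute_residuals(z, rates, split, model, k=10)
        res.nn = res.recorded.copy()
        res.direct = res.recorded.copy()
        m = encoding.model_metrics(res, split)
        np.testing.assert_allclose(m.ve_nn_control, 1.0)
        np.testing.assert_allclose(m.r_control_1s.dropna(), 1.0)

    def test_mean_prediction_gives_zero_ve(self, rng):
        z, rates, split = _toy_setup(rng)
        model = encoding.train_encoder(z, rates, split, hidden=16,
                                       conv_channels=8, latent_dim=4,
                                       max_epochs=5, patience=5, seed=0)
        res = encoding.compute_residuals(z, rates, split, model, k=10)
        times = res.bin_times()
        ctrl = split.test_segments("control")[0]
        sel = (times >= ctrl.start) & (times < ctrl.end)
        res.nn[:] = res.recorded[sel].mean(axis=0)
        m = encoding.model_metrics(res, split)
        np.testing.assert_allclose(m.ve_nn_control, 0.0, atol=1e-9)

    def test_latent_bottleneck_must_be_smaller(self):
        with pytest.raises(ValueError):
            encoding.EncodingNetworkSpec(input_dim=10, n_units=3, hidden=8,
                                         latent_dim=8)
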