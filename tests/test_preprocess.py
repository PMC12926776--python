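import numpy as np
import pytest

from conflictdecode.preprocess import (PreprocessConfig, ScreeningRules,
                                       baseline_correct, crop,
                                       design_fir_kernel, downsample,
                                       fir_filter, harmonize_channels,
                                       preprocess, screen_trials)

from conftest import build_epochs


def _sine_epochs(freq_hz, sample_rate=1000.0, dur_s=4.0, amp=1.0):
    n_t = int(dur_s * sample_rate) + 1
    times = np.arange(n_t) / sample_rate * 1000.0 - 1000.0
    x = amp * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    data = np.tile(x, (4, 2, 1))
    return build_epochs(data, sample_rate=sample_rate, t_start=times[0])


class TestFirFilter:
    def test_dc_rejection(self):
        es = build_epochs(np.full((2, 2, 4001), 5.0), sample_rate=1000.0,
                          t_start=-1000.0)
        out = fir_filter(es, PreprocessConfig(hp_cutoff=0.5, lp_cutoff=100.0,
                                              target_rate=1000.0))
        mid = out.data[:, :, 1500:2500]
        # >= 20 dB attenuation away from the edges
        assert np.abs(mid).max() < 5.0 * 10 ** (-20 / 20)

    def test_passband_identity_5hz(self):
        es = _sine_epochs(5.0)
        out = fir_filter(es, PreprocessConfig(hp_cutoff=0.5, lp_cutoff=100.0,
                                              target_rate=1000.0))
        mid = slice(1500, 2500)
        ratio = np.sqrt(np.mean(out.data[0, 0, mid] ** 2)
                        / np.mean(es.data[0, 0, mid] ** 2))
        assert abs(ratio - 1.0) < 0.01

    def test_stopband_matches_kernel_dft(self):
        # mid-epoch response to a pure tone equals the kernel's frequency
        # response exactly (steady state of a finite kernel)
        freq = 120.0
        es = _sine_epochs(freq)
        cfg = PreprocessConfig(hp_cutoff=0.5, lp_cutoff=100.0, target_rate=1000.0)
        out = fir_filter(es, cfg)
        kernel = design_fir_kernel(1000.0, 0.5, 100.0)
        n_fft = 2 ** 18
        h = np.abs(np.fft.rfft(kernel, n_fft))
        f = np.fft.rfftfreq(n_fft, d=1e-3)
        h_at = np.interp(freq, f, h)
        # amplitude via projection on quadrature pair over whole periods
        t = es.times / 1000.0
        mid = slice(1800, 1800 + 200)  # 0.2 s = 24 whole periods of 120 Hz
        y = out.data[0, 0, mid]
        c = np.cos(2 * np.pi * freq * t[mid])
        s = np.sin(2 * np.pi * freq * t[mid])
        amp = 2 * np.hypot(y @ c, y @ s) / y.size
        assert abs(amp - h_at) < 1e-6

    def test_input_unmodified_and_nyquist_error(self):
        es = _sine_epochs(5.0, sample_rate=180.0, dur_s=2.0)
        snapshot = es.data.copy()
        with pytest.raises(ValueError, match="lp_cutoff|sample rate"):
            fir_filter(es, PreprocessConfig(hp_cutoff=0.5, lp_cutoff=100.0,
                                            target_rate=250.0))
        assert np.array_equal(es.data, snapshot)


class TestDownsample:
    def test_1000_to_250_keeps_every_4th_and_t0(self, rng):
        es = build_epochs(rng.normal(size=(3, 2, 2001)), sample_rate=1000.0,
                          t_start=-500.0)
        out = downsample(es, 250.0)
        assert out.sample_rate == 250.0
        assert 0.0 in out.times
        np.testing.assert_array_equal(out.data, es.data[:, :, 0::4])
        assert np.allclose(np.diff(out.times), 4.0)

    def test_identity_when_rates_match(self, noise_epochs):
        out = downsample(noise_epochs, noise_epochs.sample_rate)
        assert np.array_equal(out.data, noise_epochs.data)

    def test_non_integer_factor_rejected(self, noise_epochs):
        with pytest.raises(ValueError, match="integer"):
            downsample(noise_epochs, 30.0)


class TestBaseline:
    def test_window_mean_is_zero_after_correction(self, noise_epochs):
        out = baseline_correct(noise_epochs, (0.0, 200.0))
        idx = out.window_indices(0.0, 200.0)
        assert np.abs(out.data[:, :, idx].mean(axis=2)).max() < 1e-10

    def test_idempotent_on_zero_mean_data(self, noise_epochs):
        once = baseline_correct(noise_epochs, (0.0, 200.0))
        twice = baseline_correct(once, (0.0, 200.0))
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_offset_channel_matches_unoffset_run(self, rng):
        es = build_epochs(rng.normal(size=(5, 3, 80)))
        shifted = es.copy()
        shifted.data[:, 1, :] += 42.0
        a = baseline_correct(es, (0.0, 200.0))
        b = baseline_correct(shifted, (0.0, 200.0))
        np.testing.assert_allclose(b.data[:, 1, :], a.data[:, 1, :], atol=1e-10)

    def test_empty_window_rejected(self, noise_epochs):
        with pytest.raises(ValueError):
            baseline_correct(noise_epochs, (5000.0, 6000.0))


class TestHarmonize:
    def _named(self, rng, chans):
        es = build_epochs(rng.normal(size=(4, len(chans), 30)))
        es.channels = tuple(chans)
        return es

    def test_intersection_in_canonical_order(self, rng):
        a = self._named(rng, ["Fz", "Cz", "Pz"])
        b = self._named(rng, ["Cz", "Pz", "Oz"])
        ha, hb = harmonize_channels([a, b])
        assert ha.channels == hb.channels == ("Cz", "Pz")
        np.testing.assert_array_equal(ha.data, a.data[:, [1, 2], :])
        np.testing.assert_array_equal(hb.data, b.data[:, [0, 1], :])

    def test_identity_for_identical_montages(self, rng):
        a = self._named(rng, ["Cz", "Fz"])
        b = self._named(rng, ["Cz", "Fz"])
        ha, hb = harmonize_channels([a, b])
        np.testing.assert_array_equal(ha.data, a.data)

    def test_disjoint_montages_rejected(self, rng):
        a = self._named(rng, ["Fz"])
        b = self._named(rng, ["Oz"])
        with pytest.raises(ValueError, match="empty"):
            harmonize_channels([a, b])


class TestScreening:
    def test_simon_rt_limit(self, rng):
        es = build_epochs(rng.normal(size=(3, 2, 30)), task="simon",
                          rts=[300.0, 1499.0, 1501.0])
        out, report = screen_trials(es)
        assert out.n_trials == 2
        assert report["too_slow"] == 1
        np.testing.assert_allclose(out.trials["rt_ms"], [300.0, 1499.0])

    def test_all_within_limits_identity(self, rng):
        es = build_epochs(rng.normal(size=(4, 2, 30)), task="simon",
                          rts=[300.0, 400.0, 500.0, 600.0])
        out, report = screen_trials(es)
        assert out.n_trials == 4
        assert report["premature"] == report["too_slow"] == 0
        np.testing.assert_array_equal(out.data, es.data)

    def test_premature_rule(self, rng):
        es = build_epochs(rng.normal(size=(2, 2, 30)), rts=[50.0, 150.0])
        out, report = screen_trials(es, ScreeningRules(premature_ms=100.0))
        assert out.n_trials == 1 and report["premature"] == 1

    def test_retained_order_never_changes(self, rng):
        rts = rng.uniform(50, 2500, size=20)
        es = build_epochs(rng.normal(size=(20, 2, 30)), task="simon", rts=rts)
        out, _ = screen_trials(es)
        kept = rts[(rts >= 100.0) & (rts <= 1500.0)]
        np.testing.assert_allclose(out.trials["rt_ms"], kept)

    def test_correct_only_mode(self, rng):
        es = build_epochs(rng.normal(size=(4, 2, 30)), rts=[500.0] * 4,
                          correct=[1, 0, 1, 0])
        out, report = screen_trials(
            es, ScreeningRules(correct_only=True, default_rt_max_ms=4000.0))
        assert out.n_trials == 2 and report["incorrect"] == 2


def test_preprocess_chain_is_composition(rng):
    es = build_epochs(rng.normal(size=(6, 3, 4001)), sample_rate=1000.0,
                      t_start=-1000.0, rts=rng.uniform(200, 900, 6))
    cfg = PreprocessConfig(epoch_windows={"task": (-500.0, 2000.0)})
    out, report = preprocess(es, cfg)
    manual = fir_filter(es, cfg)
    manual = downsample(manual, cfg.target_rate)
    manual = crop(manual, (-500.0, 2000.0))
    manual = baseline_correct(manual, cfg.baseline_window)
    manual, _ = screen_trials(manual, cfg.screening)
    np.testing.assert_array_equal(out.data, manual.data)
    assert out.sample_rate == 250.0
    assert report["n_retained"] == out.n_trials


def test_config_validation():
    with pytest.raises(ValueError, match="cutoff"):
        PreprocessConfig(hp_cutoff=0.0)
    with pytest.raises(ValueError, match="cutoff"):
        PreprocessConfig(hp_cutoff=120.0, lp_cutoff=100.0)
    with pytest.raises(ValueError, match="exceed"):
        ScreeningRules(rt_max_ms={"x": 50.0}, premature_ms=100.0)
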