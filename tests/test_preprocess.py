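import numpy as np
import pytest
from scipy import signal as sps

from eegswitch.preprocess import (
    EpochGrid,
    FilterConfig,
    bandpass_filter,
    correct_errors,
    make_epoch_grid,
    notch_filter,
    run_filter_chain,
    sg_smooth,
    universal_threshold,
    wavelet_denoise,
)
from eegswitch.rawio import RawRecording

FS = 128


def _grid(ch1, ch2):
    data = np.stack([np.atleast_2d(ch1), np.atleast_2d(ch2)], axis=1)
    return EpochGrid(data=data, removed=np.zeros(data.shape[0], dtype=bool),
                     sampling_rate=FS)


def _tone_db(before, after, freq):
    """Attenuation in dB at one frequency, via the FFT peak ratio."""
    f = np.fft.rfftfreq(before.size, d=1.0 / FS)
    i = np.argmin(np.abs(f - freq))
    b = np.abs(np.fft.rfft(before))[i]
    a = np.abs(np.fft.rfft(after))[i]
    return 20 * np.log10(b / a)


class TestFilterConfig:
    def test_sg_order_must_be_below_frame(self):
        with pytest.raises(ValueError, match="strictly less"):
            FilterConfig(sg_order=33, sg_frame=33)

    def test_round_trips_through_dict(self):
        cfg = FilterConfig(mains_freq=60.0)
        assert FilterConfig.from_dict(cfg.to_dict()) == cfg


class TestErrorCorrection:
    def test_clean_epoch_unchanged(self):
        frame = np.sin(2 * np.pi * 5 * np.arange(FS) / FS) * 30
        grid = correct_errors(_grid(frame, frame), FilterConfig())
        np.testing.assert_array_equal(grid.data[0, 0], frame)
        assert not grid.removed.any()

    def test_saturated_second_removed(self):
        bad = np.full(FS, 32767 * 0.05)
        good = np.zeros(FS)
        grid = correct_errors(_grid(bad, good), FilterConfig())
        assert grid.removed.tolist() == [True]
        assert grid.n_retained == 0  # all 128 samples dropped

    def test_single_error_held_from_previous_sample(self):
        frame = np.linspace(-10, 10, FS)
        k = 60
        frame_bad = frame.copy()
        frame_bad[k] = 1000.0
        grid = correct_errors(_grid(frame_bad, np.zeros(FS)), FilterConfig())
        assert grid.data[0, 0][k] == frame[k - 1]
        np.testing.assert_array_equal(np.delete(grid.data[0, 0], k),
                                      np.delete(frame, k))

    def test_removal_applies_to_both_channels(self):
        bad = np.full(FS, 1000.0)
        clean = np.ones(FS)
        grid = correct_errors(_grid(bad, clean), FilterConfig())
        assert grid.removed[0]

    def test_burst_threshold_boundary(self):
        cfg = FilterConfig()
        frame = np.zeros(FS)
        frame[: cfg.error_burst_count] = 1000.0  # exactly at the limit
        grid = correct_errors(_grid(frame, np.zeros(FS)), cfg)
        assert not grid.removed[0]
        frame[cfg.error_burst_count] = 1000.0  # one more -> burst
        grid = correct_errors(_grid(frame, np.zeros(FS)), cfg)
        assert grid.removed[0]


class TestNotch:
    def test_mains_tone_attenuated(self, filter_config):
        t = np.arange(20 * FS) / FS
        x = np.sin(2 * np.pi * 50 * t)
        y = notch_filter(x, filter_config, FS)
        assert _tone_db(x, y, 50) >= 20

    def test_eeg_band_untouched(self, filter_config):
        t = np.arange(20 * FS) / FS
        x = np.sin(2 * np.pi * 10 * t)
        y = notch_filter(x, filter_config, FS)
        assert _tone_db(x, y, 10) < 1

    def test_zero_in_zero_out(self, filter_config):
        assert np.allclose(notch_filter(np.zeros(FS * 5), filter_config, FS), 0)

    def test_mains_at_nyquist_rejected(self):
        cfg = FilterConfig(mains_freq=64.0)
        with pytest.raises(ValueError):
            notch_filter(np.zeros(FS * 5), cfg, FS)


class TestBandpass:
    def test_slow_drift_removed(self, filter_config):
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 0.02 * t)  # sub-band drift
        y = bandpass_filter(x, filter_config, FS)
        assert np.sqrt(np.mean(y ** 2)) < 0.1 * np.sqrt(np.mean(x ** 2))

    def test_beta_band_untouched(self, filter_config):
        t = np.arange(20 * FS) / FS
        x = np.sin(2 * np.pi * 20 * t)
        y = bandpass_filter(x, filter_config, FS)
        assert _tone_db(x, y, 20) < 1

    def test_zero_in_zero_out(self, filter_config):
        assert np.allclose(bandpass_filter(np.zeros(FS * 5), filter_config, FS), 0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(bp_low=10.0, bp_high=5.0)

    def test_zero_phase(self, filter_config, rng):
        """Cross-correlation peak between input and output sits at lag 0."""
        t = np.arange(20 * FS) / FS
        x = np.sin(2 * np.pi * 8 * t) + 0.3 * np.sin(2 * np.pi * 19 * t)
        y = bandpass_filter(notch_filter(x, filter_config, FS),
                            filter_config, FS)
        xc = sps.correlate(y - y.mean(), x - x.mean(), mode="full")
        assert np.argmax(xc) == x.size - 1


class TestDenoise:
    def test_zero_in_zero_out(self, filter_config):
        assert np.allclose(wavelet_denoise(np.zeros(FS * 2), filter_config), 0)

    def test_universal_threshold_closed_form(self):
        # detail vector with MAD = 0.6745 gives sigma = 1
        detail = np.array([-0.6745, 0.6745, 0.6745, -0.6745])
        thr = universal_threshold(detail, 128)
        assert thr == pytest.approx(np.sqrt(2 * np.log(128)))
        assert thr == pytest.approx(3.1152, abs=5e-4)

    def test_noise_rmse_decreases_on_sparse_signal(self, filter_config, rng):
        """Universal-threshold shrinkage assumes the signal is sparse in
        the wavelet basis; on a transient/piecewise-smooth signal in
        white noise the RMSE to the clean signal strictly decreases.
        (A long pure sinusoid is *not* db4-sparse and gains nothing —
        see the methods note.)"""
        n = 10 * FS
        clean = np.zeros(n)
        for c, a, w in [(200, 80, 12), (500, -60, 8), (900, 100, 20),
                        (1100, -40, 10)]:
            clean[c - w:c + w] += a * np.hanning(2 * w)
        clean += 30.0 * (np.arange(n) > n // 2)  # a step edge
        noisy = clean + rng.normal(0, 5, size=n)
        den = wavelet_denoise(noisy, filter_config)
        rmse = lambda a: np.sqrt(np.mean((a - clean) ** 2))
        assert rmse(den) < rmse(noisy)
        assert den.size == noisy.size

    def test_noise_only_bands_suppressed(self, filter_config, rng):
        """For a low-frequency tone in noise, the noise-dominated finest
        detail band is zeroed by the hard universal threshold."""
        from eegswitch.decompose import WaveletSpec, wavedec

        t = np.arange(10 * FS) / FS
        noisy = 30 * np.sin(2 * np.pi * 2 * t) + rng.normal(0, 3, t.size)
        den = wavelet_denoise(noisy, filter_config)
        spec = WaveletSpec(mode="symmetric")
        cd1_before = wavedec(noisy, spec)[0][-1]
        cd1_after = wavedec(den, spec)[0][-1]
        assert np.dot(cd1_after, cd1_after) < 0.1 * np.dot(cd1_before,
                                                           cd1_before)

    def test_too_short_rejected(self, filter_config):
        with pytest.raises(ValueError):
            wavelet_denoise(np.zeros(8), filter_config)


class TestSavitzkyGolay:
    def test_polynomial_reproduced_exactly(self, rng):
        """SG is exact on polynomials up to the fitting order."""
        cfg = FilterConfig()
        coeffs = rng.normal(size=cfg.sg_order + 1)
        x = np.polynomial.Polynomial(coeffs)(np.linspace(0, 1, 100))
        y = sg_smooth(x, cfg)
        assert np.abs(y - x).max() < 1e-8 * max(1.0, np.abs(x).max())

    def test_constant_unchanged(self, filter_config):
        x = np.full(200, 7.5)
        np.testing.assert_allclose(sg_smooth(x, filter_config), x)

    def test_order0_equals_moving_average(self, rng):
        cfg = FilterConfig(sg_order=0, sg_frame=5)
        x = rng.normal(size=60)
        ma = np.convolve(x, np.ones(5) / 5, mode="same")
        np.testing.assert_allclose(sg_smooth(x, cfg)[2:-2], ma[2:-2],
                                   atol=1e-12)

    def test_too_short_rejected(self, filter_config):
        with pytest.raises(ValueError):
            sg_smooth(np.zeros(10), filter_config)


class TestChain:
    def _tone_recording(self, seconds=20, freq=10.0, amp=30.0):
        t = np.arange(seconds * FS) / FS
        x = amp * np.sin(2 * np.pi * freq * t)
        counts = np.round(x / 0.05)
        return RawRecording(channel1=counts, channel2=counts)

    def test_clean_recording_keeps_all_epochs(self):
        grid = run_filter_chain(self._tone_recording())
        assert grid.n_retained == grid.n_epochs == 20

    def test_all_zero_recording(self):
        rec = RawRecording(channel1=np.zeros(10 * FS), channel2=np.zeros(10 * FS))
        grid = run_filter_chain(rec)
        assert np.allclose(grid.data, 0.0)

    def test_burst_second_dropped(self):
        rec = self._tone_recording(seconds=20)
        ch1 = rec.channel1.copy()
        ch1[5 * FS: 5 * FS + 50] = 32767  # inject one saturated burst
        rec2 = RawRecording(channel1=ch1, channel2=rec.channel2)
        grid = run_filter_chain(rec2)
        assert grid.n_epochs == 20
        assert grid.n_retained == 19
        assert grid.removed[5]

    def test_trailing_partial_second_dropped(self):
        n = 10 * FS + 37
        rec = RawRecording(channel1=np.zeros(n), channel2=np.zeros(n))
        assert make_epoch_grid(rec).n_epochs == 10

    def test_out_of_band_energy_small(self):
        """A clean alpha tone passes the chain nearly untouched and the
        output stays band-limited.  The first/last two seconds are
        excluded: the zero-phase IIR filters have unavoidable warm-up
        transients at the series boundaries."""
        grid = run_filter_chain(self._tone_recording(seconds=30, freq=10.0))
        y = grid.channel_series(0)[2 * FS:-2 * FS]
        f = np.fft.rfftfreq(y.size, d=1.0 / FS)
        p = np.abs(np.fft.rfft(y)) ** 2
        in_band = p[(f > 8) & (f < 12)].sum()
        assert in_band / p.sum() > 0.99

    def test_idempotent_on_clean_signal(self):
        """Re-filtering an already filtered band-limited signal changes
        its energy by less than 5%."""
        grid1 = run_filter_chain(self._tone_recording(seconds=30, freq=10.0))
        y1 = grid1.channel_series(0)
        rec2 = RawRecording(channel1=np.round(y1 / 0.05),
                            channel2=np.round(y1 / 0.05))
        y2 = run_filter_chain(rec2).channel_series(0)
        e1, e2 = np.dot(y1, y1), np.dot(y2, y2)
        assert abs(e2 - e1) / e1 < 0.05

    def test_channel_alignment_preserved(self, default_run):
        _, rec, _ = default_run
        grid = run_filter_chain(rec)
        # retained epochs carry their original indices for both channels
        assert grid.data.shape[1] == 2
        assert grid.retained_indices.size == grid.n_retained
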