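"""Preprocessing-chain tests: EOG regression, epoching, decimation, filters."""

from __future__ import annotations

import numpy as np
import pytest

from slgraph import (
    PreprocessConfig,
    Recording,
    bandpass,
    correct_eog,
    downsample,
    epoch_and_reject,
    preprocess_recording,
    select_epochs,
)
from slgraph.montage import EOG_CHANNELS, MONTAGE_29

from conftest import make_epochset


def _recording_with_eog(rng, fs=250.0, duration=12.0, beta_v=0.12, beta_h=0.05,
                        clean_sd=10.0):
    """Clean montage noise plus known EOG propagation."""
    n = int(duration * fs)
    clean = rng.standard_normal((len(MONTAGE_29), n)) * clean_sd
    veog = 50.0 * np.sin(2 * np.pi * 0.5 * np.arange(n) / fs) + rng.standard_normal(n)
    heog = 30.0 * np.cos(2 * np.pi * 0.3 * np.arange(n) / fs) + rng.standard_normal(n)
    samples = np.vstack([clean + beta_v * veog + beta_h * heog,
                         veog[None, :], heog[None, :]])
    rec = Recording(subject_id="S1", fs=fs,
                    channel_labels=MONTAGE_29 + EOG_CHANNELS, samples=samples)
    return rec, clean, (beta_v, beta_h)


class TestCorrectEog:
    def test_recovers_propagation_coefficients(self, rng):
        # long record + weak background so the OLS sampling error is < 1%
        rec, _, (bv, bh) = _recording_with_eog(rng, duration=120.0, clean_sd=1.0)
        out = correct_eog(rec)
        betas = out.meta["eog_betas"]
        for label in ("Fp1", "Cz", "O1"):
            assert betas[label][0] == pytest.approx(bv, rel=0.01)
            assert betas[label][1] == pytest.approx(bh, rel=0.01)

    def test_removes_eog_contribution(self, rng):
        rec, clean, _ = _recording_with_eog(rng)
        out = correct_eog(rec)
        resid = out.samples[: len(MONTAGE_29)] - clean
        # residual contamination should be tiny relative to the EOG signal
        assert np.sqrt((resid**2).mean()) < 0.5

    def test_zero_eog_leaves_eeg_unchanged(self, rng):
        n = 1000
        eeg = rng.standard_normal((len(MONTAGE_29), n))
        samples = np.vstack([eeg, np.zeros((2, n))])
        rec = Recording(subject_id="S1", fs=250.0,
                        channel_labels=MONTAGE_29 + EOG_CHANNELS, samples=samples)
        out = correct_eog(rec)
        assert np.allclose(out.samples[: len(MONTAGE_29)], eeg)

    def test_missing_eog_channel_named(self, rng):
        eeg = rng.standard_normal((len(MONTAGE_29) + 1, 500))
        rec = Recording(subject_id="S1", fs=250.0,
                        channel_labels=MONTAGE_29 + ("VEOG",), samples=eeg)
        with pytest.raises(ValueError, match="HEOG"):
            correct_eog(rec)

    def test_channel_order_preserved(self, rng):
        rec, _, _ = _recording_with_eog(rng)
        out = correct_eog(rec)
        assert out.channel_labels == rec.channel_labels
        assert out.eeg_labels == MONTAGE_29
        assert np.array_equal(out.channel("VEOG"), rec.channel("VEOG"))


class TestEpochAndReject:
    def test_120s_gives_60_epochs(self, rng):
        fs = 100.0
        rec, *_ = _recording_with_eog(rng, fs=fs, duration=120.0)
        ep = epoch_and_reject(rec)
        assert ep.n_epochs == 60
        assert ep.n_samples == 200

    def test_planted_excursions_flagged_exactly(self, rng):
        rec, *_ = _recording_with_eog(rng, duration=20.0)  # 10 epochs
        samples = rec.samples.copy()
        planted = [2, 5, 7]
        for e in planted:
            samples[4, e * 500 + 100] = 300.0  # F4, above +/-150 uV
        rec = Recording(subject_id="S1", fs=rec.fs,
                        channel_labels=rec.channel_labels, samples=samples)
        ep = epoch_and_reject(rec)
        assert list(np.flatnonzero(ep.rejected_mask)) == planted

    def test_eog_channels_exempt_from_threshold(self, rng):
        rec, *_ = _recording_with_eog(rng, duration=8.0)
        samples = rec.samples.copy()
        samples[-2, 300] = 900.0  # huge blink on VEOG only
        rec = Recording(subject_id="S1", fs=rec.fs,
                        channel_labels=rec.channel_labels, samples=samples)
        ep = epoch_and_reject(rec)
        assert not ep.rejected_mask.any()

    def test_retained_epochs_are_baseline_corrected(self, rng):
        rec, *_ = _recording_with_eog(rng, duration=8.0)
        ep = epoch_and_reject(rec)
        means = ep.retained.mean(axis=2)
        assert np.allclose(means, 0.0, atol=1e-10)

    def test_all_rejected_raises(self, rng):
        eeg = np.full((len(MONTAGE_29), 1000), 500.0)
        eeg += rng.standard_normal(eeg.shape)
        samples = np.vstack([eeg, np.zeros((2, 1000))])
        rec = Recording(subject_id="S1", fs=250.0,
                        channel_labels=MONTAGE_29 + EOG_CHANNELS, samples=samples)
        with pytest.raises(ValueError, match="all epochs rejected"):
            epoch_and_reject(rec)


class TestSelectEpochs:
    def test_prefix_selection(self, rng):
        data = rng.standard_normal((12, 3, 100))
        ep = make_epochset(data)
        out = select_epochs(ep, 10)
        assert out.n_epochs == 10
        assert np.array_equal(out.data, data[:10])

    def test_rejected_epochs_skipped_in_order(self, rng):
        data = rng.standard_normal((8, 3, 100))
        ep = make_epochset(data)
        ep.rejected_mask[[1, 4]] = True
        out = select_epochs(ep, 5)
        assert np.array_equal(out.data, data[[0, 2, 3, 5, 6]])

    def test_insufficient_clean_epochs_reports_count(self, rng):
        ep = make_epochset(rng.standard_normal((4, 3, 100)))
        ep.rejected_mask[:2] = True
        with pytest.raises(ValueError, match="only 2 clean"):
            select_epochs(ep, 3)


class TestDownsample:
    def test_factor_four_shortens_epochs(self, rng):
        ep = make_epochset(rng.standard_normal((3, 4, 2000)), fs=1000.0)
        out = downsample(ep)
        assert out.fs == 250.0
        assert out.n_samples == 500

    def test_ten_hz_peak_survives(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        data = np.sin(2 * np.pi * 10 * t)[None, None, :]
        out = downsample(make_epochset(data, fs=fs))
        spec = np.abs(np.fft.rfft(out.data[0, 0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        assert freqs[np.argmax(spec)] == pytest.approx(10.0, abs=0.5)

    def test_total_sample_budget(self, rng):
        ep = make_epochset(rng.standard_normal((10, 2, 2000)), fs=1000.0)
        out = downsample(ep)
        assert out.n_epochs * out.n_samples == 5000  # 20 s at 250 Hz

    def test_non_integer_factor_rejected(self, rng):
        ep = make_epochset(rng.standard_normal((1, 2, 300)), fs=300.0)
        with pytest.raises(ValueError, match="integer multiple"):
            downsample(ep)


class TestBandpass:
    def _sine_epochs(self, freq, fs=250.0, n=2500):
        t = np.arange(n) / fs
        return make_epochset(np.sin(2 * np.pi * freq * t)[None, None, :], fs=fs)

    def test_in_band_amplitude_preserved(self):
        out = bandpass(self._sine_epochs(10.0), "alpha")
        mid = out.data[0, 0, 1000:1500]  # avoid filter edge transients
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_attenuated(self):
        out = bandpass(self._sine_epochs(10.0), "delta")
        assert np.abs(out.data[0, 0, 1000:1500]).max() < 0.1

    def test_five_bands_produced(self, rng):
        ep = make_epochset(rng.standard_normal((2, 3, 500)))
        outs = {b: bandpass(ep, b) for b in ("delta", "theta", "alpha", "beta", "gamma")}
        assert {o.band for o in outs.values()} == set(outs)

    def test_nyquist_violation_rejected(self, rng):
        ep = make_epochset(rng.standard_normal((1, 2, 400)), fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ep, "gamma")

    def test_idempotent_at_band_center(self):
        # a second pass must not touch content in the middle of the band
        ep = self._sine_epochs(10.0)
        once = bandpass(ep, "alpha")
        twice = bandpass(once, "alpha")
        mid = slice(1000, 1500)
        rms1 = np.sqrt((once.data[0, 0, mid] ** 2).mean())
        rms2 = np.sqrt((twice.data[0, 0, mid] ** 2).mean())
        assert abs(rms2 - rms1) / rms1 < 0.01


class TestFullChain:
    def test_study_shape(self, rng):
        rec, *_ = _recording_with_eog(rng, fs=1000.0, duration=24.0)
        cfg = PreprocessConfig(n_keep=10)
        out = preprocess_recording(rec, cfg)
        assert set(out) == {"delta", "theta", "alpha", "beta", "gamma"}
        for band, ep in out.items():
            assert ep.n_epochs == 10
            assert ep.fs == 250.0
            assert ep.n_samples == 500
            assert ep.band == band
            assert ep.channel_labels == MONTAGE_29
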