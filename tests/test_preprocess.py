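"""Preprocessing: resampling, epoching, normalization, filtering, trimming."""

import numpy as np
import pytest
from scipy import signal

import mfescreen as m
from mfescreen import EpochSet, MFEConfig, PreprocessConfig, RawRecording
from mfescreen.errors import (
    ConfigError,
    DegenerateChannelError,
    InvalidRateError,
    TooShortError,
)
from mfescreen.preprocess import MONTAGE_1020


def make_recording(rng, seconds=45.0, fs=200.0, **kwargs):
    n = int(seconds * fs)
    return RawRecording(
        samples=rng.standard_normal((19, n)), fs=fs, channel_names=MONTAGE_1020,
        subject_id="test", **kwargs,
    )


class TestResample:
    def test_identity_at_target_rate(self, rng):
        rec = make_recording(rng, seconds=5)
        out = m.resample_recording(rec, 200.0)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_downsample_length(self, rng):
        rec = make_recording(rng, seconds=12, fs=400.0)
        out = m.resample_recording(rec, 200.0)
        assert out.fs == 200.0
        assert out.samples.shape == (19, 2400)

    def test_sinusoid_preserved(self):
        # a 10 Hz tone resampled 512 -> 200 Hz must match the analytic tone
        t512 = np.arange(int(512 * 10)) / 512
        rec = RawRecording(
            samples=np.tile(np.sin(2 * np.pi * 10 * t512), (19, 1)),
            fs=512.0, channel_names=MONTAGE_1020,
        )
        out = m.resample_recording(rec, 200.0)
        t200 = np.arange(out.samples.shape[1]) / 200
        analytic = np.sin(2 * np.pi * 10 * t200)
        mid = slice(200, -200)  # polyphase edges excluded
        r = np.corrcoef(out.samples[0, mid], analytic[mid])[0, 1]
        assert r > 0.999

    def test_rejects_sub_nyquist_target(self, rng):
        rec = make_recording(rng, seconds=2)
        with pytest.raises(InvalidRateError):
            m.resample_recording(rec, 60.0)


class TestExtractEpochs:
    def test_default_window_count(self, rng):
        epochs = m.extract_epochs(make_recording(rng, 45), PreprocessConfig())
        assert epochs.data.shape == (15, 19, 600)

    def test_too_short_recording(self, rng):
        with pytest.raises(TooShortError, match="9000"):
            m.extract_epochs(make_recording(rng, 44), PreprocessConfig())

    def test_explicit_starts_slice_contract(self, rng):
        rec = make_recording(rng, 45)
        cfg = PreprocessConfig(n_epochs=3)
        epochs = m.extract_epochs(rec, cfg, epoch_starts=[0, 600, 1200])
        np.testing.assert_array_equal(epochs.data[1], rec.samples[:, 600:1200])

    def test_overlapping_starts_rejected(self, rng):
        rec = make_recording(rng, 45)
        with pytest.raises(ConfigError):
            m.extract_epochs(rec, PreprocessConfig(n_epochs=2), epoch_starts=[0, 300])


class TestNormalize:
    def test_affine_endpoints_single_epoch(self):
        data = np.linspace(0, 1, 600)[None, None, :]
        epochs = EpochSet(data=data, fs=200.0, channel_names=["C3"])
        out = m.normalize_channels(epochs, PreprocessConfig())
        assert out.data[0, 0, 0] == pytest.approx(-10.0)
        assert out.data[0, 0, -1] == pytest.approx(10.0)
        mid = np.argmin(np.abs(data[0, 0] - 0.5))
        assert out.data[0, 0, mid] == pytest.approx(0.0, abs=0.02)

    def test_median_frame_and_out_of_frame_values(self):
        # epoch extremes (+-1, +-2, +-4) -> median frame [-2, 2]; a sample of
        # 2 maps to +10 and 3 maps to +15 (no clipping)
        def epoch(lo, hi, extra):
            e = np.zeros(600)
            e[0], e[1], e[2] = lo, hi, extra
            return e

        data = np.stack([
            epoch(-1, 1, 0.0), epoch(-2, 2, 0.0), epoch(-4, 4, 3.0),
        ])[:, None, :]
        out = m.normalize_channels(
            EpochSet(data=data, fs=200.0, channel_names=["C3"]), PreprocessConfig()
        )
        assert out.data[1, 0, 1] == pytest.approx(10.0)   # raw value 2
        assert out.data[2, 0, 2] == pytest.approx(15.0)   # raw value 3

    def test_idempotent_once_framed(self, rng):
        epochs = EpochSet(
            data=rng.standard_normal((5, 3, 600)), fs=200.0,
            channel_names=["C3", "C4", "P4"],
        )
        cfg = PreprocessConfig()
        once = m.normalize_channels(epochs, cfg)
        twice = m.normalize_channels(once, cfg)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_flat_channel_rejected(self):
        data = np.zeros((2, 1, 600))
        with pytest.raises(DegenerateChannelError, match="C3"):
            m.normalize_channels(
                EpochSet(data=data, fs=200.0, channel_names=["C3"]), PreprocessConfig()
            )

    def test_entropy_invariant_under_normalization(self, rng):
        # scale-1 fuzzy entropy is unchanged because the map is affine and the
        # tolerance is defined relative to the epoch SD
        epoch = rng.standard_normal(600)
        epochs = EpochSet(data=epoch[None, None, :], fs=200.0, channel_names=["C3"])
        normed = m.normalize_channels(epochs, PreprocessConfig())
        cfg = MFEConfig(scales=(1,))
        before = m.mfe_profile(epoch, cfg)[0]
        after = m.mfe_profile(normed.data[0, 0], cfg)[0]
        assert after == pytest.approx(before, abs=1e-9)


class TestBandpassAndTrim:
    def test_transient_epoch_dropped(self, rng):
        epochs = EpochSet(data=rng.standard_normal((15, 2, 600)), fs=200.0,
                          channel_names=["C3", "C4"])
        out = m.bandpass_and_trim(epochs, "delta", PreprocessConfig())
        assert out.n_epochs == 14

    def test_delta_stopband_attenuation(self, rng):
        epochs = EpochSet(data=rng.standard_normal((15, 1, 600)), fs=200.0,
                          channel_names=["C3"])
        out = m.bandpass_and_trim(epochs, "delta", PreprocessConfig())
        series = out.data[:, 0, :].reshape(-1)
        f, psd = signal.welch(series, fs=200.0, nperseg=1024)
        passband = psd[(f >= 1.0) & (f <= 3.5)].mean()
        stopband = psd[f >= 8.0].mean()
        assert 10 * np.log10(passband / stopband) >= 40.0

    def test_alpha_tone_amplitude_preserved(self):
        t = np.arange(15 * 600) / 200.0
        tone = np.sin(2 * np.pi * 10.0 * t).reshape(15, 1, 600)
        epochs = EpochSet(data=tone, fs=200.0, channel_names=["C3"])
        out = m.bandpass_and_trim(epochs, "alpha", PreprocessConfig())
        steady = out.data[5, 0, :]
        amplitude = (steady.max() - steady.min()) / 2
        assert amplitude == pytest.approx(1.0, rel=0.05)

    def test_unknown_band(self, rng):
        epochs = EpochSet(data=rng.standard_normal((3, 1, 600)), fs=200.0,
                          channel_names=["C3"])
        with pytest.raises(ConfigError, match="gamma"):
            m.bandpass_and_trim(epochs, "gamma", PreprocessConfig())


class TestPipeline:
    def test_shapes_and_determinism(self, rng):
        rec = make_recording(rng, seconds=9)
        cfg = PreprocessConfig(n_epochs=3)
        banded = m.preprocess_recording(rec, cfg)
        assert set(banded) == {"all", "delta", "theta", "alpha", "beta"}
        for stack in banded.values():
            assert stack.data.shape == (2, 19, 600)
        again = m.preprocess_recording(rec, cfg)
        for band in banded:
            np.testing.assert_array_equal(banded[band].data, again[band].data)

    def test_provenance_records_order(self, rng):
        rec = make_recording(rng, seconds=9)
        banded = m.preprocess_recording(rec, PreprocessConfig(n_epochs=3))
        steps = " | ".join(banded["alpha"].provenance)
        assert steps.index("epoch") < steps.index("normalize") < steps.index("bandpass")


def test_config_validation():
    with pytest.raises(ConfigError):
        PreprocessConfig(h_max=-10, h_min=10)
    with pytest.raises(ConfigError):
        PreprocessConfig(epoch_seconds=3.0005)
    with pytest.raises(ConfigError):
        PreprocessConfig(bands={"bad": (0.1, 31.0)})
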