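import numpy as np
import pytest

from microstate_lab import (
    EEGRecording,
    average_reference,
    bandpass_notch,
    epoch,
    flag_artifacts,
    interpolate_channels,
    make_montage,
    resample,
)
from microstate_lab.preprocess import EpochSet, preprocess_recording, select_artifact_free


def sine_recording(montage, freq, fs=1000.0, seconds=10.0, amp=1.0):
    t = np.arange(int(fs * seconds)) / fs
    data = np.tile(amp * np.sin(2 * np.pi * freq * t), (montage.n_channels, 1))
    return EEGRecording(data, fs, montage)


class TestResample:
    def test_downsample_length(self, montage32):
        rec = sine_recording(montage32, 5.0)
        out = resample(rec, 125.0)
        assert out.fs == 125.0
        assert abs(out.n_samples - 1250) <= 1

    def test_identity_rate_preserves_passband(self, montage32):
        rec = sine_recording(montage32, 1.0)
        out = resample(rec, rec.fs)
        mid = slice(1000, -1000)
        err = np.abs(out.data[0, mid] - rec.data[0, mid]).max()
        assert err < 0.01

    def test_aliasing_band_suppressed(self, montage32):
        rec = sine_recording(montage32, 55.0)
        out = resample(rec, 125.0)
        ratio = np.std(out.data) / np.std(rec.data)
        assert ratio < 0.05

    def test_upsampling_refused(self, montage32):
        rec = sine_recording(montage32, 5.0, fs=125.0, seconds=2.0)
        with pytest.raises(ValueError):
            resample(rec, 250.0)


class TestBandpassNotch:
    def test_passband_sine_preserved_zero_lag(self, montage32):
        rec = sine_recording(montage32, 10.0)
        out = bandpass_notch(rec, 2.0, 20.0, 60.0)
        mid = slice(2000, 8000)
        x, y = rec.data[0, mid], out.data[0, mid]
        assert np.std(y) == pytest.approx(np.std(x), rel=0.05)
        lag = np.argmax(np.correlate(y, x, mode="full")) - (len(x) - 1)
        assert lag == 0

    def test_notch_removes_mains(self, montage32):
        rec = sine_recording(montage32, 60.0)
        out = bandpass_notch(rec, 2.0, 20.0, 60.0)
        assert np.std(out.data[0, 2000:8000]) < 0.05 * np.std(rec.data[0])

    def test_drift_attenuated(self, montage32):
        rec = sine_recording(montage32, 0.5)
        out = bandpass_notch(rec, 2.0, 20.0, 60.0)
        atten = np.std(out.data[0, 2000:8000]) / np.std(rec.data[0, 2000:8000])
        assert atten < 0.1  # > 20 dB

    def test_rejects_band_above_nyquist(self, montage32):
        rec = sine_recording(montage32, 5.0, fs=125.0, seconds=4.0)
        with pytest.raises(ValueError):
            bandpass_notch(rec, 2.0, 70.0, None)

    def test_channel_permutation_equivariance(self, montage32):
        rng = np.random.default_rng(0)
        rec = EEGRecording(rng.normal(size=(32, 2000)), 1000.0, montage32)
        perm = rng.permutation(32)
        out = bandpass_notch(rec, 2.0, 20.0, 60.0)
        rec_p = EEGRecording(rec.data[perm], 1000.0, montage32)
        out_p = bandpass_notch(rec_p, 2.0, 20.0, 60.0)
        assert np.allclose(out.data[perm], out_p.data)


class TestEpoch:
    def test_sample_counts(self, montage32):
        rec = sine_recording(montage32, 5.0, fs=125.0, seconds=10.0)
        ep = epoch(rec, 2.0)
        assert ep.data.shape == (5, 32, 250)

    def test_trailing_partial_window_dropped(self, montage32):
        rec = sine_recording(montage32, 5.0, fs=125.0, seconds=4.9)
        assert epoch(rec, 2.0).n_epochs == 2

    def test_baseline_correction(self, montage32):
        rng = np.random.default_rng(1)
        rec = EEGRecording(rng.normal(3.0, 1.0, (32, 1000)), 125.0, montage32)
        ep = epoch(rec, 2.0)
        assert np.max(np.abs(ep.data.mean(axis=2))) < 1e-9

    def test_too_short_recording_rejected(self, montage32):
        rec = sine_recording(montage32, 5.0, fs=125.0, seconds=1.0)
        with pytest.raises(ValueError):
            epoch(rec, 2.0)


class TestFlagArtifacts:
    def test_spike_epoch_flagged(self, epochs_factory):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 10, (3, 32, 250))
        data[1, :7, 50] = 500.0
        data[1, :7, 60] = -500.0  # ±500 µV spikes on ~20% of channels
        ep = flag_artifacts(epochs_factory(data))
        assert list(ep.artifact_flags) == [False, True, False]

    def test_flat_channels_flagged(self, epochs_factory):
        ep = flag_artifacts(epochs_factory(np.zeros((1, 32, 250))))
        assert len(ep.bad_channels[0]) == 32

    def test_clean_epoch_not_flagged(self, canon32):
        from microstate_lab import StateDynamics, simulate_recording

        dyn = StateDynamics((80.0,) * 4, snr=2.0, gfp_uv=10.0)
        ep, _ = simulate_recording(canon32, dyn, n_epochs=5, seed=0)
        flagged = flag_artifacts(ep)
        assert not flagged.artifact_flags.any()

    def test_flags_monotone_in_threshold(self, epochs_factory):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 60, (20, 32, 250))
        strict = flag_artifacts(epochs_factory(data), amp_uv=150.0)
        loose = flag_artifacts(epochs_factory(data), amp_uv=300.0)
        assert set(np.flatnonzero(loose.artifact_flags)) <= set(
            np.flatnonzero(strict.artifact_flags)
        )


class TestInterpolateChannels:
    def test_smooth_field_holdout(self, montage32, epochs_factory):
        # y-dipole field (first-order harmonic): held-out channel must be
        # reconstructed to within 2% of the field RMS
        field = montage32.positions[:, 1] - montage32.positions[:, 1].mean()
        data = np.tile(field[:, None], (1, 250))[None]
        ep = epochs_factory(data)
        ep = EpochSet(ep.data, ep.fs, ep.epoch_s, ep.montage, bad_channels=((5,),))
        out = interpolate_channels(ep)
        err = np.abs(out.data[0, 5] - data[0, 5]).max()
        assert err < 0.02 * np.sqrt(np.mean(field**2))
        # good channels untouched bit-for-bit
        good = np.setdiff1d(np.arange(32), [5])
        assert np.array_equal(out.data[0, good], data[0, good])

    def test_no_bad_channels_is_identity(self, epochs_factory):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(2, 32, 50))
        ep = epochs_factory(data)
        assert np.array_equal(interpolate_channels(ep).data, data)

    def test_zero_field_interpolates_to_zero(self, montage32, epochs_factory):
        data = np.zeros((1, 32, 10))
        ep = epochs_factory(data)
        ep = EpochSet(ep.data, ep.fs, ep.epoch_s, ep.montage, bad_channels=((3,),))
        assert np.max(np.abs(interpolate_channels(ep).data)) < 1e-9

    def test_refuses_too_many_bad_channels(self, epochs_factory):
        data = np.random.default_rng(0).normal(size=(1, 32, 10))
        ep = epochs_factory(data)
        bad = (tuple(range(10)),)  # > 25% of 32
        ep = EpochSet(ep.data, ep.fs, ep.epoch_s, ep.montage, bad_channels=bad)
        with pytest.raises(ValueError, match="bad channels"):
            interpolate_channels(ep)


class TestAverageReference:
    def test_frame_arithmetic(self, epochs_factory):
        data = np.zeros((1, 32, 1))
        data[0, :3, 0] = [1.0, 2.0, 3.0]
        # only the first three channels carry signal; mean over all 32
        out = average_reference(epochs_factory(data))
        expected = data[0, :, 0] - data[0, :, 0].mean()
        assert np.allclose(out.data[0, :, 0], expected)

    def test_idempotent(self, epochs_factory):
        rng = np.random.default_rng(4)
        ep = epochs_factory(rng.normal(size=(3, 32, 100)))
        once = average_reference(ep)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        assert np.max(np.abs(once.data.mean(axis=1))) < 1e-9

    def test_gfp_invariant_under_rereferencing(self, epochs_factory):
        from microstate_lab import gfp

        rng = np.random.default_rng(5)
        ep = average_reference(epochs_factory(rng.normal(size=(2, 32, 50))))
        assert np.allclose(gfp(ep), gfp(average_reference(ep)))


class TestComposedPipeline:
    def test_end_to_end_on_raw_rate_recording(self, montage32):
        rng = np.random.default_rng(6)
        t = np.arange(22000) / 1000.0
        data = 20 * np.sin(2 * np.pi * 10 * t)[None, :] * np.ones((32, 1))
        data += rng.normal(0, 5, data.shape)
        rec = EEGRecording(data, 1000.0, montage32)
        ep = preprocess_recording(rec)
        assert ep.fs == 125.0
        assert ep.n_samples == 250
        assert np.max(np.abs(ep.data.mean(axis=1))) < 1e-9  # referenced

    def test_first_n_artifact_free_selection(self, epochs_factory):
        rng = np.random.default_rng(7)
        data = rng.normal(0, 10, (6, 32, 250))
        ep = epochs_factory(data)
        flags = np.array([False, True, False, False, True, False])
        ep = EpochSet(ep.data, ep.fs, ep.epoch_s, ep.montage, artifact_flags=flags)
        out = select_artifact_free(ep, 3)
        assert np.array_equal(out.data, data[[0, 2, 3]])
        with pytest.raises(ValueError, match="artifact-free"):
            select_artifact_free(ep, 5)
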