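import numpy as np
import pytest
from scipy import signal

from stridelock import timefreq as tfm
from stridelock.io import (EEGRecording, REFERENCE_CHANNELS, SCALP_CHANNELS)

RATE = 300.0


def _eeg(data=None, n=3000, rng_seed=0, triggers=()):
    rng = np.random.default_rng(rng_seed)
    labels = SCALP_CHANNELS + REFERENCE_CHANNELS
    if data is None:
        shared = rng.normal(size=n)
        data = np.array([3 * shared + rng.normal(size=n) for _ in labels])
        data[-2:] = rng.normal(size=(2, n))
    return EEGRecording(labels, data, RATE, list(triggers))


class TestPreprocess:
    def test_rereference_identity_when_refs_zero(self):
        rec = _eeg()
        rec.data[-2:] = 0.0
        out = tfm.preprocess(rec, l_freq=None)
        np.testing.assert_allclose(out.data, rec.data[:19])

    def test_rereference_subtracts_ear_average(self):
        rec = _eeg()
        out = tfm.preprocess(rec, l_freq=None)
        ref = 0.5 * (rec.data[-2] + rec.data[-1])
        np.testing.assert_allclose(out.data, rec.data[:19] - ref)

    def test_50hz_attenuated(self):
        # 60 s of pure 50-Hz line; generous trim because the 0.1-Hz edge
        # gives the zero-phase filter a seconds-long edge transient
        n = int(60 * RATE)
        t = np.arange(n) / RATE
        line = np.sin(2 * np.pi * 50 * t)
        labels = SCALP_CHANNELS + REFERENCE_CHANNELS
        rec = EEGRecording(labels, np.vstack([np.tile(line, (19, 1)),
                                              np.zeros((2, n))]), RATE)
        out = tfm.preprocess(rec, correlation_frac=1.1)
        trim = 6000
        ratio = line[trim:-trim].var() / out.data[0, trim:-trim].var()
        assert 10 * np.log10(ratio) > 20

    def test_deviation_outlier_flagged(self):
        rec = _eeg()
        rec.data[3] = np.random.default_rng(1).normal(size=rec.n_samples) * 300
        out = tfm.preprocess(rec)
        assert SCALP_CHANNELS[3] in out.bad_channels
        assert SCALP_CHANNELS[3] not in out.labels

    def test_missing_reference_error(self):
        rec = _eeg()
        rec.labels = [l if l != "A1" else "XX" for l in rec.labels]
        with pytest.raises(ValueError, match="A1"):
            tfm.preprocess(rec)

    def test_uncorrelated_channels_abort(self):
        rng = np.random.default_rng(2)
        labels = SCALP_CHANNELS + REFERENCE_CHANNELS
        rec = EEGRecording(labels, rng.normal(size=(21, 3000)), RATE)
        with pytest.raises(RuntimeError, match="half"):
            tfm.preprocess(rec)


class TestTrialEpochs:
    def test_constant_offset_removed(self):
        rec = _eeg()
        rec.data = np.full_like(rec.data, 7.0)
        epochs, times, dropped = tfm.epoch_trials(rec, [2.0], tmax=5.0)
        assert dropped == 0
        np.testing.assert_allclose(epochs, 0.0)

    def test_early_onset_dropped(self):
        rec = _eeg()
        _, _, dropped = tfm.epoch_trials(rec, [0.05], tmax=5.0)
        assert dropped == 1

    def test_all_triggers_epoched(self):
        rec = _eeg(n=30_000)
        onsets = 1.0 + np.arange(15) * 6.0
        epochs, _, dropped = tfm.epoch_trials(rec, onsets, tmax=5.0)
        assert len(epochs) == 15
        assert dropped == 0


class TestOutlierRejection:
    def _epochs(self, sds):
        return [tfm.StepEpoch(power=np.zeros((1, 1, 2)),
                              times=np.arange(2) / RATE, duration=0.6, sd=s)
                for s in sds]

    def test_identical_epochs_kept(self):
        out = tfm.reject_outlier_epochs(self._epochs([1.0] * 100))
        assert not any(e.rejected for e in out)

    def test_single_outlier_rejected(self):
        rng = np.random.default_rng(0)
        sds = list(1 + 0.01 * rng.normal(size=99)) + [10.0]
        out = tfm.reject_outlier_epochs(self._epochs(sds))
        rejected = [i for i, e in enumerate(out) if e.rejected]
        assert rejected == [99]

    def test_clean_simulated_rejection_rate(self):
        rng = np.random.default_rng(3)
        sds = rng.normal(10, 1, 200)
        out = tfm.reject_outlier_epochs(self._epochs(sds))
        frac = np.mean([e.rejected for e in out])
        assert frac <= 0.05

    def test_few_epochs_warns(self):
        with pytest.warns(UserWarning):
            tfm.reject_outlier_epochs(self._epochs([1.0] * 5))


class TestMorlet:
    def test_fwhm_of_3hz_wavelet(self):
        w = tfm.morlet_wavelet(3.0, 0.6, RATE)
        env = np.abs(w) / np.abs(w).max()
        t = (np.arange(len(w)) - len(w) // 2) / RATE
        width = t[env >= 0.5].max() - t[env >= 0.5].min()
        assert width == pytest.approx(0.6, rel=0.05)

    def test_sinusoid_peak_at_matching_frequency(self):
        t = np.arange(int(10 * RATE)) / RATE
        x = np.sin(2 * np.pi * 10.0 * t)
        tf = tfm.morlet_tf(x[None, :], RATE)
        interior = tf.power[0, :, 600:-600]
        best = tf.freqs[np.argmax(interior.mean(axis=1))]
        assert abs(best - 10.0) <= np.diff(tf.freqs)[0]
        # constant over interior time
        pk = interior[np.argmax(interior.mean(axis=1))]
        assert pk.std() / pk.mean() < 0.01

    def test_unit_gain_flat_across_grid(self):
        t = np.arange(int(12 * RATE)) / RATE
        peaks = []
        for f, fw in zip(tfm.FREQS[::10], tfm.FWHMS[::10]):
            x = np.sin(2 * np.pi * f * t)
            tf = tfm.morlet_tf(x[None, :], RATE, freqs=np.array([f]),
                               fwhms=np.array([fw]))
            peaks.append(tf.power[0, 0, 1500:-1500].mean())
        peaks = np.array(peaks)
        assert peaks.min() / peaks.max() > 0.97

    def test_white_noise_flat_after_energy_normalization(self, rng):
        x = rng.standard_normal(int(120 * RATE))
        tf = tfm.morlet_tf(x[None, :], RATE)
        energy = np.array([tfm.wavelet_energy(f, fw, RATE)
                           for f, fw in zip(tfm.FREQS, tfm.FWHMS)])
        m = tf.power[0, :, 1000:-1000].mean(axis=1) / energy
        assert m.max() / m.min() < 1.5
        assert abs(np.median(m) - 1.0) < 0.1

    def test_above_nyquist_error(self):
        with pytest.raises(ValueError):
            tfm.morlet_tf(np.zeros((1, 1000)), 60.0)


def _linear_tf_epoch(duration=0.6, pad=0.6):
    rate = RATE
    n = int((duration + 2 * pad) * rate)
    times = np.arange(n) / rate - pad
    power = np.tile(times, (2, 3, 1))   # linear in time, per chan x freq
    return tfm.StepEpoch(power=power, times=times, duration=duration)


class TestGaitResampling:
    def test_linear_tf_linear_in_percentile(self):
        ep = _linear_tf_epoch()
        out = tfm.resample_epoch_to_gait(ep)
        expected = tfm.GAIT_GRID / 100.0 * ep.duration
        np.testing.assert_allclose(out[0, 0], expected, atol=1e-6)

    def test_endpoint_maps_to_step_onset(self):
        ep = _linear_tf_epoch(duration=0.77)
        out = tfm.resample_epoch_to_gait(ep)
        i0 = np.argmin(np.abs(tfm.GAIT_GRID))
        assert out[0, 0, i0] == pytest.approx(0.0, abs=1e-6)

    def test_jittered_durations_preserve_peak(self, rng):
        # power bump always at 50% of the step, durations jittered
        stacks = []
        for _ in range(60):
            d = rng.uniform(0.5, 0.9)
            n = int((d + 1.2) * RATE)
            times = np.arange(n) / RATE - 0.6
            pct = times / d * 100.0
            power = np.exp(-0.5 * ((pct - 50) / 8) ** 2)[None, None, :]
            ep = tfm.StepEpoch(power=power + 0.1, times=times, duration=d)
            stacks.append(tfm.resample_epoch_to_gait(ep))
        mean = np.nanmean(np.stack(stacks), axis=0)[0, 0]
        peak = tfm.GAIT_GRID[np.nanargmax(mean)]
        assert abs(peak - 50.0) <= 2.0


class TestPercentChange:
    def test_constant_power_zero(self):
        stack = np.full((5, 2, 3, 10), 4.0)
        np.testing.assert_allclose(tfm.percent_change(stack), 0.0)

    def test_plus_minus_hundred(self):
        stack = np.zeros((1, 1, 1, 10))
        stack[..., :5] = 2.0
        out = tfm.percent_change(stack)
        np.testing.assert_allclose(out[..., :5], 100.0)
        np.testing.assert_allclose(out[..., 5:], -100.0)

    def test_mean_zero_by_construction(self, rng):
        stack = rng.uniform(1, 5, size=(7, 3, 4, 20))
        out = tfm.percent_change(stack)
        np.testing.assert_allclose(out.mean(axis=(0, 3)), 0.0, atol=1e-9)

    def test_zero_baseline_error(self):
        with pytest.raises(ValueError):
            tfm.percent_change(np.zeros((2, 1, 1, 4)))


class TestSaccadeLocked:
    def test_quartile_assignment(self):
        assert tfm.assign_quartile(np.array([10.0]))[0] == 0
        assert tfm.assign_quartile(np.array([60.0]))[0] == 2
        assert tfm.assign_quartile(np.array([99.9]))[0] == 3

    def _tf(self, n=9000):
        rng = np.random.default_rng(4)
        power = rng.uniform(1, 2, size=(2, 3, n))
        return tfm.TFRepresentation(power, np.array([5.0, 10.0, 15.0]),
                                    np.full(3, 0.3), RATE, ["a", "b"])

    def test_pools(self):
        tf = self._tf()
        onsets = [5.0, 8.0, 11.0, 14.0, 17.0, 20.0]
        pcts = [10.0, 60.0, 30.0, 80.0, 55.0, 5.0]
        locked, omitted = tfm.saccade_locked(tf, onsets, pcts)
        assert omitted == 0
        assert np.array_equal(locked.quartile, [0, 2, 1, 3, 2, 0])
        stance = locked.pool("stance")
        swing = locked.pool("swing")
        assert stance.shape == swing.shape

    def test_unassigned_omitted(self):
        tf = self._tf()
        locked, omitted = tfm.saccade_locked(tf, [5.0, 8.0, 11.0],
                                             [np.nan, 20.0, 70.0])
        assert omitted == 1
        assert len(locked.quartile) == 2

    def test_edge_epochs_omitted(self):
        tf = self._tf()
        _, omitted = tfm.saccade_locked(tf, [0.1, 10.0], [10.0, 10.0])
        assert omitted == 1

    def test_baseline_mean_zero(self):
        tf = self._tf()
        locked, _ = tfm.saccade_locked(tf, [5.0, 8.0, 11.0],
                                       [10.0, 40.0, 90.0])
        np.testing.assert_allclose(locked.values.mean(axis=(0, 3)), 0.0,
                                   atol=1e-4)

    def test_gait_contrast_sign(self):
        # inject higher power at stance-phase saccades; pools must reflect it
        rng = np.random.default_rng(6)
        power = np.ones((1, 2, 30000)) + rng.uniform(0, 0.01, (1, 2, 30000))
        onsets = 2.0 + np.arange(40) * 2.2
        pcts = np.tile([10.0, 60.0], 20)
        for t, p in zip(onsets, pcts):
            if p < 25:
                i = int(t * RATE)
                power[:, :, i - 150:i + 300] *= 2.0
        tf = tfm.TFRepresentation(power, np.array([5.0, 10.0]),
                                  np.full(2, 0.3), RATE, ["a"])
        locked, _ = tfm.saccade_locked(tf, onsets, pcts)
        assert locked.pool("stance").mean() > locked.pool("swing").mean()
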