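import numpy as np
import pytest

from stridelock.io import GazeHeadRecording
from stridelock.saccades import (BlinkInterval, SaccadeDetectionParams,
                                 compute_smoothed_velocity, detect_blinks,
                                 detect_saccades, detect_saccades_in_recording,
                                 estimate_thresholds, gaze_to_angles,
                                 interpolate_blinks)


def _recording(n=900, rate=90.0):
    time = np.arange(n) / rate
    return GazeHeadRecording(
        time=time,
        head_pos=np.tile([0.0, 1.7, 0.0], (n, 1)),
        gaze_origin=np.tile([0.0, 1.65, 0.08], (n, 1)),
        gaze_dir=np.tile([0.0, 0.0, 1.0], (n, 1)),
        trial_id=np.zeros(n, int),
        rate=rate,
    )


class TestBlinks:
    def test_constant_streams_no_blinks(self):
        assert detect_blinks(_recording()) == []

    def test_single_frame_jump_one_interval(self):
        rec = _recording()
        rec.gaze_origin = rec.gaze_origin.copy()
        rec.gaze_origin[400, 1] += 1.0
        ivs = detect_blinks(rec)
        assert len(ivs) == 1
        assert ivs[0].start <= rec.time[400] <= ivs[0].end

    def test_three_dropouts_three_intervals(self):
        rec = _recording(n=2700)
        rec.gaze_origin = rec.gaze_origin.copy()
        spans = [(400, 410), (600, 620), (900, 925)]   # >= 150 ms apart
        for a, b in spans:
            rec.gaze_origin[a:b, 1] += 1.2
        ivs = detect_blinks(rec)
        assert len(ivs) == 3
        for iv, (a, b) in zip(ivs, spans):
            assert iv.start <= rec.time[a]
            assert iv.end >= rec.time[b - 1]
            assert iv.interp_start == pytest.approx(iv.start - 0.1)
            assert iv.interp_end == pytest.approx(iv.end + 0.1)

    def test_empty_recording_error(self):
        rec = _recording(n=0)
        with pytest.raises(ValueError):
            detect_blinks(rec)


class TestInterpolation:
    def test_linear_ramp_exact(self):
        rec = _recording()
        ramp = np.linspace(0, 1, rec.n_samples)
        rec.gaze_origin = rec.gaze_origin + ramp[:, None]
        expected = rec.gaze_origin.copy()
        out = interpolate_blinks(rec, [BlinkInterval(4.0, 4.2)])
        np.testing.assert_allclose(out.gaze_origin, expected, atol=1e-12)

    def test_constant_unchanged(self):
        rec = _recording()
        out = interpolate_blinks(rec, [BlinkInterval(2.0, 2.0)])
        np.testing.assert_allclose(out.gaze_origin, rec.gaze_origin)
        np.testing.assert_allclose(out.gaze_dir, rec.gaze_dir)

    def test_sinusoid_chord(self):
        rec = _recording()
        t = rec.time
        rec.gaze_origin = rec.gaze_origin.copy()
        rec.gaze_origin[:, 0] = np.sin(2 * np.pi * 1.0 * t)
        iv = BlinkInterval(5.0, 5.2)
        out = interpolate_blinks(rec, [iv])
        inside = (t >= iv.interp_start) & (t <= iv.interp_end)
        i0 = np.nonzero(inside)[0][0] - 1
        i1 = np.nonzero(inside)[0][-1] + 1
        chord = np.interp(t[inside], [t[i0], t[i1]],
                          [rec.gaze_origin[i0, 0], rec.gaze_origin[i1, 0]])
        np.testing.assert_allclose(out.gaze_origin[inside, 0], chord,
                                   atol=1e-12)

    def test_edge_interval_clamped_with_warning(self):
        rec = _recording()
        with pytest.warns(UserWarning, match="clamped"):
            interpolate_blinks(rec, [BlinkInterval(0.0, 0.05)])


class TestAngles:
    def test_straight_ahead(self):
        out = gaze_to_angles(np.array([[0.0, 0.0, 1.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.0]], atol=1e-12)

    def test_five_degrees_azimuth(self):
        d = np.array([[np.sin(np.radians(5)), 0.0, np.cos(np.radians(5))]])
        np.testing.assert_allclose(gaze_to_angles(d), [[5.0, 0.0]],
                                   atol=1e-10)

    def test_round_trip_random_vectors(self, rng):
        v = rng.normal(size=(500, 3))
        v[:, 2] = np.abs(v[:, 2]) + 0.5   # keep in the forward hemisphere
        v /= np.linalg.norm(v, axis=1)[:, None]
        ang = np.radians(gaze_to_angles(v))
        back = np.column_stack([np.cos(ang[:, 1]) * np.sin(ang[:, 0]),
                                np.sin(ang[:, 1]),
                                np.cos(ang[:, 1]) * np.cos(ang[:, 0])])
        np.testing.assert_allclose(back, v, atol=1e-9)

    def test_zero_norm_error(self):
        with pytest.raises(ValueError):
            gaze_to_angles(np.zeros((3, 3)))


class TestVelocity:
    def test_linear_ramp(self):
        t = np.arange(200) / 90.0
        angles = np.column_stack([10.0 * t, np.zeros_like(t)])
        v = compute_smoothed_velocity(angles, 90.0)
        np.testing.assert_allclose(v[3:, 0], 10.0, atol=1e-9)
        np.testing.assert_allclose(v[:, 1], 0.0, atol=1e-12)

    def test_constant_angles(self):
        v = compute_smoothed_velocity(np.ones((100, 2)), 90.0)
        np.testing.assert_allclose(v, 0.0)

    def test_white_noise_variance_reduction(self, rng):
        # oracle: the mean of 5 consecutive first differences telescopes to
        # (x[k+2] − x[k−3])/5, so interior variance is raw variance / 25
        # (the naive /5 would hold only for independent velocity samples)
        x = rng.normal(size=(100_000, 2))
        raw = np.diff(x, axis=0) * 90.0
        v = compute_smoothed_velocity(x, 90.0)
        interior = v[10:-10]
        assert interior.var() == pytest.approx(raw.var() / 25, rel=0.05)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            compute_smoothed_velocity(np.ones((50, 2)), 90.0, window=4)


class TestThresholds:
    def test_closed_form(self):
        v = np.tile([-1.0, 0.0, 1.0], 30)
        vel = np.column_stack([v, v])
        ex, ey = estimate_thresholds(vel)
        assert ex == pytest.approx(6.0)
        assert ey == pytest.approx(6.0)

    def test_scale_homogeneity(self, rng):
        vel = rng.normal(size=(1000, 2))
        e1 = estimate_thresholds(vel)
        e2 = estimate_thresholds(vel * 3.5)
        np.testing.assert_allclose(np.array(e2), 3.5 * np.array(e1))

    def test_gaussian_monte_carlo(self, rng):
        # oracle: for N(0,1), median(v²) = median(χ²₁) = 0.4549², median(v)=0,
        # so σ_median -> 0.6745 and η -> 6·0.6745 = 4.047
        vel = rng.normal(size=(100_000, 2))
        ex, ey = estimate_thresholds(vel)
        assert ex == pytest.approx(6 * 0.67449, rel=0.02)
        assert ey == pytest.approx(6 * 0.67449, rel=0.02)

    def test_degenerate_axis_error(self):
        vel = np.column_stack([np.zeros(100), np.random.default_rng(0)
                               .normal(size=100)])
        with pytest.raises(ValueError, match="axis 0"):
            estimate_thresholds(vel, trial=7)


class TestDetection:
    def _detect(self, vel, thr=(1.0, 1.0), **kw):
        n = len(vel)
        time = np.arange(n) / 90.0
        angles = np.zeros((n, 2))
        return detect_saccades(vel, thr, time, angles, trial_id=0, rate=90.0,
                               **kw)

    def test_single_sample_rejected(self):
        vel = np.zeros((100, 2))
        vel[50, 0] = 10.0
        assert self._detect(vel) == []

    def test_three_sample_event_onset(self):
        vel = np.zeros((100, 2))
        vel[40:43, 0] = 10.0
        events = self._detect(vel)
        assert len(events) == 1
        assert events[0].onset == pytest.approx(40 / 90.0)
        assert events[0].duration == pytest.approx(3 / 90.0)

    def test_all_zero_velocity(self):
        assert self._detect(np.zeros((100, 2))) == []

    def test_elliptic_combination(self):
        # each axis at 0.8 of its threshold -> combined 1.28 > 1
        vel = np.zeros((100, 2))
        vel[30:33] = 0.8
        events = self._detect(vel)
        assert len(events) == 1

    def test_blink_adjacent_discarded(self):
        vel = np.zeros((100, 2))
        vel[40:43, 0] = 10.0
        events = self._detect(
            vel, blink_intervals=[BlinkInterval(40 / 90 - 0.12, 40 / 90)])
        assert events == []


class TestEndToEnd:
    def test_fidelity_against_truth(self, gaze_session):
        rec, truth, sacc = gaze_session
        det = detect_saccades_in_recording(rec)
        d = np.sort(det["onset_s"].to_numpy())
        t = np.sort(sacc["onset"].to_numpy())
        tol = 1.0 / rec.rate + 1e-9
        used = set()
        hits = 0
        for x in t:
            c = np.abs(d - x)
            i = int(np.argmin(c))
            if c[i] <= tol and i not in used:
                used.add(i)
                hits += 1
        assert hits / len(t) >= 0.95       # recall, onsets within ±1 sample
        assert hits / len(d) >= 0.95       # precision

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        n = 1800
        angles = rng.normal(0, 0.05, size=(n, 2))
        angles[500:504] += np.cumsum(np.ones((4, 2)), axis=0)
        angles[504:] += 4.0

        def events_for(a):
            vel = compute_smoothed_velocity(a, 90.0)
            thr = estimate_thresholds(vel)
            return detect_saccades(vel, thr, np.arange(n) / 90.0, a, 0)

        e1 = events_for(angles)
        e2 = events_for(angles * 7.0)
        assert [e.onset for e in e1] == [e.onset for e in e2]
        assert any(abs(e.onset - 500 / 90.0) <= 2 / 90.0 for e in e1)

    def test_false_alarm_bound_on_fixation_noise(self):
        rng = np.random.default_rng(8)
        n = 90 * 60    # one minute of pure fixation noise
        rec = _recording(n)
        az = rng.normal(0, 0.05, n)
        el = rng.normal(0, 0.05, n)
        rec.gaze_dir = np.column_stack(
            [np.cos(np.radians(el)) * np.sin(np.radians(az)),
             np.sin(np.radians(el)),
             np.cos(np.radians(el)) * np.cos(np.radians(az))])
        det = detect_saccades_in_recording(rec)
        assert len(det) <= 6   # <= 1 event per 10 s

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SaccadeDetectionParams(smooth_window=4)
        with pytest.raises(ValueError):
            SaccadeDetectionParams(min_samples=0)
        with pytest.raises(ValueError):
            SaccadeDetectionParams(lambda_mult=0)
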