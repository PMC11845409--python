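"""Blink handling and 2D velocity-threshold saccade detection.

Blinks are frame-to-frame position jumps beyond a criterion (0.8 m) and are
linearly interpolated with a 100-ms margin on both sides.  Gaze directions
are converted to head-frame angles, differentiated, smoothed with a 5-sample
moving average, and saccades are maximal runs of samples outside the per-trial
elliptic threshold (vx/ηx)² + (vy/ηy)² > 1 lasting at least two samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .io import GazeHeadRecording


@dataclass
class SaccadeDetectionParams:
    lambda_mult: float = 6.0
    min_samples: int = 2
    smooth_window: int = 5
    blink_jump: float = 0.8       # m
    blink_margin: float = 0.1     # s, interpolation margin on each side

    def __post_init__(self):
        if self.lambda_mult <= 0:
            raise ValueError("lambda_mult must be > 0")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd")


@dataclass
class BlinkInterval:
    start: float
    end: float
    margin: float = 0.1

    @property
    def interp_start(self) -> float:
        return self.start - self.margin

    @property
    def interp_end(self) -> float:
        return self.end + self.margin


@dataclass
class SaccadeEvent:
    onset: float
    duration: float
    peak_velocity: float        # deg/s
    amplitude: float            # deg
    start_angle: tuple          # (azimuth, elevation) deg
    end_angle: tuple
    trial_id: int


def detect_blinks(rec: GazeHeadRecording, jump: float = 0.8,
                  margin: float = 0.1) -> list[BlinkInterval]:
    """Flag frames whose gaze streams jump more than ``jump`` metres.

    Checked axes: gaze origin x/y/z and the gaze point (origin + direction)
    x/y/z.  Intervals closer than 100 ms are merged.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    point = rec.gaze_origin + rec.gaze_dir
    streams = np.hstack([rec.gaze_origin, point])
    deltas = np.abs(np.diff(streams, axis=0))
    bad_step = np.any(deltas > jump, axis=1)
    # a jump into and out of a displaced span marks both boundary frames
    bad = np.zeros(rec.n_samples, bool)
    bad[:-1] |= bad_step
    bad[1:] |= bad_step
    # sustained displacements: deviation from a rolling median catches the
    # span between the entry and exit jumps (blinks last up to ~300 ms)
    if bad.any():
        win = int(round(0.7 * rec.rate)) | 1
        baseline = median_filter(streams, size=(win, 1), mode="nearest")
        bad |= np.any(np.abs(streams - baseline) > jump, axis=1)
    if not bad.any():
        return []

    idx = np.nonzero(bad)[0]
    gaps = np.nonzero(np.diff(rec.time[idx]) > 0.1)[0]
    starts = np.concatenate([[0], gaps + 1])
    ends = np.concatenate([gaps, [len(idx) - 1]])
    return [BlinkInterval(float(rec.time[idx[s]]), float(rec.time[idx[e]]),
                          margin) for s, e in zip(starts, ends)]


def interpolate_blinks(rec: GazeHeadRecording,
                       intervals: list[BlinkInterval]) -> GazeHeadRecording:
    """Linearly interpolate gaze streams across each blink ± margin.

    All six gaze axes (origin and direction x/y/z) are replaced by the line
    between the window's boundary samples; directions are renormalized.
    Head position is untouched.  Windows clipped by the recording edge are
    clamped with a warning.
    """
    out = rec.copy()
    t = rec.time
    for iv in intervals:
        lo, hi = iv.interp_start, iv.interp_end
        if lo < t[0] or hi > t[-1]:
            warnings.warn("blink window clamped at recording edge")
        i0 = np.searchsorted(t, lo, "left")
        i1 = np.searchsorted(t, hi, "right") - 1
        a = max(i0 - 1, 0)
        b = min(i1 + 1, len(t) - 1)
        span = t[b] - t[a]
        if span <= 0:
            continue
        w = (t[i0:i1 + 1] - t[a]) / span
        for arr in (out.gaze_origin, out.gaze_dir):
            arr[i0:i1 + 1] = arr[a] + np.outer(w, arr[b] - arr[a])
    norms = np.linalg.norm(out.gaze_dir, axis=1)
    norms[norms == 0] = 1.0
    out.gaze_dir = out.gaze_dir / norms[:, None]
    return out


def gaze_to_angles(gaze_dir: np.ndarray) -> np.ndarray:
    """Head-frame gaze angles (azimuth, elevation) in degrees.

    Frame convention: z forward, x right, y up; azimuth = atan2(x, z),
    elevation = atan2(y, hypot(x, z)).
    """
    x, y, z = gaze_dir[:, 0], gaze_dir[:, 1], gaze_dir[:, 2]
    if np.any((x == 0) & (y == 0) & (z == 0)):
        raise ValueError("zero-norm gaze direction")
    az = np.degrees(np.arctan2(x, z))
    el = np.degrees(np.arctan2(y, np.hypot(x, z)))
    return np.column_stack([az, el])


def _shrinking_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available (shrunk) window."""
    h = window // 2
    csum = np.cumsum(np.concatenate([[0.0], x]))
    n = len(x)
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_smoothed_velocity(angles: np.ndarray, rate: float,
                              window: int = 5) -> np.ndarray:
    """First-difference angular velocity (deg/s) smoothed by a moving average."""
    if window % 2 == 0:
        raise ValueError("smooth_window must be odd")
    if len(angles) < window + 1:
        raise ValueError("too few samples for smoothing window")
    vel = np.empty_like(angles, dtype=float)
    vel[1:] = np.diff(angles, axis=0) * rate
    vel[0] = 0.0   # duplicating vel[1] could fabricate a 2-sample run
    return np.column_stack([_shrinking_mean(vel[:, 0], window),
                            _shrinking_mean(vel[:, 1], window)])


def estimate_thresholds(velocity: np.ndarray, lambda_mult: float = 6.0,
                        trial: int | None = None) -> tuple[float, float]:
    """Median-based velocity thresholds η = λ·σ per axis.

    σ = sqrt(median(v²) − median(v)²), the outlier-robust scale of the
    velocity distribution.
    """
    if len(velocity) < 10:
        raise ValueError("need at least 10 velocity samples")
    out = []
    for ax in range(2):
        v = velocity[:, ax]
        var = np.median(v ** 2) - np.median(v) ** 2
        if var <= 0:
            raise ValueError(
                f"degenerate velocity on axis {ax}"
                + (f" in trial {trial}" if trial is not None else ""))
        out.append(lambda_mult * np.sqrt(var))
    return tuple(out)


def detect_saccades(velocity: np.ndarray, thresholds: tuple,
                    time: np.ndarray, angles: np.ndarray,
                    trial_id: int, min_samples: int = 2,
                    blink_intervals: list[BlinkInterval] | None = None,
                    rate: float | None = None,
                    raw_velocity: np.ndarray | None = None,
                    raw_thresholds: tuple | None = None) -> list[SaccadeEvent]:
    """Maximal supra-threshold runs lasting at least ``min_samples`` samples.

    A sample is supra-threshold when (vx/ηx)² + (vy/ηy)² > 1.  Events within
    one sample of a blink interpolation window are discarded.

    The centered moving average spreads saccade energy up to two samples
    beyond the true edges; when ``raw_velocity`` (unsmoothed) and its
    thresholds are supplied, each run's onset and offset are refined to the
    first/last raw-supra-threshold sample inside the run.
    """
    ex, ey = thresholds
    crit = (velocity[:, 0] / ex) ** 2 + (velocity[:, 1] / ey) ** 2 > 1.0
    if not crit.any():
        return []
    rate = rate or 1.0 / np.median(np.diff(time))
    edges = np.diff(crit.astype(int))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if crit[0]:
        starts = np.concatenate([[0], starts])
    if crit[-1]:
        ends = np.concatenate([ends, [len(crit)]])

    raw_crit = None
    if raw_velocity is not None and raw_thresholds is not None:
        rx, ry = raw_thresholds
        raw_crit = (raw_velocity[:, 0] / rx) ** 2 \
            + (raw_velocity[:, 1] / ry) ** 2 > 1.0

    events = []
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        if raw_crit is not None and raw_crit[s:e].any():
            inside = np.nonzero(raw_crit[s:e])[0]
            s, e = s + inside[0], s + inside[-1] + 1
        t_on = float(time[s])
        t_off = float(time[e - 1])
        if blink_intervals and any(
                iv.interp_start - 1.0 / rate <= t_off
                and t_on <= iv.interp_end + 1.0 / rate
                for iv in blink_intervals):
            continue
        speed = np.hypot(velocity[s:e, 0], velocity[s:e, 1])
        a0, a1 = angles[s], angles[min(e, len(angles) - 1)]
        events.append(SaccadeEvent(
            onset=t_on,
            duration=(e - s) / rate,
            peak_velocity=float(speed.max()),
            amplitude=float(np.hypot(*(a1 - a0))),
            start_angle=(float(a0[0]), float(a0[1])),
            end_angle=(float(a1[0]), float(a1[1])),
            trial_id=int(trial_id),
        ))
    return events


def detect_saccades_in_recording(rec: GazeHeadRecording,
                                 params: SaccadeDetectionParams | None = None
                                 ) -> pd.DataFrame:
    """Full per-trial detection chain on one recording.

    Returns a table with one row per saccade: trial, onset_s, duration_s,
    amplitude_deg, peak_vel plus an empty stride_pct column for the gait
    stage to fill.
    """
    params = params or SaccadeDetectionParams()
    blinks = detect_blinks(rec, params.blink_jump, params.blink_margin)
    clean = interpolate_blinks(rec, blinks)
    rows = []
    for trial in np.unique(clean.trial_id):
        sel = clean.trial_id == trial
        angles = gaze_to_angles(clean.gaze_dir[sel])
        vel = compute_smoothed_velocity(angles, clean.rate,
                                        params.smooth_window)
        raw_vel = compute_smoothed_velocity(angles, clean.rate, 1)
        try:
            thr = estimate_thresholds(vel, params.lambda_mult, trial=int(trial))
            raw_thr = estimate_thresholds(raw_vel, params.lambda_mult,
                                          trial=int(trial))
        except ValueError:
            continue
        events = detect_saccades(vel, thr, clean.time[sel], angles,
                                 trial, params.min_samples, blinks, clean.rate,
                                 raw_velocity=raw_vel, raw_thresholds=raw_thr)
        for ev in events:
            rows.append((ev.trial_id, ev.onset, ev.duration, ev.amplitude,
                         ev.peak_velocity))
    df = pd.DataFrame(rows, columns=["trial", "onset_s", "duration_s",
                                     "amplitude_deg", "peak_vel"])
    df["stride_pct"] = np.nan
    return df
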