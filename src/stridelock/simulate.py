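"""Session generator with full ground truth.

Produces head trajectories with a sinusoidal vertical bob (one cosine cycle
per step, trough at footfall), gaze streams whose saccade-onset rate is
modulated at a configurable number of cycles per stride, and EEG whose
band-limited power is modulated by step phase — everything the downstream
stages assume, with the injected parameters recorded for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.interpolate import PchipInterpolator

from .io import (
    Condition, EEGRecording, GazeHeadRecording, RecordingBundle,
    SCALP_CHANNELS, REFERENCE_CHANNELS, write_eeg, write_events, write_tracking,
)

STEP_BOUNDS = (0.4, 1.2)  # s, physiological truncation for step durations

#: walkway length / 5-s stream per condition -> average speed (m/s)
CONDITION_SPEED = {Condition.STATIC: 0.0, Condition.SLOW: 0.7,
                   Condition.NATURAL: 1.4}


@dataclass
class WalkSimParams:
    condition: Condition = Condition.NATURAL
    step_duration_mean: float = 0.61
    step_duration_sd: float = 0.06
    bob_amplitude: float = 0.04       # m, peak-to-trough
    head_height_mean: float = 1.7     # m
    n_trials: int = 100
    trial_duration: float = 5.0       # s
    tracking_rate: float = 90.0       # Hz

    def __post_init__(self):
        self.condition = Condition(self.condition)
        if self.step_duration_mean <= 2.0 / self.tracking_rate:
            raise ValueError("step_duration_mean too short for tracking rate")
        if self.bob_amplitude < 0:
            raise ValueError("bob_amplitude must be >= 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @classmethod
    def for_condition(cls, condition, **kw) -> "WalkSimParams":
        condition = Condition(condition)
        presets = {
            Condition.SLOW: dict(step_duration_mean=0.72, step_duration_sd=0.09,
                                 bob_amplitude=0.03),
            Condition.NATURAL: dict(step_duration_mean=0.61,
                                    step_duration_sd=0.06, bob_amplitude=0.045),
            Condition.STATIC: dict(bob_amplitude=0.0),
        }
        opts = presets[condition] | kw
        return cls(condition=condition, **opts)


@dataclass
class SaccadeSimParams:
    base_rate: float = 1.5            # saccades/s
    modulation_depth: float = 0.3     # m in [0, 1]
    modulation_freq: float = 2.0      # cycles per stride
    modulation_phase: float = 0.0     # rad
    amplitude_mean: float = 3.0       # deg
    amplitude_sd: float = 1.0
    amplitude_min: float = 0.5        # deg, lower clip
    saccade_duration: float = 0.044   # s (4 samples at 90 Hz)
    min_isi: float = 0.0              # s, extra refractory between saccades
    gaze_noise_sd: float = 0.05       # deg RMS per axis
    blink_rate: float = 2.0           # blinks/min

    def __post_init__(self):
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must lie in [0, 1]")
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.modulation_freq <= 0:
            raise ValueError("modulation_freq must be > 0")


@dataclass
class EEGSimParams:
    eeg_rate: float = 300.0
    background: float = 10.0          # 1/f noise RMS, uV
    gait_band: tuple = (8.0, 12.0)    # Hz
    gait_mod_depth: float = 0.5
    gait_mod_phase: float = 0.0       # rad
    osc_amp: float = 5.0              # uV RMS of the band-limited oscillation
    osc_kind: str = "narrowband"      # or "sine" (center-frequency sinusoid)
    saccade_transient_amp: float = 0.0  # uV

    def __post_init__(self):
        lo, hi = self.gait_band
        if not (3.0 <= lo < hi <= 40.0):
            raise ValueError("gait_band must satisfy 3 <= lo < hi <= 40 Hz")
        if not 0 <= self.gait_mod_depth <= 1:
            raise ValueError("gait_mod_depth must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator injected, for oracle comparisons."""

    trial_onsets: np.ndarray
    trial_duration: float
    #: per trial: phase-grid times [virtual pre-trial footfall, f0, f1, …,
    #: one footfall past trial end]; u(grid[i]) = i − 1, so u = 0 at the
    #: first real footfall f0 (trials start mid-step, u(onset) ≈ −0.5)
    footfalls_by_trial: list
    walk_params: dict
    saccades: pd.DataFrame | None = None     # onset, trial, stride_pct, step_pct, amplitude, duration
    blink_intervals: list = field(default_factory=list)
    saccade_params: dict | None = None
    eeg_params: dict | None = None

    @property
    def trough_times(self) -> np.ndarray:
        """All real footfall times inside trials, strictly increasing."""
        out = []
        for onset, ff in zip(self.trial_onsets, self.footfalls_by_trial):
            ff = np.asarray(ff)
            out.append(ff[(ff >= onset) & (ff < onset + self.trial_duration)])
        return np.concatenate(out) if out else np.array([])

    @property
    def stride_windows(self) -> list:
        """(start, mid, end) trough triples per trial, one-step overlap."""
        windows = []
        for onset, ff in zip(self.trial_onsets, self.footfalls_by_trial):
            ff = np.asarray(ff)
            ff = ff[(ff >= onset) & (ff < onset + self.trial_duration)]
            for i in range(len(ff) - 2):
                windows.append((ff[i], ff[i + 1], ff[i + 2]))
        return windows

    def step_count(self, times: np.ndarray) -> np.ndarray:
        """Continuous step count u(t): u(footfall_i) = i within each trial.

        NaN outside trials or where the trial has no gait (static).
        """
        times = np.asarray(times, float)
        u = np.full(times.shape, np.nan)
        for onset, ff in zip(self.trial_onsets, self.footfalls_by_trial):
            ff = np.asarray(ff, float)
            sel = (times >= onset) & (times < onset + self.trial_duration)
            if not sel.any() or len(ff) < 2:
                continue
            u[sel] = np.interp(times[sel], ff, np.arange(len(ff)) - 1.0)
        return u

    def rate_phase(self, times) -> np.ndarray:
        """Stride phase in [0, 100) driving the modulated rates.

        Piecewise linear in the step count u (one stride = two steps,
        strides start on even footfalls).
        """
        return (self.step_count(times) % 2.0) / 2.0 * 100.0

    def stride_pct(self, times) -> np.ndarray:
        """True stride percentile, linear in time across each stride.

        Matches the analysis convention 100·(t − start)/(end − start) for
        strides built from even-parity footfall pairs; NaN outside strides.
        """
        times = np.asarray(times, float)
        pct = np.full(times.shape, np.nan)
        for onset, grid in zip(self.trial_onsets, self.footfalls_by_trial):
            ff = np.asarray(grid, float)[1:]      # real footfalls
            ff = ff[ff < onset + self.trial_duration]
            if len(ff) < 3:
                continue
            sel = (times >= ff[0]) & (times < ff[-1 if len(ff) % 2 else -2])
            if not sel.any():
                continue
            idx = np.searchsorted(ff, times[sel], "right") - 1
            start = idx - (idx % 2)
            ok = start + 2 < len(ff)
            t_ok = times[sel][ok]
            s = start[ok]
            vals = np.full(sel.sum(), np.nan)
            vals[ok] = 100.0 * (t_ok - ff[s]) / (ff[s + 2] - ff[s])
            pct[sel] = vals
        return pct

    def step_pct(self, times) -> np.ndarray:
        return (self.step_count(times) % 1.0) * 100.0

    def to_json(self, path) -> None:
        payload = {
            "trial_onsets": np.asarray(self.trial_onsets).tolist(),
            "trial_duration": self.trial_duration,
            "footfalls_by_trial": [np.asarray(f).tolist()
                                   for f in self.footfalls_by_trial],
            "walk_params": self.walk_params,
            "saccades": (self.saccades.to_dict("list")
                         if self.saccades is not None else None),
            "blink_intervals": [list(map(float, b)) for b in self.blink_intervals],
            "saccade_params": self.saccade_params,
            "eeg_params": self.eeg_params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trial_onsets=np.array(d["trial_onsets"]),
            trial_duration=d["trial_duration"],
            footfalls_by_trial=[np.array(f) for f in d["footfalls_by_trial"]],
            walk_params=d["walk_params"],
            saccades=(pd.DataFrame(d["saccades"])
                      if d["saccades"] is not None else None),
            blink_intervals=[tuple(b) for b in d["blink_intervals"]],
            saccade_params=d["saccade_params"],
            eeg_params=d["eeg_params"],
        )


def _draw_step_durations(rng, mean, sd, total, lo=STEP_BOUNDS[0],
                         hi=STEP_BOUNDS[1]):
    """Draw i.i.d. truncated-normal step durations summing past ``total``."""
    durs = []
    acc = 0.0
    while acc <= total:
        if sd <= 0:
            d = mean
        else:
            a, b = (lo - mean) / sd, (hi - mean) / sd
            d = float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                          random_state=rng))
        durs.append(d)
        acc += d
    return np.array(durs)


def simulate_walk(params: WalkSimParams, seed) -> tuple[GazeHeadRecording, GroundTruth]:
    """Simulate head trajectories for ``n_trials`` back-to-back trials.

    Vertical head position is mean height − (bob/2)·cos(2π·u(t)) with u the
    accumulated step count, so footfalls (integer u) are trajectory troughs.
    """
    rng = np.random.default_rng(seed)
    if params.trial_duration < params.step_duration_mean and \
            params.condition is not Condition.STATIC:
        raise ValueError("trial shorter than one step")
    rate = params.tracking_rate
    n_per_trial = int(round(params.trial_duration * rate))
    n_total = n_per_trial * params.n_trials
    time = np.arange(n_total) / rate
    trial_id = np.repeat(np.arange(params.n_trials), n_per_trial)
    trial_onsets = np.arange(params.n_trials) * params.trial_duration

    head = np.zeros((n_total, 3))
    head[:, 1] = params.head_height_mean
    speed = CONDITION_SPEED[params.condition]
    footfalls_by_trial = []
    walking = params.condition is not Condition.STATIC and params.bob_amplitude >= 0

    for k, onset in enumerate(trial_onsets):
        sl = slice(k * n_per_trial, (k + 1) * n_per_trial)
        # forward position advances continuously (no teleport between
        # trials, which would masquerade as blink-scale jumps)
        head[sl, 2] = speed * time[sl]
        if params.condition is Condition.STATIC:
            footfalls_by_trial.append(np.array([]))
            continue
        durs = _draw_step_durations(rng, params.step_duration_mean,
                                    params.step_duration_sd,
                                    params.trial_duration + STEP_BOUNDS[1])
        # trial starts mid-step: first real footfall half a step in, and a
        # virtual pre-trial footfall anchors the phase grid (u = -1 there)
        f0 = onset + durs[0] / 2
        grid = np.concatenate([[f0 - durs[0], f0],
                               f0 + np.cumsum(durs[1:])])
        footfalls_by_trial.append(grid)
        # monotone cubic phase: footfalls stay exactly at integer u but the
        # trajectory is C1-smooth there, like a real head bob
        u = PchipInterpolator(grid, np.arange(len(grid)) - 1.0)(time[sl])
        head[sl, 1] = params.head_height_mean \
            - 0.5 * params.bob_amplitude * np.cos(2 * np.pi * u)

    truth = GroundTruth(trial_onsets=trial_onsets,
                        trial_duration=params.trial_duration,
                        footfalls_by_trial=footfalls_by_trial,
                        walk_params=_params_dict(params))
    gaze_origin = head + np.array([0.0, -0.05, 0.08])
    gaze_dir = np.tile([0.0, 0.0, 1.0], (n_total, 1))
    rec = GazeHeadRecording(time=time, head_pos=head, gaze_origin=gaze_origin,
                            gaze_dir=gaze_dir, trial_id=trial_id, rate=rate)
    return rec, truth


def _angles_to_dir(az_deg, el_deg):
    az = np.deg2rad(az_deg)
    el = np.deg2rad(el_deg)
    return np.column_stack([np.cos(el) * np.sin(az), np.sin(el),
                            np.cos(el) * np.cos(az)])


def simulate_gaze(rec: GazeHeadRecording, truth: GroundTruth,
                  params: SaccadeSimParams, seed) -> tuple[GazeHeadRecording, pd.DataFrame]:
    """Superpose a gait-modulated saccade train on fixation noise.

    Saccade onsets are Bernoulli-thinned on the tracking grid with rate
    λ(t) = λ0·(1 + m·cos(2π·f·pct(t)/100 + φ0)); the truth table records each
    onset with its true stride percentile.  Returns the updated recording
    (gaze_dir and gaze_origin filled in) and the saccade truth table.
    """
    rng = np.random.default_rng(seed)
    rate = rec.rate
    n = rec.n_samples
    time = rec.time

    phase = truth.rate_phase(time)
    lam = np.full(n, params.base_rate)
    has_phase = ~np.isnan(phase)
    lam[has_phase] *= 1.0 + params.modulation_depth * np.cos(
        2 * np.pi * params.modulation_freq * phase[has_phase] / 100.0
        + params.modulation_phase)
    if np.any(lam < 0):
        raise ValueError("negative instantaneous rate (modulation_depth > 1?)")

    # blink windows first so saccades can avoid them
    total_dur = n / rate
    n_blinks = rng.poisson(params.blink_rate * total_dur / 60.0)
    blink_intervals = []
    blink_mask = np.zeros(n, bool)
    for _ in range(n_blinks):
        dur = rng.uniform(0.1, 0.3)
        start = rng.uniform(0, total_dur - dur)
        i0, i1 = int(start * rate), int((start + dur) * rate)
        blink_intervals.append((i0 / rate, i1 / rate))
        lo = max(0, i0 - int(0.15 * rate))
        hi = min(n, i1 + int(0.15 * rate))
        blink_mask[lo:hi] = True

    p = np.clip(lam / rate, 0, 1)
    hits = rng.random(n) < p
    hits[blink_mask] = False
    d_samp = max(2, int(round(params.saccade_duration * rate)))

    # overlapping displacement profiles superpose, so no refractory is
    # needed for rate conservation; min_isi > 0 thins bursts on request
    refractory = int(round(params.min_isi * rate))
    onsets = []
    last_onset = -10 ** 9
    for i in np.nonzero(hits)[0]:
        if i - last_onset <= refractory or i + d_samp >= n:
            continue
        # keep saccades within one trial
        if rec.trial_id[i] != rec.trial_id[min(i + d_samp, n - 1)]:
            continue
        onsets.append(i)
        last_onset = i

    az = np.zeros(n)
    el = np.zeros(n)
    fix = np.zeros(2)
    # raised-sine velocity -> smooth position profile from 0 to 1
    profile = 0.5 * (1 - np.cos(np.pi * np.arange(1, d_samp + 1) / d_samp))
    rows = []
    for i in onsets:
        amp = max(params.amplitude_min,
                  rng.normal(params.amplitude_mean, params.amplitude_sd))
        if np.hypot(*fix) > 15.0:
            psi = np.arctan2(-fix[1], -fix[0]) + rng.normal(0, 0.3)
        else:
            psi = rng.uniform(0, 2 * np.pi)
        delta = amp * np.array([np.cos(psi), np.sin(psi)])
        az[i:i + d_samp] += delta[0] * profile
        el[i:i + d_samp] += delta[1] * profile
        az[i + d_samp:] += delta[0]
        el[i + d_samp:] += delta[1]
        fix = fix + delta
        t = time[i]
        rows.append((t, int(rec.trial_id[i]), float(truth.stride_pct([t])[0]),
                     float(truth.step_pct([t])[0]), amp, d_samp / rate))

    az += rng.normal(0, params.gaze_noise_sd, n)
    el += rng.normal(0, params.gaze_noise_sd, n)

    out = rec.copy()
    out.gaze_dir = _angles_to_dir(az, el)
    out.gaze_origin = rec.head_pos + np.array([0.0, -0.05, 0.08])
    for b0, b1 in blink_intervals:
        i0, i1 = int(round(b0 * rate)), int(round(b1 * rate))
        out.gaze_origin[i0:i1 + 1, 1] += 1.0   # > 0.8 m criterion

    sacc = pd.DataFrame(rows, columns=["onset", "trial", "stride_pct",
                                       "step_pct", "amplitude", "duration"])
    truth.saccades = sacc
    truth.blink_intervals = blink_intervals
    truth.saccade_params = _params_dict(params)
    return out, sacc


def _pink_noise(rng, n, rms):
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def simulate_eeg(truth: GroundTruth, params: EEGSimParams, seed) -> EEGRecording:
    """Generate EEG whose band-limited power follows the step cycle.

    Each scalp channel is 1/f background plus a band-limited oscillation whose
    instantaneous amplitude is (1 + depth·cos(2π·step_pct/100 + phase)).
    Trial triggers (code 1) are placed at trial onsets.
    """
    rng = np.random.default_rng(seed)
    rate = params.eeg_rate
    total = truth.trial_onsets[-1] + truth.trial_duration
    n = int(round(total * rate))
    time = np.arange(n) / rate

    pct = truth.step_pct(time)
    mod = np.ones(n)
    ok = ~np.isnan(pct)
    mod[ok] += params.gait_mod_depth * np.cos(
        2 * np.pi * pct[ok] / 100.0 + params.gait_mod_phase)

    lo, hi = params.gait_band
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    labels = SCALP_CHANNELS + REFERENCE_CHANNELS
    data = np.zeros((len(labels), n))

    # one shared oscillation source and a shared background component give
    # the inter-channel correlation structure real scalp EEG has
    if params.osc_kind == "sine":
        # osc_amp is the sinusoid amplitude (variance osc_amp²/2)
        osc = np.sin(2 * np.pi * 0.5 * (lo + hi) * time)
    else:
        osc = signal.sosfiltfilt(sos, rng.standard_normal(n))
        osc /= osc.std()
    shared = _pink_noise(rng, n, 1.0) if params.background > 0 else 0.0
    w_shared, w_local = np.sqrt(0.6), np.sqrt(0.4)
    for c in range(len(SCALP_CHANNELS)):
        chan = np.zeros(n)
        if params.background > 0:
            chan += params.background * (
                w_shared * shared + w_local * _pink_noise(rng, n, 1.0))
        if params.osc_amp > 0:
            chan += params.osc_amp * osc * mod
        data[c] = chan

    if params.saccade_transient_amp and truth.saccades is not None:
        width = int(0.05 * rate)
        kernel = signal.windows.gaussian(2 * width + 1, width / 2.5)
        for t in truth.saccades["onset"]:
            i = int(round(t * rate))
            j0, j1 = max(0, i - width), min(n, i + width + 1)
            k0 = j0 - (i - width)
            data[:len(SCALP_CHANNELS), j0:j1] += \
                params.saccade_transient_amp * kernel[k0:k0 + (j1 - j0)]

    for ref in REFERENCE_CHANNELS:
        data[labels.index(ref)] = rng.normal(0, 1.0, n)

    triggers = [(float(t), 1) for t in truth.trial_onsets]
    truth.eeg_params = _params_dict(params)
    return EEGRecording(labels=list(labels), data=data, rate=rate,
                        triggers=triggers)


def _params_dict(params) -> dict:
    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, Condition):
            d[k] = v.value
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def simulate_session(out_dir, participant_id: str, condition,
                     walk: WalkSimParams | None = None,
                     saccade: SaccadeSimParams | None = None,
                     eeg: EEGSimParams | None = None,
                     seed=0) -> tuple[RecordingBundle, GroundTruth]:
    """Write one participant x condition session to ``out_dir``.

    Produces ``tracking.tsv``, ``eeg.edf``, ``events.tsv`` and
    ``truth.json``; identical seeds produce identical files.
    """
    condition = Condition(condition)
    walk = walk or WalkSimParams.for_condition(condition)
    saccade = saccade or SaccadeSimParams()
    eeg = eeg or EEGSimParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed).spawn(3)
    rec, truth = simulate_walk(walk, ss[0])
    rec, _ = simulate_gaze(rec, truth, saccade, ss[1])
    eeg_rec = simulate_eeg(truth, eeg, ss[2])

    prefix = f"{participant_id}_{condition.value}"
    tracking_path = out_dir / f"{prefix}_tracking.tsv"
    eeg_path = out_dir / f"{prefix}_eeg.edf"
    events_path = out_dir / f"{prefix}_events.tsv"
    write_tracking(tracking_path, rec)
    write_eeg(eeg_path, eeg_rec)

    rows = []
    for k, onset in enumerate(truth.trial_onsets):
        rows.append((onset, truth.trial_duration, "trial", k))
        for j in range(25):
            rows.append((onset + 0.2 * j, 0.1, "image", k))
    write_events(events_path, pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "trial_id"]))
    truth.to_json(out_dir / f"{prefix}_truth.json")

    bundle = RecordingBundle(tracking_path=tracking_path, eeg_path=eeg_path,
                             events_path=events_path,
                             participant_id=participant_id,
                             condition=condition,
                             tracking_rate=walk.tracking_rate,
                             eeg_rate=eeg.eeg_rate)
    return bundle, truth
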