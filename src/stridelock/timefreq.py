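"""EEG preprocessing, epoching, Morlet time-frequency and gait resampling.

Preprocessing re-references to the earlobe average and band-passes 0.1-40 Hz.
Power comes from convolution with complex Morlet wavelets (50 linear center
frequencies 3-40 Hz, time-domain FWHM shrinking linearly from 600 ms to
100 ms).  Step epochs are mapped onto a -30%…+130% step-cycle grid and
normalized to percent change about the full-epoch baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EEGRecording, REFERENCE_CHANNELS

N_FREQS = 50
FREQS = np.linspace(3.0, 40.0, N_FREQS)
FWHMS = np.linspace(0.6, 0.1, N_FREQS)            # s, linear over the grid
GAIT_GRID = np.arange(-30.0, 130.5, 0.5)          # % step cycle, 321 points

QUARTILE_EDGES = (0.0, 25.0, 50.0, 75.0, 100.0)
STANCE_QUARTILES = (0, 3)
SWING_QUARTILES = (1, 2)


@dataclass
class TFRepresentation:
    power: np.ndarray          # channels x freqs x time
    freqs: np.ndarray
    fwhms: np.ndarray
    rate: float
    labels: list


@dataclass
class StepEpoch:
    power: np.ndarray          # channels x freqs x time (variable length)
    times: np.ndarray          # s, relative to step onset
    duration: float            # step duration, s
    sd: float = np.nan
    rejected: bool = False
    reason: str = ""


@dataclass
class NormalizedGaitTF:
    values: np.ndarray         # channels x freqs x gait grid, percent change
    grid: np.ndarray
    freqs: np.ndarray
    labels: list
    n_epochs: int


@dataclass
class SaccadeLockedTF:
    values: np.ndarray         # epochs x channels x freqs x time, pct change
    times: np.ndarray
    quartile: np.ndarray       # per-epoch quartile index 0-3
    freqs: np.ndarray
    labels: list

    def pool(self, which: str) -> np.ndarray:
        """Mean map over the stance (Q1∪Q4) or swing (Q2∪Q3) pool."""
        quartiles = STANCE_QUARTILES if which == "stance" else SWING_QUARTILES
        mask = np.isin(self.quartile, quartiles)
        return self.values[mask].mean(axis=0)


def preprocess(rec: EEGRecording, l_freq: float = 0.1, h_freq: float = 40.0,
               deviation_z: float = 5.0, correlation_r: float = 0.4,
               correlation_frac: float = 0.01) -> EEGRecording:
    """Re-reference to mean(A1, A2), band-pass, and flag bad channels.

    Bad channels: robust amplitude z-score above ``deviation_z`` (deviation
    criterion), or best inter-channel correlation below ``correlation_r`` in
    more than ``correlation_frac`` of 1-s windows (correlation criterion).
    Flagged channels are dropped.
    """
    for ch in REFERENCE_CHANNELS:
        if ch not in rec.labels:
            raise ValueError(f"reference channel {ch} missing")
    ref = 0.5 * (rec.channel("A1") + rec.channel("A2"))
    scalp = [l for l in rec.labels if l not in REFERENCE_CHANNELS]
    idx = [rec.labels.index(l) for l in scalp]
    data = rec.data[idx] - ref

    if l_freq is not None:
        # 6th order, zero-phase: >20 dB two-pass attenuation one octave-
        # fraction past the 40-Hz edge (a 4th-order design falls short)
        sos = signal.butter(6, [l_freq, h_freq], btype="bandpass",
                            fs=rec.rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=1)

    bad = set()
    # deviation: robust z of the per-channel robust amplitude
    amp = np.median(np.abs(data - np.median(data, axis=1, keepdims=True)),
                    axis=1)
    med, mad = np.median(amp), np.median(np.abs(amp - np.median(amp)))
    if mad > 0:
        z = (amp - med) / (1.4826 * mad)
        bad |= {scalp[i] for i in np.nonzero(np.abs(z) > deviation_z)[0]}
    # correlation: windowed best correlation with any other channel
    win = int(rec.rate)
    n_win = data.shape[1] // win
    if n_win >= 2 and len(scalp) >= 2:
        low_counts = np.zeros(len(scalp))
        for w in range(n_win):
            seg = data[:, w * win:(w + 1) * win]
            sd = seg.std(axis=1)
            ok = sd > 0
            cc = np.corrcoef(seg[ok]) if ok.sum() >= 2 else None
            best = np.full(len(scalp), 1.0)
            if cc is not None:
                np.fill_diagonal(cc, -1)
                best[ok] = cc.max(axis=1)
            best[~ok] = 0.0
            low_counts += best < correlation_r
        frac = low_counts / n_win
        bad |= {scalp[i] for i in np.nonzero(frac > correlation_frac)[0]}

    if len(bad) > len(scalp) / 2:
        raise RuntimeError(f"more than half the channels are bad: {sorted(bad)}")
    keep = [i for i, l in enumerate(scalp) if l not in bad]
    return EEGRecording([scalp[i] for i in keep], data[keep], rec.rate,
                        list(rec.triggers), sorted(bad))


def epoch_trials(rec: EEGRecording, onsets, tmin: float = -0.1,
                 tmax: float = 6.5) -> tuple[np.ndarray, np.ndarray, int]:
    """Fixed-window trial epochs, baseline-corrected to the pre-onset period.

    Returns (epochs, times, n_dropped); out-of-bounds epochs are dropped.
    """
    n_lo = int(round(tmin * rec.rate))
    n_hi = int(round(tmax * rec.rate))
    times = np.arange(n_lo, n_hi) / rec.rate
    epochs = []
    dropped = 0
    for onset in onsets:
        i = int(round(onset * rec.rate))
        if i + n_lo < 0 or i + n_hi > rec.n_samples:
            dropped += 1
            continue
        ep = rec.data[:, i + n_lo:i + n_hi].copy()
        base = ep[:, times < 0].mean(axis=1, keepdims=True)
        epochs.append(ep - base)
    return (np.array(epochs) if epochs else
            np.empty((0, rec.data.shape[0], len(times)))), times, dropped


def morlet_wavelet(freq: float, fwhm: float, rate: float) -> np.ndarray:
    """Complex Morlet wavelet with unit passband gain.

    Gaussian envelope with time-domain FWHM ``fwhm``; the wavelet is divided
    by the envelope sum so a unit sinusoid at ``freq`` yields a response of
    magnitude 1/2 regardless of frequency.
    """
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    half = int(np.ceil(4 * sigma * rate))
    t = np.arange(-half, half + 1) / rate
    env = np.exp(-t ** 2 / (2 * sigma ** 2))
    return env * np.exp(2j * np.pi * freq * t) / env.sum()


def wavelet_energy(freq: float, fwhm: float, rate: float) -> float:
    w = morlet_wavelet(freq, fwhm, rate)
    return float(np.sum(np.abs(w) ** 2))


def morlet_tf(data: np.ndarray, rate: float, freqs: np.ndarray = FREQS,
              fwhms: np.ndarray = FWHMS, labels=None) -> TFRepresentation:
    """Time-frequency power of continuous data (channels x time)."""
    data = np.atleast_2d(data)
    if np.max(freqs) >= rate / 2:
        raise ValueError("requested frequency at or above Nyquist")
    nchan, ntime = data.shape
    power = np.empty((nchan, len(freqs), ntime), dtype=np.float32)
    for j, (f, fw) in enumerate(zip(freqs, fwhms)):
        w = morlet_wavelet(f, fw, rate)
        conv = signal.fftconvolve(data, w[None, :], mode="same", axes=1)
        power[:, j, :] = np.abs(conv) ** 2
    return TFRepresentation(power, np.asarray(freqs), np.asarray(fwhms),
                            rate, labels or [f"ch{i}" for i in range(nchan)])


def epoch_steps(tf: TFRepresentation, step_onsets, step_ends,
                pad: float = 0.6, raw: np.ndarray | None = None
                ) -> list[StepEpoch]:
    """Cut step epochs (onset − pad … completion + pad) out of continuous TF.

    Epoch SD (for outlier rejection) is computed over channels x time of the
    broadband signal if ``raw`` is given, else of the TF power.
    """
    rate = tf.rate
    ntime = tf.power.shape[2]
    epochs = []
    for t0, t1 in zip(step_onsets, step_ends):
        i0 = int(round((t0 - pad) * rate))
        i1 = int(round((t1 + pad) * rate))
        if i0 < 0 or i1 > ntime:
            continue
        sl = slice(i0, i1)
        src = raw[:, sl] if raw is not None else tf.power[:, :, sl]
        epochs.append(StepEpoch(
            power=tf.power[:, :, sl],
            times=np.arange(i0, i1) / rate - t0,
            duration=t1 - t0,
            sd=float(np.std(src)),
        ))
    return epochs


def reject_outlier_epochs(epochs: list[StepEpoch]) -> list[StepEpoch]:
    """Flag epochs whose SD falls outside Q1 − 1.5·IQR … Q3 + 1.5·IQR."""
    if len(epochs) < 10:
        warnings.warn("fewer than 10 epochs: quartiles unstable")
    sds = np.array([e.sd for e in epochs])
    q1, q3 = np.percentile(sds, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    for e in epochs:
        if e.sd > hi or e.sd < lo:
            e.rejected = True
            e.reason = "sd outlier"
    return epochs


def resample_epoch_to_gait(epoch: StepEpoch,
                           grid: np.ndarray = GAIT_GRID) -> np.ndarray:
    """Map one step epoch's TF power onto the step-cycle percentage grid.

    Step onset maps to 0%, completion to 100%; buffer points come from the
    surrounding pads.  Grid points outside the epoch are NaN.
    """
    rate = 1.0 / (epoch.times[1] - epoch.times[0])
    targets = grid / 100.0 * epoch.duration          # s relative to onset
    pos = (targets - epoch.times[0]) * rate
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    valid = (i0 >= 0) & (i0 < len(epoch.times) - 1)
    i0c = np.clip(i0, 0, len(epoch.times) - 2)
    P = epoch.power
    out = P[:, :, i0c] * (1 - frac) + P[:, :, i0c + 1] * frac
    out[:, :, ~valid] = np.nan
    return out


def percent_change(stack: np.ndarray) -> np.ndarray:
    """Percent change about the grand baseline per channel x frequency.

    ``stack`` is (epochs, channels, freqs, grid); the baseline is the mean
    over epochs and the full grid.  NaNs (missing buffer samples) are
    ignored and propagated.
    """
    base = np.nanmean(stack, axis=(0, 3), keepdims=True)
    if np.any(base <= 0):
        raise ValueError("non-positive baseline power")
    return 100.0 * (stack - base) / base


def gait_tf(tf: TFRepresentation, step_onsets, step_ends,
            grid: np.ndarray = GAIT_GRID, pad: float = 0.6,
            raw: np.ndarray | None = None) -> NormalizedGaitTF:
    """Full chain: step epochs → outlier rejection → gait grid → % change."""
    epochs = reject_outlier_epochs(
        epoch_steps(tf, step_onsets, step_ends, pad, raw))
    kept = [e for e in epochs if not e.rejected]
    if not kept:
        raise ValueError("no step epochs retained")
    stack = np.stack([resample_epoch_to_gait(e, grid) for e in kept])
    normed = percent_change(stack)
    return NormalizedGaitTF(np.nanmean(normed, axis=0), grid, tf.freqs,
                            tf.labels, len(kept))


def assign_quartile(step_pct: np.ndarray) -> np.ndarray:
    """Quartile index 0-3 of the step-cycle percentile [0, 100)."""
    return np.minimum((np.asarray(step_pct) // 25).astype(int), 3)


def saccade_locked(tf: TFRepresentation, saccade_onsets, step_pcts,
                   trial_bounds=None, tmin: float = -0.6, tmax: float = 1.1
                   ) -> tuple[SaccadeLockedTF, int]:
    """Saccade-locked TF epochs labelled by gait quartile.

    Saccades without a phase assignment, or whose epoch crosses the trial or
    recording bounds, are omitted (count returned).  Percent-change
    normalization uses the all-saccade average as baseline.
    """
    rate = tf.rate
    n_lo, n_hi = int(round(tmin * rate)), int(round(tmax * rate))
    times = np.arange(n_lo, n_hi) / rate
    epochs, quartiles = [], []
    omitted = 0
    for onset, pct in zip(saccade_onsets, step_pcts):
        if pct is None or np.isnan(pct):
            omitted += 1
            continue
        if trial_bounds is not None:
            t0, t1 = trial_bounds(onset)
            if onset + tmin < t0 or onset + tmax > t1:
                omitted += 1
                continue
        i = int(round(onset * rate))
        if i + n_lo < 0 or i + n_hi > tf.power.shape[2]:
            omitted += 1
            continue
        epochs.append(tf.power[:, :, i + n_lo:i + n_hi])
        quartiles.append(assign_quartile(pct))
    if not epochs:
        raise ValueError("no saccade epochs retained")
    stack = np.stack(epochs)
    base = stack.mean(axis=(0, 3), keepdims=True)   # all-saccade baseline
    normed = 100.0 * (stack - base) / base
    return SaccadeLockedTF(normed, times, np.array(quartiles), tf.freqs,
                           tf.labels), omitted
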