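"""Step/stride phase extraction from vertical head position.

Troughs of the (low-passed, detrended) vertical head trajectory mark
footfalls; consecutive trough triples define strides, and any event time can
be mapped to a stride-completion percentile in [0, 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class TroughParams:
    lowpass_hz: float = 6.0
    min_separation: float = 0.35      # s
    prominence_frac: float = 0.25     # of median peak-to-trough amplitude
    duration_bounds: tuple = (0.4, 1.2)
    min_amplitude: float = 0.005      # m; below this the trial has no gait


@dataclass
class StepTable:
    trough_times: np.ndarray
    step_durations: np.ndarray        # diff of troughs
    trial_id: int
    usable: bool = True
    flags: list = field(default_factory=list)
    bad_steps: np.ndarray = None      # bool per step, duration out of bounds

    @property
    def n_steps(self) -> int:
        return len(self.step_durations)


@dataclass
class Stride:
    start: float
    mid: float
    end: float

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def percentile(self, t: float) -> float:
        return 100.0 * (t - self.start) / (self.end - self.start)


@dataclass
class PhaseAssignment:
    event_time: float
    stride_index: int
    percentile: float         # [0, 100) of the stride
    percentile_step: float    # [0, 100) of the containing step


def detect_troughs(time: np.ndarray, head_z: np.ndarray, rate: float,
                   params: TroughParams | None = None,
                   trial_id: int = 0) -> StepTable:
    """Locate footfalls as prominent local minima of vertical head position.

    The trace is zero-phase low-passed at 6 Hz and linearly detrended; minima
    must be separated by at least 0.35 s and have prominence at least 25% of
    the trial's median peak-to-trough amplitude.
    """
    params = params or TroughParams()
    if time[-1] - time[0] < 1.0:
        raise ValueError("trial shorter than 1 s")
    sos = signal.butter(4, params.lowpass_hz, btype="low", fs=rate,
                        output="sos")
    z = signal.sosfiltfilt(sos, head_z)
    z = signal.detrend(z)

    if np.ptp(z) < params.min_amplitude:
        return StepTable(np.array([]), np.array([]), trial_id, usable=False,
                         flags=["no gait amplitude"],
                         bad_steps=np.array([], bool))

    dist = max(1, int(round(params.min_separation * rate)))
    # amplitude scale from well-separated interior minima
    cand0, _ = signal.find_peaks(-z, distance=dist)
    if len(cand0) == 0:
        return StepTable(np.array([]), np.array([]), trial_id, usable=False,
                         flags=["no troughs"], bad_steps=np.array([], bool))
    med_p2p = np.median(signal.peak_prominences(-z, cand0)[0])

    # candidates on a reflect-padded trace so edge troughs keep a flank;
    # separation is enforced afterwards (most prominent first) because
    # mirror copies would otherwise shadow true minima near the edges
    pad = int(round(0.5 * rate))
    # odd (antisymmetric) reflection continues the boundary trend, so a
    # trough right before the trial edge keeps its full prominence
    left = 2 * z[0] - z[pad:0:-1]
    right = 2 * z[-1] - z[-2:-pad - 2:-1]
    zp = np.concatenate([left, z, right])
    cand, _ = signal.find_peaks(-zp)
    prom = signal.peak_prominences(-zp, cand)[0]
    sel = prom >= params.prominence_frac * med_p2p
    cand, prom = cand[sel] - pad, prom[sel]
    sel = (cand >= 0) & (cand < len(z))
    cand, prom = cand[sel], prom[sel]
    chosen: list[int] = []
    for i in np.argsort(-prom):
        if all(abs(cand[i] - j) >= dist for j in chosen):
            chosen.append(int(cand[i]))
    keep = np.sort(chosen)
    if len(keep) == 0:
        return StepTable(np.array([]), np.array([]), trial_id, usable=False,
                         flags=["no troughs"], bad_steps=np.array([], bool))
    # sub-sample refinement: parabola vertex over a ±100-ms window
    half = max(2, int(round(0.1 * rate)))
    trough_times = np.empty(len(keep))
    for j, i in enumerate(keep):
        lo, hi = max(0, i - half), min(len(z), i + half + 1)
        tv = time[i]
        if hi - lo >= 5:
            c = np.polyfit(time[lo:hi] - time[i], z[lo:hi], 2)
            if c[0] > 0 and abs(c[1] / (2 * c[0])) <= 0.05:
                tv = time[i] - c[1] / (2 * c[0])
        trough_times[j] = tv

    if len(trough_times) < 2:
        return StepTable(trough_times, np.array([]), trial_id, usable=False,
                         flags=["fewer than 2 troughs"],
                         bad_steps=np.array([], bool))
    durations = np.diff(trough_times)
    lo, hi = params.duration_bounds
    bad = (durations < lo) | (durations > hi)
    flags = ["steps out of duration bounds"] if bad.any() else []
    return StepTable(trough_times, durations, trial_id, usable=True,
                     flags=flags, bad_steps=bad)


def build_strides(steps: StepTable, convention: str = "one-step-overlap"
                  ) -> list[Stride]:
    """Combine consecutive trough triples into strides.

    ``one-step-overlap``: every triple (i, i+1, i+2); ``disjoint``:
    non-overlapping triples only.  Strides containing a flagged step are
    excluded.
    """
    tt = steps.trough_times
    if len(tt) < 3:
        return []
    if convention == "one-step-overlap":
        idx = range(len(tt) - 2)
    elif convention == "disjoint":
        idx = range(0, len(tt) - 2, 2)
    else:
        raise ValueError(f"unknown stride convention {convention!r}")
    strides = []
    for i in idx:
        if steps.bad_steps is not None and (
                steps.bad_steps[i] or steps.bad_steps[i + 1]):
            continue
        strides.append(Stride(tt[i], tt[i + 1], tt[i + 2]))
    return strides


def resample_stride(time: np.ndarray, series: np.ndarray, stride: Stride,
                    n: int = 200) -> np.ndarray:
    """Linearly interpolate a series onto ``n`` equally spaced stride points.

    Point k sits at stride completion k/n (0% … 99.5% for n = 200).
    """
    if stride.start < time[0] or stride.end > time[-1]:
        raise ValueError("stride window outside data span")
    targets = stride.start + (stride.end - stride.start) * np.arange(n) / n
    return np.interp(targets, time, series)


def assign_phase(event_times, strides: list[Stride]
                 ) -> tuple[list[PhaseAssignment], int]:
    """Map each event time to every stride containing it.

    Returns the assignments plus the count of events falling outside all
    strides (dropped).
    """
    event_times = np.asarray(event_times, float)
    if len(strides) == 0:
        return [], len(event_times)
    starts = np.array([s.start for s in strides])
    ends = np.array([s.end for s in strides])
    out = []
    dropped = 0
    for t in event_times:
        hit = np.nonzero((starts <= t) & (t < ends))[0]
        if hit.size == 0:
            dropped += 1
            continue
        for i in hit:
            s = strides[i]
            if t < s.mid:
                pct_step = 100.0 * (t - s.start) / (s.mid - s.start)
            else:
                pct_step = 100.0 * (t - s.mid) / (s.end - s.mid)
            out.append(PhaseAssignment(float(t), int(i),
                                       float(s.percentile(t)),
                                       float(pct_step)))
    return out, dropped


def assign_step_phase(event_times, steps: StepTable
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Percentile within the containing *step* for each event.

    Returns (percentiles, assigned_mask); events outside steps get NaN.
    """
    event_times = np.asarray(event_times, float)
    pct = np.full(len(event_times), np.nan)
    tt = steps.trough_times
    if len(tt) >= 2:
        idx = np.searchsorted(tt, event_times, "right") - 1
        ok = (idx >= 0) & (idx < len(tt) - 1)
        if steps.bad_steps is not None and steps.bad_steps.size:
            bad = np.zeros(len(event_times), bool)
            bad[ok] = steps.bad_steps[idx[ok]]
            ok &= ~bad
        sel = np.nonzero(ok)[0]
        i = idx[sel]
        pct[sel] = 100.0 * (event_times[sel] - tt[i]) / (tt[i + 1] - tt[i])
    return pct, ~np.isnan(pct)


def exclude_bad_trials(steps: StepTable, dropout_s: float = 0.0,
                       max_dropout: float = 0.25,
                       max_bad_frac: float = 0.2) -> tuple[bool, list]:
    """Automated trial exclusion: dropout, duration bounds, too few troughs.

    Returns (keep, reasons).
    """
    reasons = []
    if dropout_s > max_dropout:
        reasons.append("dropout")
    if len(steps.trough_times) < 3:
        reasons.append("too few troughs")
    elif steps.bad_steps is not None and steps.n_steps > 0 and \
            steps.bad_steps.mean() > max_bad_frac:
        reasons.append("duration bounds")
    return (len(reasons) == 0, reasons)
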