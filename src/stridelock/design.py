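"""Closed-form arithmetic on the experimental-design constants."""

from __future__ import annotations

import math

TRACKING_RATE_HZ = 90.0
EEG_RATE_HZ = 300.0
TRIAL_DURATION_S = 5.0
WALKWAY_NATURAL_M = 7.0
WALKWAY_SLOW_M = 3.5
STIMULUS_WIDTH_M = 0.1225
STIMULUS_DISTANCE_M = 1.0
IMAGE_MS = 100.0
GAP_MS = 100.0


def walking_speed(walkway_m: float, stream_s: float = TRIAL_DURATION_S) -> float:
    """Average speed implied by covering a walkway during one stream (m/s)."""
    return walkway_m / stream_s


def stimulus_visual_angle(width_m: float = STIMULUS_WIDTH_M,
                          distance_m: float = STIMULUS_DISTANCE_M) -> float:
    """Full visual angle (degrees) subtended by a flat stimulus."""
    return math.degrees(2 * math.atan(width_m / 2 / distance_m))


def min_saccade_duration_ms(n_samples: int = 2,
                            rate_hz: float = TRACKING_RATE_HZ) -> int:
    """Duration of ``n_samples`` at the tracking rate, truncated to whole ms."""
    return int(n_samples / rate_hz * 1000.0)


def presentation_rate_hz(image_ms: float = IMAGE_MS,
                         gap_ms: float = GAP_MS) -> float:
    """Image rate implied by the stimulus-onset asynchrony."""
    return 1000.0 / (image_ms + gap_ms)
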