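"""Analysis configuration: every downstream tunable with paper defaults.

Serializing a config to YAML and reloading reproduces identical results —
all stochastic stages derive their generators from ``seed`` through fixed
per-stage spawns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

STAGE_NAMES = ("simulate", "permutation_null", "participant_null",
               "cluster_test", "topographic_test")


@dataclass
class AnalysisConfig:
    seed: int = 0
    bundles: list = field(default_factory=list)   # dicts of RecordingBundle kwargs

    # saccade detection
    lambda_mult: float = 6.0
    min_samples: int = 2
    smooth_window: int = 5
    blink_jump: float = 0.8

    # gait extraction
    lowpass_hz: float = 6.0
    min_separation: float = 0.35
    prominence_frac: float = 0.25
    duration_bounds: tuple = (0.4, 1.2)
    stride_convention: str = "one-step-overlap"

    # cyclic statistics
    n_bins: int = 40
    freq_start: float = 0.2
    freq_stop: float = 10.0
    freq_step: float = 0.2
    n_permutations: int = 1000
    band: tuple = (1.5, 2.5)
    prevalence_alpha: float = 0.05
    prevalence_beta: float = 1.0

    # EEG
    run_eeg: bool = True
    cluster_permutations: int = 2000
    cluster_p_thresh: float = 0.01

    def __post_init__(self):
        if self.n_permutations <= 0:
            raise ValueError("n_permutations must be positive")
        if self.cluster_permutations <= 0:
            raise ValueError("cluster_permutations must be positive")
        self.duration_bounds = tuple(self.duration_bounds)
        self.band = tuple(self.band)

    @property
    def frequency_grid(self) -> np.ndarray:
        n = int(round((self.freq_stop - self.freq_start) / self.freq_step)) + 1
        return np.round(self.freq_start + self.freq_step * np.arange(n), 10)

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        """Deterministic per-stage seed derived from the top-level seed."""
        return np.random.SeedSequence((self.seed, STAGE_NAMES.index(stage)))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["duration_bounds"] = list(self.duration_bounds)
        d["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
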