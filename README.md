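# stridelock

Analysis pipeline for testing whether eye-movement onsets and EEG
time–frequency power entrain to the walking stride cycle, exercised
end-to-end on a synthetic-data generator with known ground truth.

Stages:

1. **Synthetic sessions** (`stridelock.simulate`) — head trajectories with a
   sinusoidal vertical bob (trough at footfall; per-condition step-duration
   statistics), gaze streams whose saccade-onset rate is modulated at a
   configurable number of cycles per stride, blinks, and EEG whose
   band-limited power follows the step cycle.  Everything is written to
   standard formats (tracking TSV, EDF, BIDS-style events TSV) together with
   a truth JSON.
2. **Saccade detection** (`stridelock.saccades`) — blink detection by the
   0.8-m jump criterion with ±100-ms linear interpolation, head-frame gaze
   angles, first-difference velocities smoothed with a 5-sample moving
   average, per-trial median-based thresholds (η = 6σ), and elliptic
   2D threshold crossings of at least 2 samples (22 ms).
3. **Gait extraction** (`stridelock.gait`) — footfalls as prominent troughs
   of the low-passed vertical head position, strides from consecutive
   trough triples (one-step overlap by default), stride-percentile
   assignment of event times, and automated trial exclusion.
4. **Cyclic statistics** (`stridelock.cyclic`) — 40-bin phase histograms,
   first-order Fourier fits on a forced 0.2–10 cycles-per-stride grid
   (linear least squares at each fixed frequency), a label-shuffling
   permutation null (95th-percentile R² bound per frequency), Bayesian
   population prevalence (MAP + 95% HPDI), and the Rayleigh test.
5. **EEG time–frequency** (`stridelock.timefreq`) — earlobe re-referencing,
   0.1–40 Hz zero-phase band-pass, deviation/correlation bad-channel
   flagging, complex Morlet transform (50 linear frequencies 3–40 Hz,
   FWHM 600→100 ms), step epochs with IQR outlier rejection, resampling to a
   −30…+130% step-cycle grid, percent-change normalization, and
   saccade-locked epochs pooled by gait quartile (stance = Q1∪Q4).
6. **Cluster statistics** (`stridelock.clusters`) — dependent-samples t-maps,
   p < 0.01 two-tailed thresholding, same-sign 4-connected clusters,
   sign-flip permutation null of the maximum cluster mass, and a
   channel-adjacency variant for topographic band maps.

## CLI

```bash
stridelock --out-dir results --seed 1 simulate --participant p01 --condition natural
stridelock --out-dir results detect-saccades results/p01_natural_tracking.tsv
stridelock --out-dir results extract-gait results/p01_natural_tracking.tsv
stridelock prevalence -k 14 -n 19 --alpha 0.025
stridelock --config analysis.yaml --out-dir results run-all
```

`run-all` reads an `AnalysisConfig` YAML (see `stridelock.config`) listing
the recording bundles and every tunable, and writes saccade/stride tables
(TSV), frequency-scan + prevalence summaries (JSON), gait-locked TF tensors
(NPZ) and cluster reports (JSON).  All randomness flows from the single
top-level seed; rerunning a config reproduces identical outputs.

## Conventions worth knowing

- Stride percentiles are half-open `[0, 100)` and linear in time across the
  two steps of a stride; strides overlap by one step unless `disjoint` is
  requested.
- The Fourier fit reports `f(x) = a0 + A·cos(2πwx/100 + φ)` with
  `φ = atan2(−b1, a1)`.
- Prevalence defaults to the nominal test level α = 0.05; pass
  `alpha=0.025` to reproduce the one-sided reading used by the printed
  estimates.
- Morlet wavelets are unit-passband-gain normalized, so a unit sinusoid
  yields peak power 0.25 at every grid frequency.
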