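"""Oscillation statistics for event likelihood across the stride cycle.

Event phases are counted into 40 equal bins, fitted at each forced frequency
with a first-order Fourier model f(x) = a0 + a1·cos(θ) + b1·sin(θ)
(θ = 2π·w·x/100), and the goodness of fit is compared against a
label-shuffling permutation null.  Participant-level significance counts
feed a Bayesian population-prevalence posterior; fitted phases feed a
Rayleigh test of circular non-uniformity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_GRID = np.round(np.arange(1, 51) * 0.2, 10)  # 0.2 … 10.0 cps
DEFAULT_BAND = (1.5, 2.5)                             # cps, step-rate band


def bin_centers(n_bins: int = 40) -> np.ndarray:
    width = 100.0 / n_bins
    return width * (np.arange(n_bins) + 0.5)


@dataclass
class BinnedPhaseSeries:
    values: np.ndarray                 # per-bin counts or rates
    centers: np.ndarray
    normalization: str = "raw"         # or "relative"


@dataclass
class FourierFit:
    w: float
    a0: float
    a1: float
    b1: float
    r2: float

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a1, self.b1))

    @property
    def phase(self) -> float:
        """Phase φ of the a0 + A·cos(θ + φ) form."""
        return float(np.arctan2(-self.b1, self.a1))

    def predict(self, x: np.ndarray) -> np.ndarray:
        theta = 2 * np.pi * self.w * np.asarray(x) / 100.0
        return self.a0 + self.a1 * np.cos(theta) + self.b1 * np.sin(theta)


@dataclass
class FourierScanResult:
    grid: np.ndarray
    r2: np.ndarray
    best: FourierFit

    @property
    def best_frequency(self) -> float:
        return self.best.w


@dataclass
class PermutationNull:
    grid: np.ndarray
    bound95: np.ndarray                # per-frequency 95th percentile of R²
    n_perm: int


@dataclass
class PrevalencePosterior:
    k: int
    n: int
    alpha: float
    beta: float
    gamma: np.ndarray
    density: np.ndarray
    map: float
    hpdi: tuple


@dataclass
class PhaseClusteringResult:
    n: int
    rbar: float
    z: float
    p: float


def bin_phases(percentiles, n_bins: int = 40) -> BinnedPhaseSeries:
    """Count events into ``n_bins`` half-open percentile bins [0, 100)."""
    percentiles = np.asarray(percentiles, float)
    if percentiles.size == 0:
        raise ValueError("no event phases to bin")
    if np.any((percentiles < 0) | (percentiles >= 100)):
        raise ValueError("percentiles must lie in [0, 100)")
    counts, _ = np.histogram(percentiles, bins=n_bins, range=(0, 100))
    return BinnedPhaseSeries(counts.astype(float), bin_centers(n_bins))


def relative_change(series: BinnedPhaseSeries) -> BinnedPhaseSeries:
    """Express bin values as relative change from the participant mean."""
    mean = series.values.mean()
    if mean == 0:
        raise ValueError("cannot normalize a series with zero mean")
    return BinnedPhaseSeries((series.values - mean) / mean, series.centers,
                             "relative")


def _design(x: np.ndarray, w: float) -> np.ndarray:
    theta = 2 * np.pi * w * x / 100.0
    return np.column_stack([np.ones_like(x), np.cos(theta), np.sin(theta)])


def fit_fourier(values: np.ndarray, w: float,
                x: np.ndarray | None = None) -> FourierFit:
    """Exact least-squares first-order Fourier fit at fixed frequency ``w``."""
    values = np.asarray(values, float)
    if x is None:
        x = bin_centers(len(values))
    X = _design(np.asarray(x, float), w)
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    ss_tot = np.sum((values - values.mean()) ** 2)
    r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid ** 2) / ss_tot
    return FourierFit(float(w), *map(float, coef), float(max(0.0, r2)))


def scan_frequencies(values: np.ndarray, grid: np.ndarray = DEFAULT_GRID,
                     x: np.ndarray | None = None) -> FourierScanResult:
    """Fit every grid frequency; best = argmax R² (ties to lower frequency)."""
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty frequency grid")
    fits = [fit_fourier(values, w, x) for w in grid]
    r2 = np.array([f.r2 for f in fits])
    return FourierScanResult(grid, r2, fits[int(np.argmax(r2))])


def _r2_many(Y: np.ndarray, grid: np.ndarray, x: np.ndarray) -> np.ndarray:
    """R² for each row of Y at each grid frequency, vectorized.

    Returns (n_series, n_freq).
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    ss_tot = np.sum(Yc ** 2, axis=1)
    out = np.empty((Y.shape[0], len(grid)))
    for j, w in enumerate(grid):
        X = _design(x, w)
        Q, _ = np.linalg.qr(X)
        proj = (Y @ Q) @ Q.T
        ss_res = np.sum((Y - proj) ** 2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = 1.0 - ss_res / ss_tot
        out[:, j] = np.where(ss_tot > 0, np.clip(r2, 0.0, 1.0), 0.0)
    return out


def permutation_null(participant_series: np.ndarray, n_perm: int = 1000,
                     seed=None, grid: np.ndarray = DEFAULT_GRID,
                     x: np.ndarray | None = None) -> PermutationNull:
    """Per-frequency 95th-percentile R² bound under bin-label shuffling.

    Each permutation independently shuffles the bin labels within every
    participant (sampling without replacement), averages across participants,
    and re-runs the full frequency scan.
    """
    P = np.asarray(participant_series, float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise ValueError("need >= 2 participants (rows)")
    if n_perm < 100:
        warnings.warn("n_perm < 100: unstable null bound")
    n_part, n_bins = P.shape
    if x is None:
        x = bin_centers(n_bins)
    rng = np.random.default_rng(seed)
    means = np.empty((n_perm, n_bins))
    for i in range(n_perm):
        perm = rng.permuted(np.broadcast_to(np.arange(n_bins),
                                            (n_part, n_bins)), axis=1)
        means[i] = np.take_along_axis(P, perm, axis=1).mean(axis=0)
    r2 = _r2_many(means, np.asarray(grid, float), x)
    bound = np.percentile(r2, 95, axis=0)
    return PermutationNull(np.asarray(grid, float), bound, n_perm)


def participant_entrainment(values: np.ndarray, n_perm: int = 1000,
                            seed=None, grid: np.ndarray = DEFAULT_GRID,
                            band: tuple = DEFAULT_BAND,
                            x: np.ndarray | None = None) -> dict:
    """Single-participant scan against that participant's shuffling null."""
    values = np.asarray(values, float)
    if x is None:
        x = bin_centers(len(values))
    scan = scan_frequencies(values, grid, x)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(values) for _ in range(n_perm)])
    r2 = _r2_many(perms, np.asarray(grid, float), x)
    bound = np.percentile(r2, 95, axis=0)
    sig = scan.r2 > bound
    in_band = (scan.grid >= band[0]) & (scan.grid <= band[1])
    return {
        "scan": scan,
        "bound95": bound,
        "per_frequency": sig,
        "band_significant": bool(np.any(sig & in_band)),
    }


def test_entrainment(scan: FourierScanResult, null: PermutationNull,
                     band: tuple = DEFAULT_BAND) -> dict:
    """Significance per frequency (strict exceedance) and over a cps band."""
    if not np.allclose(scan.grid, null.grid):
        raise ValueError("scan and null grids differ")
    sig = scan.r2 > null.bound95
    in_band = (scan.grid >= band[0]) & (scan.grid <= band[1])
    return {
        "per_frequency": sig,
        "band": band,
        "band_significant": bool(np.any(sig & in_band)),
    }


def prevalence(k: int, n: int, alpha: float, beta: float = 1.0,
               grid_size: int = 10001) -> PrevalencePosterior:
    """Bayesian population prevalence of a within-participant effect.

    Posterior over the population proportion γ of participants truly showing
    the effect, given k significant tests out of n at false-positive rate α
    and sensitivity β, under a uniform prior:
    p(γ) ∝ θ^k (1−θ)^(n−k) with θ = γβ + (1−γ)α.
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    if not 0 < alpha < beta <= 1:
        raise ValueError("need 0 < alpha < beta <= 1")
    gamma = np.linspace(0, 1, grid_size)
    theta = gamma * beta + (1 - gamma) * alpha
    with np.errstate(divide="ignore"):
        log_post = np.zeros_like(gamma)
        if k > 0:
            log_post += k * np.log(theta)
        if n - k > 0:
            log_post += (n - k) * np.log1p(-theta)
    log_post -= log_post.max()
    density = np.exp(log_post)
    density /= np.trapezoid(density, gamma)

    map_grid = float(gamma[np.argmax(density)])
    map_analytic = float(np.clip((k / n - alpha) / (beta - alpha), 0.0, 1.0))
    if abs(map_grid - map_analytic) > 2.0 / (grid_size - 1):
        raise RuntimeError("grid MAP disagrees with analytic mode")

    # HPDI by density water-filling (posterior is unimodal)
    order = np.argsort(density)[::-1]
    weights = density / density.sum()
    mass = np.cumsum(weights[order])
    cutoff = order[: np.searchsorted(mass, 0.95) + 1]
    hpdi = (float(gamma[cutoff.min()]), float(gamma[cutoff.max()]))
    return PrevalencePosterior(k, n, alpha, beta, gamma, density,
                               map_grid, hpdi)


def rayleigh_test(phases) -> PhaseClusteringResult:
    """Rayleigh test of circular non-uniformity.

    Z = n·R̄² with R̄ the mean resultant length; p by the standard
    small-sample approximation.
    """
    phases = np.asarray(phases, float)
    n = len(phases)
    if n < 3:
        raise ValueError("need at least 3 phases")
    rbar = float(np.abs(np.exp(1j * phases).mean()))
    R = n * rbar
    z = n * rbar ** 2
    p = float(np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - R ** 2)) - (1 + 2 * n)))
    return PhaseClusteringResult(n, rbar, z, min(p, 1.0))
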