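"""Cluster-based permutation inference on 2D statistic maps.

Per-pixel dependent-samples t-scores are thresholded at an uncorrected
p < 0.01 (two-tailed), same-sign 4-connected components are formed, and each
cluster's t-mass is compared against the permutation distribution of the
maximum absolute cluster mass (sign-flip permutations; paired contrasts are
reduced to difference maps first).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])

#: approximate 2D positions of the 10-20 montage (x right, y anterior)
CHANNEL_POSITIONS = {
    "Fp1": (-0.3, 1.0), "Fp2": (0.3, 1.0),
    "F7": (-0.8, 0.55), "F3": (-0.4, 0.55), "Fz": (0.0, 0.55),
    "F4": (0.4, 0.55), "F8": (0.8, 0.55),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "P7": (-0.8, -0.55), "P3": (-0.4, -0.55), "Pz": (0.0, -0.55),
    "P4": (0.4, -0.55), "P8": (0.8, -0.55),
    "O1": (-0.3, -1.0), "O2": (0.3, -1.0),
}


@dataclass
class Cluster:
    pixels: list               # list of (i, j) member indices
    sign: int
    mass: float
    peak: tuple                # (i, j) of max |t|
    p_cluster: float | None = None

    @property
    def size(self) -> int:
        return len(self.pixels)


def t_map(maps: np.ndarray, paired_with: np.ndarray | None = None
          ) -> tuple[np.ndarray, int]:
    """One-sample (or paired-difference) t-scores per pixel.

    ``maps`` is (participants, ...); returns (t, df).  Zero-variance pixels
    get t = 0 with a warning.
    """
    X = np.asarray(maps, float)
    if paired_with is not None:
        X = X - np.asarray(paired_with, float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance pixels: t set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(zero, 0.0, mean / (sd / np.sqrt(n)))
    return t, n - 1


def threshold_clusters(t: np.ndarray, df: int, p_thresh: float = 0.01
                       ) -> list[Cluster]:
    """Same-sign 4-connected components of supra-threshold pixels."""
    if df < 2:
        raise ValueError("df must be >= 2")
    tcrit = stats.t.ppf(1 - p_thresh / 2, df)
    clusters = []
    for sign in (1, -1):
        mask = t * sign > tcrit
        labels, n = ndimage.label(mask, structure=FOUR_CONN)
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            vals = t[tuple(idx.T)]
            peak = idx[np.argmax(np.abs(vals))]
            clusters.append(Cluster([tuple(p) for p in idx], sign,
                                    float(vals.sum()), tuple(peak)))
    return clusters


def _max_mass(t: np.ndarray, df: int, p_thresh: float) -> float:
    cl = threshold_clusters(t, df, p_thresh)
    return max((abs(c.mass) for c in cl), default=0.0)


def permutation_cluster_p(maps: np.ndarray, clusters: list[Cluster],
                          n_perm: int = 2000, seed=None,
                          p_thresh: float = 0.01,
                          paired_with: np.ndarray | None = None
                          ) -> list[Cluster]:
    """Corrected cluster p-values from sign-flip permutations.

    Each permutation flips the sign of each participant's map (for a paired
    contrast, of each participant's difference map), rebuilds the t-map and
    records the maximum |cluster mass|; p = (1 + #{null ≥ observed}) /
    (n_perm + 1).
    """
    if n_perm < 500:
        warnings.warn("n_perm < 500: unstable cluster p-values")
    X = np.asarray(maps, float)
    if paired_with is not None:
        X = X - np.asarray(paired_with, float)
    n = X.shape[0]
    df = n - 1
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    flat = X.reshape(n, -1)
    shape = X.shape[1:]
    sqrt_n = np.sqrt(n)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        Y = flat * signs[:, None]
        mean = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sd == 0, 0.0, mean / (sd / sqrt_n)).reshape(shape)
        null[i] = _max_mass(t, df, p_thresh)
    for c in clusters:
        c.p_cluster = float((1 + np.sum(null >= abs(c.mass))) / (n_perm + 1))
    return clusters


def cluster_test(maps: np.ndarray, n_perm: int = 2000, seed=None,
                 p_thresh: float = 0.01,
                 paired_with: np.ndarray | None = None) -> list[Cluster]:
    """Observed clusters with corrected p-values, in one call."""
    t, df = t_map(maps, paired_with)
    clusters = threshold_clusters(t, df, p_thresh)
    if clusters:
        clusters = permutation_cluster_p(maps, clusters, n_perm, seed,
                                         p_thresh, paired_with)
    return clusters


def channel_adjacency(labels, max_dist: float = 0.62) -> dict:
    """Neighbour sets from 2D montage distances (2-6 neighbours/channel)."""
    pos = {l: np.array(CHANNEL_POSITIONS[l]) for l in labels}
    adj = {l: set() for l in labels}
    for a in labels:
        for b in labels:
            if a != b and np.linalg.norm(pos[a] - pos[b]) <= max_dist:
                adj[a].add(b)
    if any(len(v) == 0 for v in adj.values()):
        warnings.warn("adjacency graph has isolated channels")
    return {k: sorted(v) for k, v in adj.items()}


def _label_graph(mask: np.ndarray, adjacency_idx: list) -> list:
    """Connected components of supra-threshold (channel, bin) cells.

    Neighbours: same channel adjacent bin, adjacent channel same bin.
    """
    nchan, nbin = mask.shape
    seen = np.zeros_like(mask, bool)
    comps = []
    for c in range(nchan):
        for b in range(nbin):
            if not mask[c, b] or seen[c, b]:
                continue
            comp = []
            q = deque([(c, b)])
            seen[c, b] = True
            while q:
                ci, bi = q.popleft()
                comp.append((ci, bi))
                neigh = [(ci, bi - 1), (ci, bi + 1)] + \
                        [(cj, bi) for cj in adjacency_idx[ci]]
                for cj, bj in neigh:
                    if 0 <= bj < nbin and 0 <= cj < nchan \
                            and mask[cj, bj] and not seen[cj, bj]:
                        seen[cj, bj] = True
                        q.append((cj, bj))
            comps.append(comp)
    return comps


def topographic_clusters(t: np.ndarray, df: int, labels,
                         adjacency: dict | None = None,
                         p_thresh: float = 0.05) -> list[Cluster]:
    """Clusters over a channels x bins map using montage adjacency."""
    if adjacency is None:
        adjacency = channel_adjacency(labels)
    adjacency_idx = [[labels.index(n) for n in adjacency.get(l, [])]
                     for l in labels]
    tcrit = stats.t.ppf(1 - p_thresh / 2, df)
    clusters = []
    for sign in (1, -1):
        mask = t * sign > tcrit
        for comp in _label_graph(mask, adjacency_idx):
            idx = np.array(comp)
            vals = t[tuple(idx.T)]
            peak = comp[int(np.argmax(np.abs(vals)))]
            clusters.append(Cluster(comp, sign, float(vals.sum()),
                                    tuple(peak)))
    return clusters


def topographic_cluster_test(maps: np.ndarray, labels,
                             adjacency: dict | None = None,
                             n_perm: int = 2000, seed=None,
                             p_thresh: float = 0.05,
                             paired_with: np.ndarray | None = None
                             ) -> list[Cluster]:
    """Sign-flip permutation test over the channel x bin graph."""
    if adjacency is None:
        adjacency = channel_adjacency(labels)
    adjacency_idx = [[labels.index(n) for n in adjacency.get(l, [])]
                     for l in labels]
    X = np.asarray(maps, float)
    if paired_with is not None:
        X = X - np.asarray(paired_with, float)
    n = X.shape[0]
    df = n - 1
    t, _ = t_map(X)
    observed = topographic_clusters(t, df, labels, adjacency, p_thresh)
    if not observed:
        return observed
    tcrit = stats.t.ppf(1 - p_thresh / 2, df)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    sqrt_n = np.sqrt(n)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        Y = X * signs[:, None, None]
        mean = Y.mean(axis=0)
        sd = Y.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            tp = np.where(sd == 0, 0.0, mean / (sd / sqrt_n))
        best = 0.0
        for sign in (1, -1):
            for comp in _label_graph(tp * sign > tcrit, adjacency_idx):
                mass = abs(float(tp[tuple(np.array(comp).T)].sum()))
                best = max(best, mass)
        null[i] = best
    for c in observed:
        c.p_cluster = float((1 + np.sum(null >= abs(c.mass))) / (n_perm + 1))
    return observed
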