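"""Nonparametric cluster-corrected inference and t-test batteries.

The cluster permutation test is the standard sign-flip one-sample variant:
cell-wise t statistics are thresholded at the t value corresponding to the
cluster-forming p, suprathreshold cells are grouped into connected clusters
(4-connectivity on 2-D lattices, with optional circular wrap on designated
axes), each cluster is scored by its mass (sum of t), and the observed
masses are compared against the permutation null of the maximum cluster
mass under random sign flips of whole subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .geometry import angular_difference

__all__ = [
    "ClusterTestResult",
    "cluster_permutation_1samp",
    "ThresholdedMaps",
    "threshold_map_ttests",
    "estimator_ttests",
]


def _t_onesamp(data: np.ndarray) -> np.ndarray:
    """One-sample t against 0 along axis 0."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    return mean / (sd / np.sqrt(n) + 1e-300)


def _label_clusters(mask: np.ndarray, circular_axes: tuple) -> np.ndarray:
    """Connected-component labels under 4-connectivity with circular wrap."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return labels
    # merge components touching across each circular seam (union-find)
    parent = np.arange(n_labels + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for ax in circular_axes:
        first = np.take(labels, 0, axis=ax)
        last = np.take(labels, -1, axis=ax)
        both = (first > 0) & (last > 0)
        for a, b in zip(first[both].ravel(), last[both].ravel()):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    remap = np.array([find(x) for x in range(n_labels + 1)])
    return remap[labels]


def _max_cluster_mass(t_map: np.ndarray, threshold: float, tails: int,
                      circular_axes: tuple) -> float:
    best = 0.0
    signs = (1, -1) if tails == 2 else (1,)
    for sign in signs:
        mask = sign * t_map > threshold
        if not mask.any():
            continue
        labels = _label_clusters(mask, circular_axes)
        masses = ndimage.sum_labels(np.abs(t_map), labels,
                                    index=np.unique(labels[labels > 0]))
        if masses.size:
            best = max(best, float(masses.max()))
    return best


@dataclass
class ClusterTestResult:
    """Clusters, masses and permutation p-values on the tested lattice."""

    t_map: np.ndarray
    threshold: float
    cluster_masks: list          # boolean arrays, one per observed cluster
    cluster_masses: np.ndarray   # |sum of t| per cluster
    cluster_signs: np.ndarray    # +1 / -1 per cluster
    p_values: np.ndarray
    n_permutations: int
    tails: int
    alpha: float

    def significant_mask(self, alpha: float | None = None) -> np.ndarray:
        alpha = self.alpha if alpha is None else alpha
        out = np.zeros(self.t_map.shape, dtype=bool)
        for mask, p in zip(self.cluster_masks, self.p_values):
            if p <= alpha:
                out |= mask
        return out


def cluster_permutation_1samp(
    data: np.ndarray,
    alpha: float = 0.01,
    cluster_p: float = 0.01,
    n_perm: int = 4096,
    tails: int = 2,
    circular_axes: tuple = (),
    seed: int = 0,
) -> ClusterTestResult:
    """Sign-flip cluster permutation test of mean 0 across subjects.

    ``data`` is ``(n_subjects, *lattice)``. The cluster-forming threshold
    is the t quantile for ``cluster_p`` (two-tailed when ``tails == 2``);
    cluster p-values are ``(1 + #{null max mass >= observed}) /
    (1 + n_perm)``, honouring the Monte-Carlo resolution floor.
    """
    data = np.asarray(data, dtype=float)
    n_sub = data.shape[0]
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    lattice = data.shape[1:]
    df = n_sub - 1
    if tails == 2:
        threshold = float(stats.t.ppf(1.0 - cluster_p / 2.0, df))
    else:
        threshold = float(stats.t.ppf(1.0 - cluster_p, df))

    t_obs = _t_onesamp(data)

    # observed clusters
    cluster_masks, cluster_masses, cluster_signs = [], [], []
    for sign in ((1, -1) if tails == 2 else (1,)):
        mask = sign * t_obs > threshold
        if not mask.any():
            continue
        labels = _label_clusters(mask, circular_axes)
        for lab in np.unique(labels[labels > 0]):
            m = labels == lab
            cluster_masks.append(m)
            cluster_masses.append(float(np.abs(t_obs[m]).sum()))
            cluster_signs.append(sign)
    cluster_masses = np.asarray(cluster_masses)
    cluster_signs = np.asarray(cluster_signs, dtype=int)

    # permutation null of the max cluster mass (vectorised t computation:
    # the second moment is sign-invariant, only the mean flips)
    rng = np.random.default_rng(seed)
    flat = data.reshape(n_sub, -1)
    sumsq = (flat ** 2).sum(axis=0)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n_sub)
        mean = signs @ flat / n_sub
        var = (sumsq / n_sub - mean ** 2) * n_sub / df
        t_perm = (mean / (np.sqrt(var / n_sub) + 1e-300)).reshape(lattice)
        null_max[i] = _max_cluster_mass(t_perm, threshold, tails, circular_axes)

    if cluster_masses.size:
        exceed = (null_max[None, :] >= cluster_masses[:, None]).sum(axis=1)
        p_values = (1.0 + exceed) / (1.0 + n_perm)
    else:
        p_values = np.empty(0)
    return ClusterTestResult(t_map=t_obs, threshold=threshold,
                             cluster_masks=cluster_masks,
                             cluster_masses=cluster_masses,
                             cluster_signs=cluster_signs,
                             p_values=p_values, n_permutations=n_perm,
                             tails=tails, alpha=alpha)


@dataclass
class ThresholdedMaps:
    """Cell-wise one-sample t masks of posterior maps against chance."""

    t_map: np.ndarray
    p_map: np.ndarray
    masks: dict                    # threshold -> boolean map


def threshold_map_ttests(maps: np.ndarray, chance: float,
                         thresholds=(0.05, 0.01), tails: int = 1) -> ThresholdedMaps:
    """Per-cell one-sample t-tests of subject maps against chance.

    ``maps`` is ``(n_subjects, *lattice)`` of posterior probabilities; the
    default is a one-tailed test for probability above chance.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    t_map = _t_onesamp(maps - chance)
    if tails == 1:
        p_map = stats.t.sf(t_map, df=n - 1)
    else:
        p_map = 2 * stats.t.sf(np.abs(t_map), df=n - 1)
    masks = {thr: p_map < thr for thr in thresholds}
    return ThresholdedMaps(t_map=t_map, p_map=p_map, masks=masks)


def estimator_ttests(peaks_deg, centroids_deg, reference_deg) -> dict:
    """t-test battery on circular position estimates.

    Signed circular differences to the reference angle are computed first;
    standard one-sample t-tests (peaks vs reference, centroids vs
    reference) and a paired t-test (peaks vs centroids) are run on the
    signed differences. Returns ``{name: (t, p)}``.
    """
    peaks = np.asarray(peaks_deg, dtype=float)
    cents = np.asarray(centroids_deg, dtype=float)
    d_peak = angular_difference(peaks, reference_deg)
    d_cent = angular_difference(cents, reference_deg)
    d_pair = angular_difference(peaks, cents)
    def _t1(d):
        if np.allclose(d, 0.0):        # degenerate: no difference at all
            return 0.0, 1.0
        t, p = stats.ttest_1samp(d, 0.0)
        return float(t), float(p)

    return {"peak_vs_reference": _t1(d_peak),
            "centroid_vs_reference": _t1(d_cent),
            "peak_vs_centroid": _t1(d_pair)}
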