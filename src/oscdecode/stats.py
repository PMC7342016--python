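"""Group-level nonparametric inference for decoding and RSA results.

The group statistic (mean accuracy or mean correlation over participants) is
tested against chance with a sign-permutation test: under the null each
participant's chance-centered map is equally likely to appear with either
sign, so the null distribution is built by randomly flipping whole
participant maps.  Family-wise error over time (or time x time) maps is
controlled with cluster-size inference on the permutation distribution of
maximum cluster size; correlation-based analyses use Benjamini-Hochberg FDR
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests


@dataclass
class PermutationResult:
    """Observed p-map plus the shared permutation draws behind it."""

    p_map: np.ndarray  # same shape as one participant map
    observed: np.ndarray  # group-mean map (chance-centered)
    perm_stats: np.ndarray  # (n_perm + 1, *map_shape); row 0 = identity
    perm_p_maps: np.ndarray  # p-maps of every draw against the same null
    tail: str
    chance_level: float


@dataclass
class ClusterResult:
    """Cluster-size-corrected significance for a 1-D or 2-D map."""

    p_map: np.ndarray
    clusters: list[tuple[np.ndarray, int]]  # (boolean member mask, size)
    null_max_sizes: np.ndarray
    size_threshold: int
    significant_mask: np.ndarray
    cluster_p_values: list[float]
    n_permutations: int


def sign_permutation_p(
    values: np.ndarray,
    n_perm: int = 10_000,
    tail: str = "right",
    chance_level: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> PermutationResult:
    """Participant sign-permutation test of the group mean against chance.

    Each permutation flips every participant's entire (chance-centered) map
    by an independent +-1 and recomputes the group mean; the same seeded
    permutation schedule is shared across all map cells.  The identity
    permutation is included, so the smallest attainable p is
    ``1 / (n_perm + 1)``.

    Parameters
    ----------
    values : (n_participants, *map_shape) array.
    tail : "right" (greater than chance) or "two".
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 1 or values.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    if not np.all(np.isfinite(values)):
        raise ValueError("nonfinite values")
    if tail not in ("right", "two"):
        raise ValueError("tail must be 'right' or 'two'")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is very low for permutation inference")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    centered = values - chance_level
    n_sub = centered.shape[0]
    map_shape = centered.shape[1:]
    flat = centered.reshape(n_sub, -1)

    signs = np.empty((n_perm + 1, n_sub))
    signs[0] = 1.0  # identity permutation first
    signs[1:] = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    perm_stats = (signs @ flat) / n_sub  # (n_perm+1, n_cells)

    stats = np.abs(perm_stats) if tail == "two" else perm_stats
    # p of each draw against the pooled empirical distribution, per cell:
    # p_k = #(stat_j >= stat_k) / (n_perm + 1); ties all count
    n_total = n_perm + 1
    sorted_asc = np.sort(stats, axis=0)
    p_all = np.empty_like(stats)
    for c in range(stats.shape[1]):
        ge_counts = n_total - np.searchsorted(sorted_asc[:, c], stats[:, c], side="left")
        p_all[:, c] = ge_counts / n_total
    p_map = p_all[0].reshape(map_shape)
    return PermutationResult(
        p_map=p_map,
        observed=perm_stats[0].reshape(map_shape),
        perm_stats=perm_stats.reshape((n_total,) + map_shape),
        perm_p_maps=p_all.reshape((n_total,) + map_shape),
        tail=tail,
        chance_level=chance_level,
    )


def _label_clusters(mask: np.ndarray, connectivity_2d: int = 8):
    """Connected components: adjacency in 1-D, 4- or 8-connectivity in 2-D."""
    if mask.ndim == 1:
        structure = np.ones(3, dtype=bool)
    elif mask.ndim == 2:
        structure = (
            np.ones((3, 3), dtype=bool)
            if connectivity_2d == 8
            else ndimage.generate_binary_structure(2, 1)
        )
    else:
        raise ValueError("only 1-D and 2-D maps supported")
    labeled, n = ndimage.label(mask, structure=structure)
    return labeled, n


def cluster_correct(
    perm: PermutationResult,
    cluster_def_p: float = 0.05,
    cluster_p: float = 0.05,
    bonferroni_factor: int = 1,
    connectivity_2d: int = 8,
) -> ClusterResult:
    """Cluster-size inference from a shared permutation schedule.

    The observed p-map and every permutation's p-map (all computed against
    the same empirical null) are thresholded at ``cluster_def_p``; the
    maximum supra-threshold cluster size per permutation forms the null.  An
    observed cluster is significant if the fraction of permutations reaching
    its size is below ``cluster_p / bonferroni_factor`` (e.g. factor 3 when
    three frequency bands are tested).
    """
    obs_mask = perm.p_map < cluster_def_p
    labeled, n_clusters = _label_clusters(obs_mask, connectivity_2d)

    null_max = np.zeros(perm.perm_p_maps.shape[0] - 1, dtype=int)
    for k in range(1, perm.perm_p_maps.shape[0]):
        m = perm.perm_p_maps[k] < cluster_def_p
        if m.any():
            lab, nc = _label_clusters(m, connectivity_2d)
            null_max[k - 1] = np.bincount(lab.ravel())[1:].max() if nc else 0

    alpha = cluster_p / bonferroni_factor
    n_perm = len(null_max)
    clusters: list[tuple[np.ndarray, int]] = []
    cluster_ps: list[float] = []
    significant = np.zeros_like(obs_mask)
    for ci in range(1, n_clusters + 1):
        member = labeled == ci
        size = int(member.sum())
        p_cluster = float((null_max >= size).sum() / n_perm) if n_perm else 1.0
        clusters.append((member, size))
        cluster_ps.append(p_cluster)
        if p_cluster < alpha:
            significant |= member
    # smallest size that would reach significance under the null
    if n_perm:
        sizes = np.arange(0, null_max.max() + 2)
        exceed = np.array([(null_max >= s).mean() for s in sizes])
        reach = np.flatnonzero(exceed < alpha)
        size_threshold = int(sizes[reach[0]]) if len(reach) else int(null_max.max() + 1)
    else:
        size_threshold = 0
    return ClusterResult(
        p_map=perm.p_map,
        clusters=clusters,
        null_max_sizes=null_max,
        size_threshold=size_threshold,
        significant_mask=significant,
        cluster_p_values=cluster_ps,
        n_permutations=n_perm,
    )


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up; returns (reject flags, adjusted p)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must be in [0, 1]")
    reject, adjusted, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, adjusted


def peak_latency_ci(
    maps: np.ndarray,
    times: np.ndarray | tuple[np.ndarray, np.ndarray],
    n_boot: int = 10_000,
    ci: float = 95.0,
    rng: np.random.Generator | int | None = None,
):
    """Peak of the group-mean accuracy and a bootstrap CI over participants.

    For 1-D maps the peak is the argmax of the group mean; for 2-D
    (perception x imagery) maps the peak of each axis' marginal mean is
    reported.  CIs are percentile bootstrap over participants.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need >= 2 participants")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def _peaks(group_mean: np.ndarray):
        if group_mean.ndim == 1:
            if np.allclose(group_mean, group_mean.flat[0]):
                raise ValueError("flat map: peak undefined")
            return (float(np.asarray(times)[int(np.argmax(group_mean))]),)
        t0, t1 = times
        m0 = group_mean.mean(axis=1)
        m1 = group_mean.mean(axis=0)
        if np.allclose(group_mean, group_mean.flat[0]):
            raise ValueError("flat map: peak undefined")
        return (
            float(np.asarray(t0)[int(np.argmax(m0))]),
            float(np.asarray(t1)[int(np.argmax(m1))]),
        )

    observed = _peaks(maps.mean(axis=0))
    n_sub = maps.shape[0]
    boots = np.empty((n_boot, len(observed)))
    for b in range(n_boot):
        idx = rng.integers(0, n_sub, size=n_sub)
        boots[b] = _peaks(maps[idx].mean(axis=0))
    lo = (100.0 - ci) / 2.0
    intervals = [
        (float(np.percentile(boots[:, k], lo)), float(np.percentile(boots[:, k], 100 - lo)))
        for k in range(len(observed))
    ]
    return {"peak": observed, "ci": intervals}
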