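"""Voxelwise t contrasts with nonparametric cluster-mass inference.

Supra-threshold voxels (two-sided parametric p below the cluster-forming
alpha) are grouped into sign-separated connected components; the sum of
member t statistics is the cluster mass.  Significance is assessed
against a Monte-Carlo null of the maximum absolute cluster mass per
permutation (per-subject condition swaps for dependent designs, group
label reshuffles for independent designs), which controls family-wise
error across clusters.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

DEPENDENT = "dependent"
INDEPENDENT = "independent"


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class StatMap:
    """Voxelwise t map (flat, NaN at invalid voxels) with its design."""

    t: np.ndarray
    df: int
    design: str
    grid_shape: tuple[int, int, int]

    @property
    def p(self) -> np.ndarray:
        """Two-sided parametric p per voxel."""
        with np.errstate(invalid="ignore"):
            return 2.0 * stats.t.sf(np.abs(self.t), self.df)

    @property
    def n_valid(self) -> int:
        return int(np.isfinite(self.t).sum())


@dataclass
class Cluster:
    voxels: np.ndarray          # flat indices
    mass: float                 # sum of member t statistics
    sign: int                   # +1 / -1
    peak_voxel: int = -1
    p_mc: float = np.nan
    significant: bool = False

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class ClusterResult:
    stat: StatMap
    clusters: list[Cluster]
    null_distribution: np.ndarray
    alpha: float
    min_size: int
    connectivity: int
    n_perm: int

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]

    def cluster_mask(self, index: int) -> np.ndarray:
        mask = np.zeros(int(np.prod(self.stat.grid_shape)), dtype=bool)
        mask[self.clusters[index].voxels] = True
        return mask


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _dependent_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t on paired differences, per voxel (NaN-propagating)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per voxel (group a minus group b)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    ssa = ((a - ma) ** 2).sum(axis=0)
    ssb = ((b - mb) ** 2).sum(axis=0)
    s2 = (ssa + ssb) / (na + nb - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    t[~np.isfinite(t)] = np.nan
    return t


def voxelwise_t(maps_a: np.ndarray, maps_b: np.ndarray, design: str,
                grid_shape: tuple[int, int, int]) -> StatMap:
    """Voxelwise t contrast between two condition/group map stacks.

    ``maps_a`` / ``maps_b`` are (n_subjects, n_voxels); dependent designs
    require paired rows, independent designs two disjoint groups (n >= 2
    each).  Voxels invalid (NaN) in any required subject are dropped;
    zero-variance voxels become NaN with a logged count.
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if design == DEPENDENT:
        if a.shape != b.shape:
            raise ValueError("dependent design requires paired map stacks")
        if a.shape[0] < 2:
            raise ValueError("need at least two subjects")
        t = _dependent_t(a - b)
        df = a.shape[0] - 1
    elif design == INDEPENDENT:
        if a.shape[0] < 2 or b.shape[0] < 2:
            raise ValueError("each group needs n >= 2")
        if a.shape[1] != b.shape[1]:
            raise ValueError("groups must share the voxel grid")
        t = _independent_t(a, b)
        df = a.shape[0] + b.shape[0] - 2
    else:
        raise ValueError(f"unknown design {design!r}")
    valid_in = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
    n_dropped = int((valid_in & np.isnan(t)).sum())
    if n_dropped:
        logger.info("voxelwise_t: %d zero-variance voxels invalidated", n_dropped)
    t[~valid_in] = np.nan
    return StatMap(t=t, df=df, design=design, grid_shape=grid_shape)


# ---------------------------------------------------------------------------
# cluster formation
# ---------------------------------------------------------------------------

def _threshold(df: int, alpha: float) -> float:
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def _masses_from_t(t3: np.ndarray, t_crit: float, structure: np.ndarray):
    """Label sign-separated supra-threshold components; yield (slices of
    flat indices, masses) per sign."""
    results = []
    for sign in (1, -1):
        supra = (sign * t3) > t_crit
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            continue
        masses = ndimage.sum(t3, labels, index=np.arange(1, n + 1))
        results.append((sign, labels, masses))
    return results


def form_clusters(stat: StatMap, alpha: float = 0.005,
                  connectivity: int = 26) -> list[Cluster]:
    """Connected components of supra-threshold voxels, per sign.

    Thresholding is on the two-sided parametric p (< alpha); cluster mass
    is the sum of member t statistics.  The minimum-size rule is applied
    at the reporting stage (see cluster_p), not here.
    """
    t3 = np.where(np.isfinite(stat.t), stat.t, 0.0).reshape(stat.grid_shape)
    t_crit = _threshold(stat.df, alpha)
    clusters: list[Cluster] = []
    for sign, labels, masses in _masses_from_t(t3, t_crit, _structure(connectivity)):
        for k, mass in enumerate(masses, start=1):
            vox = np.flatnonzero(labels.reshape(-1) == k)
            peak = vox[np.argmax(sign * t3.reshape(-1)[vox])]
            clusters.append(Cluster(voxels=vox, mass=float(mass), sign=sign,
                                    peak_voxel=int(peak)))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_mass(t_flat: np.ndarray, grid_shape, t_crit: float,
              structure: np.ndarray) -> float:
    t3 = np.where(np.isfinite(t_flat), t_flat, 0.0).reshape(grid_shape)
    best = 0.0
    for _sign, _labels, masses in _masses_from_t(t3, t_crit, structure):
        m = np.abs(masses).max()
        if m > best:
            best = float(m)
    return best


def monte_carlo_null(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    design: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.005,
    connectivity: int = 26,
    grid_shape: tuple[int, int, int] | None = None,
    exhaustive: bool = False,
) -> np.ndarray:
    """Null distribution of the maximum absolute cluster mass.

    Dependent designs swap the two conditions per subject (sign flips of
    the paired differences); independent designs reshuffle group labels
    preserving group sizes.  Each permutation recomputes the t map and
    clusters with the identical alpha/connectivity and records the
    largest |mass| over both signs (0 when no cluster forms).  With
    ``exhaustive=True`` (dependent only) all 2^n sign patterns are
    enumerated instead of sampled.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if grid_shape is None:
        raise ValueError("grid_shape is required")
    rng = np.random.default_rng(seed)
    structure = _structure(connectivity)

    if design == DEPENDENT:
        d = a - b
        n = d.shape[0]
        df = n - 1
        t_crit = _threshold(df, alpha)
        sumsq = (d ** 2).sum(axis=0)
        valid = ~np.isnan(sumsq)
        if exhaustive:
            signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        means = signs @ d / n                         # (P, V)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (sumsq[None, :] - n * means**2) / (n - 1)
            t_all = means / np.sqrt(var / n)
        t_all[:, ~valid] = np.nan
    elif design == INDEPENDENT:
        x = np.vstack([a, b])
        na, nb = a.shape[0], b.shape[0]
        n = na + nb
        df = n - 2
        t_crit = _threshold(df, alpha)
        x2 = x ** 2
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        G = np.zeros((n_perm, n))
        for p in range(n_perm):
            G[p, perms[p, :na]] = 1.0
        sum_all = x.sum(axis=0)
        sumsq_all = x2.sum(axis=0)
        sa = G @ x
        sqa = G @ x2
        sb = sum_all[None, :] - sa
        sqb = sumsq_all[None, :] - sqa
        ma, mb = sa / na, sb / nb
        ssa = sqa - na * ma**2
        ssb = sqb - nb * mb**2
        with np.errstate(invalid="ignore", divide="ignore"):
            s2 = (ssa + ssb) / df
            t_all = (ma - mb) / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    else:
        raise ValueError(f"unknown design {design!r}")

    return np.array([
        _max_mass(t_all[p], grid_shape, t_crit, structure)
        for p in range(t_all.shape[0])
    ])


def cluster_p(clusters: list[Cluster], null: np.ndarray,
              min_size: int = 10, alpha_cluster: float = 0.05) -> list[Cluster]:
    """Monte-Carlo p per cluster with the add-one convention.

    p_mc = (1 + #{null >= |mass|}) / (n_perm + 1); a cluster is
    significant iff p_mc < alpha_cluster and it contains at least
    ``min_size`` voxels.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    for c in clusters:
        c.p_mc = float((1 + np.sum(null >= abs(c.mass))) / (null.size + 1))
        c.significant = bool(c.p_mc < alpha_cluster and c.size >= min_size)
    return clusters


def cluster_permutation_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    design: str,
    grid_shape: tuple[int, int, int],
    alpha: float = 0.005,
    min_size: int = 10,
    connectivity: int = 26,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Observed clusters plus Monte-Carlo inference in one call."""
    stat = voxelwise_t(maps_a, maps_b, design, grid_shape)
    clusters = form_clusters(stat, alpha=alpha, connectivity=connectivity)
    null = monte_carlo_null(maps_a, maps_b, design, n_perm=n_perm, seed=seed,
                            alpha=alpha, connectivity=connectivity,
                            grid_shape=grid_shape)
    clusters = cluster_p(clusters, null, min_size=min_size)
    return ClusterResult(stat=stat, clusters=clusters, null_distribution=null,
                         alpha=alpha, min_size=min_size,
                         connectivity=connectivity, n_perm=len(null))
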