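"""Two-sample cluster-based permutation test on 2D spatial maps.

Pointwise two-sample t statistics are thresholded at a cluster-forming
p-value (default 0.01, two-sided), adjacent suprathreshold cells (4-connected,
positive and negative t handled separately) are grouped into clusters of at
least 2 cells, and each observed cluster's mass — the sum of |t| over its
member cells — is compared with the null distribution of the maximum cluster
mass obtained by shuffling condition labels over rows.  This controls the
family-wise error over cells while exploiting their spatial dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SpatialMapSet",
    "Cluster",
    "ClusterResult",
    "pointwise_t_map",
    "form_clusters",
    "permutation_test",
]

#: 4-connectivity structuring element
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SpatialMapSet:
    """Per-subject 2D maps with two-level condition labels.

    ``maps`` is ``(n_subjects, H, W)``; ``labels`` assigns each row to one of
    exactly two conditions; ``mask`` flags valid cells (True = analysed).
    """

    maps: np.ndarray
    labels: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.maps.ndim != 3:
            raise ValueError("maps must be (n_subjects, H, W)")
        if self.labels.shape[0] != self.maps.shape[0]:
            raise ValueError("one label per map row required")
        levels = np.unique(self.labels)
        if levels.size != 2:
            raise ValueError(f"exactly two conditions required, got {levels.size}")
        if self.mask is None:
            self.mask = np.ones(self.maps.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.maps.shape[1:]:
                raise ValueError("mask shape must match map shape")

    @property
    def group_sizes(self) -> tuple[int, int]:
        levels = np.unique(self.labels)
        return int(np.sum(self.labels == levels[0])), int(np.sum(self.labels == levels[1]))


@dataclass
class Cluster:
    """One suprathreshold connected component."""

    cells: np.ndarray  # (k, 2) array of (row, col) indices
    mass: float  # sum of |t| over member cells
    sign: int  # +1 or -1
    p_value: float = float("nan")

    @property
    def size(self) -> int:
        return self.cells.shape[0]


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray
    n_permutations: int
    threshold_p: float
    df: int
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < alpha]


def _group_arrays(mset: SpatialMapSet) -> tuple[np.ndarray, np.ndarray]:
    levels = np.unique(mset.labels)
    flat = mset.maps.reshape(mset.maps.shape[0], -1)
    return flat[mset.labels == levels[0]], flat[mset.labels == levels[1]]


def _pooled_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; 0/0 cells become NaN."""
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / denom


def _welch_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[0], x2.shape[0]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    se2 = x1.var(axis=0, ddof=1) / n1 + x2.var(axis=0, ddof=1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / np.sqrt(se2)


def pointwise_t_map(mset: SpatialMapSet, equal_var: bool = True) -> tuple[np.ndarray, int]:
    """Per-cell two-sample t map and its degrees of freedom.

    Pooled-variance t with ``df = n1 + n2 - 2`` by default (Welch optional).
    Cells with zero variance in both groups (or outside the mask) are NaN and
    excluded from clustering.
    """
    n1, n2 = mset.group_sizes
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 maps per condition")
    x1, x2 = _group_arrays(mset)
    t = (_pooled_t if equal_var else _welch_t)(x1, x2)
    t_map = t.reshape(mset.maps.shape[1:])
    t_map = np.where(mset.mask, t_map, np.nan)
    return t_map, n1 + n2 - 2


def _label_clusters(
    t_map: np.ndarray, t_crit: float, min_cells: int
) -> list[tuple[np.ndarray, float, int]]:
    """Connected suprathreshold components as (cells, mass, sign) triples."""
    finite = np.nan_to_num(t_map, nan=0.0)
    out: list[tuple[np.ndarray, float, int]] = []
    for sign in (1, -1):
        above = (sign * finite) > t_crit
        labels, n_lab = ndimage.label(above, structure=_STRUCTURE_4)
        if n_lab == 0:
            continue
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n_lab + 1))
        masses = ndimage.sum_labels(np.abs(finite), labels, index=np.arange(1, n_lab + 1))
        for lab in range(1, n_lab + 1):
            if sizes[lab - 1] >= min_cells:
                cells = np.argwhere(labels == lab)
                out.append((cells, float(masses[lab - 1]), sign))
    return out


def _max_cluster_mass(t_map: np.ndarray, t_crit: float, min_cells: int) -> float:
    """Largest cluster mass in a map; 0.0 when no cluster survives."""
    finite = np.nan_to_num(t_map, nan=0.0)
    best = 0.0
    for sign in (1, -1):
        above = (sign * finite) > t_crit
        labels, n_lab = ndimage.label(above, structure=_STRUCTURE_4)
        if n_lab == 0:
            continue
        idx = np.arange(1, n_lab + 1)
        sizes = ndimage.sum_labels(above, labels, index=idx)
        masses = ndimage.sum_labels(np.abs(finite), labels, index=idx)
        ok = sizes >= min_cells
        if np.any(ok):
            best = max(best, float(masses[ok].max()))
    return best


def form_clusters(
    t_map: np.ndarray,
    df: int,
    threshold_p: float = 0.01,
    min_cells: int = 2,
) -> list[Cluster]:
    """Clusters of adjacent suprathreshold cells.

    The cluster-forming threshold is the two-sided p = ``threshold_p``
    critical t for ``df`` degrees of freedom; positive and negative t cells
    cluster separately under 4-connectivity, and components smaller than
    ``min_cells`` (default 2 — a spatial extent threshold of 1 neighbour) are
    discarded.
    """
    t_crit = float(stats.t.ppf(1.0 - threshold_p / 2.0, df))
    return [
        Cluster(cells=cells, mass=mass, sign=sign)
        for cells, mass, sign in _label_clusters(t_map, t_crit, min_cells)
    ]


def permutation_test(
    mset: SpatialMapSet,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
    threshold_p: float = 0.01,
    min_cells: int = 2,
    equal_var: bool = True,
) -> ClusterResult:
    """Cluster-based permutation test by row-label shuffling.

    The null distribution is the maximum surviving cluster mass over each of
    ``n_perm`` random relabellings of the rows; each observed cluster gets
    ``p = (1 + #{null >= mass}) / (n_perm + 1)`` (never exactly zero).
    Deterministic for a fixed seed.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse null distribution", stacklevel=2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t_map, df = pointwise_t_map(mset, equal_var=equal_var)
    t_crit = float(stats.t.ppf(1.0 - threshold_p / 2.0, df))
    observed = _label_clusters(t_map, t_crit, min_cells)

    n = mset.maps.shape[0]
    n1, _ = mset.group_sizes
    flat = mset.maps.reshape(n, -1)
    valid = mset.mask.ravel()
    shape = mset.maps.shape[1:]
    t_fn = _pooled_t if equal_var else _welch_t

    null = np.zeros(n_perm)
    for p in range(n_perm):
        order = rng.permutation(n)
        g1, g2 = flat[order[:n1]], flat[order[n1:]]
        t_perm = t_fn(g1, g2)
        t_perm[~valid] = np.nan
        null[p] = _max_cluster_mass(t_perm.reshape(shape), t_crit, min_cells)

    clusters = []
    for cells, mass, sign in observed:
        p_val = (1.0 + float(np.sum(null >= mass))) / (n_perm + 1.0)
        clusters.append(Cluster(cells=cells, mass=mass, sign=sign, p_value=p_val))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(
        clusters=clusters,
        t_map=t_map,
        n_permutations=n_perm,
        threshold_p=threshold_p,
        df=df,
        null_max_mass=null,
    )
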