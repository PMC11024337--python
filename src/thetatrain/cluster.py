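"""Sensor-space cluster-based permutation statistics.

Implements the mass-univariate t-map -> suprathreshold clustering ->
max-cluster-mass permutation scheme for one-sample, paired and independent
designs, with channel adjacency derived from montage geometry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist

from .io_brainvision import ChannelMontage

logger = logging.getLogger(__name__)

__all__ = [
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "build_adjacency",
    "cluster_permutation_test",
]


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive channel neighbourhood relation."""

    labels: list[str]
    matrix: sp.csr_matrix  # boolean, (n_channels, n_channels)
    max_dist_mm: float

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("adjacency matrix shape does not match labels")
        if (m != m.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must be irreflexive")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def neighbors(self, label: str) -> list[str]:
        i = self.labels.index(label)
        return [self.labels[j] for j in self.matrix[i].indices]

    def mean_degree(self) -> float:
        return float(self.matrix.sum() / self.n_channels)


def build_adjacency(
    montage: ChannelMontage, max_dist_mm: float = 50.0
) -> AdjacencyGraph:
    """Channels are neighbours iff their Euclidean distance is <= threshold."""
    if len(montage) < 2:
        raise ValueError("need at least 2 channels with positions")
    dist = squareform(pdist(montage.positions))
    mat = (dist <= max_dist_mm) & ~np.eye(len(montage), dtype=bool)
    isolated = [l for l, row in zip(montage.labels, mat) if not row.any()]
    if isolated:
        logger.warning("channels with no neighbours at %g mm: %s",
                       max_dist_mm, ", ".join(isolated))
    return AdjacencyGraph(list(montage.labels), sp.csr_matrix(mat), max_dist_mm)


@dataclass
class Cluster:
    members: list[tuple]  # bin indices, (channel,) or (channel, *extra)
    size: int
    mass: float
    p: float

    @property
    def channels(self) -> set[int]:
        return {m[0] for m in self.members}


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    stat_map: np.ndarray
    n_perm: int
    tail: int
    threshold: float
    design: str
    exact: bool = False
    seed: int | None = None
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p <= alpha]


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _bin_adjacency(channel_adj: sp.csr_matrix, extra_shape: tuple[int, ...]) -> sp.csr_matrix:
    """Adjacency over flattened (channel, *extra) bins.

    Two bins are adjacent iff their channels are identical or neighbours and
    every extra coordinate differs by at most one bin.
    """
    n_ch = channel_adj.shape[0]
    adj = (channel_adj + sp.eye(n_ch, dtype=bool, format="csr")).astype(bool)
    for n in extra_shape:
        band = sp.diags(
            [np.ones(n - 1), np.ones(n), np.ones(n - 1)],
            offsets=[-1, 0, 1], dtype=bool, format="csr",
        ) if n > 1 else sp.eye(1, dtype=bool, format="csr")
        adj = sp.kron(adj, band, format="csr").astype(bool)
    adj = adj.tolil()
    adj.setdiag(False)
    return adj.tocsr()


def _find_clusters(
    stat: np.ndarray, threshold: float, bin_adj: sp.csr_matrix
) -> list[tuple[np.ndarray, float]]:
    """Connected suprathreshold components; returns (flat indices, mass)."""
    flat = stat.ravel()
    mask = flat > threshold
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = bin_adj[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for c in range(n_comp):
        members = idx[labels == c]
        out.append((members, float(flat[members].sum())))
    return out


def _max_cluster_mass(
    stat: np.ndarray, threshold: float, bin_adj: sp.csr_matrix
) -> float:
    clusters = _find_clusters(stat, threshold, bin_adj)
    return max((m for _, m in clusters), default=0.0)


def _t_one_sample_signed(data2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorised one-sample t over sign-flip patterns.

    ``data2d``: (n_subjects, n_bins); ``signs``: (n_perm, n_subjects) of +-1.
    """
    n = data2d.shape[0]
    sumsq = (data2d ** 2).sum(axis=0)  # invariant to sign flips
    means = signs @ data2d / n
    var = (sumsq / n - means ** 2) * n / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    return t


def _t_independent_indicator(
    data2d: np.ndarray, indicator: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Vectorised pooled-variance two-sample t over label permutations.

    ``indicator``: (n_perm, n_subjects) 0/1 rows with exactly ``n1`` ones
    marking group-1 membership.
    """
    total = data2d.sum(axis=0)
    total_sq = (data2d ** 2).sum(axis=0)
    s1 = indicator @ data2d
    sq1 = indicator @ (data2d ** 2)
    m1 = s1 / n1
    m2 = (total - s1) / n2
    ss = (sq1 - n1 * m1 ** 2) + ((total_sq - sq1) - n2 * m2 ** 2)
    pooled = ss / (n1 + n2 - 2)
    pooled = np.maximum(pooled, 0.0)
    denom = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (m1 - m2) / denom, 0.0)
    return t


def cluster_permutation_test(
    a: np.ndarray,
    b: np.ndarray | None = None,
    design: str = "one_sample",
    adjacency: AdjacencyGraph | None = None,
    alpha: float = 0.05,
    tail: int = 1,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test over subject-wise sensor maps.

    Parameters
    ----------
    a, b
        Arrays of shape ``(n_subjects, n_channels, *extra)``.  For
        ``one_sample`` tests, ``b`` is omitted; for ``paired`` tests, ``b``
        holds the matched condition; for ``independent`` tests, ``b`` holds
        the second group.
    design
        ``one_sample`` | ``paired`` | ``independent``.
    tail
        ``+1`` tests for positive effects, ``-1`` for negative.

    Notes
    -----
    The cluster-forming threshold is the one-tailed ``cluster_alpha``
    quantile of the t distribution at the design's degrees of freedom.
    Cluster mass is the sum of member t values; the family-wise null is the
    maximum cluster mass across permutations (sign flips for
    one-sample/paired, full label reshuffles for independent).  When the
    number of distinct permutations is at most ``n_perm`` the test switches
    to exact enumeration.
    """
    if adjacency is None:
        raise ValueError("adjacency is required")
    if tail not in (1, -1):
        raise ValueError("tail must be +1 or -1")
    if design not in ("one_sample", "paired", "independent"):
        raise ValueError(f"unknown design {design!r}")

    a = np.asarray(a, dtype=float)
    if design == "paired":
        if b is None:
            raise ValueError("paired design requires b")
        b = np.asarray(b, dtype=float)
        if b.shape != a.shape:
            raise ValueError("paired inputs must share shape")
        data = a - b
        design_kind = "flip"
    elif design == "one_sample":
        data = a
        design_kind = "flip"
    else:
        if b is None:
            raise ValueError("independent design requires b")
        b = np.asarray(b, dtype=float)
        if b.shape[1:] != a.shape[1:]:
            raise ValueError("groups must share map shape")
        design_kind = "shuffle"

    if tail == -1:
        # run the +1 machinery on negated data
        res = cluster_permutation_test(
            -a, None if b is None else -b, design=design, adjacency=adjacency,
            alpha=alpha, tail=1, cluster_alpha=cluster_alpha,
            n_perm=n_perm, seed=seed,
        )
        res.tail = -1
        res.stat_map = -res.stat_map
        for c in res.clusters:
            c.mass = -c.mass
        res.threshold = -res.threshold
        return res

    if design_kind == "flip":
        n = data.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        df = n - 1
        map_shape = data.shape[1:]
        data2d = data.reshape(n, -1)
        # same code path as the permutations so the identity pattern ties
        # the observed statistic bit-for-bit
        obs_t = _t_one_sample_signed(data2d, np.ones((1, n)))[0]
        n_distinct = 2 ** n
        exact = n_distinct <= n_perm
        if exact:
            logger.info("switching to exact enumeration of %d sign flips", n_distinct)
            signs = np.array(list(product((1.0, -1.0), repeat=n)))
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        perm_t = _t_one_sample_signed(data2d, signs)
    else:
        n1, n2 = a.shape[0], b.shape[0]
        if min(n1, n2) < 2:
            raise ValueError("need at least 2 subjects per group")
        df = n1 + n2 - 2
        map_shape = a.shape[1:]
        data2d = np.concatenate([a, b]).reshape(n1 + n2, -1)
        obs_ind = np.zeros((1, n1 + n2))
        obs_ind[0, :n1] = 1.0
        obs_t = _t_independent_indicator(data2d, obs_ind, n1, n2)[0]
        n_distinct = math.comb(n1 + n2, n1)
        exact = n_distinct <= n_perm
        if exact:
            logger.info("switching to exact enumeration of %d label splits", n_distinct)
            indicator = np.zeros((n_distinct, n1 + n2))
            for i, combo in enumerate(combinations(range(n1 + n2), n1)):
                indicator[i, list(combo)] = 1.0
        else:
            rng = np.random.default_rng(seed)
            indicator = np.zeros((n_perm, n1 + n2))
            for row in indicator:
                row[rng.choice(n1 + n2, size=n1, replace=False)] = 1.0
        perm_t = _t_independent_indicator(data2d, indicator, n1, n2)

    threshold = float(t_dist.ppf(1.0 - cluster_alpha, df))
    n_ch = map_shape[0]
    if adjacency.n_channels != n_ch:
        raise ValueError(
            f"adjacency has {adjacency.n_channels} channels, maps have {n_ch}"
        )
    bin_adj = _bin_adjacency(adjacency.matrix, map_shape[1:])

    observed = _find_clusters(obs_t, threshold, bin_adj)
    null_max = np.array([
        _max_cluster_mass(row, threshold, bin_adj) for row in perm_t
    ])

    clusters = []
    for members, mass in observed:
        # tolerance so the identity permutation always ties the observed
        # mass despite BLAS summation-order differences
        tol = 1e-9 * max(1.0, abs(mass))
        n_ge = float((null_max >= mass - tol).sum())
        if exact:
            p = n_ge / null_max.size
        else:
            p = (1.0 + n_ge) / (1.0 + null_max.size)
        coords = np.unravel_index(members, map_shape)
        member_tuples = list(zip(*(c.tolist() for c in coords)))
        clusters.append(Cluster(member_tuples, len(members), mass, p))
    clusters.sort(key=lambda c: (c.p, -abs(c.mass)))

    return ClusterResult(
        clusters=clusters,
        stat_map=obs_t.reshape(map_shape),
        n_perm=int(null_max.size),
        tail=tail,
        threshold=threshold,
        design=design,
        exact=exact,
        seed=seed,
        null_max_mass=null_max,
    )
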