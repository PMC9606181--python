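"""Hierarchical modularity: Euclidean distances between correlation
profiles, complete-linkage agglomeration, and fractional-height tree cuts.

Each region's coactivation profile is its row of the group correlation
matrix (self-correlation entry included by default).  Profiles are
hierarchically clustered with complete linkage (inter-cluster distance =
maximum pairwise distance, which guarantees monotone merge heights); the
dendrogram is cut at a fraction of its maximum merge height — 0.70 by
default — and the number of resulting modules, profiled over a grid of cut
fractions, summarises the modular structuring of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .correlation import CorrelationMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "CutProfile",
    "euclidean_distance_matrix",
    "complete_linkage",
    "tree_cut",
    "cut_profile",
    "DEFAULT_CUT_FRACTION",
    "DEFAULT_CUT_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_CUT_FRACTION = 0.70
#: Fraction grid for module-count profiles (includes the 0.70 primary cut).
DEFAULT_CUT_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


@dataclass(frozen=True)
class DistanceMatrix:
    group_label: str
    d: pd.DataFrame  # symmetric, zero diagonal
    excluded_regions: tuple[str, ...] = ()

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.d.columns)

    @property
    def values(self) -> np.ndarray:
        return self.d.to_numpy()


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree: R-1 merges of (cluster_a, cluster_b, height, size).

    Cluster ids follow the scipy convention: leaves are 0..R-1; the cluster
    formed at merge step t gets id R+t.
    """

    group_label: str
    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    @property
    def max_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0

    def linkage_matrix(self) -> np.ndarray:
        """scipy-style (R-1) x 4 linkage array."""
        return np.asarray([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaf_order(self) -> tuple[str, ...]:
        """Dendrogram display order: left subtree's leaves before the right's."""
        n = len(self.leaves)
        children = {n + t: (a, b) for t, (a, b, _h, _s) in enumerate(self.merges)}

        def walk(node: int):
            if node < n:
                yield self.leaves[node]
            else:
                a, b = children[node]
                yield from walk(a)
                yield from walk(b)

        root = n + len(self.merges) - 1 if self.merges else 0
        return tuple(walk(root))


@dataclass(frozen=True)
class CutProfile:
    group_label: str
    fractions: tuple[float, ...]
    module_counts: tuple[int, ...]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fraction": self.fractions, "n_modules": self.module_counts}
        )


def euclidean_distance_matrix(
    corr: CorrelationMatrix, include_diagonal: bool = True
) -> DistanceMatrix:
    """Pairwise Euclidean distances between correlation-profile rows.

    Regions whose correlations are entirely missing (zero-variance regions)
    are excluded first and logged, so the distance matrix is complete.  With
    ``include_diagonal=False`` the two self-correlation coordinates of each
    pair are dropped from the profiles before taking the norm.
    """
    excluded = corr.missing_regions()
    if excluded:
        logger.info(
            "group %s: excluding %d region(s) without defined correlations: %s",
            corr.group_label, len(excluded), excluded,
        )
    keep = [r for r in corr.region_names if r not in excluded]
    if len(keep) < 3:
        raise ValueError("fewer than 3 usable regions for distance computation")
    sub = corr.r.loc[keep, keep].to_numpy()
    if np.isnan(sub).any():
        raise ValueError("correlation matrix still contains missing entries")

    if include_diagonal:
        d = squareform(pdist(sub, metric="euclidean"))
    else:
        n = len(keep)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = np.ones(n, dtype=bool)
                mask[[i, j]] = False
                diff = sub[i, mask] - sub[j, mask]
                d[i, j] = d[j, i] = float(np.sqrt((diff * diff).sum()))
    frame = pd.DataFrame(d, index=keep, columns=keep)
    return DistanceMatrix(
        group_label=corr.group_label, d=frame, excluded_regions=tuple(excluded)
    )


def complete_linkage(dist: DistanceMatrix) -> Dendrogram:
    """Complete-linkage agglomeration of the distance matrix.

    At each step the pair of clusters with the smallest maximum pairwise
    distance merges; ties break on the lexicographically smallest cluster-id
    pair, so the merge order is fully deterministic.  Complete linkage is
    monotone: merge heights never decrease.
    """
    d0 = dist.values
    if not np.isfinite(d0).all():
        raise ValueError("distance matrix contains non-finite values")
    n = d0.shape[0]
    # current inter-cluster complete-linkage distances, indexed by cluster id
    dd: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = float(d0[i, j])
    active: dict[int, int] = {i: 1 for i in range(n)}  # id -> size
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dd.items(), key=lambda kv: (kv[1], kv[0]))
        size = active[a] + active[b]
        merges.append((a, b, h, size))
        del active[a], active[b]
        # complete linkage: d(new, c) = max(d(a, c), d(b, c))
        new_d = {}
        for c in active:
            da = dd[(min(a, c), max(a, c))]
            db = dd[(min(b, c), max(b, c))]
            new_d[c] = max(da, db)
        dd = {
            (i, j): v
            for (i, j), v in dd.items()
            if i not in (a, b) and j not in (a, b)
        }
        for c, v in new_d.items():
            dd[(min(c, next_id), max(c, next_id))] = v
        active[next_id] = size
        next_id += 1
    return Dendrogram(
        group_label=dist.group_label,
        leaves=tuple(dist.region_names),
        merges=tuple(merges),
    )


def tree_cut(dend: Dendrogram, fraction: float = DEFAULT_CUT_FRACTION) -> dict[str, int]:
    """Cut the dendrogram at ``fraction`` x its maximum merge height.

    Merges with height <= the cut height are kept (so fraction = 1.0 always
    yields a single module); merges strictly above the cut are undone.
    Labels are deterministic: modules are numbered by their first leaf in
    panel order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    n = len(dend.leaves)
    cut_height = fraction * dend.max_height
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (a, b, h, _s) in enumerate(dend.merges):
        if h <= cut_height:
            new = n + t
            parent[find(a)] = new
            parent[find(b)] = new
    canon: dict[int, int] = {}
    labels: dict[str, int] = {}
    for i, leaf in enumerate(dend.leaves):
        root = find(i)
        canon.setdefault(root, len(canon))
        labels[leaf] = canon[root]
    return labels


def cut_profile(
    dend: Dendrogram, fractions: tuple[float, ...] = DEFAULT_CUT_GRID
) -> CutProfile:
    """Module count at each cut fraction (fractions sorted ascending)."""
    fracs = tuple(float(f) for f in fractions)
    if list(fracs) != sorted(fracs):
        raise ValueError("fractions must be sorted ascending")
    counts = tuple(len(set(tree_cut(dend, f).values())) for f in fracs)
    return CutProfile(
        group_label=dend.group_label, fractions=fracs, module_counts=counts
    )
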