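"""Ward clustering of genotype stability-rank profiles.

Genotypes are described by their rank under each stability index (the
``*_R`` columns plus the yield rank); similarity of two genotypes is
the squared Euclidean distance between their rank vectors, and groups
are formed by Ward's minimum-variance agglomeration applied directly
to those squared distances (the classical Ward criterion).  The
Lance-Williams recurrence is implemented here rather than delegated so
that merge heights stay on the squared-distance scale and ties break
deterministically on the smallest (i, j) label pair; tests cross-check
the heights against scipy's Euclidean-scale Ward.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "Dendrogram",
    "rank_distance",
    "ward_cluster",
    "cut_clusters",
    "to_newick",
]


@dataclasses.dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: (node_a, node_b, height, size) per merge.

    Leaves are numbered 0..n-1 in input order; merge *m* creates node
    ``n + m``.  Heights are Ward merge distances on the squared-
    Euclidean scale and are nondecreasing.
    """

    merges: list[tuple[int, int, float, int]]
    labels: list

    @property
    def n(self) -> int:
        return len(self.labels)


def rank_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """Squared Euclidean distance between genotype rank profiles.

    All-NA columns are dropped with a warning; any remaining NA is an
    error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genotypes to compute distances")
    p = profiles.dropna(axis=1, how="all")
    if p.shape[1] < profiles.shape[1]:
        import warnings

        dropped = sorted(set(profiles.columns) - set(p.columns))
        warnings.warn(f"dropping all-NA rank columns {dropped}", stacklevel=2)
    x = p.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("rank profiles contain missing values")
    sq = (x**2).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2 * x @ x.T
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    d = (d + d.T) / 2
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def ward_cluster(dist: pd.DataFrame) -> Dendrogram:
    """Ward agglomeration on a squared-Euclidean distance matrix.

    Uses the Lance-Williams update
    ``d(k, i+j) = ((n_i+n_k) d_ik + (n_j+n_k) d_jk - n_k d_ij) / (n_i+n_j+n_k)``
    and always merges the currently closest pair, breaking exact ties
    on the smallest (i, j) node-id pair.
    """
    labels = list(dist.index)
    n = len(labels)
    d = dist.to_numpy(dtype=float).copy()
    sizes = {i: 1 for i in range(n)}
    active = dict(enumerate(range(n)))  # node id -> row index in d
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        ids = sorted(active)
        best = None
        for a_pos, i in enumerate(ids):
            for j in ids[a_pos + 1:]:
                dij = d[active[i], active[j]]
                if best is None or dij < best[0] or (dij == best[0] and (i, j) < (best[1], best[2])):
                    best = (dij, i, j)
        h, i, j = best
        ri, rj = active[i], active[j]
        ni, nj = sizes[i], sizes[j]
        merges.append((i, j, float(h), ni + nj))
        # Lance-Williams update into row ri
        for k in active:
            if k in (i, j):
                continue
            rk = active[k]
            nk = sizes[k]
            d[ri, rk] = d[rk, ri] = (
                (ni + nk) * d[ri, rk] + (nj + nk) * d[rj, rk] - nk * h
            ) / (ni + nj + nk)
        del active[i], active[j], sizes[i], sizes[j]
        active[next_id] = ri
        sizes[next_id] = ni + nj
        next_id += 1
    return Dendrogram(merges, labels)


def cut_clusters(dendro: Dendrogram, k: int) -> pd.Series:
    """Labels for the k-group partition (cut after the first n-k merges).

    Group ids are 1..k, numbered by the smallest leaf index they
    contain.
    """
    n = dendro.n
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    parent = {}
    for m, (a, b, _, _) in enumerate(dendro.merges[: n - k]):
        parent[a] = parent[b] = n + m

    def root(x):
        while x in parent:
            x = parent[x]
        return x

    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(root(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=min)
    out = np.empty(n, dtype=int)
    for gid, leaves in enumerate(ordered, start=1):
        out[leaves] = gid
    return pd.Series(out, index=pd.Index(dendro.labels), name="cluster")


def to_newick(dendro: Dendrogram) -> str:
    """Newick export with branch lengths from merge heights.

    A child's branch length is the height difference between its
    parent's merge and its own (leaves sit at height 0).
    """
    n = dendro.n
    height = {i: 0.0 for i in range(n)}
    node = {i: str(dendro.labels[i]) for i in range(n)}
    for m, (a, b, h, _) in enumerate(dendro.merges):
        nid = n + m
        height[nid] = h
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
    return node[n + len(dendro.merges) - 1] + ";"
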