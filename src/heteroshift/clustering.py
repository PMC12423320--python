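"""Unsupervised hierarchical clustering of methylation profiles.

Manhattan distance with pairwise-complete handling of missing values and
agglomerative average linkage (UPGMA), the combination used to group
methylome samples by mutation type and heteroplasmy load.  The linkage is
written here rather than delegated so that ties merge deterministically by
smallest leaf index, making dendrograms reproducible across platforms; on
tie-free input it agrees with any standard UPGMA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = ["LinkageTree", "manhattan_distance_matrix", "average_linkage",
           "cut_to_groups", "to_newick", "plot_heatmap"]


@dataclass(frozen=True)
class LinkageTree:
    """UPGMA merge history.

    Leaves are numbered 0..n-1 in input order; merge t creates cluster
    n+t.  Each merge is (node_i, node_j, height, size) with node_i < node_j
    and size the number of leaves under the new cluster.
    """

    merges: tuple
    leaf_labels: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)


def manhattan_distance_matrix(data, axis: str = "samples",
                              min_shared_fraction: float = 0.5) -> pd.DataFrame:
    """Pairwise Manhattan distances between samples (or probes).

    Missing values are handled pairwise-complete: the absolute-difference
    sum runs over coordinates non-missing in both entities and is rescaled
    by (total coordinates / shared coordinates).  A pair sharing fewer than
    ``min_shared_fraction`` of coordinates (or none at all) is an error.
    """
    if isinstance(data, BetaMatrix):
        df = data.values
    else:
        df = data
    if axis == "samples":
        X = df.to_numpy(dtype=float).T
        labels = list(df.columns)
    elif axis == "probes":
        X = df.to_numpy(dtype=float)
        labels = list(df.index)
    else:
        raise ValueError("axis must be 'samples' or 'probes'")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 entities")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(X[i]) & ~np.isnan(X[j])
            used = int(ok.sum())
            if used == 0:
                raise ValueError(
                    f"entities {labels[i]!r} and {labels[j]!r} share no "
                    "non-missing coordinates")
            if used < min_shared_fraction * p:
                raise ValueError(
                    f"entities {labels[i]!r} and {labels[j]!r} share only "
                    f"{used}/{p} coordinates")
            d = float(np.abs(X[i, ok] - X[j, ok]).sum()) * (p / used)
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def average_linkage(dist) -> LinkageTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the arithmetic mean over all cross pairs
    (implemented by the size-weighted Lance-Williams update).  When several
    pairs share the minimum distance, the pair whose representative
    (smallest original leaf index per cluster) is lexicographically
    smallest merges first.
    """
    if isinstance(dist, pd.DataFrame):
        labels = tuple(str(c) for c in dist.columns)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        labels = tuple(str(i) for i in range(D.shape[0]))
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]

    # active cluster state: id -> (size, smallest original leaf index)
    size = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(D[i, j])

    def pairkey(i, j):
        return (i, j) if i < j else (j, i)

    merges = []
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1],
                            min(rep[kv[0][0]], rep[kv[0][1]]),
                            max(rep[kv[0][0]], rep[kv[0][1]])))
        (i, j), height = best
        merges.append((i, j, height, size[i] + size[j]))
        # Lance-Williams average-linkage update
        for k in active:
            if k in (i, j):
                continue
            dik = d.pop(pairkey(i, k))
            djk = d.pop(pairkey(j, k))
            d[(k, next_id)] = (  # k < next_id always: new ids only grow
                (size[i] * dik + size[j] * djk) / (size[i] + size[j]))
        del d[(i, j)]
        size[next_id] = size[i] + size[j]
        rep[next_id] = min(rep[i], rep[j])
        active.discard(i)
        active.discard(j)
        active.add(next_id)
        next_id += 1
    return LinkageTree(merges=tuple(merges), leaf_labels=labels)


def cut_to_groups(tree: LinkageTree, k: int) -> np.ndarray:
    """Cut the tree into k groups by removing the k-1 highest merges.

    Returns an integer label per leaf (input order); group numbers are
    assigned stably by each group's leftmost leaf.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t, (i, j, _, _) in enumerate(tree.merges[: n - k]):
        new = n + t
        parent[find(i)] = new
        parent[find(j)] = new

    roots = [find(i) for i in range(n)]
    order = {}
    labels = np.empty(n, dtype=int)
    for leaf in range(n):
        r = roots[leaf]
        if r not in order:
            order[r] = len(order)
        labels[leaf] = order[r]
    return labels


def to_newick(tree: LinkageTree) -> str:
    """Newick string with merge heights as cumulative node depths.

    A child's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so root-to-leaf path lengths equal the final
    merge height — the ultrametric reading of a UPGMA dendrogram.
    """
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    node = {i: tree.leaf_labels[i] for i in range(n)}
    for t, (i, j, h, _) in enumerate(tree.merges):
        new = n + t
        bi = h - height[i]
        bj = h - height[j]
        node[new] = f"({node[i]}:{bi:.10g},{node[j]}:{bj:.10g})"
        height[new] = h
    return node[n + len(tree.merges) - 1] + ";" if tree.merges else \
        node[0] + ";"


def plot_heatmap(matrix: BetaMatrix, tree: LinkageTree, path) -> None:
    """Minimal beta-value heatmap with samples in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = _leaf_order(tree)
    vals = matrix.values.iloc[:, order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(vals.to_numpy(dtype=float), aspect="auto",
                   cmap="RdYlGn_r", vmin=0, vmax=1)
    ax.set_xticks(range(len(vals.columns)))
    ax.set_xticklabels(vals.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="beta value")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _leaf_order(tree: LinkageTree) -> list:
    n = tree.n_leaves
    children = {n + t: (i, j) for t, (i, j, _, _) in enumerate(tree.merges)}
    root = n + len(tree.merges) - 1 if tree.merges else 0

    order = []
    stack = [root]
    while stack:
        x = stack.pop()
        if x < n:
            order.append(x)
        else:
            i, j = children[x]
            stack.append(j)
            stack.append(i)
    return order
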