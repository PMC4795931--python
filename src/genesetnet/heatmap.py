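"""Binary gene-by-theme association matrices and their ordering by
average-linkage (UPGMA) hierarchical clustering on Euclidean distances.

Each gene's row is its 0/1 functional-association profile; the Euclidean
distance between two profiles is sqrt(Hamming distance).  UPGMA here is the
unweighted flavour: the distance between two clusters is the size-weighted
mean of the original pairwise distances between their leaves.  Clustering is
implemented in-package because a fully deterministic tie-break (smallest
(row-index, row-index) pair) and leaf-order convention (lower-index cluster
kept left) are part of the output contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .types import GenesetnetError

log = logging.getLogger(__name__)


def build_binary_matrix(pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """0/1 gene-by-theme matrix from (gene_id, theme_id) association pairs.

    Rows and columns are ordered by first appearance; duplicate pairs
    collapse silently; genes or themes with no pair never appear (so there
    are no all-zero rows).
    """
    genes: dict[str, int] = {}
    themes: dict[str, int] = {}
    cells: set[tuple[str, str]] = set()
    for g, t in pairs:
        genes.setdefault(g, len(genes))
        themes.setdefault(t, len(themes))
        cells.add((g, t))
    m = np.zeros((len(genes), len(themes)), dtype=int)
    for g, t in cells:
        m[genes[g], themes[t]] = 1
    return pd.DataFrame(m, index=list(genes), columns=list(themes))


def matrix_from_file(path: Union[str, Path], sep: str = "\t") -> pd.DataFrame:
    """Read a user-supplied matrix (first row = theme ids, first column =
    gene ids); nonzero values are coerced to 1 with a warning."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        log.warning("%s: nonzero values coerced to 1", path)
    out = (vals != 0).astype(int)
    return pd.DataFrame(out, index=df.index.astype(str), columns=df.columns.astype(str))


def euclidean_distances(m: pd.DataFrame) -> np.ndarray:
    """Square symmetric Euclidean distance matrix over rows (genes)."""
    if len(m) < 2:
        raise GenesetnetError("need at least 2 rows to compute distances")
    return squareform(pdist(m.to_numpy(dtype=float), metric="euclidean"))


@dataclass
class Dendrogram:
    """UPGMA merge history over n leaves.

    ``merges`` lists (cluster_i, cluster_j, height, new_cluster_id) with
    leaves numbered 0..n-1 and internal clusters n, n+1, ...; ``leaf_order``
    is the left-to-right traversal permutation of the input row indices.
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    labels: Optional[list[str]] = None

    def ordered_labels(self) -> list[str]:
        if self.labels is None:
            return [str(i) for i in self.leaf_order]
        return [self.labels[i] for i in self.leaf_order]

    def to_newick(self) -> str:
        """Newick string with merge heights as node heights (branch lengths
        are parent height minus child height)."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        node: dict[int, str] = {
            i: (self.labels[i] if self.labels else str(i)) for i in range(self.n_leaves)
        }
        last = None
        for i, j, h, new in self.merges:
            # ultrametric tree: every child of a merge at height h sits at h/2
            left = f"{node[i]}:{h / 2 - height[i]:.6g}"
            right = f"{node[j]}:{h / 2 - height[j]:.6g}"
            node[new] = f"({left},{right})"
            height[new] = h / 2
            last = new
        if last is None:  # single leaf
            return f"{node[0]};"
        return f"{node[last]};"


def average_linkage(d: np.ndarray, labels: Optional[Sequence[str]] = None) -> Dendrogram:
    """Unweighted average-linkage (UPGMA) clustering of a distance matrix.

    At each step the pair of clusters with the smallest average
    inter-cluster distance merges; the average is the mean of the original
    leaf-to-leaf distances (size-weighted Lance–Williams update).  Ties are
    broken by the smallest (min-leaf-index, min-leaf-index) pair, and the
    cluster containing the lower leaf index is kept on the left, making the
    leaf order deterministic.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise GenesetnetError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise GenesetnetError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    if labels is not None and len(labels) != n:
        raise GenesetnetError("labels length must match matrix size")

    # active clusters: id -> (set of leaf indices, min leaf index, ordered leaves)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    rep: dict[int, int] = {i: i for i in range(n)}  # min leaf index, for tie-breaks
    dist: dict[tuple[int, int], float] = {}
    active = set(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i, j]

    def dget(a: int, b: int) -> float:
        return dist[(a, b) if a < b else (b, a)]

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                key = (dget(a, b), min(rep[a], rep[b]), max(rep[a], rep[b]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_h, _ri, _rj), a, b = best
        h = dget(a, b)
        # keep the cluster with the lower leaf index on the left
        left, right = (a, b) if rep[a] <= rep[b] else (b, a)
        new = next_id
        next_id += 1
        na, nb = len(members[a]), len(members[b])
        for c in active:
            if c in (a, b):
                continue
            dist[(min(c, new), max(c, new))] = (
                na * dget(a, c) + nb * dget(b, c)
            ) / (na + nb)
        active -= {a, b}
        active.add(new)
        members[new] = members[left] + members[right]
        rep[new] = min(rep[a], rep[b])
        merges.append((left, right, h, new))

    root = next(iter(active))
    return Dendrogram(
        n_leaves=n,
        merges=merges,
        leaf_order=members[root],
        labels=list(labels) if labels is not None else None,
    )


def cluster_rows(m: pd.DataFrame) -> Dendrogram:
    """UPGMA dendrogram over the rows of a binary association matrix."""
    return average_linkage(euclidean_distances(m), labels=list(m.index))


def export_matrix(
    m: pd.DataFrame,
    dendrogram: Optional[Dendrogram] = None,
    sort: Literal["cluster", "name", "none"] = "cluster",
    path: Optional[Union[str, Path]] = None,
    image_path: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Order the matrix rows and optionally write TSV and a heatmap image.

    sort="cluster" uses the dendrogram leaf order, "name" lexicographic row
    ids, "none" the input order.
    """
    if sort == "cluster":
        if dendrogram is None:
            dendrogram = cluster_rows(m)
        ordered = m.loc[dendrogram.ordered_labels()]
    elif sort == "name":
        ordered = m.loc[sorted(m.index)]
    elif sort == "none":
        ordered = m
    else:
        raise GenesetnetError(f"unknown sort mode {sort!r}")
    if path is not None:
        ordered.to_csv(path, sep="\t", index_label="gene_id")
    if image_path is not None:
        _plot_heatmap(ordered, image_path)
    return ordered


def _plot_heatmap(m: pd.DataFrame, path: Union[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(3, 0.3 * m.shape[1] + 2), max(3, 0.25 * m.shape[0] + 1))
    )
    ax.pcolormesh(m.to_numpy(), cmap="Greys", edgecolors="lightgrey", linewidth=0.3)
    ax.set_xticks(np.arange(m.shape[1]) + 0.5, m.columns, rotation=90, fontsize=7)
    ax.set_yticks(np.arange(m.shape[0]) + 0.5, m.index, fontsize=7)
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
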