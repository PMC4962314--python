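"""Average-linkage clustering and heatmap rendering of enrichment matrices.

Rows (cell types) and columns (loci) of the -ln p matrix are clustered by
UPGMA (average linkage) on Euclidean distances, and the matrix is drawn
with both axes in dendrogram leaf order under a white-to-red colormap, so
increasingly significant tests show increasingly red.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from chromenrich.enrichment import EnrichmentMatrix


@dataclass
class DistanceMatrix:
    """Labeled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class Dendrogram:
    """A UPGMA merge tree in scipy linkage form plus its leaf labels."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1) x 4 linkage matrix; empty for n == 1

    @property
    def leaf_order(self) -> list[str]:
        if len(self.labels) == 1:
            return list(self.labels)
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2] if self.linkage.size else np.empty(0)

    def to_newick(self) -> str:
        """Newick serialization with branch lengths from merge heights."""
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def euclidean_distances(m: EnrichmentMatrix, axis: str = "rows") -> DistanceMatrix:
    """Pairwise Euclidean distances between row or column vectors."""
    if axis not in ("rows", "cols"):
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    df = m.values if axis == "rows" else m.values.T
    labels = list(df.index)
    if len(labels) == 1:
        warnings.warn("only one vector along the requested axis; degenerate 1x1 distances")
        return DistanceMatrix(labels=labels, d=np.zeros((1, 1)))
    d = squareform(pdist(df.to_numpy(), metric="euclidean"))
    return DistanceMatrix(labels=labels, d=d)


def average_linkage(d: DistanceMatrix) -> Dendrogram:
    """UPGMA merge tree: each step joins the pair of clusters with the
    smallest average inter-cluster distance."""
    if len(d.labels) == 1:
        return Dendrogram(labels=list(d.labels), linkage=np.empty((0, 4)))
    Z = hierarchy.linkage(squareform(d.d, checks=False), method="average")
    return Dendrogram(labels=list(d.labels), linkage=Z)


def render_heatmap(
    m: EnrichmentMatrix,
    row_tree: Dendrogram | None = None,
    col_tree: Dendrogram | None = None,
    path: str = "heatmap.png",
) -> str:
    """Render the matrix with axes in dendrogram leaf order.

    White encodes 0 (-ln q of a non-significant test); fully saturated
    red encodes the matrix maximum.  Returns the written path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    df = m.values
    if row_tree is not None:
        if set(row_tree.labels) != set(df.index):
            raise ValueError("row tree leaves do not match matrix rows")
        df = df.loc[row_tree.leaf_order]
    if col_tree is not None:
        if set(col_tree.labels) != set(df.columns):
            raise ValueError("column tree leaves do not match matrix columns")
        df = df[col_tree.leaf_order]

    cmap = LinearSegmentedColormap.from_list("white_red", ["#ffffff", "#cc0000"])
    vmax = float(df.to_numpy().max())
    fig_w = max(4.0, 0.4 * df.shape[1] + 2)
    fig_h = max(3.0, 0.3 * df.shape[0] + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(df.to_numpy(), cmap=cmap, vmin=0.0, vmax=vmax if vmax > 0 else 1.0,
                   aspect="auto", interpolation="nearest")
    ax.set_xticks(range(df.shape[1]), labels=df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(df.shape[0]), labels=df.index, fontsize=7)
    label = "-ln q" if m.scale == "neg_ln_q" else "-ln p"
    fig.colorbar(im, ax=ax, label=label, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)
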