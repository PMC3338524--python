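"""Two-dimensional clustering and rendering of the status matrix.

The species x category status matrix (+1 enriched, 0 neither, -1
impoverished, NaN no-data) is clustered hierarchically on rows and
columns independently with Euclidean distance (missing cells imputed as 0
for distance purposes only) and rendered as a three-colour heatmap with
marginal dendrograms.  The reordered matrix is also written as TSV so the
figure is fully inspectable as text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_LINKAGE = "complete"

STATUS_COLORS = {
    1.0: "#b2182b",   # enriched
    0.0: "#f7f7f7",   # neither
    -1.0: "#2166ac",  # impoverished
    "missing": "#bdbdbd",
}


@dataclass
class ClusterResult:
    matrix: pd.DataFrame          # input matrix, label-sorted
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    dropped_rows: list[str]
    dropped_cols: list[str]
    imputed_cells: int

    @property
    def ordered(self) -> pd.DataFrame:
        return self.matrix.loc[self.row_order, self.col_order]


def _axis_linkage(values: np.ndarray, labels: list[str], method: str):
    if values.shape[0] < 2:
        return None, list(labels)
    link = hierarchy.linkage(pdist(values, metric="euclidean"), method=method)
    order = hierarchy.leaves_list(link)
    return link, [labels[i] for i in order]


def cluster_matrix(
    matrix: pd.DataFrame, *, method: str = DEFAULT_LINKAGE
) -> ClusterResult:
    """Cluster rows and columns of a status matrix.

    Rows/columns that are entirely no-data are dropped (reported in the
    result).  Labels are sorted before clustering so the outcome depends
    only on cell values and labels, never on input ordering; remaining
    ties in the dendrogram follow that deterministic label order.
    """
    m = matrix.sort_index(axis=0).sort_index(axis=1)
    dropped_rows = [str(i) for i in m.index[m.isna().all(axis=1)]]
    dropped_cols = [str(c) for c in m.columns[m.isna().all(axis=0)]]
    m = m.drop(index=dropped_rows, columns=dropped_cols)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns with data")
    imputed = int(m.isna().sum().sum())
    filled = m.fillna(0.0)
    row_link, row_order = _axis_linkage(
        filled.to_numpy(), [str(i) for i in m.index], method
    )
    col_link, col_order = _axis_linkage(
        filled.to_numpy().T, [str(c) for c in m.columns], method
    )
    return ClusterResult(
        matrix=m,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        dropped_rows=dropped_rows,
        dropped_cols=dropped_cols,
        imputed_cells=imputed,
    )


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Export a SciPy linkage as a Newick string with merge heights."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        blen = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{blen:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{blen:.6g}"

    return walk(tree, tree.dist) + ";"


def write_ordered_matrix(result: ClusterResult, path: str | Path) -> None:
    out = result.ordered.copy()
    out.index.name = "species"
    out.to_csv(path, sep="\t", float_format="%.0f", na_rep="NA")


def render_heatmap(
    result: ClusterResult,
    path: str | Path,
    *,
    tsv_path: str | Path | None = None,
    title: str = "Functional-divergence enrichment status",
) -> None:
    """Draw the clustered heatmap (three statuses + no-data colour).

    Writes an image (format from the file suffix) and, when ``tsv_path``
    is given, the reordered matrix as TSV.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    data = result.ordered.to_numpy(dtype=float)
    cmap = ListedColormap(
        [STATUS_COLORS[-1.0], STATUS_COLORS[0.0], STATUS_COLORS[1.0]]
    )
    cmap.set_bad(STATUS_COLORS["missing"])
    norm = BoundaryNorm([-1.5, -0.5, 0.5, 1.5], cmap.N)

    n_rows, n_cols = data.shape
    fig = plt.figure(figsize=(max(6, 0.35 * n_cols + 3), max(5, 0.22 * n_rows + 2)))
    grid = fig.add_gridspec(
        2, 2, width_ratios=[1, 4], height_ratios=[1, 4], wspace=0.02, hspace=0.02
    )

    if result.col_linkage is not None:
        ax_top = fig.add_subplot(grid[0, 1])
        hierarchy.dendrogram(
            result.col_linkage, ax=ax_top, no_labels=True, color_threshold=0,
            above_threshold_color="k",
        )
        ax_top.axis("off")
    if result.row_linkage is not None:
        ax_left = fig.add_subplot(grid[1, 0])
        hierarchy.dendrogram(
            result.row_linkage, ax=ax_left, orientation="left", no_labels=True,
            color_threshold=0, above_threshold_color="k",
        )
        ax_left.axis("off")
        ax_left.invert_yaxis()

    ax = fig.add_subplot(grid[1, 1])
    ax.imshow(
        np.ma.masked_invalid(data), aspect="auto", cmap=cmap, norm=norm,
        interpolation="nearest",
    )
    ax.set_xticks(range(n_cols), result.col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(n_rows), result.row_order, fontsize=6)
    ax.yaxis.tick_right()
    ax.set_title(title, fontsize=10)
    ax.legend(
        handles=[
            Patch(color=STATUS_COLORS[1.0], label="enriched"),
            Patch(color=STATUS_COLORS[0.0], label="neither"),
            Patch(color=STATUS_COLORS[-1.0], label="impoverished"),
            Patch(color=STATUS_COLORS["missing"], label="no data"),
        ],
        loc="upper left", bbox_to_anchor=(1.08, 1), fontsize=7, frameon=False,
    )
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    if tsv_path is not None:
        write_ordered_matrix(result, tsv_path)
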