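"""Per-node heatmaps over two experimental dimensions, with optional
hierarchical clustering and optimal leaf ordering of the axes.

Each observed node can carry a small heatmap: for two chosen dimensions among
{individual, cell_type, condition, dosage} the grid cell (r, c) at timepoint t
is the mean of the node's channel over the two *unselected* dimensions.

Axis ordering uses average-linkage agglomerative clustering on per-label
profiles (the concatenation of that label's grid values across all
timepoints, so the ordering reflects temporal dynamics) followed by optimal
leaf ordering: among the 2^(n-1) leaf sequences reachable by flipping the
dendrogram's internal nodes, the one minimizing the summed distance between
adjacent leaves, found by dynamic programming over subtree end-leaf pairs.
Ties are broken lexicographically by label so orderings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .data import DimensionIndex, MeasurementTable
from .errors import ContractError

HEATMAP_DIMS = ("individual", "cell_type", "condition", "dosage")


@dataclass
class HeatmapGrid:
    """A node's 2-D value grid per timepoint plus axis orderings.

    ``values[t]`` is a |rows| x |cols| float array with NaN for missing
    cells; ``row_order``/``col_order`` are permutations of the label index
    ranges (identity until :func:`order_axes` is applied).
    """

    node_id: str
    dim1: str
    dim2: str
    row_labels: list[str]
    col_labels: list[str]
    values: dict[float, np.ndarray]
    row_order: list[int] = field(default_factory=list)
    col_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.row_order:
            self.row_order = list(range(len(self.row_labels)))
        if not self.col_order:
            self.col_order = list(range(len(self.col_labels)))

    def ordered(self, t: float) -> np.ndarray:
        return self.values[t][np.ix_(self.row_order, self.col_order)]

    def grand_mean(self, t: float) -> float:
        """Mean over all present cells at t (both heatmap dims collapsed)."""
        g = self.values[t]
        return float(np.nanmean(g)) if np.isfinite(g).any() else float("nan")


def build_heatmap(table: MeasurementTable, index: DimensionIndex, node_id: str,
                  channel: str, dim1: str, dim2: str) -> HeatmapGrid:
    """Grid for one node: cell (r, c, t) = mean of the node's channel over
    the two unselected dimensions at that label pair and timepoint."""
    if dim1 == dim2:
        raise ContractError("heatmap dimensions must differ")
    for d in (dim1, dim2):
        if d not in HEATMAP_DIMS:
            raise ContractError(f"heatmap dimension must be one of {HEATMAP_DIMS}")
    row_labels = [str(x) for x in index.labels(dim1)]
    col_labels = [str(x) for x in index.labels(dim2)]
    sub = table.df[table.df["channel"] == channel]
    grouped = sub.groupby([dim1, dim2, "timepoint"], sort=False, observed=True)[
        "value"].mean()
    times = sorted(index.timepoints)
    values: dict[float, np.ndarray] = {}
    for t in times:
        grid = np.full((len(row_labels), len(col_labels)), np.nan)
        for r, rl in enumerate(row_labels):
            for c, cl in enumerate(col_labels):
                key = (rl, cl, t)
                if key in grouped.index:
                    grid[r, c] = grouped.loc[key]
        values[t] = grid
    return HeatmapGrid(node_id=node_id, dim1=dim1, dim2=dim2,
                       row_labels=row_labels, col_labels=col_labels, values=values)


# ---------------------------------------------------------------------------
# clustering


def axis_profiles(grid: HeatmapGrid, axis: str = "rows") -> tuple[list[str], np.ndarray]:
    """Per-label clustering profiles: concatenation over timepoints of the
    label's grid values. NaNs are imputed with the profile mean (for
    clustering only; the painted grid keeps showing no-data)."""
    times = sorted(grid.values)
    if axis == "rows":
        labels = grid.row_labels
        mats = [grid.values[t] for t in times]
        prof = np.concatenate(mats, axis=1)
    elif axis == "cols":
        labels = grid.col_labels
        mats = [grid.values[t].T for t in times]
        prof = np.concatenate(mats, axis=1)
    else:
        raise ContractError("axis must be 'rows' or 'cols'")
    prof = prof.astype(float).copy()
    for i in range(prof.shape[0]):
        row = prof[i]
        if np.isnan(row).any():
            m = np.nanmean(row) if np.isfinite(row).any() else 0.0
            row[np.isnan(row)] = m
    return list(labels), prof


def cluster(profiles: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[int]]:
    """Average-linkage agglomerative clustering over Euclidean distances.

    Leaves are presented to the linkage in lexicographic label order so that
    zero-distance merge ties resolve deterministically; the returned linkage
    matrix is over that sorted leaf order (see :func:`optimal_leaf_order`).
    """
    if len(labels) < 2:
        raise ContractError("clustering needs at least 2 leaves")
    order = sorted(range(len(labels)), key=lambda i: labels[i])
    return linkage(profiles[order], method="average", metric="euclidean"), order


def ordering_cost(order: list[int], dist: np.ndarray) -> float:
    """Sum of distances between adjacent leaves in the given order."""
    return float(sum(dist[a, b] for a, b in zip(order, order[1:])))


def optimal_leaf_order(Z: np.ndarray, dist: np.ndarray,
                       labels: list[str] | None = None) -> list[int]:
    """Best leaf sequence of the dendrogram ``Z`` under flips.

    Dynamic program over (subtree, left end-leaf, right end-leaf): for a
    merge of subtrees A and B every ordering places one of them on the left,
    and the junction cost is dist[right end of left part, left end of right
    part]. Runs in polynomial time; ties (equal cost) are broken by the
    lexicographically smallest label sequence, falling back to leaf indices.
    """
    n = dist.shape[0]
    if n == 1:
        return [0]
    keys = labels if labels is not None else [str(i) for i in range(n)]

    # best[(v, l, r)] = (cost, order tuple) for subtree v laid out l ... r
    best: list[dict[tuple[int, int], tuple[float, tuple[int, ...]]]] = []

    root, nodes = to_tree(Z, rd=True)
    for v in nodes:
        if v.is_leaf():
            best.append({(v.id, v.id): (0.0, (v.id,))})
        else:
            left = best[v.left.id]
            right = best[v.right.id]
            table: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
            # A on the left, B on the right — and the flip
            for first, second in ((left, right), (right, left)):
                for (l1, r1), (c1, o1) in first.items():
                    for (l2, r2), (c2, o2) in second.items():
                        cost = c1 + dist[r1, l2] + c2
                        cand = (cost, o1 + o2)
                        key = (l1, r2)
                        cur = table.get(key)
                        if cur is None or _better(cand, cur, keys):
                            table[key] = cand
            best.append(table)

    entries = list(best[root.id].values())
    winner = entries[0]
    for cand in entries[1:]:
        if _better(cand, winner, keys):
            winner = cand
    return list(winner[1])


def _better(cand: tuple[float, tuple[int, ...]], cur: tuple[float, tuple[int, ...]],
            keys: list[str]) -> bool:
    if cand[0] < cur[0] - 1e-12:
        return True
    if cand[0] > cur[0] + 1e-12:
        return False
    return [keys[i] for i in cand[1]] < [keys[i] for i in cur[1]]


def order_axes(grid: HeatmapGrid, rows: bool = True, cols: bool = False) -> HeatmapGrid:
    """Cluster and optimally order the requested axes of a heatmap in place.

    Axes with fewer than 2 labels are left in input order. Returns the grid.
    """
    for axis, flag in (("rows", rows), ("cols", cols)):
        labels_all = grid.row_labels if axis == "rows" else grid.col_labels
        if not flag or len(labels_all) < 2:
            continue
        labels, prof = axis_profiles(grid, axis)
        Z, sort_order = cluster(prof, labels)
        sorted_labels = [labels[i] for i in sort_order]
        dist = squareform(pdist(prof[sort_order], metric="euclidean"))
        leaf_perm = optimal_leaf_order(Z, dist, sorted_labels)
        perm = [sort_order[i] for i in leaf_perm]  # back to original indices
        if axis == "rows":
            grid.row_order = perm
        else:
            grid.col_order = perm
    return grid


def build_node_heatmaps(table: MeasurementTable, index: DimensionIndex, linkmap,
                        dim1: str, dim2: str, cluster_rows: bool = False,
                        cluster_cols: bool = False) -> dict[str, HeatmapGrid]:
    """Heatmaps for every channel-linked node, keyed by node id."""
    out: dict[str, HeatmapGrid] = {}
    for link in linkmap.channel_links:
        grid = build_heatmap(table, index, link.node_id, link.channel, dim1, dim2)
        if cluster_rows or cluster_cols:
            order_axes(grid, rows=cluster_rows, cols=cluster_cols)
        out[link.node_id] = grid
    return out
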