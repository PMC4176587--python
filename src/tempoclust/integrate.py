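"""Cross-study integration of expression-response comparisons.

Each study contributes one column of per-gene log2 ratios (case vs its
own matched control) plus a per-gene significance flag taken from the
original study's own criteria.  Harmonisation proceeds in four steps:

1. quantile normalization across the studies that supply complete data,
   forcing identical value distributions so no single experiment
   dominates;
2. sign-preserving piecewise-linear scaling of every study to a common
   range, keeping the within-study rank order of responses and the
   up/down semantics of the log2 ratio (zero stays zero);
3. selection of genes recurrently significant — flagged in at least
   ``min_count`` of the comparisons;
4. hierarchical clustering (Euclidean distance, complete linkage) of the
   selected gene x study matrix on both axes, exported as an ordered
   matrix with dendrogram leaf orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

DEFAULT_RANGE = (-4.03, 4.07)


@dataclass
class StudyComparison:
    """One meta-analysis column: per-gene log2 ratio vs matched control."""

    study_id: str
    ratios: pd.Series
    significant: pd.Series
    note: str = ""

    def __post_init__(self) -> None:
        present = self.ratios.dropna()
        if not np.isfinite(present.to_numpy(dtype=float)).all():
            raise ValueError(f"study {self.study_id!r}: non-finite log2 ratios")
        self.significant = self.significant.reindex(self.ratios.index, fill_value=False)


@dataclass
class IntegratedMatrix:
    """Harmonised, selected and ordered gene x study matrix."""

    matrix: pd.DataFrame          # selected genes x studies, dendrogram order
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list[str]
    col_order: list[str]
    significance_counts: pd.Series
    selected_genes: list[str] = field(default_factory=list)
    # labels in linkage input order (leaf id -> label), for newick export
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)


def quantile_normalize(M: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common reference distribution.

    The reference is the per-rank mean of the column-sorted values; ties
    within a column receive the mean of the reference values at the tied
    ranks.  Requires complete data (no missing values).
    """
    if M.isna().any().any():
        raise ValueError("quantile_normalize requires complete data (no NaN)")
    if M.shape[1] == 1:
        warnings.warn("single column: quantile normalization is a no-op")
        return M.copy()
    vals = M.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average the reference values over tied input values
        tied = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=M.index, columns=M.columns)


def scale_to_range(values, target: tuple[float, float] = DEFAULT_RANGE):
    """Sign-preserving piecewise-linear map of log2 ratios onto [lo, hi].

    Positive values are multiplied by hi/max, negative values by lo/min
    (both factors positive), and zero maps to zero, so a ratio keeps its
    up/down direction and the within-study rank order of genes is
    unchanged.  All-zero input is returned unchanged.
    """
    lo, hi = target
    if not (lo < 0 < hi):
        raise ValueError(f"target range must straddle zero, got {target}")
    is_series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    out = arr.copy()
    pos = finite & (arr > 0)
    neg = finite & (arr < 0)
    if pos.any():
        out[pos] = arr[pos] * (hi / arr[pos].max())
    if neg.any():
        out[neg] = arr[neg] * (lo / arr[neg].min())
    if is_series:
        return pd.Series(out, index=values.index, name=values.name)
    return out


def select_recurrent(
    studies: list[StudyComparison], min_count: int = 2
) -> tuple[list[str], pd.Series]:
    """Genes flagged significant in at least ``min_count`` comparisons."""
    if len(studies) < 2:
        raise ValueError("need at least 2 studies")
    flags = pd.DataFrame({s.study_id: s.significant for s in studies}).fillna(False)
    counts = flags.sum(axis=1).astype(int)
    counts.name = "significant_in"
    selected = list(counts.index[counts >= min_count])
    return selected, counts


def hclust_complete(M: pd.DataFrame, axis: str = "rows") -> tuple[np.ndarray, list]:
    """Complete-linkage agglomeration (Euclidean distance) on one axis.

    Missing values are imputed to 0 with a warning before distance
    computation.  Returns the merge tree (scipy linkage matrix, heights
    non-decreasing) and the dendrogram leaf order as labels.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = M if axis == "rows" else M.T
    if data.shape[0] < 2:
        raise ValueError(f"need at least 2 items to cluster, got {data.shape[0]}")
    vals = data.to_numpy(dtype=float)
    if np.isnan(vals).any():
        warnings.warn(f"{int(np.isnan(vals).sum())} missing values imputed to 0 for clustering")
        vals = np.nan_to_num(vals, nan=0.0)
    Z = hierarchy.linkage(vals, method="complete", metric="euclidean")
    order = [data.index[i] for i in hierarchy.leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def subtree_leaf_sets(Z: np.ndarray, n_leaves: int) -> list[set[int]]:
    """Leaf index set under every internal node of a linkage tree."""
    sets: dict[int, set[int]] = {i: {i} for i in range(n_leaves)}
    out = []
    for i, (a, b, _h, _n) in enumerate(Z):
        merged = sets[int(a)] | sets[int(b)]
        sets[n_leaves + i] = merged
        out.append(merged)
    return out


def build_heatmap_matrix(
    studies: list[StudyComparison],
    min_count: int = 2,
    target_range: tuple[float, float] = DEFAULT_RANGE,
) -> IntegratedMatrix:
    """Run the full integration pipeline and return the ordered matrix.

    Studies with complete data (a ratio for every gene in the union
    universe) are quantile-normalized together; studies with partial data
    bypass that step.  All studies are then range-scaled, recurrently
    significant genes selected, and both axes clustered with complete
    linkage.
    """
    try:
        M = pd.DataFrame({s.study_id: s.ratios for s in studies})
        complete = [c for c in M.columns if M[c].notna().all()]
        if len(complete) >= 2:
            M[complete] = quantile_normalize(M[complete])
        scaled = M.apply(lambda col: scale_to_range(col, target_range))
        selected, counts = select_recurrent(studies, min_count=min_count)
        if len(selected) < 2:
            raise ValueError(
                f"only {len(selected)} genes significant in >= {min_count} comparisons"
            )
        sub = scaled.loc[selected]
        row_Z, row_order = hclust_complete(sub, axis="rows")
        col_Z, col_order = hclust_complete(sub, axis="columns")
    except ValueError as err:
        raise ValueError(f"integration failed: {err}") from err
    ordered = sub.loc[row_order, col_order]
    return IntegratedMatrix(
        matrix=ordered, row_linkage=row_Z, col_linkage=col_Z,
        row_order=list(row_order), col_order=list(col_order),
        significance_counts=counts, selected_genes=list(selected),
        row_labels=list(sub.index), col_labels=list(sub.columns),
    )
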