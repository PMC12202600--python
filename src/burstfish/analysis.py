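"""Downstream analysis: count statistics, fold changes and the clustergram.

Covers the non-inference statistics of a typical time-course experiment:
Mann–Whitney U tests of RNA counts against the basal time point with
Bonferroni correction, normalization of posterior-mean parameter estimates to
the basal time point (fold changes), and hierarchical clustering of the
resulting (gene, stimulus) fold-change profiles with Euclidean distance and
average (UPGMA) linkage, serialized as a Newick dendrogram.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "rna_count_tests",
    "fold_change_table",
    "cluster_rows",
    "linkage_to_newick",
]


def rna_count_tests(
    counts_by_time: Mapping[object, Sequence[float]],
    basal_label: object,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise Mann–Whitney U tests of each time point against basal.

    Two-sided tests; exact null distribution when both groups have n <= 20 and
    no ties, normal approximation with tie correction otherwise. Bonferroni
    adjustment multiplies each raw p by the number of comparisons in the
    family (capped at 1); adjusted p below ``alpha`` is flagged significant.
    """
    if basal_label not in counts_by_time:
        raise ValueError(f"basal label {basal_label!r} not among groups")
    basal = np.asarray(counts_by_time[basal_label], dtype=float)
    others = [t for t in counts_by_time if t != basal_label]
    if not others:
        raise ValueError("need at least one non-basal group")
    for label in counts_by_time:
        if len(counts_by_time[label]) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    n_comp = len(others)
    rows = []
    for t in others:
        x = np.asarray(counts_by_time[t], dtype=float)
        pooled = np.concatenate([x, basal])
        exact = len(x) <= 20 and len(basal) <= 20 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            x, basal, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        p_adj = min(1.0, float(res.pvalue) * n_comp)
        rows.append(
            {
                "time": t,
                "U": float(res.statistic),
                "p_raw": float(res.pvalue),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def fold_change_table(fits: pd.DataFrame, basal_label: object) -> pd.DataFrame:
    """Posterior-mean fold changes relative to the basal time point.

    ``fits`` holds one row per (gene, condition, time_h, parameter) with a
    ``mean`` column. Returns a matrix with (gene, condition) rows and
    (parameter, time_h) columns; the basal column is identically 1.
    """
    required = {"gene", "condition", "time_h", "parameter", "mean"}
    missing = required - set(fits.columns)
    if missing:
        raise ValueError(f"fits table missing columns: {sorted(missing)}")
    dup = fits.duplicated(subset=["gene", "condition", "time_h", "parameter"])
    if dup.any():
        raise ValueError("fits table has duplicate (gene, condition, time_h, parameter) rows")
    wide = fits.pivot_table(
        index=["gene", "condition"], columns=["parameter", "time_h"], values="mean", aggfunc="first"
    )
    out = {}
    for (param, t) in wide.columns:
        basal_col = (param, basal_label)
        if basal_col not in wide.columns:
            raise ValueError(f"no basal time point {basal_label!r} for parameter {param!r}")
        basal_vals = wide[basal_col]
        if (basal_vals <= 0).any() or basal_vals.isna().any():
            bad = basal_vals.index[(basal_vals <= 0) | basal_vals.isna()].tolist()
            raise ValueError(f"non-positive or missing basal mean for {param!r} in groups {bad}")
        out[(param, t)] = wide[(param, t)] / basal_vals
    fc = pd.DataFrame(out, index=wide.index)
    fc.columns = pd.MultiIndex.from_tuples(fc.columns, names=["parameter", "time_h"])
    return fc.sort_index(axis=1)


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix to Newick; branch lengths from merge heights."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right}):0;"


def cluster_rows(matrix: pd.DataFrame) -> dict:
    """UPGMA clustering of fold-change rows (Euclidean distance, average linkage).

    Ties in merge order follow scipy's deterministic convention (lower
    original index first). Missing entries are rejected. Returns the linkage
    matrix, the dendrogram leaf order (labels and indices) and a Newick
    serialization whose node heights are the merge heights.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    values = np.asarray(matrix, dtype=float)
    if np.isnan(values).any():
        raise ValueError("fold-change matrix contains missing entries")
    Z = hierarchy.linkage(values, method="average", metric="euclidean")
    leaves = hierarchy.leaves_list(Z)
    labels = [
        "|".join(str(part) for part in idx) if isinstance(idx, tuple) else str(idx)
        for idx in matrix.index
    ]
    return {
        "linkage": Z,
        "leaf_order": [labels[i] for i in leaves],
        "leaf_indices": leaves.tolist(),
        "newick": linkage_to_newick(Z, labels),
        "labels": labels,
    }
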