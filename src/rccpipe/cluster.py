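"""Hierarchical clustering, heatmap matrices and volcano coordinates.

Heatmap input is log2 normalized expression, optionally z-scaled per gene so
every gene contributes equal variance; samples and genes are clustered
agglomeratively on Euclidean distance (average linkage by default).  Cutting
the sample tree at k = 2 gives the unsupervised two-group partition that, on
well-separated data, should recover the known case/control labels.

Volcano coordinates are the signed log2 fold change on x against
-log10 p on y; p = 0 is mapped to a finite capped y and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .diffexpr import DEResult

LINKAGES = ("average", "complete", "ward")
VOLCANO_Y_CAP = 320.0  # ~ -log10 of the smallest positive double


@dataclass
class ClusterResult:
    scaled: pd.DataFrame              # genes x samples, z-scaled if requested
    sample_linkage: np.ndarray        # scipy linkage matrices
    gene_linkage: np.ndarray
    sample_leaf_order: list[str]
    gene_leaf_order: list[str]
    sample_clusters: pd.Series        # cluster label per sample at k=2
    constant_genes: list[str]         # rows zeroed by scaling


def zscale_rows(log2_values: pd.DataFrame, ddof: int = 1) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-score (mean 0, variance 1); constant rows become all-zero."""
    mean = log2_values.mean(axis=1)
    sd = log2_values.std(axis=1, ddof=ddof)
    constant = list(log2_values.index[sd == 0])
    safe_sd = sd.replace(0.0, 1.0)
    scaled = log2_values.sub(mean, axis=0).div(safe_sd, axis=0)
    return scaled, constant


def cluster(
    log2_values: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
    scale_genes: bool = True,
) -> ClusterResult:
    """Agglomerative clustering of samples (columns) and genes (rows)."""
    if distance != "euclidean":
        raise ValueError(f"unsupported distance {distance!r}")
    if linkage not in LINKAGES:
        raise ValueError(f"unsupported linkage {linkage!r}; choose from {LINKAGES}")
    if log2_values.shape[0] < 2 or log2_values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples")
    if log2_values.isna().any().any():
        bad = log2_values.stack(future_stack=True)
        cell = bad.index[bad.isna()][0]
        raise ValueError(f"NaN in clustering input at (gene, sample) = {cell}")

    if scale_genes:
        scaled, constant = zscale_rows(log2_values)
    else:
        scaled, constant = log2_values.copy(), []

    sample_link = hierarchy.linkage(scaled.T.to_numpy(), method=linkage, metric="euclidean")
    gene_link = hierarchy.linkage(scaled.to_numpy(), method=linkage, metric="euclidean")
    sample_order = [scaled.columns[i] for i in hierarchy.leaves_list(sample_link)]
    gene_order = [scaled.index[i] for i in hierarchy.leaves_list(gene_link)]
    labels = hierarchy.fcluster(sample_link, t=2, criterion="maxclust")
    sample_clusters = pd.Series(labels, index=scaled.columns, name="cluster")
    return ClusterResult(
        scaled=scaled,
        sample_linkage=sample_link,
        gene_linkage=gene_link,
        sample_leaf_order=sample_order,
        gene_leaf_order=gene_order,
        sample_clusters=sample_clusters,
        constant_genes=constant,
    )


def adjusted_rand_index(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """ARI between two labelings over the same samples (pair-counting form)."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b.reindex(labels_a.index)).codes
    contingency = pd.crosstab(a, b).to_numpy()

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    total = comb2(contingency.sum())
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def volcano_table(de: DEResult) -> pd.DataFrame:
    """Rows of (gene, log2fc, neg_log10_p, call, p_capped)."""
    table = de.table
    with np.errstate(divide="ignore"):
        y = -np.log10(table["p"].to_numpy())
    capped = ~np.isfinite(y)
    y = np.where(capped, VOLCANO_Y_CAP, y)
    return pd.DataFrame(
        {
            "log2fc": table["delta"],
            "neg_log10_p": y,
            "call": table["call"],
            "p_capped": capped,
        },
        index=table.index,
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(link)

    def recurse(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
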