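"""Standardized temporal-profile hierarchical clustering.

Each significant gene is summarized by its per-day mean ln-normalized
expression, standardized per gene (centered and scaled to unit SD over
days) so clustering groups genes by the *shape* of their temporal pattern
rather than its level.  Agglomerative clustering with Euclidean distance
and Ward linkage produces one dendrogram; labels at the nested cut levels
(default 3, 8, 21) come from cutting that single tree, so coarser clusters
are unions of finer ones by construction.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

DEFAULT_CUTS = (3, 8, 21)


@dataclass
class ClusterAssignment:
    labels: pd.DataFrame        # genes x cut levels (columns "k3", "k8", ...)
    linkage: np.ndarray         # scipy linkage matrix
    cuts: tuple[int, ...]

    def genes_in(self, level: int, cluster: int) -> list[str]:
        col = f"k{level}"
        return list(self.labels.index[self.labels[col] == cluster])


def day_mean_profiles(
    values: pd.DataFrame, metadata: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Per-day arithmetic means of ln-normalized values (genes x days)."""
    if genes is not None:
        values = values.loc[list(genes)]
    days = metadata.loc[values.columns, "day"]
    levels = sorted(days.unique())
    out = {}
    for d in levels:
        cols = [s for s in values.columns if days[s] == d]
        if not cols:
            raise ValueError(f"day {d!r} has no retained sample")
        out[d] = values[cols].mean(axis=1)
    return pd.DataFrame(out, index=values.index)[levels]


def standardize_profiles(
    profiles: pd.DataFrame, per_gene: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Z-profiles: center each gene over days and scale by its own SD.

    Constant profiles map to all-zeros and are flagged.  ``per_gene=False``
    scales by the pooled SD of all values instead (alternative reading of
    the standardization; shapes then retain level information).
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 days to standardize")
    centered = profiles.sub(profiles.mean(axis=1), axis=0)
    if per_gene:
        sd = profiles.std(axis=1, ddof=0)
    else:
        pooled = float(np.std(profiles.to_numpy(), ddof=0))
        sd = pd.Series(pooled, index=profiles.index)
    constant = sd == 0
    safe_sd = sd.replace(0, 1.0)
    z = centered.div(safe_sd, axis=0)
    z[constant] = 0.0
    return z, constant.rename("constant")


def hierarchical_cluster(
    z: pd.DataFrame, cuts=DEFAULT_CUTS
) -> ClusterAssignment:
    """Ward/Euclidean agglomeration of z-profiles, cut at each level."""
    cuts = tuple(sorted(cuts))
    if len(z) < max(cuts):
        raise ValueError(
            f"{len(z)} genes < largest requested cut {max(cuts)}"
        )
    Z = hierarchy.linkage(z.to_numpy(dtype=float), method="ward")
    labels = {}
    for k in cuts:
        labels[f"k{k}"] = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterAssignment(pd.DataFrame(labels, index=z.index), Z, cuts)


def assert_nested(assignment: ClusterAssignment) -> None:
    """Cuts of one tree must be nested: a finer cluster maps into exactly
    one coarser cluster."""
    labels = assignment.labels
    cols = [f"k{k}" for k in assignment.cuts]
    for fine, coarse in zip(cols[::-1], cols[-2::-1]):
        mapping = labels.groupby(fine)[coarse].nunique()
        if (mapping > 1).any():
            raise AssertionError(f"cut {fine} is not nested within {coarse}")


def export_cluster_lists(assignment: ClusterAssignment, outdir) -> list[str]:
    """Write one gene-id list per cluster per cut level; returns paths."""
    if assignment.labels.empty:
        warnings.warn("empty cluster assignment; nothing exported", stacklevel=2)
        return []
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for k in assignment.cuts:
        col = f"k{k}"
        for c in sorted(assignment.labels[col].unique()):
            path = os.path.join(outdir, f"cluster_k{k}_{c}.txt")
            with open(path, "w") as fh:
                for g in assignment.genes_in(k, c):
                    fh.write(f"{g}\n")
            paths.append(path)
    return paths


def to_newick(assignment: ClusterAssignment) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    tree = hierarchy.to_tree(assignment.linkage)
    names = list(assignment.labels.index)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
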