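"""Epithelial / erythropoietic separation of the significant gene set.

Late-term yolk-sac libraries mix two cell populations: endodermal
epithelial cells and a declining erythropoietic compartment whose globin
and heme-synthesis transcripts dominate early libraries.  Clusters (at the
finest cut of the temporal dendrogram) that are enriched for user-supplied
erythroid marker genes are labeled erythropoietic and their members
inherit the label; remaining significant genes are treated as epithelial.
The epithelial subset is then upper-quartile renormalized on its own, so
that the shrinking erythroid fraction no longer inflates the apparent
expression of stable epithelial genes, and the pairwise day contrasts are
re-run on the subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats

from .normalization import NormalizedMatrix, normalize
from .tag_alignment import CountMatrix
from .temporal_clustering import ClusterAssignment

EPITHELIAL = "epithelial"
ERYTHROPOIETIC = "erythropoietic"
UNASSIGNED = "unassigned"

# A cluster must show at least this marker odds ratio AND pass the
# hypergeometric test.  The odds ratio (odds of being a marker inside the
# cluster vs outside) is used as the effect-size gate because a simple
# fraction ratio is bounded above by 1/(marker share) and becomes
# unattainable when the erythroid compartment is a large share of the
# significant set.
DEFAULT_ENRICHMENT = 2.0
DEFAULT_PVAL = 0.01


@dataclass
class CellTypePartition:
    classes: pd.Series           # gene -> class
    cluster_evidence: pd.DataFrame  # per finest-cut cluster: size, markers, p

    @property
    def epithelial_genes(self) -> list[str]:
        return list(self.classes.index[self.classes == EPITHELIAL])

    @property
    def erythropoietic_genes(self) -> list[str]:
        return list(self.classes.index[self.classes == ERYTHROPOIETIC])


MIN_CLUSTER_SIZE = 20


def classify_genes(
    assignment: ClusterAssignment,
    markers,
    enrichment: float = DEFAULT_ENRICHMENT,
    p_cut: float = DEFAULT_PVAL,
    level: Optional[int] = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
) -> CellTypePartition:
    """Label clusters erythropoietic by marker enrichment.

    A cluster is erythropoietic iff its marker odds ratio (odds of being
    a marker inside the cluster vs outside, Haldane-corrected) is at
    least ``enrichment`` *and* the hypergeometric tail probability of its
    marker count is below ``p_cut``.  An empty marker list labels
    everything epithelial.

    Labeling uses the finest cut level whose average cluster still holds
    ``min_cluster_size`` genes (clusters much smaller than that cannot
    reach hypergeometric significance even when pure); at study scale
    (thousands of significant genes) this is simply the finest cut.
    ``level`` overrides the choice.
    """
    genes = assignment.labels.index
    markers = sorted(set(markers) & set(genes))
    if not markers:
        warnings.warn(
            "no marker gene present in the clustered set; all genes epithelial",
            stacklevel=2,
        )
    if level is None:
        usable = [k for k in assignment.cuts
                  if len(genes) / k >= min_cluster_size]
        level = max(usable) if usable else min(assignment.cuts)
    elif level not in assignment.cuts:
        raise ValueError(f"no cut at level {level}")
    labels = assignment.labels[f"k{level}"]
    N, K = len(genes), len(markers)
    marker_set = set(markers)

    rows = []
    ery_clusters = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        n = len(members)
        k = sum(1 for g in members if g in marker_set)
        frac = k / n if n else 0.0
        # Haldane-corrected odds ratio: markers in vs out of the cluster
        odds_in = (k + 0.5) / (n - k + 0.5)
        odds_out = (K - k + 0.5) / (N - n - (K - k) + 0.5)
        oratio = odds_in / odds_out
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        is_ery = bool(K and oratio >= enrichment and p < p_cut)
        if is_ery:
            ery_clusters.append(c)
        rows.append(
            {"cluster": c, "size": n, "markers": k, "marker_fraction": frac,
             "odds_ratio": oratio, "pvalue": p, "erythropoietic": is_ery}
        )
    classes = pd.Series(EPITHELIAL, index=genes, name="class")
    classes[labels.isin(ery_clusters)] = ERYTHROPOIETIC
    return CellTypePartition(classes, pd.DataFrame(rows).set_index("cluster"))


def renormalize_subset(counts: CountMatrix, genes) -> NormalizedMatrix:
    """Upper-quartile normalization recomputed on a gene subset only."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    return normalize(counts.subset_genes(genes))
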