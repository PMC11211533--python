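"""Statistical procedures used to compare cohorts.

Defaults follow common practice for the comparisons they serve: the
two-proportion z-test pools the variance and applies the Yates continuity
correction; the t-test is Welch's (unequal variance); gene-level
prevalence is related by Pearson correlation; ethnic-group profiles are
clustered agglomeratively on Jaccard distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .errors import AnalysisError, ValidationError


@dataclass
class StatResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    extra: Optional[dict] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p-value out of (0,1]: {self.p_value}")


def two_proportion_test(x1: int, n1: int, x2: int, n2: int,
                        continuity: bool = True) -> StatResult:
    """Pooled two-proportion z-test, two-sided, optional Yates correction.

    The correction subtracts ``(1/n1 + 1/n2)/2`` from the absolute
    difference of proportions, clamped at zero so that equal proportions
    give z = 0, p = 1. The corrected p-value is never smaller than the
    uncorrected one.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        raise AnalysisError("degenerate table: pooled proportion is 0 or 1")
    diff = p1 - p2
    cc = 0.5 * (1.0 / n1 + 1.0 / n2) if continuity else 0.0
    z_mag = max(abs(diff) - cc, 0.0) / se
    z = math.copysign(z_mag, diff) if diff != 0 else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(z_mag))
    method = "two-proportion z, pooled" + (", Yates continuity" if continuity else "")
    return StatResult(statistic=z, p_value=max(p, np.nextafter(0, 1)), method=method)


def welch_t(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise AnalysisError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue) if res.pvalue > 0 else np.nextafter(0, 1),
                      df=df, method="Welch t, two-sided")


def prevalence_correlation(per_gene_a: Mapping[str, float],
                           per_gene_b: Mapping[str, float],
                           n_outliers: int = 2) -> StatResult:
    """Pearson correlation of per-gene variant counts between two cohorts.

    Genes absent from one side are imputed as zero so the union of genes is
    compared. Also fits the least-squares line and flags the genes with the
    largest absolute residuals (the discordant genes), reported in
    ``extra``.
    """
    genes = sorted(set(per_gene_a) | set(per_gene_b))
    if len(genes) < 3:
        raise ValueError("need at least 3 genes in the union")
    x = np.array([per_gene_a.get(g, 0) for g in genes], dtype=float)
    y = np.array([per_gene_b.get(g, 0) for g in genes], dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        raise AnalysisError("zero variance in per-gene counts")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    residuals = y - (slope * x + intercept)
    order = np.argsort(-np.abs(residuals))
    outliers = [genes[i] for i in order[:n_outliers]]
    return StatResult(statistic=float(r),
                      p_value=float(p) if p > 0 else np.nextafter(0, 1),
                      df=float(len(genes) - 2), method="Pearson r",
                      extra={"slope": float(slope), "intercept": float(intercept),
                             "outlier_genes": outliers})


@dataclass
class GroupTree:
    """Rooted group dendrogram with a Newick serialization."""

    leaves: list[str]
    linkage: np.ndarray
    newick: str
    method: str


def _to_newick(node: hierarchy.ClusterNode, labels: Sequence[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    parts = []
    for child in (node.left, node.right):
        # ultrametric convention: node height = merge distance / 2
        length = max(node.dist - child.dist, 0.0) / 2.0
        parts.append(f"{_to_newick(child, labels)}:{length:.6g}")
    return "(" + ",".join(sorted(parts)) + ")"


def cluster_groups(matrix: pd.DataFrame, distance: str = "jaccard",
                   linkage: str = "average") -> GroupTree:
    """Agglomeratively cluster group presence/absence profiles.

    Rows are groups, columns variants. Pairwise distances default to
    Jaccard on binary profiles; the tree is built under the requested
    linkage. Rows are sorted by label before clustering so the result is
    invariant to input row order, and sibling subtrees are ordered
    lexicographically in the Newick string.
    """
    if matrix.shape[0] < 2:
        raise AnalysisError("need at least 2 groups to cluster")
    matrix = matrix.sort_index()
    empty = matrix.index[(matrix.to_numpy() != 0).sum(axis=1) == 0]
    if len(empty):
        raise ValidationError(f"all-absent profile for group(s): {', '.join(empty)}")
    data = matrix.to_numpy()
    dists = pdist(data.astype(bool) if distance == "jaccard" else data,
                  metric=distance)
    link = hierarchy.linkage(dists, method=linkage)
    root = hierarchy.to_tree(link)
    labels = list(matrix.index)
    newick = _to_newick(root, labels) + ";"
    return GroupTree(leaves=labels, linkage=link, newick=newick,
                     method=f"{distance}+{linkage}")


def jaccard_distance(a: set, b: set) -> float:
    """1 − |A∩B| / |A∪B|; zero for two empty sets."""
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)
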