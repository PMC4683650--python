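"""Cultivar-panel polymorphism scoring and UPGMA clustering.

A marker panel scored on a set of inbred cultivars yields, per cultivar
pair, the number of markers whose amplicon sizes differ (polymorphic).  A
pair where either cultivar failed to amplify is *uninformative* and excluded
from the count, but the percentage denominator stays at the full marker
total, matching how such panel tables are conventionally reported.
Percentages are rounded half-away-from-zero to integers.

Clustering is classic UPGMA on the polymorphic-fraction distance
(count / total markers): repeatedly merge the closest pair of clusters,
averaging distances weighted by cluster sizes; node height is half the
merge distance, so the tree is ultrametric.  Ties are broken by merging the
lexicographically smallest pair of cluster labels, which makes the tree
deterministic across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def score_pair(size_a, size_b) -> Literal["polymorphic", "monomorphic", "uninformative"]:
    """Score one marker between two cultivars from their amplicon sizes."""
    if pd.isna(size_a) or pd.isna(size_b):
        return "uninformative"
    return "polymorphic" if size_a != size_b else "monomorphic"


@dataclass
class PolymorphismMatrix:
    """Pairwise polymorphic-marker counts and integer percentages."""

    counts: pd.DataFrame
    percentages: pd.DataFrame
    total_markers: int

    def validate(self) -> None:
        c = self.counts.to_numpy(float)
        assert np.allclose(c, c.T), "counts must be symmetric"
        assert np.all(np.diag(c) == 0), "diagonal must be zero"
        assert c.max() <= self.total_markers

    def to_table_layout(self) -> pd.DataFrame:
        """Counts above the diagonal, percentages (with %) below, empty diagonal."""
        names = list(self.counts.index)
        out = pd.DataFrame("", index=names, columns=names, dtype=object)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j > i:
                    out.loc[a, b] = str(int(self.counts.loc[a, b]))
                elif j < i:
                    out.loc[a, b] = f"{int(self.percentages.loc[a, b])}%"
        return out


def polymorphism_matrix(genotypes: pd.DataFrame) -> PolymorphismMatrix:
    """Score a marker x cultivar amplicon-size table into pairwise counts.

    ``count(a, b)`` is the number of markers where both cultivars amplified
    and their product sizes differ; ``percentage(a, b)`` is the count over
    the full marker total, rounded to an integer.
    """
    if genotypes.shape[1] < 2:
        raise ValueError("need at least 2 cultivars")
    names = list(genotypes.columns)
    total = len(genotypes)
    values = genotypes.to_numpy(float)
    counts = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = values[:, i], values[:, j]
            informative = ~np.isnan(a) & ~np.isnan(b)
            n = int(np.sum(informative & (a != b)))
            counts.iloc[i, j] = counts.iloc[j, i] = n
    percentages = counts.map(lambda n: round_half_away(100.0 * n / total))
    result = PolymorphismMatrix(counts=counts, percentages=percentages, total_markers=total)
    result.validate()
    return result


def allele_summary(genotypes: pd.DataFrame) -> tuple[pd.Series, int]:
    """Per-marker distinct-allele counts and the number of markers with missing cells."""
    n_alleles = genotypes.apply(lambda row: row.dropna().nunique(), axis=1)
    n_alleles.name = "n_alleles"
    markers_with_missing = int(genotypes.isna().any(axis=1).sum())
    return n_alleles, markers_with_missing


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of an ultrametric UPGMA tree; ``height`` is half the merge distance."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    size: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for child in self.children for leaf in child.leaves()]

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = ",".join(
            f"{child._newick_inner()}:{self.height - child.height:.6g}" for child in self.children
        )
        return f"({parts})"


@dataclass
class Dendrogram:
    """A UPGMA tree plus the merge history in scipy linkage layout."""

    root: TreeNode
    leaf_names: list[str]
    linkage: np.ndarray  # (n-1, 4): child i, child j, merge distance, cluster size

    def newick(self) -> str:
        return self.root.newick()

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Tree distance between every leaf pair (2x height of the join node)."""
        names = self.leaf_names
        out = pd.DataFrame(0.0, index=names, columns=names)

        def walk(node: TreeNode):
            if node.is_leaf:
                return
            groups = [child.leaves() for child in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            out.loc[a, b] = out.loc[b, a] = 2.0 * node.height
            for child in node.children:
                walk(child)

        walk(self.root)
        return out


def upgma(distance: pd.DataFrame) -> Dendrogram:
    """Cluster a symmetric zero-diagonal distance matrix with UPGMA.

    Average linkage weighted by cluster sizes (i.e. the unweighted
    pair-group arithmetic mean over all leaf pairs); equal-distance ties are
    resolved toward the lexicographically smallest pair of cluster labels,
    a cluster's label being its smallest leaf name.
    """
    values = distance.to_numpy(float)
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(values) != 0) or np.any(values < 0):
        raise ValueError("distance matrix must be non-negative with a zero diagonal")
    names = list(distance.index)
    n = len(names)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=names[i]) for i in range(n)}
    labels: dict[int, str] = {i: names[i] for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    linkage_rows = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            dist.keys(),
            key=lambda ij: (dist[ij], tuple(sorted((labels[ij[0]], labels[ij[1]])))),
        )
        i, j = best
        d = dist[best]
        a, b = nodes[i], nodes[j]
        merged = TreeNode(height=d / 2.0, children=[a, b], size=a.size + b.size)
        linkage_rows.append([i, j, d, merged.size])
        nodes[next_id] = merged
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        for k in active:
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (a.size * d_ik + b.size * d_jk) / (a.size + b.size)
        dist = {
            (p, q): v for (p, q), v in dist.items()
            if p not in (i, j) and q not in (i, j)
        }
        active.add(next_id)
        next_id += 1
    root = nodes[next_id - 1]
    return Dendrogram(root=root, leaf_names=names, linkage=np.array(linkage_rows))


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class PanelDiversity:
    """Diversity analysis of a marker x cultivar amplicon-size panel.

    Parameters
    ----------
    genotypes : DataFrame
        Markers as rows, cultivars as columns, cells the amplicon size in bp
        (NaN = no product).

    ``fit()`` scores every cultivar pair, summarizes per-marker allele
    counts, and clusters the cultivars by UPGMA on the polymorphic-fraction
    distance.
    """

    def __init__(self, genotypes: pd.DataFrame):
        if genotypes.shape[1] < 2:
            raise ValueError("need at least 2 cultivars")
        self.genotypes = genotypes

    @classmethod
    def from_tsv(cls, path) -> "PanelDiversity":
        from indelmark.io import read_tsv
        return cls(read_tsv(path))

    def fit(self) -> "PanelDiversityResults":
        matrix = polymorphism_matrix(self.genotypes)
        n_alleles, markers_with_missing = allele_summary(self.genotypes)
        dist = matrix.counts.astype(float) / matrix.total_markers
        tree = upgma(dist)
        return PanelDiversityResults(
            model=self,
            polymorphism=matrix,
            n_alleles=n_alleles,
            markers_with_missing=markers_with_missing,
            dendrogram=tree,
        )


@dataclass
class PanelDiversityResults:
    """Fitted panel-diversity results: pairwise matrix, allele summary, tree."""

    model: PanelDiversity
    polymorphism: PolymorphismMatrix
    n_alleles: pd.Series
    markers_with_missing: int
    dendrogram: Dendrogram

    def summary(self) -> str:
        counts = self.polymorphism.counts
        off = counts.to_numpy(float)[~np.eye(len(counts), dtype=bool)]
        two_allele = int((self.n_alleles == 2).sum())
        lines = [
            "Panel diversity summary",
            "=======================",
            f"markers: {self.polymorphism.total_markers}   cultivars: {counts.shape[0]}",
            f"pairwise polymorphic markers: min {int(off.min())}, max {int(off.max())}",
            f"markers with two alleles: {two_allele} "
            f"({round_half_away(100 * two_allele / len(self.n_alleles))}%)",
            f"markers with >2 alleles: {int((self.n_alleles > 2).sum())}",
            f"markers with missing amplification: {self.markers_with_missing}",
            "",
            self.polymorphism.to_table_layout().to_string(),
            "",
            "UPGMA tree: " + self.dendrogram.newick(),
        ]
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        """Draw the UPGMA dendrogram (matplotlib)."""
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        scipy_dendrogram(
            self.dendrogram.linkage.astype(float),
            labels=self.dendrogram.leaf_names,
            ax=ax,
            leaf_rotation=90,
        )
        ax.set_ylabel("polymorphic fraction (merge distance)")
        return ax
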