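"""Subpopulation profiling: clustering, sigup naming, condition proportions.

Within the fast- and slow-classified subpopulations, cells are clustered
on a k-nearest-neighbor graph over principal components (Leiden
modularity optimization), each cluster's significantly upregulated genes
("sigups") are found by one-vs-rest rank-sum tests with
Benjamini-Hochberg correction and a fold-change floor, and clusters are
named after their sigups: a unique sigup set gives "G+", clusters
sharing the same sigups are indexed "G+(1)", "G+(2)" by descending
size, and clusters without sigups become "Unknown".  Per-condition
cluster proportions and combined fractions of designated clusters
quantify how the composition shifts across disease conditions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "cluster_subpopulation", "find_sigups", "name_clusters",
    "condition_proportions", "combine_clusters", "compare_marker_expression",
    "ClusterAnnotation", "ProportionTable",
]


@dataclass(frozen=True)
class ClusterAnnotation:
    cluster: int
    sigups: frozenset
    name: str
    size: int


@dataclass
class ProportionTable:
    """condition x cluster-name counts and within-condition fractions."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ProportionTable":
        totals = counts.sum(axis=1)
        empty = totals[totals == 0].index.tolist()
        if empty:
            logger.warning("dropping condition(s) with zero cells: %s", empty)
            counts = counts.drop(index=empty)
            totals = totals.drop(index=empty)
        return cls(counts=counts, fractions=counts.div(totals, axis=0))


def cluster_subpopulation(expr_subset, n_neighbors: int = 15,
                          resolution: float = 1.0, seed: int = 0,
                          n_pcs: int = 30) -> np.ndarray:
    """Leiden community labels for one subpopulation's expression.

    PCA (at most ``n_pcs`` components) -> kNN graph -> Leiden modularity
    (RBConfiguration) at the given resolution.  Deterministic given the
    seed; ``n_neighbors`` is clamped (with a warning) for tiny inputs.
    """
    X = np.asarray(expr_subset, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"cannot cluster {n} cells (need at least 3)")
    if n_neighbors > n - 1:
        logger.warning("n_neighbors=%d clamped to %d for %d cells",
                       n_neighbors, n - 1, n)
        n_neighbors = n - 1
    n_comp = int(min(n_pcs, X.shape[1], n - 1))
    Xc = X - X.mean(axis=0)
    if n_comp < min(X.shape[1], n - 1):
        Xc = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(Xc)
    _, idx = nn.kneighbors(Xc)
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in idx[i, 1:] if i != j}
    graph = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    return np.asarray(part.membership, dtype=int)


def find_sigups(expr_subset: pd.DataFrame, labels, alpha: float = 0.05,
                min_lfc: float = 1.0) -> pd.DataFrame:
    """Significantly upregulated genes per cluster (one-vs-rest).

    Per cluster and gene: a one-sided Wilcoxon rank-sum test (cluster >
    rest) BH-adjusted across genes within the cluster; sigups need
    adjusted p < alpha and a log2 fold-change (mean difference on the
    log scale) >= min_lfc.  Returns a table (cluster, gene, lfc, p_adj)
    restricted to the sigups.
    """
    labels = np.asarray(labels)
    expr = pd.DataFrame(expr_subset)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("sigup discovery needs at least 2 clusters")
    rows = []
    X = expr.to_numpy(dtype=float)
    for c in clusters:
        inside = labels == c
        xin, xout = X[inside], X[~inside]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = scipy.stats.mannwhitneyu(
                xin, xout, alternative="greater", axis=0)
        p = np.nan_to_num(p, nan=1.0)
        p_adj = multipletests(p, method="fdr_bh")[1]
        lfc = xin.mean(axis=0) - xout.mean(axis=0)
        hit = (p_adj < alpha) & (lfc >= min_lfc)
        for gix in np.flatnonzero(hit):
            rows.append((int(c), expr.columns[gix], float(lfc[gix]),
                         float(p_adj[gix])))
    return pd.DataFrame(rows, columns=["cluster", "gene", "lfc", "p_adj"])


def name_clusters(sigups: pd.DataFrame, sizes: dict[int, int]
                  ) -> list[ClusterAnnotation]:
    """Apply the sigup naming grammar.

    One cluster with sigup set {G,...} is named "G+" using the
    largest-fold-change sigup G; several clusters sharing an identical
    sigup set become "G+(1)", "G+(2)", ... indexed by descending size;
    clusters without sigups are "Unknown" (indexed the same way when
    several).  Pure function of (sigups, sizes).
    """
    sets: dict[int, frozenset] = {c: frozenset() for c in sizes}
    best_gene: dict[frozenset, tuple[float, str]] = {}
    if len(sigups):
        for c, grp in sigups.groupby("cluster"):
            sets[int(c)] = frozenset(grp["gene"])
        for c, s in sets.items():
            if not s:
                continue
            grp = sigups[sigups["cluster"] == c]
            top = grp.loc[grp["lfc"].idxmax()]
            prev = best_gene.get(s)
            if prev is None or top["lfc"] > prev[0]:
                best_gene[s] = (float(top["lfc"]), str(top["gene"]))

    # identical sigup sets share a base name by construction; distinct sets
    # whose top genes coincide are disambiguated by the same indexing
    groups: dict[str, list[int]] = {}
    for c, s in sets.items():
        base = "Unknown" if not s else f"{best_gene[s][1]}+"
        groups.setdefault(base, []).append(c)

    annotations: dict[int, ClusterAnnotation] = {}
    for base, members in groups.items():
        members = sorted(members, key=lambda c: (-sizes[c], c))
        for i, c in enumerate(members, start=1):
            name = base if len(members) == 1 else f"{base}({i})"
            annotations[c] = ClusterAnnotation(cluster=c, sigups=sets[c],
                                               name=name, size=sizes[c])
    out = sorted(annotations.values(), key=lambda a: (-a.size, a.cluster))
    names = [a.name for a in out]
    assert len(set(names)) == len(names), "cluster names must be unique"
    return out


def condition_proportions(labels, conditions) -> ProportionTable:
    """Tally cluster (or class) proportions per condition."""
    labels = pd.Series(np.asarray(labels, dtype=object), name="label")
    conditions = pd.Series(np.asarray(conditions, dtype=object),
                           name="condition")
    if len(labels) != len(conditions):
        raise ValueError("labels and conditions differ in length")
    counts = pd.crosstab(conditions, labels)
    counts = counts[sorted(counts.columns)]
    return ProportionTable.from_counts(counts)


def combine_clusters(table: ProportionTable, names) -> pd.Series:
    """Per-condition summed fraction of the named clusters."""
    missing = [n for n in names if n not in table.fractions.columns]
    if missing:
        raise KeyError(f"cluster name(s) not in table: {missing}")
    if not list(names):
        return pd.Series(0.0, index=table.fractions.index, name="combined")
    return table.fractions[list(names)].sum(axis=1).rename("combined")


def compare_marker_expression(expr, genes, conditions,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Condition-pair rank-sum comparison for selected marker genes.

    For each gene and unordered condition pair: two-sided Wilcoxon
    rank-sum statistic, BH-adjusted p (across all gene x pair tests)
    and the mean log-expression difference.  Intended for the
    muscle-atrophy markers Fbxo32 (atrogin-1) and Trim63 (murf-1).
    """
    expr = pd.DataFrame(expr)
    missing = [g for g in genes if g not in expr.columns]
    if missing:
        raise KeyError(f"gene(s) not in expression matrix: {missing}")
    conditions = pd.Series(np.asarray(conditions, dtype=object))
    if len(conditions) != len(expr):
        raise ValueError("conditions length does not match expression rows")
    levels = list(pd.unique(conditions))
    rows = []
    for gene in genes:
        vals = expr[gene].to_numpy(dtype=float)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = vals[(conditions == levels[i]).to_numpy()]
                b = vals[(conditions == levels[j]).to_numpy()]
                stat, p = scipy.stats.mannwhitneyu(a, b,
                                                   alternative="two-sided")
                rows.append((gene, levels[i], levels[j], float(stat),
                             float(p), float(a.mean() - b.mean())))
    out = pd.DataFrame(rows, columns=["gene", "condition_a", "condition_b",
                                      "statistic", "p_value", "mean_diff"])
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
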