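"""Family co-expression clustering and mitochondrial enrichment.

Families are correlated pairwise by Spearman rank correlation across
samples; the correlation-matrix rows are clustered by complete-linkage
agglomeration on Euclidean distances (the convention of standard
heatmap tooling); and each cluster is tested for enrichment of
mitochondria-derived families with a two-sided Fisher's exact test. The
"center square" of a co-expression heatmap is formalized here as the
cluster with the highest mean intra-cluster correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


class CoexpressionError(ValueError):
    pass


def pairwise_spearman(E: pd.DataFrame) -> pd.DataFrame:
    """Family x family Spearman correlation matrix from a samples x
    families RPM table.

    Zero-variance families are excluded (logged), since their rank
    correlation is undefined.
    """
    if len(E) < 3:
        raise CoexpressionError("need at least 3 samples")
    variable = E.columns[E.nunique() > 1]
    dropped = [c for c in E.columns if c not in set(variable)]
    if dropped:
        logger.info("pairwise_spearman: excluding %d zero-variance families",
                    len(dropped))
    ranks = E[variable].rank(axis=0, method="average")
    C = ranks.corr(method="pearson")  # Pearson of average ranks == Spearman
    np.fill_diagonal(C.values, 1.0)
    return C


@dataclass
class ClusterAssignment:
    """Partition of families from cutting a complete-linkage tree."""

    labels: pd.Series  # family -> cluster id (1..k)
    linkage: np.ndarray  # scipy linkage matrix
    k: int
    leaf_order: list[str]

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])

    @property
    def clusters(self) -> list[int]:
        return sorted(self.labels.unique())


def cluster_families(C: pd.DataFrame, k: int) -> ClusterAssignment:
    """Complete-linkage clustering of correlation-matrix rows.

    Rows of ``C`` (each family's correlation profile) are the feature
    vectors; distances are Euclidean. Families are processed in
    lexicographic order so ties break deterministically.
    """
    if k < 2:
        raise CoexpressionError("k must be >= 2")
    if k > len(C):
        raise CoexpressionError(f"k={k} exceeds {len(C)} families")
    order = sorted(C.index)
    X = C.loc[order, order].to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaves = [order[i] for i in hierarchy.leaves_list(Z)]
    return ClusterAssignment(pd.Series(flat, index=order), Z, k, leaves)


def top_cluster(C: pd.DataFrame, assignment: ClusterAssignment,
                min_size: int = 3) -> int:
    """Cluster with the highest mean intra-cluster (off-diagonal)
    correlation among clusters of at least ``min_size`` families.

    The size floor formalizes "block": a heatmap's visually coherent
    square is a group of families, not an incidental tight pair. If no
    cluster reaches ``min_size`` the floor relaxes to 2, then to 1.
    """
    for floor in (min_size, 2, 1):
        best, best_score = None, -np.inf
        for cl in assignment.clusters:
            members = assignment.members(cl)
            if len(members) < floor:
                continue
            if len(members) == 1:
                score = -np.inf
            else:
                sub = C.loc[members, members].to_numpy()
                score = sub[np.triu_indices(len(members), k=1)].mean()
            if score > best_score:
                best, best_score = cl, score
        if best is not None:
            return best
    return assignment.clusters[0]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    Returns (odds ratio a*d/(b*c), p). The p-value sums hypergeometric
    probabilities of all tables as or less probable than the observed
    one (the classical two-sided convention).
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    return float(odds), float(p)


@dataclass
class EnrichmentResult:
    """2x2 membership x origin table with Fisher's exact test.

    Table cells: a = in-cluster mitochondrial, b = in-cluster genomic,
    c = out-of-cluster mitochondrial, d = out-of-cluster genomic. The
    odds ratio is (a*d)/(b*c); with a zero in b or c it is reported as
    inf (or NaN for 0/0).
    """

    cluster: int
    table: tuple[int, int, int, int]
    odds_ratio: float
    pvalue: float
    degenerate: bool = False


def fisher_mt_enrichment(assignment: ClusterAssignment,
                         origins: pd.Series | dict,
                         cluster: int) -> EnrichmentResult:
    """Fisher's exact test for mitochondrial-family enrichment in one
    cluster.

    Two-sided p-value by hypergeometric enumeration (summing the
    probabilities of all tables as or less probable than the observed
    one). If every family shares one origin the margins are degenerate
    and P = 1 is reported with a flag.
    """
    origins = pd.Series(origins)
    if cluster not in set(assignment.clusters):
        raise CoexpressionError(f"no cluster {cluster!r}")
    fams = list(assignment.labels.index)
    missing = [f for f in fams if f not in origins.index]
    if missing:
        raise CoexpressionError(f"families without origin label: {missing}")
    in_cl = assignment.labels == cluster
    is_mt = origins.loc[fams] == "mitochondrial"
    a = int((in_cl & is_mt.values).sum())
    b = int((in_cl & ~is_mt.values).sum())
    c = int((~in_cl & is_mt.values).sum())
    d = int((~in_cl & ~is_mt.values).sum())
    if a + c == 0 or b + d == 0:
        return EnrichmentResult(cluster, (a, b, c, d), float("nan"), 1.0,
                                degenerate=True)
    odds, p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentResult(cluster, (a, b, c, d), odds, p)


def enrich_all_clusters(assignment: ClusterAssignment,
                        origins: pd.Series | dict) -> pd.DataFrame:
    """Fisher enrichment of every cluster, Bonferroni-adjusted over the
    number of clusters tested."""
    rows = []
    m = len(assignment.clusters)
    for cl in assignment.clusters:
        r = fisher_mt_enrichment(assignment, origins, cl)
        a, b, c, d = r.table
        rows.append({"cluster": cl, "n_families": a + b, "n_mt_in": a,
                     "odds_ratio": r.odds_ratio, "p": r.pvalue,
                     "p_adj": min(1.0, r.pvalue * m),
                     "degenerate": r.degenerate})
    return pd.DataFrame(rows).set_index("cluster")
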