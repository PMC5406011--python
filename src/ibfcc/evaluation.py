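"""Cluster-quality criteria against ground-truth class labels.

Four external criteria are provided, all computed from the class-by-cluster
contingency table: the clustering F-Measure (class-weighted best harmonic
mean of precision and recall; higher is better), the clustering entropy
(cluster-size-weighted entropy of within-cluster class proportions; lower
is better), hypergeometric enrichment p-values per (class, cluster) pair
with the clustering score CS summarizing them (lower is better), and the
count of empty clusters, a known pathology of fuzzy-c-means-type methods
on sparse high-dimensional data.

In enrichment analysis each class label plays the role of an annotation
term: given ``N`` objects of which ``M`` carry the annotation, the p-value
of a cluster of size ``n`` containing ``m`` annotated objects is the
hypergeometric upper tail P(X >= m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "EvaluationReport",
    "contingency",
    "f_measure",
    "entropy_score",
    "cluster_pvalue",
    "clustering_score",
    "count_empty_clusters",
    "evaluate",
]


@dataclass
class ContingencyTable:
    """Class-by-cluster cross-tabulation n_ij with marginal totals."""

    counts: np.ndarray  # classes x clusters
    class_ids: list = field(default_factory=list)
    cluster_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (classes x clusters)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not self.class_ids:
            self.class_ids = list(range(self.counts.shape[0]))
        if not self.cluster_ids:
            self.cluster_ids = list(range(self.counts.shape[1]))

    @property
    def class_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def cluster_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvaluationReport:
    """Bundle of external quality criteria for one clustering run."""

    f_measure: float
    entropy: float
    per_cluster_pvalues: list[float]
    clustering_score: float
    empty_clusters: int
    entropy_log_base: float = 2.0
    cutoff: float = 0.05

    def to_dict(self) -> dict:
        return {
            "f_measure": self.f_measure,
            "entropy": self.entropy,
            "per_cluster_pvalues": self.per_cluster_pvalues,
            "clustering_score": self.clustering_score,
            "empty_clusters": self.empty_clusters,
            "entropy_log_base": self.entropy_log_base,
            "cutoff": self.cutoff,
        }


def contingency(assignments, labels, n_clusters: int | None = None) -> ContingencyTable:
    """Tally objects by (class label, cluster index).

    ``n_clusters`` may exceed ``max(assignments) + 1`` so that clusters left
    empty by defuzzification appear as all-zero columns.
    """
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if assignments.shape[0] != labels.shape[0]:
        raise ValueError(
            f"{assignments.shape[0]} assignments but {labels.shape[0]} labels"
        )
    if assignments.shape[0] == 0:
        raise ValueError("need at least one object")
    class_ids, class_idx = np.unique(labels, return_inverse=True)
    C = int(assignments.max()) + 1 if n_clusters is None else int(n_clusters)
    counts = np.zeros((len(class_ids), C), dtype=int)
    np.add.at(counts, (class_idx, assignments), 1)
    return ContingencyTable(
        counts=counts, class_ids=list(class_ids), cluster_ids=list(range(C))
    )


def f_measure(table: ContingencyTable) -> float:
    """Class-weighted best-cluster F score.

    F(i,j) is the harmonic mean of precision n_ij/n_j and recall n_ij/n_i;
    the overall score weights each class's best F(i,j) by the class
    prevalence n_i/n.  Empty clusters offer no candidates and are skipped.
    """
    n = table.total
    if n < 1:
        raise ValueError("empty contingency table")
    counts = table.counts.astype(float)
    n_i = counts.sum(axis=1)
    n_j = counts.sum(axis=0)
    if np.any(n_i < 1):
        raise ValueError("every class must contain at least one object")
    nonempty = n_j > 0
    if not np.any(nonempty):
        return 0.0
    counts = counts[:, nonempty]
    # 2 prec rec / (prec + rec) = 2 n_ij / (n_i + n_j), zero when n_ij = 0
    F = 2.0 * counts / (n_i[:, None] + n_j[None, nonempty])
    return float(np.sum((n_i / n) * F.max(axis=1)))


def entropy_score(table: ContingencyTable, log_base: float = 2.0) -> float:
    """Cluster-size-weighted entropy of within-cluster class proportions.

    E_j = -sum_i p_ij log(p_ij) with p_ij = n_ij / n_j; the overall score
    is sum_j (n_j/n) E_j.  Zero means every cluster is pure.  Empty
    clusters contribute nothing.
    """
    n = table.total
    if n < 1:
        raise ValueError("empty contingency table")
    counts = table.counts.astype(float)
    n_j = counts.sum(axis=0)
    nonempty = n_j > 0
    p = counts[:, nonempty] / n_j[nonempty]
    plogp = np.zeros_like(p)
    pos = p > 0
    plogp[pos] = p[pos] * np.log(p[pos])
    ent = -plogp.sum(axis=0) / np.log(log_base)
    return float(np.sum((n_j[nonempty] / n) * ent))


def cluster_pvalue(universe_N: int, annotated_M: int, cluster_n: int, hits_m: int) -> float:
    """Hypergeometric upper-tail enrichment p-value P(X >= m).

    Probability of drawing ``hits_m`` or more annotated objects when
    ``cluster_n`` objects are drawn without replacement from a universe of
    ``universe_N`` objects of which ``annotated_M`` are annotated.  The tail
    runs over the feasible support only, so infeasible requests clamp
    rather than go negative.
    """
    if not 0 <= hits_m <= cluster_n <= universe_N:
        raise ValueError("need 0 <= m <= n <= N")
    if not 0 <= annotated_M <= universe_N:
        raise ValueError("need 0 <= M <= N")
    if hits_m == 0:
        return 1.0
    # scipy evaluates the tail via log-gamma internally; sf(m-1) = P(X >= m)
    p = float(stats.hypergeom.sf(hits_m - 1, universe_N, annotated_M, cluster_n))
    return min(max(p, 0.0), 1.0)


def clustering_score(pvalues_per_cluster, cutoff: float = 0.05) -> float:
    """CS: mean of significant clusters' min p-values, insignificant ones
    contributing the cutoff.

    A cluster is significant when its smallest enrichment p-value falls
    below ``cutoff`` (the alpha level).  With ns significant and nl
    insignificant clusters, CS = (sum of significant min-p + nl*cutoff)
    / (ns + nl).  Lower is better; if nothing is significant CS = cutoff.
    """
    p = np.asarray(list(pvalues_per_cluster), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one cluster p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    sig = p < cutoff
    ns = int(sig.sum())
    nl = int(p.size - ns)
    return float((p[sig].sum() + nl * cutoff) / (ns + nl))


def count_empty_clusters(assignments, C: int) -> int:
    """Number of cluster indices in [0, C) receiving no objects."""
    assignments = np.asarray(assignments)
    if assignments.size and (assignments.min() < 0 or assignments.max() >= C):
        raise ValueError("assignments out of range [0, C)")
    return int(C - np.unique(assignments).size)


def min_pvalues_per_cluster(table: ContingencyTable) -> list[float]:
    """Smallest class-enrichment p-value of each nonempty cluster.

    Each ground-truth class acts as an annotation term; for every nonempty
    cluster the hypergeometric upper-tail p-value is computed per class and
    the minimum retained.
    """
    n = table.total
    n_i = table.class_totals
    out: list[float] = []
    for j in range(table.counts.shape[1]):
        n_j = int(table.cluster_totals[j])
        if n_j == 0:
            continue
        ps = [
            cluster_pvalue(n, int(n_i[i]), n_j, int(table.counts[i, j]))
            for i in range(table.counts.shape[0])
        ]
        out.append(min(ps))
    return out


def evaluate(
    assignments,
    labels,
    C: int | None = None,
    log_base: float = 2.0,
    cutoff: float = 0.05,
) -> EvaluationReport:
    """All quality criteria for one hard clustering against class labels."""
    assignments = np.asarray(assignments)
    if C is None:
        C = int(assignments.max()) + 1
    table = contingency(assignments, labels, n_clusters=C)
    pvals = min_pvalues_per_cluster(table)
    return EvaluationReport(
        f_measure=f_measure(table),
        entropy=entropy_score(table, log_base=log_base),
        per_cluster_pvalues=pvals,
        clustering_score=clustering_score(pvals, cutoff=cutoff),
        empty_clusters=count_empty_clusters(assignments, C),
        entropy_log_base=log_base,
        cutoff=cutoff,
    )
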