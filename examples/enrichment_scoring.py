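"""Score cluster significance with hypergeometric enrichment p-values.

Treats each ground-truth class as an annotation term and asks, per
cluster: what is the probability of containing this many (or more)
members of the class by chance?  The per-cluster minimum p-values are
then summarized by the clustering score CS (lower is better).
"""

from ibfcc import cluster_pvalue, clustering_score, contingency
from ibfcc.evaluation import min_pvalues_per_cluster

# 12 objects, two classes, a good cluster 0 and a mixed cluster 1
assignments = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
labels = ["a", "a", "a", "a", "a", "b", "a", "b", "b", "b", "b", "b"]

table = contingency(assignments, labels)
print("class x cluster contingency table:")
print(table.counts)

# one p-value by hand: cluster 0 holds 5 of the 6 'a' objects in a draw of 6
p = cluster_pvalue(universe_N=12, annotated_M=6, cluster_n=6, hits_m=5)
print(f"\nP(>=5 of 6 draws annotated 'a' | 6 of 12 annotated) = {p:.4f}")

pvals = min_pvalues_per_cluster(table)
cs = clustering_score(pvals, cutoff=0.05)
print(f"per-cluster min p-values: {[f'{q:.4f}' for q in pvals]}")
print(f"clustering score CS = {cs:.4f} (clusters with p >= 0.05 contribute "
      "the 0.05 cutoff; lower CS = more significant clustering)")
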