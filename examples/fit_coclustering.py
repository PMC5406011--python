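"""Fit ibFCC on a planted co-cluster matrix and inspect what it found.

Generates a sparse 90x30 matrix with three planted object-block x
feature-block co-clusters, fits the information-bottleneck fuzzy
co-clustering with scale-matched temperatures, and prints the recovered
partition quality.
"""

import numpy as np

from ibfcc import BlockSpec, FitConfig, defuzzify, evaluate, fit, generate_block_data
from ibfcc.tuning import suggest_temperatures

data, feature_blocks = generate_block_data(BlockSpec(C=3, seed=1))
print(f"data: {data.n_objects} objects x {data.n_features} features, "
      f"{(data.values == 0).mean():.0%} zeros")

T_u, T_v = suggest_temperatures(data, C=3)
print(f"scale-matched temperatures: T_u={T_u:.3g}, T_v={T_v:.3g}")

result = fit(data, FitConfig(C=3, T_u=T_u, T_v=T_v, seed=0))
print(f"converged={result.converged} after {result.iterations} iterations; "
      f"objective {result.objective_trace[0]:.6f} -> {result.objective_trace[-1]:.6f}")

assignments, sizes = defuzzify(result.model.U)
report = evaluate(assignments, data.labels, C=3)
print(f"cluster sizes: {[int(s) for s in sizes]} (planted: [30, 30, 30])")
print(f"F-Measure={report.f_measure:.3f} (1.0 = planted blocks recovered exactly), "
      f"entropy={report.entropy:.3f} (0.0 = every cluster pure)")

# feature memberships: per-cluster distributions over the 30 features.
# Once a cluster is pure its rows sit close to the centroid, every feature
# contributes little divergence, and V relaxes toward uniform (1/30 ~ 0.033).
for c in range(3):
    v = result.model.V[c]
    print(f"cluster {c}: feature membership range [{v.min():.4f}, {v.max():.4f}] "
          f"(uniform would be {1 / len(v):.4f})")
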