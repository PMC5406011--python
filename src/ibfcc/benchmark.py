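"""Multi-seed, multi-algorithm comparison sweeps.

Fuzzy co-clustering runs converge to local optima, so algorithms are
compared over repeated random initializations; per-seed rows are always
kept alongside the summary means so run-to-run variance stays inspectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import ALGORITHMS, fit_algorithm
from .core import defuzzify
from .data import DataMatrix
from .evaluation import evaluate

__all__ = ["compare_algorithms"]


def compare_algorithms(
    data: DataMatrix,
    algorithms=ALGORITHMS,
    C: int = 3,
    seeds=range(10),
    log_base: float = 2.0,
    cutoff: float = 0.05,
    **fit_kwargs,
) -> pd.DataFrame:
    """Run each algorithm once per seed and score against the data's labels.

    Returns a tidy table with one row per (algorithm, seed) carrying
    F-Measure, entropy, clustering score, empty-cluster count, iteration
    count and runtime, followed by one ``seed='mean'`` summary row per
    algorithm.  ``fit_kwargs`` (T_u, T_v, m, xi, tau_max, ...) are passed
    to every fit.
    """
    if data.labels is None:
        raise ValueError("comparison requires ground-truth labels on the data")
    rows = []
    for algorithm in algorithms:
        kwargs = dict(fit_kwargs)
        if algorithm != "fcm" and not {"T_u", "T_v"} <= set(kwargs):
            from .tuning import suggest_temperatures

            T_u, T_v = suggest_temperatures(data, C, algorithm=algorithm)
            kwargs.setdefault("T_u", T_u)
            kwargs.setdefault("T_v", T_v)
        for seed in seeds:
            result = fit_algorithm(data, algorithm, C=C, seed=int(seed), **kwargs)
            assignments, _ = defuzzify(result.model.U)
            report = evaluate(
                assignments, data.labels, C=C, log_base=log_base, cutoff=cutoff
            )
            rows.append(
                {
                    "algorithm": algorithm,
                    "seed": int(seed),
                    "C": C,
                    "f_measure": report.f_measure,
                    "entropy": report.entropy,
                    "clustering_score": report.clustering_score,
                    "empty_clusters": report.empty_clusters,
                    "iterations": result.iterations,
                    "converged": result.converged,
                    "runtime_s": result.runtime_s,
                }
            )
    per_seed = pd.DataFrame(rows)
    metric_cols = [
        "f_measure",
        "entropy",
        "clustering_score",
        "empty_clusters",
        "iterations",
        "runtime_s",
    ]
    summaries = []
    for algorithm, grp in per_seed.groupby("algorithm", sort=False):
        row = {"algorithm": algorithm, "seed": "mean", "C": C}
        row.update({c: float(np.mean(grp[c])) for c in metric_cols})
        row["converged"] = bool(grp["converged"].all())
        summaries.append(row)
    return pd.concat([per_seed, pd.DataFrame(summaries)], ignore_index=True)
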