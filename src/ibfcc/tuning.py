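"""Data-driven defaults for the entropy-weight temperatures T_u and T_v.

The temperatures are user-set parameters with no universal value: they must
match the scale of the exponent arguments in the membership updates, which
in turn tracks the magnitude of the distance tensor.  After row
normalization the information-bottleneck distances have magnitude roughly
1/(N*K), so fixed defaults like 1.0 leave memberships uniform on one
dataset and saturate them on another.

The heuristic here measures the mean distance d_bar of the fully fuzzy
starting state (uniform memberships, equal cluster sizes) and sets

    T_u = d_bar / 10         (the U-exponent is a feature-weighted MEAN of
                              d, so its informative variation is a modest
                              fraction of d_bar)
    T_v = 2 * N * d_bar / C  (the V-exponent is a membership-weighted SUM
                              over the ~N/C objects of a cluster, so its
                              scale is N/C times d_bar; the factor 2 keeps
                              feature memberships soft enough that no
                              cluster collapses onto a single feature)

The same reasoning applies to FCCM (whose exponents aggregate the raw
relatedness values) and FCCI (squared centroid gaps), with d_bar replaced
by the corresponding quantity's mean.
"""

from __future__ import annotations

import numpy as np

from .core import compute_centroids, compute_ib_distances
from .data import DataMatrix, normalize_rows

__all__ = ["suggest_temperatures"]


def suggest_temperatures(
    data: DataMatrix,
    C: int,
    algorithm: str = "ibfcc",
    epsilon: float = 1e-6,
    normalize: bool = True,
) -> tuple[float, float]:
    """Scale-matched (T_u, T_v) for one dataset, cluster count and algorithm."""
    if normalize:
        data = normalize_rows(data, epsilon)
    N, K = data.values.shape
    if algorithm == "ibfcc":
        U0 = np.full((C, N), 1.0 / C)
        P = compute_centroids(U0, data)
        sizes = np.full(C, max(N // C, 1))
        d_bar = float(compute_ib_distances(data, P, sizes).d.mean())
    elif algorithm == "fccm":
        d_bar = float(data.values.mean())
    elif algorithm == "fcci":
        d_bar = float(((data.values - data.values.mean(axis=0)) ** 2).mean())
    elif algorithm == "fcm":
        raise ValueError("FCM has no temperature parameters (it uses the fuzzifier m)")
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if d_bar <= 0:
        raise ValueError("degenerate data: zero mean distance scale")
    return d_bar / 10.0, 2.0 * N * d_bar / C
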