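"""Comparison algorithms: FCM, FCCM and FCCI.

All three share the ibFCC data types and FitResult contract so the
benchmark harness can sweep algorithms interchangeably.

* FCM (fuzzy c-means) is one-dimensional fuzzy clustering: it minimizes
  sum_ci u_ci^m ||x_i - v_c||^2 with the classic inverse-distance-ratio
  membership update.  Features are not clustered; V is reported uniform.
* FCCM is entropy-regularized fuzzy co-clustering that MAXIMIZES the
  aggregation sum_cij u_ci v_cj d_ij of raw relatedness, minus the two
  entropy terms, via softmax updates.
* FCCI runs the same alternating loop as ibFCC but with the squared
  Euclidean gap D_cij = (x_ij - p_cj)^2 in place of the information-
  bottleneck distance (aggregation minimized, entropy terms added).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .core import (
    CoClusterModel,
    FitResult,
    IBDistanceTensor,
    InvalidConfigError,
    compute_centroids,
    defuzzify,
    init_memberships,
    objective,
    update_feature_memberships,
    update_object_memberships,
)
from .data import DataMatrix, normalize_rows

__all__ = ["BaselineConfig", "fcm_fit", "fccm_fit", "fcci_fit", "fit_algorithm"]

ALGORITHMS = ("ibfcc", "fcm", "fccm", "fcci")


@dataclass
class BaselineConfig:
    """Hyperparameters for the baseline algorithms.

    ``m`` is the FCM fuzzifier (> 1); ``T_u``/``T_v`` are the entropy
    weights used by FCCM and FCCI.  ``xi``, ``tau_max`` and ``seed`` have
    the same meaning as in :class:`~ibfcc.core.FitConfig`.
    """

    algorithm: str
    C: int
    m: float = 2.0
    T_u: float = 1.0
    T_v: float = 1.0
    xi: float = 1e-5
    tau_max: int = 100
    seed: int = 0
    epsilon: float = 1e-6
    normalize: bool = True

    def validate(self, n_objects: int) -> None:
        if self.algorithm not in ("fcm", "fccm", "fcci"):
            raise InvalidConfigError(f"unknown baseline algorithm {self.algorithm!r}")
        if not 2 <= self.C <= n_objects:
            raise InvalidConfigError(
                f"C must satisfy 2 <= C <= N (got C={self.C}, N={n_objects})"
            )
        if self.algorithm == "fcm" and self.m <= 1:
            raise InvalidConfigError("FCM fuzzifier m must exceed 1")
        if self.algorithm != "fcm" and (self.T_u <= 0 or self.T_v <= 0):
            raise InvalidConfigError("T_u and T_v must be positive")
        if self.xi <= 0 or self.tau_max < 1:
            raise InvalidConfigError("xi must be positive and tau_max >= 1")


def _prepare(data: DataMatrix, config: BaselineConfig) -> DataMatrix:
    return normalize_rows(data, config.epsilon) if config.normalize else data


def fcm_fit(data: DataMatrix, config: BaselineConfig) -> FitResult:
    """Fuzzy c-means by alternating centroid and membership updates.

    Membership: u_ci = 1 / sum_c' (D_ci / D_c'i)^(1/(m-1)) with
    D_ci = ||x_i - v_c||^2; an object coinciding with a centroid receives
    full membership there.  Centroids are u^m-weighted means.  The
    objective sum u^m D is non-increasing across iterations.
    """
    t0 = time.perf_counter()
    config.validate(data.n_objects)
    data = _prepare(data, config)
    X = data.values
    N, K = X.shape
    C, m = config.C, config.m
    U, _ = init_memberships(C, N, K, config.seed)

    trace: list[float] = []
    converged = False
    tau = 0
    for tau in range(1, config.tau_max + 1):
        Um = U**m
        centroids = (Um @ X) / Um.sum(axis=1)[:, None]
        sq = ((X[None, :, :] - centroids[:, None, :]) ** 2).sum(axis=2)  # C,N
        zero_hits = sq <= 1e-14
        U_new = np.zeros_like(U)
        coincident = zero_hits.any(axis=0)
        if np.any(coincident):
            # full membership split among coinciding centroids
            hits = zero_hits[:, coincident]
            U_new[:, coincident] = hits / hits.sum(axis=0, keepdims=True)
        free = ~coincident
        if np.any(free):
            # ratios relative to the nearest centroid keep the powers bounded
            rel = sq[:, free] / sq[:, free].min(axis=0, keepdims=True)
            inv = rel ** (-1.0 / (m - 1.0))
            U_new[:, free] = inv / inv.sum(axis=0, keepdims=True)
        trace.append(float((U_new**m * sq).sum()))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta <= config.xi:
            converged = True
            break

    Um = U**m
    centroids = (Um @ X) / Um.sum(axis=1)[:, None]
    _, sizes = defuzzify(U)
    V = np.full((C, K), 1.0 / K)  # FCM does not partition features
    model = CoClusterModel(U=U, V=V, P=centroids, sizes=sizes)
    return FitResult(
        model=model,
        objective_trace=trace,
        iterations=tau,
        converged=converged,
        config=config,  # type: ignore[arg-type]
        runtime_s=time.perf_counter() - t0,
        algorithm="fcm",
    )


def fccm_fit(data: DataMatrix, config: BaselineConfig) -> FitResult:
    """FCCM: entropy-regularized co-clustering maximizing raw aggregation.

    u_ci is proportional to exp(sum_j v_cj d_ij / T_u) normalized over
    clusters; v_cj proportional to exp(sum_i u_ci d_ij / T_v) normalized
    over features.  The objective (aggregation minus entropies) is
    non-decreasing across iterations.
    """
    t0 = time.perf_counter()
    config.validate(data.n_objects)
    data = _prepare(data, config)
    D = data.values  # N x K relatedness, not a per-cluster distance
    N, K = D.shape
    C = config.C
    U, V = init_memberships(C, N, K, config.seed)

    def fccm_objective(U: np.ndarray, V: np.ndarray) -> float:
        agg = float(np.einsum("ci,cj,ij->", U, V, D))
        ent_u = float(np.sum(np.where(U > 0, U * np.log(np.where(U > 0, U, 1.0)), 0.0)))
        ent_v = float(np.sum(np.where(V > 0, V * np.log(np.where(V > 0, V, 1.0)), 0.0)))
        return agg - config.T_u * ent_u - config.T_v * ent_v

    trace: list[float] = []
    converged = False
    tau = 0
    for tau in range(1, config.tau_max + 1):
        ev = (U @ D) / config.T_v  # C,K
        ev -= ev.max(axis=1, keepdims=True)
        V = np.exp(ev)
        V /= V.sum(axis=1, keepdims=True)
        eu = (V @ D.T) / config.T_u  # C,N
        eu -= eu.max(axis=0, keepdims=True)
        U_new = np.exp(eu)
        U_new /= U_new.sum(axis=0, keepdims=True)
        trace.append(fccm_objective(U_new, V))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta <= config.xi:
            converged = True
            break

    P = compute_centroids(U, data)
    _, sizes = defuzzify(U)
    model = CoClusterModel(U=U, V=V, P=P, sizes=sizes)
    return FitResult(
        model=model,
        objective_trace=trace,
        iterations=tau,
        converged=converged,
        config=config,  # type: ignore[arg-type]
        runtime_s=time.perf_counter() - t0,
        algorithm="fccm",
    )


def squared_gap_distances(data: DataMatrix, P: np.ndarray) -> IBDistanceTensor:
    """FCCI's distance tensor: D_cij = (x_ij - p_cj)^2."""
    d = (data.values[None, :, :] - P[:, None, :]) ** 2
    return IBDistanceTensor(d=d, t=np.zeros_like(d))


def fcci_fit(data: DataMatrix, config: BaselineConfig) -> FitResult:
    """FCCI: the ibFCC loop with a squared Euclidean per-feature distance.

    Centroids are membership-weighted means; the U- and V-updates are the
    same entropy-regularized softmins over the aggregated distances.
    """
    t0 = time.perf_counter()
    config.validate(data.n_objects)
    data = _prepare(data, config)
    N, K = data.values.shape
    U, V = init_memberships(config.C, N, K, config.seed)

    trace: list[float] = []
    converged = False
    tau = 0
    for tau in range(1, config.tau_max + 1):
        P = compute_centroids(U, data)
        dist = squared_gap_distances(data, P)
        V = update_feature_memberships(U, dist, config.T_v)
        U_new = update_object_memberships(V, dist, config.T_u)
        trace.append(objective(U_new, V, dist, config.T_u, config.T_v))
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta <= config.xi:
            converged = True
            break

    P = compute_centroids(U, data)
    _, sizes = defuzzify(U)
    model = CoClusterModel(U=U, V=V, P=P, sizes=sizes)
    return FitResult(
        model=model,
        objective_trace=trace,
        iterations=tau,
        converged=converged,
        config=config,  # type: ignore[arg-type]
        runtime_s=time.perf_counter() - t0,
        algorithm="fcci",
    )


def fit_algorithm(data: DataMatrix, algorithm: str, **kwargs) -> FitResult:
    """Dispatch by algorithm name ('ibfcc', 'fcm', 'fccm' or 'fcci')."""
    from .core import FitConfig, fit

    if algorithm == "ibfcc":
        allowed = {f for f in FitConfig.__dataclass_fields__}
        cfg = FitConfig(**{k: v for k, v in kwargs.items() if k in allowed})
        return fit(data, cfg)
    if algorithm in ("fcm", "fccm", "fcci"):
        allowed = {f for f in BaselineConfig.__dataclass_fields__} - {"algorithm"}
        bcfg = BaselineConfig(
            algorithm=algorithm, **{k: v for k, v in kwargs.items() if k in allowed}
        )
        return {"fcm": fcm_fit, "fccm": fccm_fit, "fcci": fcci_fit}[algorithm](
            data, bcfg
        )
    raise InvalidConfigError(f"unknown algorithm {algorithm!r}")
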