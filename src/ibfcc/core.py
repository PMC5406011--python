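"""The ibFCC fuzzy co-clustering algorithm.

ibFCC simultaneously partitions the N objects and K features of a
nonnegative matrix into C fuzzy co-clusters by Picard iteration over
closed-form membership updates.  It minimizes

    J = sum_cij u_ci v_cj d_cij + T_u sum_ci u_ci ln u_ci
                                + T_v sum_cj v_cj ln v_cj

subject to sum_c u_ci = 1 for every object i and sum_j v_cj = 1 for every
cluster c.  The distance d_cij is the j-th component of the information-
bottleneck merge cost: the loss of mutual information with the feature
variable incurred by merging object i (a singleton cluster with prior 1/N)
into cluster c (prior |c|/N, where |c| is the defuzzified cluster size):

    t_cij = (x_ij + |c| p_cj) / (1 + |c|)
    d_cij = (1/N) x_ij ln(x_ij / t_cij) + (|c|/N) p_cj ln(p_cj / t_cij)

with centroids p_cj computed as membership-weighted row means.  The entropy
terms weighted by T_u and T_v control how fuzzy the memberships are: large
T gives uniform memberships, small T gives nearly hard assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix, normalize_rows

__all__ = [
    "FitConfig",
    "CoClusterModel",
    "IBDistanceTensor",
    "FitResult",
    "init_memberships",
    "compute_centroids",
    "defuzzify",
    "compute_ib_distances",
    "ib_merge_cost",
    "update_feature_memberships",
    "update_object_memberships",
    "objective",
    "objective_lower_bound",
    "fit",
]


class InvalidConfigError(ValueError):
    """Raised when a fitting configuration violates its invariants."""


@dataclass
class FitConfig:
    """Hyperparameters of an ibFCC run.

    Attributes
    ----------
    C : int
        Number of co-clusters (2 <= C <= N); chosen by the user.
    T_u : float
        Object-membership fuzziness weight (> 0).  Larger values give
        softer object memberships.
    T_v : float
        Feature-membership fuzziness weight (> 0).
    xi : float
        Convergence tolerance: iteration stops when the largest absolute
        change of any object membership falls to ``xi`` or below.
    tau_max : int
        Iteration cap.
    seed : int
        Seed for the random membership initialization.
    epsilon : float
        Smoothing constant used when row-normalizing the data.
    normalize : bool
        Whether to row-normalize the data to distributions before fitting
        (recommended; the IB distance is defined on distributions).
    """

    C: int
    T_u: float = 1.0
    T_v: float = 1.0
    xi: float = 1e-5
    tau_max: int = 100
    seed: int = 0
    epsilon: float = 1e-6
    normalize: bool = True

    def validate(self, n_objects: int) -> None:
        if not 2 <= self.C <= n_objects:
            raise InvalidConfigError(
                f"C must satisfy 2 <= C <= N (got C={self.C}, N={n_objects})"
            )
        if self.T_u <= 0 or self.T_v <= 0:
            raise InvalidConfigError("T_u and T_v must be positive")
        if self.xi <= 0:
            raise InvalidConfigError("xi must be positive")
        if self.tau_max < 1:
            raise InvalidConfigError("tau_max must be at least 1")


@dataclass
class CoClusterModel:
    """A fitted fuzzy co-clustering.

    U is C x N (u_ci, columns sum to 1 over clusters), V is C x K (v_cj,
    rows sum to 1 over features), P is the C x K centroid matrix, and
    ``sizes`` holds the defuzzified cluster sizes |c| (summing to N).
    """

    U: np.ndarray
    V: np.ndarray
    P: np.ndarray
    sizes: np.ndarray

    @property
    def assignments(self) -> np.ndarray:
        """Hard object assignments (argmax over clusters, lowest index wins)."""
        return defuzzify(self.U)[0]


@dataclass
class IBDistanceTensor:
    """The C x N x K information-bottleneck distances d_cij and blends t_cij."""

    d: np.ndarray
    t: np.ndarray


@dataclass
class FitResult:
    """Outcome of a fitting run: model, objective trajectory, and bookkeeping."""

    model: CoClusterModel
    objective_trace: list[float]
    iterations: int
    converged: bool
    config: FitConfig
    max_constraint_violation: float = 0.0
    runtime_s: float | None = None
    algorithm: str = "ibfcc"
    extras: dict = field(default_factory=dict)


def init_memberships(
    C: int, N: int, K: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random strictly positive memberships satisfying both sum constraints.

    U entries are i.i.d. uniform(0,1) renormalized per object column;
    V likewise per cluster row.  The same seed reproduces the same matrices.
    """
    if C > N:
        raise InvalidConfigError(f"cannot place {N} objects into {C} clusters")
    if C < 2 or K < 1:
        raise InvalidConfigError("need C >= 2 and K >= 1")
    rng = np.random.default_rng(seed)
    U = rng.uniform(0.1, 1.0, size=(C, N))
    U /= U.sum(axis=0, keepdims=True)
    V = rng.uniform(0.1, 1.0, size=(C, K))
    V /= V.sum(axis=1, keepdims=True)
    return U, V


def compute_centroids(U: np.ndarray, data: DataMatrix) -> np.ndarray:
    """Membership-weighted mean rows: p_cj = sum_i u_ci x_ij / sum_i u_ci."""
    weights = U.sum(axis=1)
    if np.any(weights <= 0):
        raise ValueError("a cluster has zero total membership; cannot form centroid")
    return (U @ data.values) / weights[:, None]


def defuzzify(U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard assignments and cluster sizes from a fuzzy membership matrix.

    Each object goes to its highest-membership cluster; ties break to the
    lowest cluster index (np.argmax's convention), which keeps the result
    deterministic.
    """
    assignments = np.argmax(U, axis=0)
    C = U.shape[0]
    sizes = np.bincount(assignments, minlength=C)
    return assignments, sizes


def _xlogx_over(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num * ln(num/den) with the KL convention 0 ln(0/t) = 0."""
    num_b, den_b = np.broadcast_arrays(np.asarray(num, float), np.asarray(den, float))
    out = np.zeros(num_b.shape)
    pos = num_b > 0
    out[pos] = num_b[pos] * np.log(num_b[pos] / den_b[pos])
    return out


def compute_ib_distances(
    data: DataMatrix, P: np.ndarray, sizes: np.ndarray
) -> IBDistanceTensor:
    """Information-bottleneck distance of every object row from every centroid.

    For cluster c with defuzzified size ``|c|`` and centroid row p_c, the
    blend t_cij = (x_ij + |c| p_cj)/(1 + |c|) is the prior-weighted mixture
    of the object row and the centroid, and

        d_cij = (1/N) x_ij ln(x_ij/t_cij) + (|c|/N) p_cj ln(p_cj/t_cij).

    Summed over j this equals the mutual-information loss of merging the
    singleton cluster {i} (prior 1/N) into cluster c (prior |c|/N); each
    component is nonnegative by the log-sum inequality.  Empty clusters
    (|c| = 0) are treated as |c| = 1: a truly empty cluster would make
    d_cij vanish for every object and act as a universal attractor.
    """
    x = data.values
    if np.any(x < 0) or np.any(P < 0):
        raise ValueError("data and centroids must be nonnegative")
    N = x.shape[0]
    sz = np.maximum(np.asarray(sizes, dtype=float), 1.0)[:, None, None]  # C,1,1
    xb = x[None, :, :]  # 1,N,K
    pb = P[:, None, :]  # C,1,K
    t = (xb + sz * pb) / (1.0 + sz)
    d = _xlogx_over(xb, t) / N + (sz / N) * _xlogx_over(pb, t)
    # exact zeros where both x and p vanish (t = 0 there); clip fp dust
    d = np.where((xb == 0) & (pb == 0), 0.0, d)
    d = np.maximum(d, 0.0)
    return IBDistanceTensor(d=d, t=np.broadcast_to(t, d.shape).copy())


def ib_merge_cost(
    prior1: float,
    dist1: np.ndarray,
    prior2: float,
    dist2: np.ndarray,
    atol: float = 1e-8,
) -> float:
    """Mutual-information loss of merging two clusters (test oracle).

    For clusters with priors p(c1), p(c2) and conditional feature
    distributions p(y|c1), p(y|c2), merging them replaces both with the
    prior-weighted mixture, and the information about Y lost is

        sum_{i in {1,2}} p(c_i) sum_y p(y|c_i) ln( p(y|c_i) / p(y|merged) ).

    This is a scaled Jensen-Shannon divergence and is always nonnegative.
    """
    if prior1 <= 0 or prior2 <= 0:
        raise ValueError("priors must be positive")
    d1 = np.asarray(dist1, dtype=float)
    d2 = np.asarray(dist2, dtype=float)
    for name, dist in (("dist1", d1), ("dist2", d2)):
        if abs(dist.sum() - 1.0) > atol:
            raise ValueError(f"{name} must sum to 1 (got {dist.sum():.6g})")
    merged = (prior1 * d1 + prior2 * d2) / (prior1 + prior2)
    cost = prior1 * _xlogx_over(d1, merged).sum() + prior2 * _xlogx_over(d2, merged).sum()
    return float(cost)


def _softmin(neg_exponents: np.ndarray, axis: int) -> np.ndarray:
    """exp(e)/sum exp(e) along ``axis``, shifted by the max for stability."""
    shifted = neg_exponents - neg_exponents.max(axis=axis, keepdims=True)
    w = np.exp(shifted)
    return w / w.sum(axis=axis, keepdims=True)


def update_feature_memberships(
    U: np.ndarray, dist: IBDistanceTensor, T_v: float
) -> np.ndarray:
    """Closed-form V-update: softmin over features of membership-weighted cost.

    v_cj = exp(-sum_i u_ci d_cij / T_v), normalized over j per cluster.
    """
    if not np.all(np.isfinite(dist.d)):
        raise ValueError("distance tensor contains non-finite values")
    agg = np.einsum("ci,cij->cj", U, dist.d)  # C,K
    return _softmin(-agg / T_v, axis=1)


def update_object_memberships(
    V: np.ndarray, dist: IBDistanceTensor, T_u: float
) -> np.ndarray:
    """Closed-form U-update: softmin over clusters of feature-weighted cost.

    u_ci = exp(-sum_j v_cj d_cij / T_u), normalized over c per object.
    """
    if not np.all(np.isfinite(dist.d)):
        raise ValueError("distance tensor contains non-finite values")
    agg = np.einsum("cj,cij->ci", V, dist.d)  # C,N
    return _softmin(-agg / T_u, axis=0)


def _entropy_term(M: np.ndarray) -> float:
    """sum m ln m with 0 ln 0 = 0."""
    pos = M > 0
    return float(np.sum(M[pos] * np.log(M[pos])))


def objective(
    U: np.ndarray,
    V: np.ndarray,
    dist: IBDistanceTensor,
    T_u: float,
    T_v: float,
) -> float:
    """The ibFCC objective: aggregation cost plus entropy regularizers."""
    agg = float(np.einsum("ci,cj,cij->", U, V, dist.d))
    return agg + T_u * _entropy_term(U) + T_v * _entropy_term(V)


def objective_lower_bound(config: FitConfig, N: int, K: int) -> float:
    """The constant M = T_u N ln(1/C) + T_v C ln(1/K) bounding J from below.

    The aggregation term is nonnegative and each entropy term is minimized
    by the uniform membership, so no iterate can push J below M.
    """
    return config.T_u * N * np.log(1.0 / config.C) + config.T_v * config.C * np.log(
        1.0 / K
    )


def fit(data: DataMatrix, config: FitConfig) -> FitResult:
    """Fit ibFCC by Picard iteration.

    Each iteration recomputes, in order: defuzzified cluster sizes,
    centroids from the current U, the IB distance tensor, then the V- and
    U-updates.  Iteration stops when the largest absolute change of any
    object membership is at most ``config.xi``, or at ``config.tau_max``
    iterations.  The objective is recorded after every iteration.
    """
    import time

    t0 = time.perf_counter()
    config.validate(data.n_objects)
    if config.normalize:
        data = normalize_rows(data, config.epsilon)
    N, K = data.values.shape
    U, V = init_memberships(config.C, N, K, config.seed)

    trace: list[float] = []
    converged = False
    max_violation = 0.0
    tau = 0
    for tau in range(1, config.tau_max + 1):
        _, sizes = defuzzify(U)
        P = compute_centroids(U, data)
        dist = compute_ib_distances(data, P, sizes)
        V = update_feature_memberships(U, dist, config.T_v)
        U_new = update_object_memberships(V, dist, config.T_u)
        trace.append(objective(U_new, V, dist, config.T_u, config.T_v))
        max_violation = max(
            max_violation,
            float(np.abs(U_new.sum(axis=0) - 1.0).max()),
            float(np.abs(V.sum(axis=1) - 1.0).max()),
        )
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta <= config.xi:
            converged = True
            break

    _, sizes = defuzzify(U)
    P = compute_centroids(U, data)
    model = CoClusterModel(U=U, V=V, P=P, sizes=sizes)
    return FitResult(
        model=model,
        objective_trace=trace,
        iterations=tau,
        converged=converged,
        config=config,
        max_constraint_violation=max_violation,
        runtime_s=time.perf_counter() - t0,
        algorithm="ibfcc",
    )
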