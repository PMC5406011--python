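# Methods

## The co-clustering model

ibFCC partitions the `N` objects and `K` features of a nonnegative matrix
into `C` fuzzy co-clusters by minimizing an aggregation cost plus two
entropy regularizers,

```
J(U, V) = Σ_cij u_ci v_cj d_cij + T_u Σ_ci u_ci ln u_ci + T_v Σ_cj v_cj ln v_cj,
```

with `Σ_c u_ci = 1` per object and `Σ_j v_cj = 1` per cluster. Setting the
gradient of the Lagrangian to zero gives closed-form block updates — a
softmin over clusters for `U` and over features for `V` — which are
alternated (Picard iteration) with a centroid and distance refresh:

1. defuzzify `U` (argmax per object, ties to the lowest cluster index) to
   get cluster sizes `|c|`;
2. centroids `p_cj = Σ_i u_ci x_ij / Σ_i u_ci` (membership-weighted means —
   a pragmatic surrogate, since the exact minimizing centroid for the IB
   distance has no closed form);
3. distances `d_cij = (1/N) x_ij ln(x_ij/t_cij) + (|c|/N) p_cj ln(p_cj/t_cij)`
   with the blend `t_cij = (x_ij + |c| p_cj)/(1 + |c|)`;
4. `V`-update, then `U`-update;
5. stop when `max_ci |u_ci(τ) − u_ci(τ−1)| ≤ ξ` or `τ = τ_max`.

Summed over features, `d_cij` is exactly the loss of mutual information
with the feature variable incurred by merging the singleton cluster `{i}`
(prior `1/N`) with cluster `c` (prior `|c|/N`): a Jensen–Shannon-type
divergence, nonnegative term by term (log-sum inequality), and zero when
the object row equals the centroid. `ib_merge_cost` implements the generic
two-cluster information loss independently and serves as the test oracle
for the tensor computation.

### Convergence properties, and what is *not* guaranteed

Each membership update is a true block minimizer of `J` with the other
factors fixed (verified in tests against random feasible alternatives),
and `J` is bounded below by `M = T_u N ln(1/C) + T_v C ln(1/K)` (the
aggregation term is nonnegative; each entropy term is minimized by the
uniform membership). Monotone decrease across *full* iterations is,
however, **not** guaranteed: the centroid formula is a heuristic surrogate
and the defuzzified sizes `|c|` enter the distances discretely, so a size
flip can raise `J`. In practice most runs converge in 10–30 iterations;
occasionally a run oscillates between size configurations until `τ_max`
(the result is then the last iterate, flagged `converged=False`). Tests
assert the block-minimizer property and the bound, not full-iteration
monotonicity.

## Data preparation

The IB distance is defined on conditional feature distributions, so rows
are normalized before fitting (`normalize=True`, the default): rows
containing zeros get `epsilon = 1e-6` added to every entry, then each row
is divided by its sum, making rows strictly positive distributions. An
all-zero row with `epsilon = 0` is a degenerate-input error. Natural
logarithms are used throughout the core, with the conventions
`0·ln 0 = 0` and `0·ln(0/t) = 0`; if `x_ij = p_cj = 0` then `d_cij = 0`.

**Empty clusters.** If defuzzification leaves cluster `c` empty, `|c| = 0`
would make `d_cij ≡ 0` for every object — a universal attractor. The
distance computation therefore substitutes `|c| = 1` (singleton-merge
semantics); the centroid remains defined because fuzzy memberships stay
strictly positive. Sizes are refreshed every iteration.

## Choosing the temperatures

`T_u` and `T_v` are user parameters with no universal default. After row
normalization `d_cij` has magnitude roughly `1/(N·K)`, so a fixed `T` of
order 1 leaves memberships uniform on realistic sizes. The package derives
scale-matched values (`ibfcc.tuning.suggest_temperatures`) from
`d̄` = mean distance of the fully fuzzy start (uniform `U`, equal sizes):

- `T_u = d̄ / 10` — the `U`-exponent is a feature-weighted *mean* of `d`,
  whose informative variation is a fraction of `d̄`;
- `T_v = 2 N d̄ / C` — the `V`-exponent is a *sum* over the ≈`N/C` members
  of a cluster, so its scale is `N d̄ / C`; the factor 2 keeps feature
  memberships soft enough that no cluster collapses onto a single feature.

The divisors were fixed once by a robustness scan over seven planted-block
configurations (maximizing mean recovery F-Measure with zero empty
clusters) and apply unchanged to all data. The same rule is used for the
baselines with `d̄` replaced by the corresponding scale: mean relatedness
for FCCM, mean squared centroid gap for FCCI.

## Baselines

- **FCM** — one-dimensional fuzzy c-means, fuzzifier `m = 2` by default:
  inverse-distance-ratio memberships and `u^m`-weighted centroids; the
  objective is provably non-increasing (asserted in tests). Objects
  coinciding with a centroid get full membership there. Features are not
  clustered (`V` is reported uniform).
- **FCCM** — entropy-regularized co-clustering that *maximizes* aggregation
  of the raw relatedness `d_ij` (softmax updates); its objective is
  non-decreasing. The optimization direction follows the original
  formulation of the method.
- **FCCI** — the same alternating loop as ibFCC with the squared Euclidean
  gap `(x_ij − p_cj)²` in place of the IB distance (distance minimized,
  entropy terms added, softmin updates).

All three share the data types, preparation, stopping rule and result
contract of the core, so the benchmark harness sweeps them
interchangeably.

## Evaluation criteria

From the class-by-cluster contingency table `n_ij`:

- **F-Measure** `F = Σ_i (n_i/n) max_j 2 n_ij/(n_i + n_j)` (the weighted
  best harmonic mean of precision `n_ij/n_j` and recall `n_ij/n_i`);
  empty clusters offer no candidates and are skipped.
- **Entropy** `E = Σ_j (n_j/n) E_j`, `E_j = −Σ_i p_ij log p_ij` with
  `p_ij = n_ij/n_j`. The log base is a parameter (default 2); empty
  clusters contribute nothing.
- **Enrichment p-value**: treating each class as an annotation term, the
  hypergeometric upper tail `P(X ≥ m)` of observing `m` annotated objects
  in a cluster of size `n` drawn from a universe of `N` with `M`
  annotated (scipy's log-gamma implementation; the tail is restricted to
  the feasible support). The **clustering score** averages significant
  clusters' minimum p-values, with insignificant clusters contributing
  the `cutoff` (α = 0.05).
- **Empty-cluster count**, reported separately rather than folded into
  F/entropy.

## The synthetic generator

`generate_block_data` emulates sparse nonnegative matrices with planted
co-cluster structure: a block-diagonal mean grid (in-block mean `signal`,
default 1.0; elsewhere `background`, default 0.1 — a 10:1 contrast), entry
noise `max(0, Normal(mean, noise_sd))` with `noise_sd = 0.05` (clamping
preserves nonnegativity without rejection sampling), and independent
zeroing with probability `sparsity` (default 0.5; the sparse
high-dimensional benchmark uses 0.8 with K = 200). Feature blocks are
planted disjoint. Planted object blocks double as ground-truth labels.

What this does *not* emulate: heavy-tailed count distributions and burstiness
of real document-term matrices, correlated features, overlapping
co-clusters, and class imbalance. Passing the recovery tests therefore
shows the optimization machinery works as specified on well-posed block
structure, not that the method attains any particular accuracy on real
corpora.

## Numerical choices

- Softmax/softmin exponents are shifted by their per-column (or per-row)
  maximum before exponentiation; all membership post-conditions are
  shift-invariant, so any equivalent stabilization is conformant.
- Distance entries are clipped at 0 to remove negative floating-point
  dust (each term is provably ≥ 0).
- FCM membership ratios are computed relative to the nearest centroid to
  bound the powers; squared distances ≤ 1e-14 count as coincident.
- Defaults: `ξ = 1e-5`, `τ_max = 100`, `epsilon = 1e-6`, defuzzification
  ties to the lowest cluster index, a single integer seed drives all
  initialization.

## Known limitations

- `C` must be chosen by the user; there is no model selection.
- The centroid surrogate plus discrete size refresh means no monotone
  convergence guarantee (see above); use several restarts (the `compare`
  harness and the benchmark protocol default to 10).
- On planted-block synthetics with matched `C` and scale-matched
  temperatures, FCCM is an equally strong recoverer — the sparse-data
  advantages of the IB distance reported on real corpora (fewer empty
  clusters, higher F) appear here as parity on F with consistently zero
  empty clusters, not as a strict ordering; see the benchmark example.
- Feature memberships `V` flatten toward uniform once clusters are pure
  (all features then contribute near-zero divergence), so `V` is most
  informative early in a fit or on imperfectly separated clusters.
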