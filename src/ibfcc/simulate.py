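"""Synthetic planted-co-cluster matrices.

Generates sparse nonnegative object-by-feature matrices with a known
block-diagonal co-cluster structure: object block b and feature block b
intersect in a region of elevated mean (``signal``) against a low
background, with truncated-Gaussian noise and independent zeroing to mimic
the sparse, high-dimensional matrices (document-term counts, expression
panels) the co-clustering algorithms target.  The planted object blocks
double as ground-truth class labels for the evaluation criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = ["BlockSpec", "generate_block_data"]


@dataclass
class BlockSpec:
    """Recipe for one planted-block matrix.

    Attributes
    ----------
    C : int
        Number of planted co-clusters.
    objects_per_cluster, features_per_cluster : list of int
        Block sizes along each axis (length C, all >= 1).
    signal : float
        Mean of in-block entries; must exceed ``background``.
    background : float
        Mean of out-of-block entries (>= 0).
    sparsity : float
        Probability in [0, 1) of independently zeroing each entry.
    noise_sd : float
        Standard deviation of the additive Gaussian noise; draws are
        clamped at zero to preserve nonnegativity.
    seed : int
        Seed; identical specs with identical seeds reproduce bitwise.
    """

    C: int
    objects_per_cluster: list[int] = field(default_factory=lambda: [30, 30, 30])
    features_per_cluster: list[int] = field(default_factory=lambda: [10, 10, 10])
    signal: float = 1.0
    background: float = 0.1
    sparsity: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.C < 1:
            raise ValueError("C must be at least 1")
        if len(self.objects_per_cluster) != self.C or len(self.features_per_cluster) != self.C:
            raise ValueError("objects/features_per_cluster must have length C")
        if any(v < 1 for v in self.objects_per_cluster + self.features_per_cluster):
            raise ValueError("all block sizes must be >= 1")
        if not self.signal > self.background >= 0:
            raise ValueError("need signal > background >= 0")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_block_data(spec: BlockSpec) -> tuple[DataMatrix, np.ndarray]:
    """Draw one planted-block matrix.

    Returns the DataMatrix (with planted object-block labels attached) and
    the planted feature-block labels.  Entry means form a block-diagonal
    grid (signal on the diagonal blocks, background elsewhere); each entry
    is max(0, Normal(mean, noise_sd)), then zeroed with probability
    ``sparsity``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    obj_labels = np.repeat(np.arange(spec.C), spec.objects_per_cluster)
    feat_labels = np.repeat(np.arange(spec.C), spec.features_per_cluster)
    means = np.where(
        obj_labels[:, None] == feat_labels[None, :], spec.signal, spec.background
    )
    values = np.maximum(0.0, rng.normal(means, spec.noise_sd))
    if spec.sparsity > 0:
        values[rng.random(values.shape) < spec.sparsity] = 0.0
    n, k = values.shape
    data = DataMatrix(
        values=values,
        object_ids=[f"obj{i}" for i in range(n)],
        feature_ids=[f"feat{j}" for j in range(k)],
        labels=[int(c) for c in obj_labels],
    )
    return data, feat_labels
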