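"""Object-by-feature data container and row preparation.

The algorithms in this package operate on a nonnegative matrix whose rows
are objects (documents, samples) and whose columns are features (words,
measurements).  The information-bottleneck distance is defined on
conditional distributions over features, so rows are normalized to strictly
positive probability vectors before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class DegenerateInputError(ValueError):
    """Raised when an input matrix cannot be prepared (e.g. an all-zero row)."""


@dataclass
class DataMatrix:
    """A nonnegative N x K object-by-feature table with optional class labels.

    Attributes
    ----------
    values : ndarray of shape (N, K)
        Nonnegative relatedness measures x_ij between object i and feature j.
    object_ids : list of str
        N identifiers, one per row.
    feature_ids : list of str
        K identifiers, one per column.
    labels : list or None
        Optional ground-truth class label per object, used only by the
        evaluation module.
    """

    values: np.ndarray
    object_ids: list[str] = field(default=None)  # type: ignore[assignment]
    feature_ids: list[str] = field(default=None)  # type: ignore[assignment]
    labels: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, k = self.values.shape
        if n < 1 or k < 1:
            raise ValueError("matrix must have at least one row and one column")
        if np.any(self.values < 0):
            raise ValueError("matrix entries must be nonnegative")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix entries must be finite")
        if self.object_ids is None:
            self.object_ids = [f"obj{i}" for i in range(n)]
        if self.feature_ids is None:
            self.feature_ids = [f"feat{j}" for j in range(k)]
        if len(self.object_ids) != n:
            raise ValueError(f"expected {n} object ids, got {len(self.object_ids)}")
        if len(self.feature_ids) != k:
            raise ValueError(f"expected {k} feature ids, got {len(self.feature_ids)}")
        if self.labels is not None and len(self.labels) != n:
            raise ValueError(f"expected {n} labels, got {len(self.labels)}")

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def normalize_rows(data: DataMatrix, epsilon: float = 1e-6) -> DataMatrix:
    """Scale each row to a strictly positive distribution summing to one.

    Rows containing any zero entry first get ``epsilon`` added to every
    entry (smoothing), then every row is divided by its sum.  Rows already
    strictly positive are left unsmoothed, so the operation is idempotent
    up to epsilon re-smoothing.

    Parameters
    ----------
    data : DataMatrix
        Nonnegative input matrix.
    epsilon : float
        Smoothing constant added to rows that contain zeros.

    Raises
    ------
    DegenerateInputError
        If a row is entirely zero and ``epsilon`` is zero, since such a row
        cannot be normalized.
    """
    x = data.values.copy()
    has_zero = np.any(x == 0.0, axis=1)
    all_zero = np.all(x == 0.0, axis=1)
    if epsilon <= 0 and np.any(all_zero):
        bad = int(np.flatnonzero(all_zero)[0])
        raise DegenerateInputError(
            f"row {data.object_ids[bad]!r} is entirely zero and epsilon is 0; "
            "cannot normalize to a distribution"
        )
    x[has_zero] += epsilon
    sums = x.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        bad = int(np.flatnonzero(sums.ravel() <= 0)[0])
        raise DegenerateInputError(
            f"row {data.object_ids[bad]!r} has nonpositive sum after smoothing"
        )
    return replace(data, values=x / sums)
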