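"""Readers and writers for matrices, labels, memberships and reports.

Dense matrices travel as CSV/TSV with a header row of feature ids and a
first column of object ids; sparse matrices as MatrixMarket coordinate
files with optional sidecar id files (one id per line, ``<stem>.rows.txt``
and ``<stem>.cols.txt``).  Labels are a two-column CSV (object_id, class).
Fit results and evaluation reports serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .core import CoClusterModel, FitResult, defuzzify
from .data import DataMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "attach_labels",
    "write_memberships",
    "write_assignments",
    "write_fit_result",
    "write_report",
]


class FormatError(ValueError):
    """Raised for malformed input files."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    if suffix in (".mtx",):
        return "mtx"
    raise FormatError(f"cannot infer matrix format from {path.name!r}; pass format=")


def read_matrix(path, fmt: str | None = None) -> DataMatrix:
    """Read an object-by-feature matrix from CSV, TSV or MatrixMarket.

    For MatrixMarket files, object/feature ids are read from
    ``<stem>.rows.txt`` / ``<stem>.cols.txt`` beside the matrix if present,
    otherwise generated.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"malformed {fmt} matrix {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path} has a header but no feature columns")
        values = df.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise FormatError(f"{path} contains missing or non-finite entries")
        if np.any(values < 0):
            raise FormatError(f"{path} contains negative entries")
        return DataMatrix(
            values=values,
            object_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
        )
    if fmt == "mtx":
        mat = spio.mmread(path)
        values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=float)
        if np.any(values < 0):
            raise FormatError(f"{path} contains negative entries")
        rows_file = path.with_suffix("").with_suffix(".rows.txt")
        cols_file = path.with_suffix("").with_suffix(".cols.txt")
        object_ids = (
            rows_file.read_text().split() if rows_file.exists() else None
        )
        feature_ids = (
            cols_file.read_text().split() if cols_file.exists() else None
        )
        return DataMatrix(values=values, object_ids=object_ids, feature_ids=feature_ids)
    raise FormatError(f"unknown matrix format {fmt!r}")


def write_matrix(data: DataMatrix, path, fmt: str | None = None) -> None:
    """Write a DataMatrix as CSV, TSV or MatrixMarket (with id sidecars)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(data.values, index=data.object_ids, columns=data.feature_ids)
        df.to_csv(path, sep=sep, float_format="%.15g")
        return
    if fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(data.values), precision=15)
        path.with_suffix("").with_suffix(".rows.txt").write_text(
            "\n".join(data.object_ids) + "\n"
        )
        path.with_suffix("").with_suffix(".cols.txt").write_text(
            "\n".join(data.feature_ids) + "\n"
        )
        return
    raise FormatError(f"unknown matrix format {fmt!r}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (object_id, class) CSV into an id -> label mapping."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"malformed labels file {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise FormatError(
            f"labels file {path} must have exactly two columns (object_id, class); "
            f"found {df.shape[1]}"
        )
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"labels file {path} repeats object id {dup!r}")
    return dict(zip(ids, df.iloc[:, 1].astype(str)))


def attach_labels(data: DataMatrix, label_map: dict[str, str]) -> DataMatrix:
    """Attach labels to a DataMatrix, requiring every labeled id to exist."""
    known = set(data.object_ids)
    unknown = [k for k in label_map if k not in known]
    if unknown:
        raise FormatError(
            f"label file names object id {unknown[0]!r} absent from the matrix"
        )
    missing = [i for i in data.object_ids if i not in label_map]
    if missing:
        raise FormatError(f"object {missing[0]!r} has no label in the labels file")
    return dataclasses.replace(
        data, labels=[label_map[i] for i in data.object_ids]
    )


def write_memberships(model: CoClusterModel, path_u, path_v, data: DataMatrix | None = None) -> None:
    """Write U (clusters x objects) and V (clusters x features) as CSV."""
    C = model.U.shape[0]
    cluster_ids = [f"cluster{c}" for c in range(C)]
    obj_ids = data.object_ids if data is not None else [f"obj{i}" for i in range(model.U.shape[1])]
    feat_ids = data.feature_ids if data is not None else [f"feat{j}" for j in range(model.V.shape[1])]
    pd.DataFrame(model.U, index=cluster_ids, columns=obj_ids).to_csv(
        path_u, float_format="%.15g"
    )
    pd.DataFrame(model.V, index=cluster_ids, columns=feat_ids).to_csv(
        path_v, float_format="%.15g"
    )


def write_assignments(model: CoClusterModel, path, data: DataMatrix | None = None) -> None:
    """Write defuzzified object assignments as two-column CSV."""
    assignments, _ = defuzzify(model.U)
    obj_ids = data.object_ids if data is not None else [f"obj{i}" for i in range(model.U.shape[1])]
    pd.DataFrame({"object_id": obj_ids, "cluster": assignments}).to_csv(
        path, index=False
    )


def _config_dict(config) -> dict:
    return dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)


def write_fit_result(result: FitResult, path) -> None:
    """Serialize a FitResult's metadata (not the matrices) to JSON."""
    doc = {
        "algorithm": result.algorithm,
        "config": _config_dict(result.config),
        "iterations": result.iterations,
        "converged": result.converged,
        "objective_trace": [float(v) for v in result.objective_trace],
        "max_constraint_violation": float(result.max_constraint_violation),
        "runtime_s": result.runtime_s,
        "cluster_sizes": [int(s) for s in result.model.sizes],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_report(report, path) -> None:
    """Serialize an EvaluationReport (or any dict-like report) to JSON."""
    doc = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")
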