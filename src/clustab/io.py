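"""File formats and run reporting.

Matrices are plain TSV/CSV with '.' decimal separators, optionally with a
single header row and a leading identifier column. Readers reject ragged
rows, non-numeric cells, missing values and out-of-range genotypes with
an error naming the offending position — malformed input is never
silently coerced.

Results are written as a labels file (one 0-based cluster index per line,
object order preserved; 1-based on request) plus a JSON report embedding
a run manifest (command, parameters, input digests, tool version) from
which the output can be regenerated bit-for-bit. Wall-clock timestamps go
to the log, never into result files, so identical runs produce identical
bytes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .cluster import ClusteringResult
from .matrix import CONTINUOUS, DataMatrix, MatrixError
from .stability import StabilityProfile

try:  # installed distribution metadata
    from importlib.metadata import version as _dist_version
    TOOL_VERSION = _dist_version("clustab")
except Exception:  # pragma: no cover
    TOOL_VERSION = "unknown"


class LoadError(MatrixError):
    """Raised when an input file cannot be parsed into a DataMatrix."""


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one run: enough to reproduce its outputs exactly."""

    command: str
    parameters: dict[str, Any]
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    version: str = TOOL_VERSION

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(command: str, parameters: dict[str, Any],
                   input_paths: list[str | Path] | None = None) -> RunManifest:
    inputs = {str(p): file_digest(p) for p in (input_paths or [])}
    return RunManifest(command=command, parameters=parameters, inputs=inputs)


def read_matrix(path: str | Path, kind: str = CONTINUOUS,
                delimiter: str = "\t", header: bool = False,
                id_column: bool = False,
                transpose: bool = False) -> DataMatrix:
    """Parse a rectangular numeric matrix file into a DataMatrix."""
    try:
        df = pd.read_csv(
            path, sep=delimiter, header=0 if header else None,
            dtype=str, keep_default_na=False, engine="python",
        )
    except pd.errors.ParserError as exc:
        raise LoadError(f"{path}: ragged or unparseable table: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise LoadError(f"{path}: file is empty") from exc
    row_ids = None
    if id_column:
        if df.shape[1] < 2:
            raise LoadError(f"{path}: id column requested but only one column")
        row_ids = df.iloc[:, 0].to_numpy()
        df = df.iloc[:, 1:]
    cells = df.to_numpy()
    numeric = np.empty(cells.shape, dtype=np.float64)
    for j in range(cells.shape[1]):
        col = pd.to_numeric(pd.Series(cells[:, j]).str.strip(),
                            errors="coerce")
        bad = col.isna().to_numpy() | (cells[:, j] == "")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            cell = cells[i, j]
            missing = cell == "" or (isinstance(cell, float) and np.isnan(cell))
            what = "missing value" if missing else f"non-numeric cell {cell!r}"
            raise LoadError(
                f"{path}: {what} at data row {i + 1}, column {j + 1}"
            )
        numeric[:, j] = col.to_numpy()
    if kind != CONTINUOUS:
        bad = (numeric != np.round(numeric)) | (numeric < 0) | (numeric > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise LoadError(
                f"{path}: genotype value {cells[i, j]!r} outside {{0,1,2}} "
                f"at data row {i + 1}, column {j + 1}"
            )
        numeric = numeric.astype(np.int64)
        row_ids = None if transpose else row_ids
        matrix = DataMatrix(numeric, kind=kind, row_ids=row_ids)
    else:
        matrix = DataMatrix(numeric, kind=kind,
                            row_ids=None if transpose else row_ids)
    return matrix.transposed() if transpose else matrix


def write_labels(labels: np.ndarray, path: str | Path,
                 one_based: bool = False) -> None:
    """One cluster index per line, preserving object order."""
    offset = 1 if one_based else 0
    Path(path).write_text(
        "".join(f"{int(v) + offset}\n" for v in labels)
    )


def read_labels(path: str | Path, one_based: bool = False) -> np.ndarray:
    offset = 1 if one_based else 0
    values = [int(line) - offset
              for line in Path(path).read_text().splitlines() if line.strip()]
    return np.asarray(values, dtype=np.int64)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def result_to_dict(result: ClusteringResult) -> dict[str, Any]:
    return _jsonable({
        "type": "clustering",
        "labels": result.labels,
        "centroids": result.centroids,
        "sse": result.sse,
        "mse": result.mse,
        "iterations": result.iterations,
        "converged": result.converged,
        "seed_used": result.seed_used,
    })


def profile_to_dict(profile: StabilityProfile) -> dict[str, Any]:
    return _jsonable({
        "type": "stability_profile",
        "ks": profile.ks,
        "median_cluster": profile.median_cluster,
        "median_baseline": profile.median_baseline,
        "gap": profile.gap,
        "best_k": profile.best_k,
        "p_value": profile.p_value,
        "structure_found": profile.structure_found,
        "baseline_kind": profile.baseline_kind,
        "seed_used": profile.seed_used,
    })


def write_result(result: ClusteringResult | StabilityProfile,
                 path: str | Path,
                 manifest: RunManifest | None = None) -> None:
    """Serialize a result (plus optional manifest) as JSON."""
    if isinstance(result, ClusteringResult):
        payload = result_to_dict(result)
    elif isinstance(result, StabilityProfile):
        payload = profile_to_dict(result)
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    if manifest is not None:
        payload["manifest"] = _jsonable(manifest.to_dict())
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def write_profile_samples(profile: StabilityProfile,
                          path: str | Path) -> None:
    """Tidy TSV of every pairwise MCA sample: columns k, group, mca."""
    rows = []
    for k in profile.ks:
        rows.extend(("cluster", k, v) for v in profile.cluster_mca[k])
        rows.extend(("baseline", k, v) for v in profile.baseline_mca[k])
    df = pd.DataFrame(rows, columns=["group", "k", "mca"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_matrix(matrix: DataMatrix, path: str | Path,
                 delimiter: str = "\t") -> None:
    """Write a DataMatrix as a headerless delimited text file."""
    fmt = "%.17g" if matrix.kind == CONTINUOUS else "%d"
    np.savetxt(path, matrix.values, fmt=fmt, delimiter=delimiter)
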