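"""Reading, validating and writing expression matrices, cell metadata and fits.

Expression input is delimited text (comma or tab, auto-detected), genes in
rows by default with a header row of cell identifiers and a first column of
gene identifiers.  Values are expected on a log scale (Ct values, log counts,
log intensities).  Cell metadata is a two-column table ``cell,capture``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellMetadata",
    "FitArtifact",
    "read_expression",
    "write_expression",
    "read_cell_meta",
    "write_cell_meta",
    "adjust_cell_size",
    "save_fit",
    "load_fit",
]

FIT_FORMAT_VERSION = 1


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A genes-by-cells matrix of log-scale expression values."""

    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        G, C = self.values.shape
        if G < 1 or C < 2:
            raise ValueError(f"need at least 1 gene and 2 cells, got {G}x{C}")
        if len(self.gene_ids) != G or len(self.cell_ids) != C:
            raise ValueError("id lists do not match matrix shape")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "missing or non-finite expression value at gene "
                f"{self.gene_ids[bad[0]]!r}, cell {self.cell_ids[bad[1]]!r}; "
                "missing data is not supported"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.cell_ids), self.values[rows])


@dataclass
class CellMetadata:
    """Per-cell capture times ``k_c`` drawn from ``T`` distinct levels."""

    cell_ids: list[str]
    capture_time: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.capture_time = np.asarray(self.capture_time, dtype=float)
        if self.capture_time.ndim != 1 or len(self.cell_ids) != self.capture_time.size:
            raise ValueError("capture_time must be 1-D and match cell_ids")
        if not np.all(np.isfinite(self.capture_time)):
            bad = self.cell_ids[int(np.argwhere(~np.isfinite(self.capture_time))[0])]
            raise ValueError(f"non-numeric capture time for cell {bad!r}")
        _check_unique(self.cell_ids, "cell")

    @property
    def capture_levels(self) -> np.ndarray:
        """Sorted distinct capture times ``kappa_1 < ... < kappa_T``."""
        return np.unique(self.capture_time)

    @property
    def n_levels(self) -> int:
        return self.capture_levels.size

    def reindex(self, cell_ids: list[str]) -> "CellMetadata":
        """Align metadata to a caller-supplied cell ordering."""
        index = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in index]
        if missing:
            raise KeyError(f"cells missing from metadata: {missing}")
        rows = [index[c] for c in cell_ids]
        return CellMetadata(list(cell_ids), self.capture_time[rows])


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_expression(path, genes_in_rows: bool = True) -> ExpressionMatrix:
    """Read a delimited expression table into a validated :class:`ExpressionMatrix`.

    The header row carries cell ids and the first column gene ids (the
    transpose if ``genes_in_rows`` is false).  Input order of genes and cells
    is preserved.  Duplicated ids, non-numeric cells and missing values all
    raise ``ValueError`` with coordinates; nothing is imputed.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if not genes_in_rows:
        df = df.T
    gene_ids = [str(g) for g in df.index]
    cell_ids = [str(c) for c in df.columns]
    _check_unique(gene_ids, "gene")
    _check_unique(cell_ids, "cell")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric expression value {cell!r} at gene "
                    f"{gene_ids[i]!r}, cell {cell_ids[j]!r}"
                ) from None
    return ExpressionMatrix(gene_ids, cell_ids, values)


def write_expression(x: ExpressionMatrix, path, sep: str = ",", genes_in_rows: bool = True) -> None:
    df = pd.DataFrame(x.values, index=x.gene_ids, columns=x.cell_ids)
    if not genes_in_rows:
        df = df.T
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_cell_meta(path) -> CellMetadata:
    """Read ``cell,capture`` metadata; non-numeric capture times raise."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if "cell" in cols and "capture" in cols:
        cell_col = df.columns[cols.index("cell")]
        cap_col = df.columns[cols.index("capture")]
    else:  # fall back to positional columns
        cell_col, cap_col = df.columns[0], df.columns[1]
    cells = [str(c) for c in df[cell_col]]
    times = np.empty(len(cells))
    for i, v in enumerate(df[cap_col]):
        try:
            times[i] = float(v)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric capture time {v!r} for cell {cells[i]!r}"
            ) from None
    return CellMetadata(cells, times)


def write_cell_meta(meta: CellMetadata, path, sep: str = ",") -> None:
    pd.DataFrame({"cell": meta.cell_ids, "capture": meta.capture_time}).to_csv(
        path, sep=sep, index=False, float_format="%.17g"
    )


def adjust_cell_size(x: ExpressionMatrix) -> ExpressionMatrix:
    """Remove per-cell location: subtract each cell's mean over genes.

    On the log scale, cell-size factors act additively on every gene of a
    cell, so removing the per-cell mean is the corresponding shift
    correction.  Idempotent, and invariant to per-cell additive shifts.
    """
    if x.n_cells < 2:
        raise ValueError("cell-size adjustment needs at least 2 cells")
    centered = x.values - x.values.mean(axis=0, keepdims=True)
    return ExpressionMatrix(list(x.gene_ids), list(x.cell_ids), centered)


# ---------------------------------------------------------------------------
# Fit serialization: a self-describing JSON container.  Python float repr
# round-trips exactly, so numeric fields are bit-comparable after load.
# ---------------------------------------------------------------------------


@dataclass
class FitArtifact:
    """A completed fit plus everything needed to reproduce or reuse it."""

    fit: "object"  # gptime.inference.FitResult
    provenance: dict = field(default_factory=dict)
    format_version: int = FIT_FORMAT_VERSION


def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _decode_arrays(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _decode_arrays(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode_arrays(v) for v in obj]
    return obj


def save_fit(artifact: FitArtifact, path) -> None:
    """Serialize a :class:`FitArtifact` to structured text (JSON)."""
    from .inference import FitResult  # local import to avoid a cycle

    fit = artifact.fit
    if not isinstance(fit, FitResult):
        raise TypeError("artifact.fit must be a FitResult")
    payload = {
        "format_version": artifact.format_version,
        "provenance": artifact.provenance,
        "fit": fit.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_encode)


def load_fit(path) -> FitArtifact:
    """Load a fit saved by :func:`save_fit`; numeric fields round-trip exactly."""
    from .inference import FitResult

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse fit file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != FIT_FORMAT_VERSION:
        raise ValueError(
            f"fit format version mismatch: file has {version}, "
            f"this build reads {FIT_FORMAT_VERSION}"
        )
    fit = FitResult.from_dict(_decode_arrays(payload["fit"]))
    return FitArtifact(fit=fit, provenance=payload.get("provenance", {}), format_version=version)
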