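"""Readers and writers for expression matrices, annotations, gene sets, tables.

Supported formats: TSV/CSV expression matrices (genes in rows, first column
gene ids), GCT 1.2, TSV/CSV sample annotations, GMT gene-set collections,
and TSV result tables.  Result tables are written with a comment header
(lines starting ``#``) carrying the tool version and, when given, the run
seed; readers skip such lines.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    DataModelError,
    ExpressionMatrix,
    GeneSetCollection,
    validate_annotation,
)

log = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.12g"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix in ("csv", "gct"):
        return suffix
    raise DataModelError(f"cannot infer matrix format from suffix {path.suffix!r}")


def read_expression_matrix(
    path, format: str | None = None, impute: str | None = None
) -> ExpressionMatrix:
    """Load a genes × samples expression matrix.

    Parameters
    ----------
    path:
        TSV/CSV file (first column gene ids, header row sample ids) or a
        GCT 1.2 file (``#1.2`` version line, dims line, Name/Description
        columns).
    format:
        ``"tsv"``, ``"csv"`` or ``"gct"``; inferred from the suffix if None.
    impute:
        ``None`` (default): any missing/non-numeric cell is a hard error
        naming the gene and sample.  ``"row_mean"``: missing cells are
        replaced by the gene's row mean and the imputed count is logged.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "gct":
        frame = _read_gct(path)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        frame.index = frame.index.astype(str)
    else:
        raise DataModelError(f"unknown matrix format {fmt!r}")

    frame = frame.apply(pd.to_numeric, errors="coerce")
    if frame.isna().any().any():
        if impute is None:
            i, j = np.argwhere(frame.isna().to_numpy())[0]
            raise DataModelError(
                f"missing or non-numeric value for gene {frame.index[i]!r}, "
                f"sample {frame.columns[j]!r} (enable impute='row_mean' to fill)"
            )
        if impute != "row_mean":
            raise DataModelError(f"unknown impute mode {impute!r}")
        n_missing = int(frame.isna().to_numpy().sum())
        frame = frame.apply(lambda row: row.fillna(row.mean()), axis=1)
        log.info("imputed %d missing cells with row means", n_missing)
        if frame.isna().any().any():
            raise DataModelError("rows with all values missing cannot be imputed")
    return ExpressionMatrix(frame)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise DataModelError(f"unsupported GCT version line {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise DataModelError("malformed GCT dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        frame = pd.read_csv(fh, sep="\t")
    if "Name" not in frame.columns or "Description" not in frame.columns:
        raise DataModelError("GCT file must have Name and Description columns")
    frame = frame.set_index("Name").drop(columns=["Description"])
    frame.index = frame.index.astype(str)
    if frame.shape != (n_genes, n_samples):
        raise DataModelError(
            f"GCT dims line says {n_genes}x{n_samples} but data is "
            f"{frame.shape[0]}x{frame.shape[1]}"
        )
    return frame


def write_expression_matrix(
    matrix: ExpressionMatrix, path, format: str | None = None
) -> None:
    """Write a matrix as TSV/CSV (gene id first column) or GCT 1.2."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            frame = matrix.data.copy()
            frame.insert(0, "Description", "na")
            frame.index.name = "Name"
            frame.to_csv(fh, sep="\t", float_format=_FLOAT_FORMAT)
    elif fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        frame = matrix.data.copy()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep=sep, float_format=_FLOAT_FORMAT)
    else:
        raise DataModelError(f"unknown matrix format {fmt!r}")


def read_sample_annotation(path) -> pd.DataFrame:
    """Load and validate a TSV/CSV sample-annotation table.

    Derives ``resilience_class`` (none/mild → resilient, severe → severe,
    moderate → other) and fills ``chronological_week`` as ceil(day/7) when
    absent.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str, "patient_id": str})
    return validate_annotation(table)


def read_gmt(path) -> GeneSetCollection:
    """Load a GMT gene-set file (name TAB description TAB member...).

    Members are deduplicated preserving first occurrence; a line with fewer
    than three fields or a repeated set name is a hard error.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataModelError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description, *members = fields
            members = [m for m in members if m]
            if not members:
                raise DataModelError(f"GMT line {lineno}: set {name!r} has no members")
            collection.add(name, description, members)
    return collection


def write_table(table: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a result table as TSV with a version/seed comment header.

    Floats are written at 12 significant digits so that re-reading
    reproduces them within 1e-9.
    """
    path = Path(path)
    header = f"# macrotime v{__version__}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        table.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_table(path) -> pd.DataFrame:
    """Read back a TSV result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
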