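"""Readers/writers for every external format the pipeline touches.

Formats: GCT 1.2/1.3 abundance matrices, GMT gene sets, TSV interaction-pair
edge lists, TSV mutation tables and YAML run configuration. Values written
by :func:`write_gct` use shortest-round-trip float formatting, so
``read_gct(write_gct(x)) == x`` exactly and re-writing a file we produced is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    AbundanceMatrix,
    AnnotationCatalog,
    MutationTable,
    PipelineConfig,
    canonical_pair,
)

__all__ = [
    "GctFormatError",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_pairs",
    "write_pairs",
    "read_mutations",
    "write_mutations",
    "read_config",
    "write_config",
]

log = logging.getLogger(__name__)

#: Missing-value tokens accepted on read (case-insensitive); written as "NA".
MISSING_TOKENS = {"", "na", "nan"}


class GctFormatError(ValueError):
    """Malformed GCT file; the message names the offending line."""


def _parse_cell(token: str) -> float:
    if token.strip().lower() in MISSING_TOKENS:
        return np.nan
    return float(token)


def _format_cell(value: float) -> str:
    if np.isnan(value):
        return "NA"
    return repr(float(value))


def read_gct(path: str | Path) -> AbundanceMatrix:
    """Read a GCT 1.2 or 1.3 matrix.

    Row-metadata columns beyond ``Description`` are preserved in ``meta``;
    GCT 1.3 column-metadata rows are skipped with a warning (sample metadata
    is carried separately in this pipeline).
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GctFormatError(f"{path}: empty file (line 1)")
    version = lines[0].strip()
    if version not in ("#1.2", "#1.3"):
        raise GctFormatError(
            f"{path}: line 1 must be '#1.2' or '#1.3', got {version!r}"
        )
    if len(lines) < 3:
        raise GctFormatError(f"{path}: truncated file, no header (line {len(lines)})")
    dims = lines[1].split("\t")
    try:
        dims = [int(d) for d in dims]
    except ValueError as exc:
        raise GctFormatError(f"{path}: line 2 dimensions not integers: {exc}") from None
    if version == "#1.2":
        if len(dims) != 2:
            raise GctFormatError(f"{path}: line 2 must hold 2 integers for GCT 1.2")
        n_rows, n_cols = dims
        n_rowmeta, n_colmeta = 1, 0
    else:
        if len(dims) != 4:
            raise GctFormatError(f"{path}: line 2 must hold 4 integers for GCT 1.3")
        n_rows, n_cols, n_rowmeta, n_colmeta = dims
    header = lines[2].split("\t")
    expected_len = 1 + n_rowmeta + n_cols
    if len(header) != expected_len:
        raise GctFormatError(
            f"{path}: line 3 has {len(header)} columns, expected {expected_len}"
        )
    meta_names = header[1 : 1 + n_rowmeta]
    sample_ids = header[1 + n_rowmeta :]
    body_start = 3
    if n_colmeta:
        log.warning("%s: skipping %d column-metadata row(s)", path, n_colmeta)
        body_start += n_colmeta
    body = lines[body_start:]
    if len(body) != n_rows:
        raise GctFormatError(
            f"{path}: expected {n_rows} data rows, found {len(body)}"
            f" (line {body_start + 1})"
        )
    ids: list[str] = []
    meta_rows: list[list[str]] = []
    values = np.empty((n_rows, n_cols))
    for i, line in enumerate(body):
        parts = line.split("\t")
        if len(parts) != expected_len:
            raise GctFormatError(
                f"{path}: line {body_start + i + 1} has {len(parts)} columns,"
                f" expected {expected_len}"
            )
        ids.append(parts[0])
        meta_rows.append(parts[1 : 1 + n_rowmeta])
        try:
            values[i] = [_parse_cell(tok) for tok in parts[1 + n_rowmeta :]]
        except ValueError as exc:
            raise GctFormatError(
                f"{path}: line {body_start + i + 1}: {exc}"
            ) from None
    index = pd.Index(ids, name="id")
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique())
        raise GctFormatError(f"{path}: duplicate feature ids: {dups}")
    data = pd.DataFrame(values, index=index, columns=sample_ids)
    meta = pd.DataFrame(meta_rows, index=index.copy(), columns=meta_names)
    return AbundanceMatrix(data, meta)


def write_gct(matrix: AbundanceMatrix, path: str | Path) -> Path:
    """Write GCT 1.3 with the matrix's row-metadata columns.

    A 1 x 1 matrix therefore produces a 4-line file: version, dimensions,
    header and one data row.
    """
    n_rows, n_cols = matrix.shape
    if n_rows == 0 or n_cols == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    meta = matrix.meta
    lines = ["#1.3", f"{n_rows}\t{n_cols}\t{meta.shape[1]}\t0"]
    lines.append("\t".join(["id", *meta.columns.astype(str), *matrix.sample_ids]))
    vals = matrix.values
    meta_vals = meta.to_numpy(dtype=str)
    for i, fid in enumerate(matrix.feature_ids):
        cells = [_format_cell(v) for v in vals[i]]
        lines.append("\t".join([str(fid), *meta_vals[i], *cells]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: name TAB description TAB member...

    Members are deduplicated preserving order; the description column is
    ignored. Lines with fewer than 3 columns raise with their line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >=3 tab-separated"
                    f" columns, got {len(parts)}"
                )
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for member in parts[2:]:
                if member:
                    seen.setdefault(member, None)
            sets[name] = list(seen)
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> Path:
    path = Path(path)
    lines = ["\t".join([name, description, *members]) for name, members in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_pairs(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a TSV edge list (gene_a, gene_b, confidence); canonicalized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_a", "gene_b"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pair file needs columns {sorted(required)}")
    conf = df["confidence"] if "confidence" in df.columns else [""] * len(df)
    pairs = []
    for a, b, c in zip(df["gene_a"], df["gene_b"], conf):
        pairs.append((*canonical_pair(a, b), "" if pd.isna(c) else str(c)))
    return pairs


def write_pairs(pairs: list[tuple[str, str, str]], path: str | Path) -> Path:
    path = Path(path)
    rows = [(*canonical_pair(a, b), c) for a, b, c in pairs]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])
    df.to_csv(path, sep="\t", index=False)
    return path


def read_mutations(path: str | Path) -> MutationTable:
    """Read a TSV mutation table with the declared header columns."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
    return MutationTable(df)


def write_mutations(table: MutationTable, path: str | Path) -> Path:
    path = Path(path)
    table.records.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return PipelineConfig.from_dict(raw)


def write_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    payload = dataclasses.asdict(config)
    for key, value in payload.items():
        if isinstance(value, tuple):
            payload[key] = list(value)
    path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return path
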