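"""Readers and writers for every on-disk artifact the pipeline touches.

Canonical tabular dialect is TSV (UTF-8, no quoting) so gene identifiers
containing commas stay unambiguous. Missing severity scores are encoded as
the literal ``NA`` to distinguish ungraded samples from score zero. Gene
identifiers are opaque, case-sensitive symbols. All readers reject rather
than coerce malformed input; every writer produces a file its paired reader
accepts.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from masldstage.errors import FormatError

SAMPLE_COLUMNS = ["sample_id", "batch", "sex", "species", "nas", "fibrosis", "group"]

_NA = "NA"


# ---------------------------------------------------------------------------
# count matrices (genes x samples, non-negative integers)
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene-by-sample count matrix.

    Expects a TSV with a header row of sample IDs and gene IDs in the first
    column. Entries must be non-negative integers; violations raise
    :class:`FormatError` naming the offending cell.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    flat = pd.to_numeric(pd.Series(raw.to_numpy().ravel()), errors="coerce")
    values = flat.to_numpy(dtype=float)
    bad = np.isnan(values) | (values != np.floor(values)) | (values < 0)
    if bad.any():
        pos = int(np.argmax(bad))
        gene = raw.index[pos // raw.shape[1]]
        sample = raw.columns[pos % raw.shape[1]]
        cell = raw.iat[pos // raw.shape[1], pos % raw.shape[1]]
        kind = "negative" if (not np.isnan(values[pos]) and values[pos] < 0) \
            else "non-integer"
        raise FormatError(
            f"{path}: {kind} entry {cell!r} at gene {gene!r}, sample {sample!r}")
    counts = pd.DataFrame(
        values.astype(np.int64).reshape(raw.shape),
        index=raw.index.astype(str), columns=raw.columns)
    counts.index.name = "gene_id"
    return counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a count matrix as TSV (genes as rows, sample-ID header)."""
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a real-valued expression matrix (same layout as counts)."""
    expr = pd.read_csv(path, sep="\t", index_col=0)
    if expr.index.has_duplicates:
        dup = expr.index[expr.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene ID {dup!r}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise FormatError(f"{path}: non-finite expression value")
    expr.index = expr.index.astype(str)
    expr.index.name = "gene_id"
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    out = expr.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read per-sample covariates (batch, sex, species, NAS, fibrosis, group).

    NAS must lie in 0..8 and fibrosis in 0..4 when present; the literal
    ``NA`` marks an ungraded sample.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if table["sample_id"].duplicated().any():
        dup = table.loc[table["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    for col, hi in (("nas", 8), ("fibrosis", 4)):
        parsed = []
        for sid, cell in zip(table["sample_id"], table[col]):
            if cell == _NA:
                parsed.append(math.nan)
                continue
            try:
                value = int(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer {col} {cell!r} for sample {sid!r}"
                ) from None
            if not 0 <= value <= hi:
                raise FormatError(
                    f"{path}: {col} {value} out of range [0, {hi}] for "
                    f"sample {sid!r}")
            parsed.append(float(value))
        table[col] = parsed
    bad_species = set(table["species"]) - {"human", "mouse"}
    if bad_species:
        raise FormatError(f"{path}: unknown species {sorted(bad_species)}")
    return table.set_index("sample_id", drop=False)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples[SAMPLE_COLUMNS].copy()
    for col in ("nas", "fibrosis"):
        out[col] = [
            _NA if (isinstance(v, float) and math.isnan(v)) else str(int(v))
            for v in out[col]
        ]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into an ordered mapping set-name -> member list."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "need name, description and at least one member")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "masldstage") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------

def ortholog_map_from_frame(pairs: pd.DataFrame) -> pd.DataFrame:
    """Normalise an ortholog pair table: collapse duplicates, flag 1:1 pairs.

    A pair is ``one_to_one`` when its human gene maps to exactly one mouse
    gene and that mouse gene maps back to exactly one human gene.
    """
    missing = [c for c in ("human_gene", "mouse_gene") if c not in pairs.columns]
    if missing:
        raise FormatError(f"ortholog map: missing required column(s) {missing}")
    out = (pairs[["human_gene", "mouse_gene"]].astype(str)
           .drop_duplicates().reset_index(drop=True))
    h_deg = out.groupby("human_gene")["mouse_gene"].transform("size")
    m_deg = out.groupby("mouse_gene")["human_gene"].transform("size")
    out["one_to_one"] = (h_deg == 1) & (m_deg == 1)
    return out


def read_ortholog_map(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return ortholog_map_from_frame(raw)


def write_ortholog_map(orth: pd.DataFrame, path: str | Path) -> None:
    orth[["human_gene", "mouse_gene"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path,
                index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index, float_format="%.10g", na_rep=_NA)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       na_values=[_NA], keep_default_na=False)
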