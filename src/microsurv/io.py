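"""Readers and writers for the pipeline's on-disk formats.

Everything is plain TSV: counts as taxa rows x sample columns (first column
the taxon identifier, optionally a GraPhlAn-style lineage string
``k__...|p__...|s__Genus_species``), metadata as one sample per row, reports
as flat tables.  Gene sets are read from GMT.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_METADATA_COLUMNS = (
    "cohort", "age", "sex", "stage", "smoking",
    "os_time", "os_event", "rfs_time", "rfs_event",
)

_RANK_PREFIXES = {
    "k": "kingdom", "p": "phylum", "c": "class", "o": "order",
    "f": "family", "g": "genus", "s": "species",
}


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


def parse_lineage(taxon_id: str) -> dict:
    """Parse a ``k__...|p__...|s__...`` lineage string into rank fields.

    Species names have underscores replaced by spaces
    (``s__Escherichia_coli`` -> ``Escherichia coli``).  Non-lineage
    identifiers yield an empty dict.
    """
    ranks = {}
    for part in taxon_id.split("|"):
        m = re.fullmatch(r"([a-z])__(.*)", part)
        if not m:
            return {}
        prefix, name = m.groups()
        if prefix in _RANK_PREFIXES:
            if prefix == "s":
                name = name.replace("_", " ")
            ranks[_RANK_PREFIXES[prefix]] = name
    return ranks


def read_counts(path) -> pd.DataFrame:
    """Read a taxa x samples counts TSV into a samples x taxa frame.

    Raises :class:`ValidationError` on duplicate identifiers or any
    non-numeric / negative / non-integer cell, naming the offending
    coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = set()
    for col in header:
        if col in seen:
            raise ValidationError(f"duplicate sample column {col!r} in {path}")
        seen.add(col)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.columns = header
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon id {dup!r} in {path}")
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"non-numeric count at taxon {row!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()
    if np.isnan(values).any() or (values < 0).any():
        raise ValidationError(f"missing or negative counts in {path}")
    counts = pd.DataFrame(np.rint(values).astype(np.int64).T,
                          index=raw.columns, columns=raw.index)
    counts.index.name = "sample"
    counts.columns.name = "taxon"
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a samples x taxa frame as a taxa x samples TSV."""
    out = counts.T
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def taxon_species_names(taxa) -> pd.Series:
    """Species labels parsed from lineage ids, falling back to the raw id."""
    return pd.Series(
        {t: parse_lineage(t).get("species", t) for t in taxa}, name="species")


def read_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata with survival outcomes, validating types.

    Missing smoking status is mapped to the explicit ``"Not reported"``
    category.  ``rfs_time > os_time`` is rejected, naming the sample.
    """
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"missing required metadata columns: {missing}")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    meta["smoking"] = meta["smoking"].fillna("Not reported").astype(str)
    for col in ("os_time", "rfs_time"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any():
            bad = meta.index[vals.isna() | (vals < 0)][0]
            raise ValidationError(f"invalid {col} for sample {bad!r}")
        meta[col] = vals.astype(float)
    for col in ("os_event", "rfs_event"):
        vals = pd.to_numeric(meta[col], errors="coerce")
        if not vals.isin([0, 1]).all():
            bad = meta.index[~vals.isin([0, 1])][0]
            raise ValidationError(
                f"{col} must be 0/1; offending sample {bad!r}")
        meta[col] = vals.astype(int)
    violating = meta.index[meta["rfs_time"] > meta["os_time"] + 1e-9]
    if len(violating):
        raise ValidationError(
            f"rfs_time exceeds os_time for sample {violating[0]!r}")
    meta["age"] = pd.to_numeric(meta["age"], errors="raise").astype(float)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def write_matrix(frame: pd.DataFrame, path, index_name="sample") -> None:
    out = frame.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets: set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"GMT line with fewer than 3 fields: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description="na") -> None:
    lines = ["\t".join([name, description, *genes])
             for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")
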