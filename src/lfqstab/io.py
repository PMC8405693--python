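"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated.  The intensity matrix has a protein-id first
column and one column per sample, with missing values written as ``NA``
(empty cells and ``NaN`` are also accepted on read).  Categories use the
GMT dialect: one set per line as name, description, then member ids.
A minimal MaxQuant ``proteinGroups.txt`` reader extracts per-sample LFQ (or
raw) intensity columns, drops reverse/contaminant rows, and log2-transforms
with zeros treated as missing.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .sets import GeneSet, GeneSetCollection

__all__ = [
    "read_intensity_tsv", "write_intensity_tsv",
    "read_design_tsv", "write_design_tsv",
    "read_gene_table_tsv", "write_gene_table_tsv",
    "read_id_map_tsv", "read_gmt", "write_gmt",
    "read_maxquant_protein_groups", "file_digest",
]

_NA_STRINGS = {"", "NA", "NaN", "nan"}


def read_intensity_tsv(path, zero_is_missing: bool = False) -> pd.DataFrame:
    """Read a proteins x samples intensity table.

    Empty cells, ``NA`` and ``NaN`` parse as missing; with
    ``zero_is_missing`` exact zeros do too.  Duplicate protein ids and
    non-numeric cells raise :class:`ParseError` naming the offender and its
    line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise ParseError(f"{path}: malformed header (expected tab-separated "
                             "protein-id column plus sample columns)")
        sample_ids = header.split("\t")[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise ParseError(f"{path}: duplicate sample ids in header")
        ids, rows = [], []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ParseError(f"{path}:{lineno}: expected "
                                 f"{len(sample_ids) + 1} fields, got {len(parts)}")
            pid = parts[0]
            if pid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate protein id {pid!r}")
            seen.add(pid)
            vals = []
            for s, cell in zip(sample_ids, parts[1:]):
                if cell in _NA_STRINGS:
                    vals.append(np.nan)
                    continue
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric value "
                                     f"{cell!r} in sample {s!r}") from None
                vals.append(np.nan if (zero_is_missing and v == 0.0) else v)
            ids.append(pid)
            rows.append(vals)
    if not ids:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=pd.Index(ids, name="protein_id"),
                        columns=sample_ids)


def write_intensity_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="protein_id")


def read_design_tsv(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group", "batch"}
    if not required <= set(design.columns):
        raise ParseError(f"{path}: design needs columns {sorted(required)}")
    return design


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_gene_table_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"gene", "logfc", "p"}
    if not required <= set(table.columns):
        raise ParseError(f"{path}: gene table needs columns {sorted(required)}")
    return table


def write_gene_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_id_map_tsv(path) -> dict:
    """Two-column protein accession -> gene symbol mapping."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ParseError(f"{path}: id map needs two columns")
    key, val = table.columns[:2]
    if table[key].duplicated().any():
        raise ParseError(f"{path}: duplicate protein ids in id map")
    return dict(zip(table[key], table[val]))


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line)."""
    path = Path(path)
    categories = []
    names = set()
    universe: list = []
    seen_members = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT lines need name, "
                                 "description and at least one member")
            name, desc, raw = parts[0], parts[1], parts[2:]
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            names.add(name)
            members: list = []
            for m in raw:
                if m in members:
                    warnings.warn(f"{path}:{lineno}: member {m!r} listed twice "
                                  f"in {name}; deduplicated", stacklevel=2)
                else:
                    members.append(m)
            categories.append(GeneSet(name, desc, tuple(members)))
            for m in members:
                if m not in seen_members:
                    seen_members.add(m)
                    universe.append(m)
    if not categories:
        raise ParseError(f"{path}: empty GMT file")
    return GeneSetCollection(categories=categories, universe=universe)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with Path(path).open("w") as fh:
        for c in sets:
            fh.write("\t".join([c.category_id, c.description, *c.members]) + "\n")


def read_maxquant_protein_groups(path, intensity_prefix: str | None = None
                                 ) -> pd.DataFrame:
    """Extract a log2 intensity matrix from a MaxQuant proteinGroups table.

    Uses ``LFQ intensity <sample>`` columns when present, otherwise
    ``Intensity <sample>``; rows flagged ``+`` in Reverse or contaminant
    columns are dropped; zero intensities become missing and the rest are
    log2-transformed.
    """
    table = pd.read_csv(path, sep="\t")
    id_col = next((c for c in ("Majority protein IDs", "Protein IDs", "id")
                   if c in table.columns), None)
    if id_col is None:
        raise ParseError(f"{path}: no protein-id column found")
    for flag in ("Reverse", "Potential contaminant", "Contaminant",
                 "Only identified by site"):
        if flag in table.columns:
            table = table[table[flag].fillna("") != "+"]
    prefixes = ([intensity_prefix] if intensity_prefix
                else ["LFQ intensity ", "Intensity "])
    for prefix in prefixes:
        cols = [c for c in table.columns if c.startswith(prefix)]
        if cols:
            break
    else:
        raise ParseError(f"{path}: no per-sample intensity columns "
                         f"(tried prefixes {prefixes})")
    ids = table[id_col].astype(str)
    if ids.duplicated().any():
        raise ParseError(f"{path}: duplicate protein ids")
    raw = table[cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        values = np.where(raw > 0, np.log2(np.where(raw > 0, raw, 1.0)), np.nan)
    samples = [c[len(prefix):] for c in cols]
    return pd.DataFrame(values, index=pd.Index(ids.to_numpy(), name="protein_id"),
                        columns=samples)


def file_digest(path) -> str:
    """SHA-256 hex digest of a file (for run manifests)."""
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()
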