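"""Readers, writers and validated in-memory containers for every on-disk artifact.

The pipeline exchanges plain tab-separated text: count matrices (entities x
samples), gene length tables, gene-to-MGS membership tables, taxonomic
annotation tables, per-sample best-hit alignment records, and QIIME "classic"
OTU tables.  All readers validate strictly — duplicate identifiers, negative
or fractional counts, conflicting memberships and ragged rows are errors, not
warnings — because every downstream step assumes these invariants.

Identifiers are opaque, case-sensitive strings.  Genus names are the one
exception: they are compared case-insensitively after whitespace stripping
(see :mod:`taxalink.validation`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

ANNOTATION_SOURCES = frozenset({"SILVA", "NCBI_nt", "NCBI_WGS", "RDP", "other"})

#: QIIME classic taxonomy column headers, matched case-insensitively.
_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage"}

_GENUS_RE = re.compile(r"g__([^;]*)")


# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------


def _check_axis_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifier(s): {dupes[:5]}")


@dataclass(frozen=True)
class CountMatrix:
    """Entities x samples matrix of non-negative integer counts.

    ``data`` is a pandas DataFrame with entity identifiers as the index and
    sample identifiers as the columns; both axes are unique and order is
    meaningful.  Values are stored as int64.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_axis_unique(df.index, "row")
        _check_axis_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValidationError("count matrix contains non-integer values")
            df = df.astype(np.int64)
        else:
            df = df.astype(np.int64, copy=False)
        if values.size and df.to_numpy().min() < 0:
            raise ValidationError("count matrix contains negative values")
        object.__setattr__(self, "data", df)

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class AbundanceMatrix:
    """Entities x samples matrix of relative abundances.

    Every column that carried any signal sums to 1 (within 1e-9); columns of
    an all-zero input stay all-zero.  Values are non-negative reals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.astype(np.float64, copy=False)
        _check_axis_unique(df.index, "row")
        _check_axis_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size:
            if values.min() < 0:
                raise ValidationError("abundance matrix contains negative values")
            colsums = values.sum(axis=0)
            bad = ~((colsums == 0) | (np.abs(colsums - 1.0) <= 1e-9))
            if bad.any():
                raise ValidationError(
                    "abundance columns must sum to 1 (or be all zero); offending "
                    f"sample(s): {list(df.columns[bad][:5])}"
                )
        object.__setattr__(self, "data", df)

    @property
    def row_ids(self) -> list[str]:
        return [str(r) for r in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]


@dataclass(frozen=True)
class QiimeOtuTable:
    """Parse result of a QIIME classic OTU table.

    ``annotations`` carries genus labels recovered from a trailing taxonomy
    column (empty when the file had none); ``n_comment_lines`` counts the
    leading ``#`` lines skipped before the header so no row is dropped
    silently.
    """

    counts: CountMatrix
    annotations: "pd.DataFrame"
    n_comment_lines: int


# Typed tables are plain pandas objects validated on read:
#   GeneLengthTable  — pd.Series, index gene_id, int64 length_nt > 0
#   MgsMembership    — pd.Series, index gene_id, values mgs_id
#   AnnotationTable  — pd.DataFrame[entity_id, genus, source, confidence]
#   AlignmentHits    — pd.DataFrame[sample_id, read_id, reference_id]
GeneLengthTable = pd.Series
MgsMembership = pd.Series
AnnotationTable = pd.DataFrame
AlignmentHits = pd.DataFrame


def make_annotation_table(rows: Iterable[tuple] | pd.DataFrame) -> AnnotationTable:
    """Build and validate an annotation table.

    ``rows`` are (entity_id, genus, source, confidence) tuples; genus and
    confidence may be None.  RDP rows must carry a confidence, and the source
    must be one of SILVA, NCBI_nt, NCBI_WGS, RDP or other.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(rows, columns=["entity_id", "genus", "source", "confidence"])
    expected = ["entity_id", "genus", "source", "confidence"]
    if list(df.columns) != expected:
        raise FormatError(f"annotation table must have columns {expected}")
    bad_source = set(df["source"]) - ANNOTATION_SOURCES
    if bad_source:
        raise ValidationError(f"unknown annotation source(s): {sorted(bad_source)}")
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    rdp = df["source"] == "RDP"
    if rdp.any() and df.loc[rdp, "confidence"].isna().any():
        missing = df.loc[rdp & df["confidence"].isna(), "entity_id"].tolist()
        raise ValidationError(f"RDP annotation without confidence for: {missing[:5]}")
    conf = df["confidence"].dropna()
    if ((conf < 0) | (conf > 1)).any():
        raise ValidationError("annotation confidence must lie in [0, 1]")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# QIIME classic OTU tables
# ---------------------------------------------------------------------------


def extract_genus(lineage: str) -> str | None:
    """Pull the genus token out of a Greengenes-style lineage string.

    Takes the token following ``g__`` up to the next ``;``; an absent or empty
    token means the genus is unknown and None is returned.
    """
    m = _GENUS_RE.search(lineage)
    if not m:
        return None
    genus = m.group(1).strip()
    return genus or None


def read_qiime_otu_table(path: str | Path) -> QiimeOtuTable:
    """Read a QIIME classic (tab-separated) OTU table.

    The header row starts with ``#OTU ID``; any ``#`` lines before it are
    comments.  A trailing column named "taxonomy" or "Consensus Lineage"
    (case-insensitive) is stripped from the counts and converted into genus
    annotations.  Counts must be non-negative integers; fractional values are
    rejected rather than rounded.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: list[str] | None = None
    n_comments = 0
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header = line.split("\t")
            data_start = i + 1
            break
        if line.startswith("#"):
            n_comments += 1
            continue
        break
    if header is None or header[0] != "#OTU ID":
        raise FormatError(f"{path}: no '#OTU ID' header line found")

    has_taxonomy = bool(header) and header[-1].strip().lower() in _TAXONOMY_HEADERS
    sample_ids = header[1:-1] if has_taxonomy else header[1:]
    _check_axis_unique(pd.Index(sample_ids), "sample")

    otu_ids: list[str] = []
    rows: list[list[int]] = []
    ann_rows: list[tuple] = []
    for lineno, line in enumerate(lines[data_start:], start=data_start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} fields, found {len(fields)}"
            )
        otu_id = fields[0]
        cells = fields[1:-1] if has_taxonomy else fields[1:]
        counts_row: list[int] = []
        for sample, cell in zip(sample_ids, cells):
            try:
                value = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {cell!r} "
                    f"(row {otu_id!r}, sample {sample!r})"
                ) from None
            if value != int(value):
                raise ValidationError(
                    f"{path}:{lineno}: fractional count {cell!r} "
                    f"(row {otu_id!r}, sample {sample!r})"
                )
            counts_row.append(int(value))
        otu_ids.append(otu_id)
        rows.append(counts_row)
        if has_taxonomy:
            genus = extract_genus(fields[-1])
            if genus is not None:
                ann_rows.append((otu_id, genus, "other", None))

    index = pd.Index(otu_ids, name="#OTU ID")
    if index.has_duplicates:
        dupes = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate OTU id(s): {dupes[:5]}")
    counts = CountMatrix(
        pd.DataFrame(rows, index=index, columns=sample_ids, dtype=np.int64)
    )
    return QiimeOtuTable(counts, make_annotation_table(ann_rows), n_comments)


def write_qiime_otu_table(
    counts: CountMatrix,
    path: str | Path,
    lineages: dict[str, str] | None = None,
) -> None:
    """Write a CountMatrix as a QIIME classic OTU table.

    ``lineages`` optionally maps OTU ids to lineage strings, emitted as a
    trailing taxonomy column.
    """
    with open(path, "w") as fh:
        header = ["#OTU ID", *counts.sample_ids]
        if lineages is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for otu_id, row in counts.data.iterrows():
            fields = [str(otu_id), *(str(int(v)) for v in row)]
            if lineages is not None:
                fields.append(lineages.get(str(otu_id), ""))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Plain TSV matrices and tables
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a plain TSV count matrix (first column entity id, header row)."""
    df = _read_tsv_matrix(path)
    values = df.to_numpy()
    if values.size and np.any(values != np.floor(values)):
        raise ValidationError(f"{path}: count matrix contains fractional values")
    if values.size and values.min() < 0:
        raise ValidationError(f"{path}: count matrix contains negative values")
    return CountMatrix(df.astype(np.int64))


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # noqa: BLE001 - rewrap parser failures
        raise FormatError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    if not np.issubdtype(df.to_numpy().dtype, np.number):
        bad = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        raise FormatError(f"{path}: non-numeric column(s): {bad[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_axis_unique(df.index, "row")
    _check_axis_unique(df.columns, "sample")
    return df


def write_count_matrix(m: CountMatrix, path: str | Path, index_label: str = "id") -> None:
    m.data.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a real-valued TSV matrix (MGS profiles, log profiles, ...)."""
    return _read_tsv_matrix(path).astype(np.float64)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def _read_tsv_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if len(df.columns) < len(columns):
        raise FormatError(
            f"{path}: expected {len(columns)} columns {columns}, found {list(df.columns)}"
        )
    df = df.iloc[:, : len(columns)]
    df.columns = columns
    return df


def read_gene_lengths(path: str | Path) -> GeneLengthTable:
    """Read a gene length table (gene_id, length_nt); lengths must be > 0."""
    df = _read_tsv_table(path, ["gene_id", "length_nt"])
    lengths = pd.to_numeric(df["length_nt"], errors="raise")
    if np.any(lengths != np.floor(lengths)):
        raise ValidationError(f"{path}: gene lengths must be integers")
    lengths = lengths.astype(np.int64)
    if (lengths <= 0).any():
        bad = df.loc[lengths <= 0, "gene_id"].tolist()
        raise ValidationError(f"{path}: non-positive gene length for: {bad[:5]}")
    series = pd.Series(lengths.to_numpy(), index=pd.Index(df["gene_id"], name="gene_id"),
                       name="length_nt")
    if series.index.has_duplicates:
        dupes = series.index[series.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    return series


def write_gene_lengths(lengths: GeneLengthTable, path: str | Path) -> None:
    lengths.rename("length_nt").to_csv(path, sep="\t", index_label="gene_id",
                                       lineterminator="\n")


def read_membership(path: str | Path) -> MgsMembership:
    """Read a gene -> MGS membership table; a gene may belong to one MGS only."""
    df = _read_tsv_table(path, ["gene_id", "mgs_id"])
    df = df.drop_duplicates()
    conflicts = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
    if conflicts:
        raise ValidationError(
            f"{path}: gene(s) assigned to more than one MGS: {conflicts[:5]}"
        )
    return pd.Series(df["mgs_id"].to_numpy(),
                     index=pd.Index(df["gene_id"], name="gene_id"), name="mgs_id")


def write_membership(membership: MgsMembership, path: str | Path) -> None:
    membership.rename("mgs_id").to_csv(path, sep="\t", index_label="gene_id",
                                       lineterminator="\n")


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read an annotation table (entity_id, genus, source, confidence)."""
    df = _read_tsv_table(path, ["entity_id", "genus", "source", "confidence"])
    df["genus"] = df["genus"].where(df["genus"].notna() & (df["genus"].str.strip() != ""),
                                    None)
    return make_annotation_table(df)


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_alignment_hits(path: str | Path) -> AlignmentHits:
    """Read best-hit alignment records (sample_id, read_id, reference_id).

    A read may map to at most one reference within a sample; conflicting
    duplicates violate best-hit semantics and are rejected.
    """
    df = _read_tsv_table(path, ["sample_id", "read_id", "reference_id"])
    df = df.drop_duplicates()
    key = df[["sample_id", "read_id"]]
    conflicts = key[key.duplicated()].drop_duplicates()
    if len(conflicts):
        pairs = list(conflicts.itertuples(index=False, name=None))
        raise ValidationError(
            f"{path}: (sample, read) pairs with conflicting references: {pairs[:5]}"
        )
    return df.reset_index(drop=True)


def write_alignment_hits(hits: AlignmentHits, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, lineterminator="\n")
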