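"""Readers and writers for the concrete syntaxes the connectors touch.

Covered formats: the GEO-SOFT sample/platform table subset, a minimal SAM
subset (mandatory columns 1-6, mapped records only), GFF gene features,
tab-delimited gene x condition matrices with an ``NA`` missing token, HTself
result tables, KEGG Mapper Search&Color gene/color lists, and plain
one-id-per-line gene lists.

Conventions shared by all parsers here:

* all coordinates are 1-based inclusive, matching SAM and GFF;
* text is UTF-8; Unix or Windows line endings are accepted on read and
  Unix endings are emitted on write;
* numbers are written in their shortest round-trippable decimal form and
  missing cells as the token ``NA``, so write -> read is an identity on
  ids and finite values.

Each reader logs a per-read tally (rows read / skipped / errored) through
the module logger.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "SoftSampleTable",
    "SamAlignment",
    "GffFeature",
    "DelimitedMatrix",
    "PlatformMapping",
    "HtselfResultRow",
    "KeggColorEntry",
    "KEGG_COLORS",
    "read_soft_sample",
    "read_sam",
    "cigar_reference_span",
    "read_gff_genes",
    "read_matrix",
    "write_matrix",
    "read_platform_mapping",
    "read_htself",
    "write_kegg_colors",
    "write_gene_list",
    "read_gene_list",
    "format_number",
]


class FormatError(ValueError):
    """A stream does not conform to the expected concrete syntax."""


class ValidationError(ValueError):
    """Structurally valid input that violates a semantic precondition."""


def format_number(value: float) -> str:
    """Shortest decimal representation that round-trips through float()."""
    return repr(float(value))


# ---------------------------------------------------------------------------
# GEO SOFT sample tables


@dataclass
class SoftSampleTable:
    """The ID/VALUE rows of one SOFT sample table.

    ``rows`` preserves file order; a value of ``None`` marks a cell that
    could not be parsed as a number (missing).
    """

    sample_id: str
    rows: list[tuple[str, float | None]]

    def value_map(self) -> dict[str, float | None]:
        """First-occurrence-wins mapping of probe/gene id to value."""
        out: dict[str, float | None] = {}
        for gid, val in self.rows:
            if gid not in out:
                out[gid] = val
        return out


_SOFT_BEGIN = "!sample_table_begin"
_SOFT_END = "!sample_table_end"


def read_soft_sample(stream: IO[str], sample_id: str | None = None) -> SoftSampleTable:
    """Parse the sample-table block of a SOFT stream.

    Only the block between ``!sample_table_begin`` and ``!sample_table_end``
    (case-insensitive) is consumed; every ``!``/``^``/``#`` metadata line
    outside it is ignored, apart from a ``^SAMPLE = <id>`` line which, when
    present, supplies the sample id. The header row must name an ID column
    (``ID`` or ``ID_REF``) and a ``VALUE`` column; extra columns are ignored.
    Unparsable value cells become missing with a logged warning.
    """
    in_table = False
    header_cols: list[str] | None = None
    id_col = value_col = -1
    rows: list[tuple[str, float | None]] = []
    n_read = n_skipped = 0
    saw_end = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        stripped = line.strip()
        if not in_table:
            if stripped.lower().startswith("^sample") and "=" in stripped:
                if sample_id is None:
                    sample_id = stripped.split("=", 1)[1].strip()
            elif stripped.lower().startswith(_SOFT_BEGIN):
                in_table = True
            continue
        if stripped.lower().startswith(_SOFT_END):
            saw_end = True
            break
        if not stripped:
            n_skipped += 1
            continue
        cells = line.split("\t")
        if header_cols is None:
            header_cols = [c.strip() for c in cells]
            upper = [c.upper() for c in header_cols]
            for candidate in ("ID_REF", "ID"):
                if candidate in upper:
                    id_col = upper.index(candidate)
                    break
            if "VALUE" in upper:
                value_col = upper.index("VALUE")
            if id_col < 0 or value_col < 0:
                raise FormatError(
                    "SOFT sample table header lacks ID/VALUE columns; "
                    f"found {header_cols!r}"
                )
            continue
        if len(cells) <= max(id_col, value_col):
            raise FormatError(
                f"SOFT sample table line {lineno}: expected at least "
                f"{max(id_col, value_col) + 1} columns, got {len(cells)}"
            )
        gid = cells[id_col].strip()
        raw_value = cells[value_col].strip()
        try:
            value: float | None = float(raw_value)
            if not math.isfinite(value):
                raise ValueError
        except ValueError:
            value = None
            logger.warning(
                "SOFT sample table line %d: unparsable value %r for id %r -> missing",
                lineno,
                raw_value,
                gid,
            )
        rows.append((gid, value))
        n_read += 1
    if not in_table or not saw_end:
        raise FormatError(
            "no SOFT sample table found (missing "
            "!sample_table_begin/!sample_table_end sentinels)"
        )
    if not rows:
        raise FormatError("SOFT sample table contains no data rows")
    logger.info(
        "SOFT read: %d rows read, %d skipped, 0 errored", n_read, n_skipped
    )
    return SoftSampleTable(sample_id=sample_id or "sample", rows=rows)


def write_soft_sample(table: SoftSampleTable, stream: IO[str]) -> None:
    """Render a sample table in the SOFT dialect accepted by the reader."""
    stream.write(f"^SAMPLE = {table.sample_id}\n")
    stream.write("!sample_table_begin\n")
    stream.write("ID_REF\tVALUE\n")
    for gid, value in table.rows:
        rendered = "null" if value is None else format_number(value)
        stream.write(f"{gid}\t{rendered}\n")
    stream.write("!sample_table_end\n")


# ---------------------------------------------------------------------------
# SAM alignments

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
#: CIGAR operations that consume reference bases.
_REF_CONSUMING = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases covered by a CIGAR string.

    Only M, D, N, = and X consume the reference; insertions, clips and
    padding do not.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR string: {cigar!r}")
    return sum(int(n) for n, op in ops if op in _REF_CONSUMING)


@dataclass(frozen=True)
class SamAlignment:
    """One mapped SAM record (mandatory columns, plus the derived span)."""

    qname: str
    flag: int
    rname: str
    pos: int
    cigar: str
    aligned_span: tuple[int, int]  # 1-based inclusive

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)


def read_sam(stream: IO[str]) -> Iterator[SamAlignment]:
    """Yield mapped alignments from a text SAM stream.

    Header lines (``@``) are skipped, as are unmapped records (flag bit
    0x4) and records whose CIGAR is ``*``. ``aligned_span`` is
    ``[pos, pos - 1 + reference_span(cigar)]``, 1-based inclusive.
    """
    n_read = n_skipped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("@"):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise FormatError(
                f"SAM line {lineno}: expected >= 6 mandatory columns, got {len(cols)}"
            )
        qname, flag_s, rname, pos_s, _mapq, cigar = cols[:6]
        try:
            flag = int(flag_s)
        except ValueError:
            raise FormatError(f"SAM line {lineno}: non-numeric flag {flag_s!r}") from None
        if flag & 0x4:
            n_skipped += 1
            continue
        try:
            pos = int(pos_s)
        except ValueError:
            raise FormatError(f"SAM line {lineno}: non-numeric pos {pos_s!r}") from None
        if pos < 1:
            raise FormatError(f"SAM line {lineno}: pos must be >= 1, got {pos}")
        if cigar == "*":
            n_skipped += 1
            logger.warning("SAM line %d: mapped record without CIGAR skipped", lineno)
            continue
        span_len = cigar_reference_span(cigar)
        n_read += 1
        yield SamAlignment(
            qname=qname,
            flag=flag,
            rname=rname,
            pos=pos,
            cigar=cigar,
            aligned_span=(pos, pos - 1 + span_len),
        )
    logger.info("SAM read: %d records read, %d skipped, 0 errored", n_read, n_skipped)


# ---------------------------------------------------------------------------
# GFF gene features

#: Attribute keys probed, in order, for the gene identifier.
_GFF_ID_KEYS = ("ID", "locus_tag", "gene_id")


def _parse_gff_attributes(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    # GFF3 style: key=value;key=value
    for chunk in attrs.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            out.setdefault(key.strip(), value.strip().strip('"'))
        else:
            # GFF2/GTF style: key "value"
            parts = chunk.split(None, 1)
            if len(parts) == 2:
                out.setdefault(parts[0].strip(), parts[1].strip().strip('"'))
    return out


@dataclass(frozen=True)
class GffFeature:
    """A gene-like feature with 1-based inclusive coordinates."""

    seqid: str
    ftype: str
    start: int
    end: int
    strand: str
    gene_id: str


def read_gff_genes(
    stream: IO[str], feature_types: frozenset[str] | set[str] = frozenset({"gene"})
) -> list[GffFeature]:
    """Parse gene features from a GFF stream.

    Only lines whose feature type is in ``feature_types`` are kept. The
    gene id is taken from the first present of the attribute keys ``ID``,
    ``locus_tag``, ``gene_id`` (GFF3 ``key=value`` and GFF2 ``key "value"``
    styles both accepted). A kept line with ``start > end`` is a format
    error; a kept line with no recognized id key is skipped with a warning.
    """
    if not feature_types:
        raise ValidationError("feature_types must be non-empty")
    features: list[GffFeature] = []
    n_skipped = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            cols = line.split()
            if len(cols) < 9:
                raise FormatError(f"GFF line {lineno}: expected 9 columns, got {len(cols)}")
            cols = cols[:8] + [" ".join(cols[8:])]
        seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
        if ftype not in feature_types:
            n_skipped += 1
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise FormatError(
                f"GFF line {lineno}: non-numeric coordinates {start_s!r}..{end_s!r}"
            ) from None
        if start > end:
            raise FormatError(f"GFF line {lineno}: start {start} > end {end}")
        attributes = _parse_gff_attributes(attrs)
        gene_id = next(
            (attributes[k] for k in _GFF_ID_KEYS if attributes.get(k)), None
        )
        if gene_id is None:
            n_skipped += 1
            logger.warning(
                "GFF line %d: no %s attribute; record skipped", lineno, "/".join(_GFF_ID_KEYS)
            )
            continue
        if strand not in {"+", "-", "."}:
            strand = "."
        features.append(GffFeature(seqid, ftype, start, end, strand, gene_id))
    logger.info(
        "GFF read: %d features kept, %d skipped, 0 errored", len(features), n_skipped
    )
    return features


# ---------------------------------------------------------------------------
# Tab-delimited matrices


@dataclass
class DelimitedMatrix:
    """A gene x condition table of semantically tagged expression values.

    ``values`` is a float array with NaN marking missing cells;
    ``concept_tag`` names the reference-ontology concept the cells
    instantiate (e.g. ``ratio_intensity_based_value``).
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    concept_tag: str = ""
    row_label: str = "gene_id"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids in matrix")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("duplicate column ids in matrix")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def column(self, col_id: str) -> np.ndarray:
        if col_id not in self.col_ids:
            raise ValidationError(
                f"unknown condition {col_id!r}; available: {self.col_ids}"
            )
        return self.values[:, self.col_ids.index(col_id)]


def write_matrix(matrix: DelimitedMatrix, stream: IO[str]) -> None:
    """Write a matrix as TSV: header of condition ids, one row per gene."""
    stream.write("\t".join([matrix.row_label, *matrix.col_ids]) + "\n")
    for i, rid in enumerate(matrix.row_ids):
        cells = [
            "NA" if math.isnan(v) else format_number(v) for v in matrix.values[i]
        ]
        stream.write("\t".join([rid, *cells]) + "\n")


def read_matrix(stream: IO[str], concept_tag: str = "") -> DelimitedMatrix:
    """Read a TSV matrix written by :func:`write_matrix`."""
    header: list[str] | None = None
    row_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        cells = line.split("\t")
        if header is None:
            if len(cells) < 1 or not cells[0].strip():
                raise FormatError("matrix header must start with a row-id column label")
            header = cells
            continue
        if len(cells) != len(header):
            raise FormatError(
                f"matrix row {lineno}: expected {len(header)} fields, got {len(cells)}"
            )
        row_ids.append(cells[0])
        row: list[float] = []
        for cell in cells[1:]:
            cell = cell.strip()
            if cell == "NA" or cell == "":
                row.append(math.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"matrix row {lineno}: unparsable cell {cell!r}"
                    ) from None
        data.append(row)
    if header is None:
        raise FormatError("empty matrix stream")
    values = (
        np.array(data, dtype=float)
        if data
        else np.empty((0, len(header) - 1), dtype=float)
    )
    return DelimitedMatrix(
        row_ids=row_ids,
        col_ids=header[1:],
        values=values,
        concept_tag=concept_tag,
        row_label=header[0],
    )


# ---------------------------------------------------------------------------
# Platform mappings, HTself tables, KEGG color lists, gene lists


@dataclass
class PlatformMapping:
    """experiment-specific id -> (official id, KEGG id or None)."""

    entries: dict[str, tuple[str, str | None]]

    def kegg_id(self, experiment_id: str) -> str | None:
        entry = self.entries.get(experiment_id)
        return entry[1] if entry else None


def read_platform_mapping(stream: IO[str]) -> PlatformMapping:
    """Read a platform gene-id mapping table.

    Accepts either plain TSV or a SOFT-wrapped platform table (metadata
    lines starting with ``!``/``^``/``#`` are skipped). Two-column rows map
    experiment id directly to a KEGG id that doubles as the official id;
    three-column rows carry distinct official and KEGG ids (an empty third
    cell means no KEGG id). Duplicate experiment ids keep the first
    occurrence with a logged warning.
    """
    entries: dict[str, tuple[str, str | None]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        stripped = line.strip()
        if not stripped or stripped[0] in "!^#":
            continue
        cells = [c.strip() for c in line.split("\t")]
        if cells[0].upper() in {"ID", "ID_REF"}:  # header row
            continue
        if len(cells) == 2:
            exp_id, kegg = cells
            entry = (kegg, kegg or None)
        elif len(cells) >= 3:
            exp_id, official, kegg = cells[0], cells[1], cells[2]
            entry = (official, kegg or None)
        else:
            raise FormatError(
                f"platform mapping line {lineno}: expected 2 or 3 columns, got {len(cells)}"
            )
        if exp_id in entries:
            logger.warning(
                "platform mapping line %d: duplicate id %r; first occurrence wins",
                lineno,
                exp_id,
            )
            continue
        entries[exp_id] = entry
    if not entries:
        raise ValidationError("platform mapping contains no entries")
    return PlatformMapping(entries=entries)


@dataclass(frozen=True)
class HtselfResultRow:
    """One gene's HTself statistic and p-value."""

    gene_id: str
    htself_value: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(
                f"p_value for {self.gene_id!r} outside [0, 1]: {self.p_value}"
            )


def read_htself(stream: IO[str]) -> list[HtselfResultRow]:
    """Read a tab-delimited gene / HTself / p-value table (optional header)."""
    rows: list[HtselfResultRow] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        if len(cells) < 3:
            raise FormatError(
                f"HTself table line {lineno}: expected 3 columns, got {len(cells)}"
            )
        try:
            stat, p = float(cells[1]), float(cells[2])
        except ValueError:
            if rows:
                raise FormatError(
                    f"HTself table line {lineno}: unparsable numbers {cells[1:3]!r}"
                ) from None
            continue  # tolerated header row
        rows.append(HtselfResultRow(cells[0], stat, p))
    return rows


def write_htself(rows: Sequence[HtselfResultRow], stream: IO[str]) -> None:
    stream.write("gene_id\thtself\tp_value\n")
    for row in rows:
        stream.write(
            f"{row.gene_id}\t{format_number(row.htself_value)}"
            f"\t{format_number(row.p_value)}\n"
        )


#: Closed color set of the KEGG Mapper Search&Color scheme used here.
KEGG_COLORS = ("red", "green", "yellow")


@dataclass(frozen=True)
class KeggColorEntry:
    """A mapped gene identifier with its regulation color."""

    gene_id: str
    color: str

    def __post_init__(self) -> None:
        if self.color not in KEGG_COLORS:
            raise ValidationError(
                f"color {self.color!r} not in {KEGG_COLORS} for gene {self.gene_id!r}"
            )


def write_kegg_colors(entries: Iterable[KeggColorEntry], stream: IO[str]) -> None:
    """Write ``gene_id<SPACE>color`` lines in input order."""
    for entry in entries:
        stream.write(f"{entry.gene_id} {entry.color}\n")


def write_gene_list(genes: Iterable[str], stream: IO[str]) -> None:
    for gene in genes:
        stream.write(f"{gene}\n")


def read_gene_list(stream: IO[str]) -> list[str]:
    return [line.strip() for line in stream if line.strip()]
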