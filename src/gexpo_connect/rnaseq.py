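"""Scenario 2 connectors: aligned RNA-Seq reads to a normalized count matrix.

The composite connector ``C3`` turns per-condition SAM alignments plus a
GFF gene annotation into a gene x condition count matrix in three serial
steps: ``C3.1`` annotates each mapped read with the overlapping gene
(reads with no overlap are removed), ``C3.2`` records each condition's
library size (the number of annotated reads), and ``C3.3`` tallies
per-gene read counts. ``C4`` then divides each count by its condition's
library size, yielding relative abundances suitable for clustering.

Read-to-gene assignment: a read is assigned to the gene on the same
reference sequence overlapping its aligned span by at least one base;
among several candidates the largest overlap wins, with exact ties broken
towards the lexicographically smallest gene id. Strand is ignored unless
``stranded=True``. Each read contributes to at most one gene, and every
occurrence of a multi-mapped read name counts independently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .core import (
    AccessPolicy,
    CompositePlan,
    ConnectorSpec,
    RunReport,
    load_equivalence_table,
)
from .formats import (
    DelimitedMatrix,
    GffFeature,
    SamAlignment,
    ValidationError,
    format_number,
    read_gff_genes,
    read_sam,
    write_matrix,
)

__all__ = [
    "AnnotatedReadSet",
    "ConditionTotals",
    "GeneIndex",
    "assign_read_to_gene",
    "c3_1_annotate",
    "c3_2_total",
    "c3_3_count",
    "c4_normalize",
    "read_totals",
    "write_totals",
    "build_c3_1_spec",
    "build_c3_2_spec",
    "build_c3_3_spec",
    "build_c3_plan",
    "build_c4_spec",
]


@dataclass
class AnnotatedReadSet:
    """One condition's reads after gene annotation.

    ``gene_hits`` holds one gene id per retained read, in read order;
    ``removed`` counts the mapped reads that overlapped no gene.
    """

    condition_id: str
    gene_hits: list[str] = field(default_factory=list)
    removed: int = 0

    @property
    def mapped_reads(self) -> int:
        return len(self.gene_hits) + self.removed


@dataclass
class ConditionTotals:
    """Per-condition library sizes (number of annotated reads)."""

    totals: dict[str, int]


class GeneIndex:
    """Interval index over gene features, one tree per reference sequence."""

    def __init__(self, features: Iterable[GffFeature], stranded: bool = False):
        self.stranded = stranded
        self.features = list(features)
        self._trees: dict[str, IntervalTree] = {}
        for feat in self.features:
            tree = self._trees.setdefault(feat.seqid, IntervalTree())
            # intervaltree is half-open; features are 1-based inclusive.
            tree.addi(feat.start, feat.end + 1, feat)

    def assign(self, aln: SamAlignment) -> str | None:
        tree = self._trees.get(aln.rname)
        if tree is None:
            return None
        start, end = aln.aligned_span
        best: tuple[int, str] | None = None
        for iv in tree.overlap(start, end + 1):
            feat: GffFeature = iv.data
            if self.stranded and feat.strand in {"+", "-"}:
                read_strand = "-" if aln.is_reverse else "+"
                if feat.strand != read_strand:
                    continue
            overlap = min(end, feat.end) - max(start, feat.start) + 1
            if overlap < 1:
                continue
            key = (overlap, feat.gene_id)
            # larger overlap wins; on equal overlap the smaller gene id wins
            if best is None or overlap > best[0] or (overlap == best[0] and feat.gene_id < best[1]):
                best = key
        return best[1] if best else None


def assign_read_to_gene(aln: SamAlignment, index: GeneIndex) -> str | None:
    """Assign a mapped read to the best-overlapping gene, or ``None``."""
    return index.assign(aln)


def c3_1_annotate(
    sam_stream: IO[str],
    features: Sequence[GffFeature] | GeneIndex,
    condition_id: str,
    stranded: bool = False,
) -> AnnotatedReadSet:
    """C3.1: replace each assignable read with its gene id, in read order."""
    index = features if isinstance(features, GeneIndex) else GeneIndex(features, stranded)
    result = AnnotatedReadSet(condition_id=condition_id)
    for aln in read_sam(sam_stream):
        gene = index.assign(aln)
        if gene is None:
            result.removed += 1
        else:
            result.gene_hits.append(gene)
    return result


def c3_2_total(
    sets: Sequence[AnnotatedReadSet], mode: str = "reads"
) -> ConditionTotals:
    """C3.2: per-condition totals used as library sizes.

    ``mode="reads"`` (default) counts annotated reads, which is the
    quantity that normalizes library size; ``mode="distinct-genes"``
    counts distinct annotated genes instead (the literal alternative
    reading of "total number of annotated genes").
    """
    if mode not in {"reads", "distinct-genes"}:
        raise ValidationError(f"mode must be 'reads' or 'distinct-genes', got {mode!r}")
    ids = [s.condition_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate condition ids: {ids}")
    if mode == "reads":
        return ConditionTotals({s.condition_id: len(s.gene_hits) for s in sets})
    return ConditionTotals({s.condition_id: len(set(s.gene_hits)) for s in sets})


def c3_3_count(sets: Sequence[AnnotatedReadSet]) -> DelimitedMatrix:
    """C3.3: gene x condition occurrence counts.

    Rows are the union of genes hit in any condition, sorted
    lexicographically; a gene absent from a condition counts 0.
    """
    ids = [s.condition_id for s in sets]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate condition ids: {ids}")
    genes = sorted({g for s in sets for g in s.gene_hits})
    values = np.zeros((len(genes), len(sets)), dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}
    for j, s in enumerate(sets):
        for g in s.gene_hits:
            values[gene_index[g], j] += 1
    return DelimitedMatrix(
        row_ids=genes,
        col_ids=ids,
        values=values,
        concept_tag="absolute_cdna_reads_counting_based_value",
    )


def c4_normalize(counts: DelimitedMatrix, totals: ConditionTotals) -> DelimitedMatrix:
    """C4: divide each count by its condition's library size.

    Every count column must have a strictly positive total; a zero or
    missing total is rejected naming the condition.
    """
    for cond in counts.col_ids:
        if cond not in totals.totals:
            raise ValidationError(f"no total for condition {cond!r}")
        if totals.totals[cond] <= 0:
            raise ValidationError(
                f"condition {cond!r} has non-positive total {totals.totals[cond]}"
            )
    divisors = np.array([totals.totals[c] for c in counts.col_ids], dtype=float)
    return DelimitedMatrix(
        row_ids=list(counts.row_ids),
        col_ids=list(counts.col_ids),
        values=counts.values / divisors[np.newaxis, :],
        concept_tag="relative_cdna_reads_counting_based_value",
    )


def write_totals(totals: ConditionTotals, stream: IO[str]) -> None:
    """One-row TSV: a header of condition ids and a row of totals."""
    conds = list(totals.totals)
    stream.write("\t".join(conds) + "\n")
    stream.write("\t".join(str(totals.totals[c]) for c in conds) + "\n")


def read_totals(stream: IO[str]) -> ConditionTotals:
    lines = [l.rstrip("\r\n") for l in stream if l.strip()]
    if len(lines) != 2:
        raise ValidationError(f"totals file must have 2 lines, got {len(lines)}")
    conds = lines[0].split("\t")
    values = lines[1].split("\t")
    if len(conds) != len(values):
        raise ValidationError("totals header and value row lengths differ")
    return ConditionTotals({c: int(v) for c, v in zip(conds, values)})


# ---------------------------------------------------------------------------
# Four-block connector specs (file level)


def build_c3_1_spec(stranded: bool = False) -> ConnectorSpec:
    """File-level C3.1 over all conditions at once.

    inputs: ``sam_paths`` (mapping condition id -> SAM path), ``gff_path``,
    ``out_dir``. Emits one ``annotated_<condition>.txt`` gene-id list per
    condition and passes the annotated sets downstream.
    """

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        with open(inputs["gff_path"], encoding="utf-8") as fh:
            features = read_gff_genes(fh)
        return features

    def lifting(features, inputs: dict, config: dict, report: RunReport):
        index = GeneIndex(features, stranded=stranded)
        sets: list[AnnotatedReadSet] = []
        for cond, sam_path in inputs["sam_paths"].items():
            with open(sam_path, encoding="utf-8") as fh:
                aset = c3_1_annotate(fh, index, cond)
            sets.append(aset)
            report.records_in += aset.mapped_reads
            report.records_out += len(aset.gene_hits)
            report.drop("no_gene_overlap", aset.removed)
        return sets

    def lowering(sets, inputs: dict, config: dict, report: RunReport):
        return sets

    def data_output(sets, inputs: dict, config: dict, report: RunReport):
        out_dir = Path(inputs["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for aset in sets:
            path = out_dir / f"annotated_{aset.condition_id}.txt"
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                for gene in aset.gene_hits:
                    fh.write(gene + "\n")
            paths[aset.condition_id] = path
        return {"annotated_sets": sets, "annotated_paths": paths}

    def check(report: RunReport) -> list[str]:
        if report.records_in != report.records_out + report.records_dropped:
            return [
                f"C3.1 read conservation violated: {report.records_in} != "
                f"{report.records_out} + {report.records_dropped}"
            ]
        return []

    return ConnectorSpec(
        id="C3.1",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C3.1"),
        consumes=("sam_paths", "gff_path", "out_dir"),
        produces=("annotated_sets", "annotated_paths"),
        check_report=check,
    )


def _sets_from_input(value: Any) -> list[AnnotatedReadSet]:
    """Accept annotated sets directly or as condition -> gene-list file paths."""
    if isinstance(value, Mapping):
        sets = []
        for cond, path in value.items():
            with open(path, encoding="utf-8") as fh:
                hits = [l.strip() for l in fh if l.strip()]
            sets.append(AnnotatedReadSet(condition_id=cond, gene_hits=hits))
        return sets
    return list(value)


def build_c3_2_spec(mode: str = "reads") -> ConnectorSpec:
    """File-level C3.2. inputs: ``annotated_sets`` (or paths), ``out_dir``."""

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        return _sets_from_input(inputs["annotated_sets"])

    def lifting(sets, inputs: dict, config: dict, report: RunReport):
        report.records_in = sum(len(s.gene_hits) for s in sets)
        totals = c3_2_total(sets, mode=config.get("total_mode", mode))
        report.records_out = len(totals.totals)
        return totals

    def lowering(totals, inputs: dict, config: dict, report: RunReport):
        return totals

    def data_output(totals, inputs: dict, config: dict, report: RunReport):
        out_dir = Path(inputs["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "totals.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            write_totals(totals, fh)
        return {"totals": totals, "totals_path": path}

    return ConnectorSpec(
        id="C3.2",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C3.2"),
        consumes=("annotated_sets", "out_dir"),
        produces=("totals", "totals_path"),
    )


def build_c3_3_spec() -> ConnectorSpec:
    """File-level C3.3. inputs: ``annotated_sets`` (or paths), ``out_dir``."""

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        return _sets_from_input(inputs["annotated_sets"])

    def lifting(sets, inputs: dict, config: dict, report: RunReport):
        report.records_in = sum(len(s.gene_hits) for s in sets)
        matrix = c3_3_count(sets)
        report.records_out = len(matrix.row_ids)
        return matrix

    def lowering(matrix, inputs: dict, config: dict, report: RunReport):
        return matrix

    def data_output(matrix, inputs: dict, config: dict, report: RunReport):
        out_dir = Path(inputs["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "counts.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            write_matrix(matrix, fh)
        return {"counts": matrix, "counts_path": path}

    return ConnectorSpec(
        id="C3.3",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C3.3"),
        consumes=("annotated_sets", "out_dir"),
        produces=("counts", "counts_path"),
    )


def build_c3_plan(
    stranded: bool = False,
    total_mode: str = "reads",
    access_policy: AccessPolicy | None = None,
) -> CompositePlan:
    """Composite C3 = C3.1 -> C3.2 -> C3.3 with explicit wiring."""
    return CompositePlan(
        id="C3",
        children=(
            build_c3_1_spec(stranded=stranded),
            build_c3_2_spec(mode=total_mode),
            build_c3_3_spec(),
        ),
        wiring={
            "C3.2": {"annotated_sets": "C3.1.annotated_sets"},
            "C3.3": {"annotated_sets": "C3.1.annotated_sets"},
        },
        access_policy=access_policy or AccessPolicy(),
    )


def build_c4_spec(access_policy: AccessPolicy | None = None) -> ConnectorSpec:
    """File-level C4. inputs: ``counts_path``, ``totals_path``, ``out_path``."""

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        from .formats import read_matrix

        with open(inputs["counts_path"], encoding="utf-8") as fh:
            counts = read_matrix(fh, concept_tag="absolute_cdna_reads_counting_based_value")
        with open(inputs["totals_path"], encoding="utf-8") as fh:
            totals = read_totals(fh)
        return counts, totals

    def lifting(pair, inputs: dict, config: dict, report: RunReport):
        counts, totals = pair
        report.records_in = len(counts.row_ids)
        relative = c4_normalize(counts, totals)
        report.records_out = len(relative.row_ids)
        return relative

    def lowering(matrix, inputs: dict, config: dict, report: RunReport):
        return matrix

    def data_output(matrix, inputs: dict, config: dict, report: RunReport):
        out_path = Path(inputs["out_path"])
        with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
            write_matrix(matrix, fh)
        return {"relative": out_path}

    return ConnectorSpec(
        id="C4",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C4"),
        access_policy=access_policy or AccessPolicy(),
        consumes=("counts_path", "totals_path", "out_path"),
        produces=("relative",),
    )
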