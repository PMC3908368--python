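"""Scenario 1 connectors: two-color microarray data into an analysis
environment and out to KEGG pathway coloring.

``C1`` merges per-condition two-color sample tables (log2 ratios of the
two channels) into one gene x condition matrix so multi-condition
normalization can run in a single pass. ``C2`` takes a differential
expression matrix, classifies each gene of a chosen condition as up- /
down-regulated / undefined against a symmetric log2-ratio threshold, maps
experiment-specific gene ids to KEGG identifiers through a platform
mapping file, and emits the gene/color list the KEGG Mapper Search&Color
Pathway service consumes (red = up, green = down, yellow = undefined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .core import (
    AccessPolicy,
    ConnectorSpec,
    RunReport,
    SemanticInstance,
    load_equivalence_table,
)
from .formats import (
    DelimitedMatrix,
    KeggColorEntry,
    PlatformMapping,
    SoftSampleTable,
    ValidationError,
    read_matrix,
    read_platform_mapping,
    read_soft_sample,
    write_kegg_colors,
    write_matrix,
)

__all__ = [
    "RegulationClass",
    "GeneExpressionThreshold",
    "c1_merge",
    "c2_classify",
    "c2_map_to_kegg",
    "c2_run",
    "build_c1_spec",
    "build_c2_spec",
    "REGULATION_COLOR",
]


class RegulationClass(Enum):
    UPREGULATED = "upregulated"
    DOWNREGULATED = "downregulated"
    UNDEFINED = "undefined"


#: Lowering of regulation classes onto the KEGG Mapper color scheme.
REGULATION_COLOR = {
    RegulationClass.UPREGULATED: "red",
    RegulationClass.DOWNREGULATED: "green",
    RegulationClass.UNDEFINED: "yellow",
}


@dataclass(frozen=True)
class GeneExpressionThreshold:
    """Symmetric regulation cut-off, in absolute log2-ratio units."""

    t: float

    def __post_init__(self) -> None:
        if not (self.t > 0) or not math.isfinite(self.t):
            raise ValidationError(f"gene expression threshold must be > 0, got {self.t}")


def c1_merge(
    tables: Sequence[SoftSampleTable],
    condition_ids: Sequence[str],
    report: RunReport | None = None,
) -> DelimitedMatrix:
    """Merge per-condition two-color sample tables into one ratio matrix.

    The row set is the union of gene ids across tables, ordered by first
    appearance; a gene absent from a table yields a missing (NA) cell in
    that condition's column. Duplicate probe ids within one table keep the
    first occurrence with a warning. Present values are carried over
    bit-exactly.
    """
    if len(tables) == 0:
        raise ValidationError("C1 requires at least one input table")
    if len(tables) != len(condition_ids):
        raise ValidationError(
            f"{len(tables)} tables but {len(condition_ids)} condition ids"
        )
    if len(set(condition_ids)) != len(condition_ids):
        raise ValidationError(f"duplicate condition ids: {list(condition_ids)}")
    gene_order: list[str] = []
    seen: set[str] = set()
    maps: list[dict[str, float | None]] = []
    for table in tables:
        if report is not None:
            report.records_in += len(table.rows)
            dups = len(table.rows) - len({g for g, _ in table.rows})
            if dups:
                report.warn(
                    f"sample {table.sample_id}: {dups} duplicate probe id(s); "
                    "first occurrence wins"
                )
        maps.append(table.value_map())
        for gid, _ in table.rows:
            if gid not in seen:
                seen.add(gid)
                gene_order.append(gid)
    values = np.full((len(gene_order), len(tables)), np.nan)
    for j, vmap in enumerate(maps):
        for i, gid in enumerate(gene_order):
            v = vmap.get(gid)
            if v is not None:
                values[i, j] = v
    if report is not None:
        report.records_out = len(gene_order)
    return DelimitedMatrix(
        row_ids=gene_order,
        col_ids=list(condition_ids),
        values=values,
        concept_tag="ratio_intensity_based_value",
    )


def c2_classify(log2_ratio: float, threshold: GeneExpressionThreshold) -> RegulationClass:
    """Classify a log2 ratio against a symmetric threshold.

    Boundaries are closed: a ratio exactly at +t is upregulated, exactly
    at -t downregulated.
    """
    if not math.isfinite(log2_ratio):
        raise ValidationError(f"log2 ratio must be finite, got {log2_ratio}")
    if log2_ratio >= threshold.t:
        return RegulationClass.UPREGULATED
    if log2_ratio <= -threshold.t:
        return RegulationClass.DOWNREGULATED
    return RegulationClass.UNDEFINED


def c2_map_to_kegg(gene_id: str, mapping: PlatformMapping) -> str | None:
    """Resolve an experiment-specific gene id to a KEGG id, or ``None``.

    The two-step resolution (experiment-specific -> official -> KEGG)
    collapses to a single lookup when the mapping file has only two
    columns, the KEGG id doubling as the official id.
    """
    if not mapping.entries:
        raise ValidationError("platform mapping is empty")
    return mapping.kegg_id(gene_id)


def c2_run(
    matrix: DelimitedMatrix,
    condition_id: str,
    threshold: GeneExpressionThreshold,
    mapping: PlatformMapping,
    scale: str = "log2",
) -> tuple[list[KeggColorEntry], RunReport]:
    """Classify one condition's values and emit the KEGG color list.

    Emission order follows the matrix row order. Genes with a missing
    value, with no KEGG mapping, or (in linear mode) a non-positive ratio
    are dropped with a per-reason tally. ``scale="linear"`` classifies on
    log2 of the stored value instead of the value itself.
    """
    if scale not in {"log2", "linear"}:
        raise ValidationError(f"scale must be log2 or linear, got {scale!r}")
    column = matrix.column(condition_id)
    report = RunReport(connector_id="C2")
    entries: list[KeggColorEntry] = []
    for gid, value in zip(matrix.row_ids, column):
        report.records_in += 1
        if math.isnan(value):
            report.drop("missing_value")
            continue
        kegg = c2_map_to_kegg(gid, mapping)
        if kegg is None:
            report.drop("no_kegg_id")
            continue
        if scale == "linear":
            if value <= 0:
                report.drop("nonpositive_linear_ratio")
                continue
            value = math.log2(value)
        cls = c2_classify(float(value), threshold)
        entries.append(KeggColorEntry(gene_id=kegg, color=REGULATION_COLOR[cls]))
        report.records_out += 1
    return entries, report


# ---------------------------------------------------------------------------
# Four-block connector specs (file level)


def build_c1_spec(access_policy: AccessPolicy | None = None) -> ConnectorSpec:
    """File-level C1: SOFT files in, one merged ratio matrix out.

    inputs: ``soft_paths`` (list), ``condition_ids`` (list), ``out_path``.
    """

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        tables = []
        for path in inputs["soft_paths"]:
            with open(path, encoding="utf-8") as fh:
                tables.append(read_soft_sample(fh))
        return tables

    def lifting(tables, inputs: dict, config: dict, report: RunReport):
        # Canonical form: separate instance lists for genes, conditions and
        # the per-condition ratio values.
        condition_ids = list(inputs["condition_ids"])
        matrix = c1_merge(tables, condition_ids, report)
        genes = [SemanticInstance(g, "gene", (g,)) for g in matrix.row_ids]
        conditions = [
            SemanticInstance(c, "experimental_condition", (c,)) for c in condition_ids
        ]
        ratios = [
            SemanticInstance(
                matrix.values[i, j],
                "ratio_intensity_based_value",
                (matrix.row_ids[i], condition_ids[j]),
            )
            for i in range(len(matrix.row_ids))
            for j in range(len(condition_ids))
        ]
        return {"genes": genes, "conditions": conditions, "ratios": ratios, "matrix": matrix}

    def lowering(canonical, inputs: dict, config: dict, report: RunReport):
        return canonical["matrix"]

    def data_output(matrix: DelimitedMatrix, inputs: dict, config: dict, report: RunReport):
        out_path = Path(inputs["out_path"])
        with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
            write_matrix(matrix, fh)
        return {"matrix": out_path}

    return ConnectorSpec(
        id="C1",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C1"),
        access_policy=access_policy or AccessPolicy(),
        consumes=("soft_paths", "condition_ids", "out_path"),
        produces=("matrix",),
    )


def build_c2_spec(access_policy: AccessPolicy | None = None) -> ConnectorSpec:
    """File-level C2: DE matrix + platform mapping in, KEGG color list out.

    inputs: ``matrix_path``, ``mapping_path``, ``out_path``; config:
    ``condition_id``, ``threshold``, optional ``scale``.
    """

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        with open(inputs["matrix_path"], encoding="utf-8") as fh:
            matrix = read_matrix(fh, concept_tag="ratio_intensity_based_value")
        with open(inputs["mapping_path"], encoding="utf-8") as fh:
            mapping = read_platform_mapping(fh)
        return matrix, mapping

    def lifting(pair, inputs: dict, config: dict, report: RunReport):
        matrix, mapping = pair
        entries, inner = c2_run(
            matrix,
            config["condition_id"],
            GeneExpressionThreshold(float(config["threshold"])),
            mapping,
            scale=config.get("scale", "log2"),
        )
        report.records_in = inner.records_in
        report.records_out = inner.records_out
        report.dropped.update(inner.dropped)
        report.warnings.extend(inner.warnings)
        return entries

    def lowering(entries, inputs: dict, config: dict, report: RunReport):
        return entries

    def data_output(entries, inputs: dict, config: dict, report: RunReport):
        out_path = Path(inputs["out_path"])
        with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
            write_kegg_colors(entries, fh)
        return {"colors": out_path}

    def check(report: RunReport) -> list[str]:
        if report.records_in != report.records_out + report.records_dropped:
            return [
                f"C2 conservation violated: in={report.records_in} != "
                f"out={report.records_out} + dropped={report.records_dropped}"
            ]
        return []

    return ConnectorSpec(
        id="C2",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C2"),
        access_policy=access_policy or AccessPolicy(),
        consumes=("matrix_path", "mapping_path", "out_path"),
        produces=("colors",),
        check_report=check,
    )
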