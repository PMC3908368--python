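"""Scenario 3 connectors: one-color intensities to virtual two-color data
and HTself results to a filtered gene list.

HTself is a self-self based statistic for low-replication two-color
microarray data; to apply it to one-color intensities the composite
connector ``C5`` fabricates virtual two-color log-ratio columns from
pairwise intensity quotients. ``C5.1`` pairs samples *within* each
biological category (virtual self-self data, used to calibrate the null),
and ``C5.2`` pairs samples *across* the two categories of interest (the
actual comparisons). ``C6`` then filters the HTself result table, keeping
genes whose statistic is at or above and whose p-value is at or below the
provided thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from .core import (
    AccessPolicy,
    CompositePlan,
    ConnectorSpec,
    RunReport,
    load_equivalence_table,
    run_composite,
)
from .formats import (
    DelimitedMatrix,
    HtselfResultRow,
    SoftSampleTable,
    ValidationError,
    read_htself,
    read_soft_sample,
    write_gene_list,
    write_matrix,
)

__all__ = [
    "CategorizedSamples",
    "PairPlan",
    "enumerate_self_self_pairs",
    "enumerate_cross_pairs",
    "compute_ratio_columns",
    "c5_run",
    "c6_filter",
    "build_c5_1_spec",
    "build_c5_2_spec",
    "build_c5_plan",
    "build_c6_spec",
]


@dataclass
class CategorizedSamples:
    """One-color intensity samples grouped by biological category."""

    categories: dict[str, list[SoftSampleTable]]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError("at least one category is required")
        ids = [t.sample_id for tables in self.categories.values() for t in tables]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"sample ids must be unique across categories: {ids}")

    def sample(self, sample_id: str) -> SoftSampleTable:
        for tables in self.categories.values():
            for t in tables:
                if t.sample_id == sample_id:
                    return t
        raise ValidationError(f"unknown sample id {sample_id!r}")

    def gene_order(self) -> list[str]:
        """Union of gene ids across all samples, by first appearance."""
        order: list[str] = []
        seen: set[str] = set()
        for tables in self.categories.values():
            for t in tables:
                for gid, _ in t.rows:
                    if gid not in seen:
                        seen.add(gid)
                        order.append(gid)
        return order


@dataclass
class PairPlan:
    """Ordered (numerator, denominator, column label) sample pairs."""

    pairs: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        keys = [(n, d) for n, d, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValidationError("pair plan contains a repeated pair")
        if any(n == d for n, d in keys):
            raise ValidationError("pair plan contains a self-pair")


def enumerate_self_self_pairs(samples: CategorizedSamples) -> PairPlan:
    """All unordered within-category pairs (virtual self-self data).

    For a category with ordered samples s1..sn, emits (si, sj) for i < j,
    so the total is the sum over categories of C(n, 2). Column labels are
    ``<category>:<numerator>/<denominator>``.
    """
    pairs: list[tuple[str, str, str]] = []
    for cat, tables in samples.categories.items():
        ids = [t.sample_id for t in tables]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j], f"{cat}:{ids[i]}/{ids[j]}"))
    return PairPlan(pairs)


def enumerate_cross_pairs(
    samples: CategorizedSamples, cat_a: str, cat_b: str
) -> PairPlan:
    """All ordered cross-category pairs, numerators from ``cat_a``.

    Enumeration order: ``cat_a`` samples in the outer loop, ``cat_b`` in
    the inner, both in input order; total = n_a * n_b.
    """
    if cat_a == cat_b:
        raise ValidationError("cross-category pairing requires two distinct categories")
    for cat in (cat_a, cat_b):
        if cat not in samples.categories:
            raise ValidationError(
                f"unknown category {cat!r}; available: {sorted(samples.categories)}"
            )
    pairs = [
        (a.sample_id, b.sample_id, f"{cat_a}/{cat_b}:{a.sample_id}/{b.sample_id}")
        for a in samples.categories[cat_a]
        for b in samples.categories[cat_b]
    ]
    return PairPlan(pairs)


def compute_ratio_columns(
    samples: CategorizedSamples,
    plan: PairPlan,
    scale: str = "log2",
    report: RunReport | None = None,
) -> DelimitedMatrix:
    """One ratio column per planned pair over the union of genes.

    Cells are ``log2(I_num / I_den)`` (or the raw quotient with
    ``scale="linear"``); a missing or non-positive intensity on either
    side yields a missing cell with a tallied warning, since
    background-subtracted one-color intensities can go non-positive.
    """
    if scale not in {"log2", "linear"}:
        raise ValidationError(f"scale must be log2 or linear, got {scale!r}")
    genes = samples.gene_order()
    values = np.full((len(genes), len(plan.pairs)), np.nan)
    for j, (num_id, den_id, _label) in enumerate(plan.pairs):
        num = samples.sample(num_id).value_map()
        den = samples.sample(den_id).value_map()
        for i, gid in enumerate(genes):
            a, b = num.get(gid), den.get(gid)
            if a is None or b is None or a <= 0 or b <= 0:
                if report is not None:
                    report.drop("unusable_intensity")
                continue
            values[i, j] = a / b if scale == "linear" else math.log2(a / b)
    if report is not None:
        report.records_in += len(genes) * len(plan.pairs)
        report.records_out += int(np.isfinite(values).sum())
    return DelimitedMatrix(
        row_ids=genes,
        col_ids=[label for _, _, label in plan.pairs],
        values=values,
        concept_tag="ratio_intensity_based_value",
    )


def c5_run(
    samples: CategorizedSamples,
    cat_a: str,
    cat_b: str,
    out_dir: str | Path,
    scale: str = "log2",
) -> tuple[Path, Path, RunReport]:
    """Composite C5 as a convenience call: C5.1 then C5.2, two matrix files."""
    plan = build_c5_plan(cat_a=cat_a, cat_b=cat_b, scale=scale)
    outputs, report = run_composite(plan, {"samples": samples, "out_dir": Path(out_dir)})
    return outputs["C5.1.selfself"], outputs["C5.2.cross"], report


def c6_filter(
    rows: Sequence[HtselfResultRow],
    stat_threshold: float,
    p_threshold: float,
    strict: bool = False,
) -> list[str]:
    """Keep genes passing both HTself-statistic and p-value thresholds.

    Non-strict (default) boundaries keep a gene with
    ``htself_value >= stat_threshold`` and ``p_value <= p_threshold``;
    ``strict=True`` uses ``>`` / ``<``. Input order is preserved.
    """
    if not (math.isfinite(stat_threshold) and math.isfinite(p_threshold)):
        raise ValidationError("thresholds must be finite")
    if strict:
        return [
            r.gene_id
            for r in rows
            if r.htself_value > stat_threshold and r.p_value < p_threshold
        ]
    return [
        r.gene_id
        for r in rows
        if r.htself_value >= stat_threshold and r.p_value <= p_threshold
    ]


# ---------------------------------------------------------------------------
# Four-block connector specs (file level)


def _load_samples(inputs: dict) -> CategorizedSamples:
    value = inputs["samples"]
    if isinstance(value, CategorizedSamples):
        return value
    categories: dict[str, list[SoftSampleTable]] = {}
    for cat, paths in value.items():
        tables = []
        for path in paths:
            with open(path, encoding="utf-8") as fh:
                tables.append(read_soft_sample(fh))
        categories[cat] = tables
    return CategorizedSamples(categories)


def _ratio_spec(connector_id: str, out_name: str, scale: str, planner) -> ConnectorSpec:
    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        return _load_samples(inputs)

    def lifting(samples, inputs: dict, config: dict, report: RunReport):
        plan = planner(samples, config)
        matrix = compute_ratio_columns(
            samples, plan, scale=config.get("scale", scale), report=report
        )
        return matrix

    def lowering(matrix, inputs: dict, config: dict, report: RunReport):
        return matrix

    def data_output(matrix, inputs: dict, config: dict, report: RunReport):
        out_dir = Path(inputs["out_dir"])
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{out_name}.tsv"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            write_matrix(matrix, fh)
        return {out_name: path}

    return ConnectorSpec(
        id=connector_id,
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table(connector_id),
        consumes=("samples", "out_dir"),
        produces=(out_name,),
    )


def build_c5_1_spec(scale: str = "log2") -> ConnectorSpec:
    """C5.1: within-category self-self ratio columns -> ``selfself.tsv``."""
    return _ratio_spec(
        "C5.1", "selfself", scale, lambda samples, config: enumerate_self_self_pairs(samples)
    )


def build_c5_2_spec(cat_a: str, cat_b: str, scale: str = "log2") -> ConnectorSpec:
    """C5.2: cross-category ratio columns -> ``cross.tsv``."""
    return _ratio_spec(
        "C5.2",
        "cross",
        scale,
        lambda samples, config: enumerate_cross_pairs(samples, cat_a, cat_b),
    )


def build_c5_plan(
    cat_a: str,
    cat_b: str,
    scale: str = "log2",
    access_policy: AccessPolicy | None = None,
) -> CompositePlan:
    """Composite C5 = C5.1 then C5.2 over the same categorized samples."""
    return CompositePlan(
        id="C5",
        children=(build_c5_1_spec(scale=scale), build_c5_2_spec(cat_a, cat_b, scale=scale)),
        access_policy=access_policy or AccessPolicy(),
    )


def build_c6_spec(access_policy: AccessPolicy | None = None) -> ConnectorSpec:
    """File-level C6. inputs: ``htself_path``, ``out_path``; config:
    ``stat_threshold``, ``p_threshold``, optional ``strict``."""

    def data_input(payload: Any, inputs: dict, config: dict, report: RunReport):
        with open(inputs["htself_path"], encoding="utf-8") as fh:
            return read_htself(fh)

    def lifting(rows, inputs: dict, config: dict, report: RunReport):
        report.records_in = len(rows)
        kept = c6_filter(
            rows,
            float(config["stat_threshold"]),
            float(config["p_threshold"]),
            strict=bool(config.get("strict", False)),
        )
        report.records_out = len(kept)
        report.drop("failed_threshold", len(rows) - len(kept))
        return kept

    def lowering(kept, inputs: dict, config: dict, report: RunReport):
        return kept

    def data_output(kept, inputs: dict, config: dict, report: RunReport):
        out_path = Path(inputs["out_path"])
        with open(out_path, "w", encoding="utf-8", newline="\n") as fh:
            write_gene_list(kept, fh)
        return {"genes": out_path}

    def check(report: RunReport) -> list[str]:
        if report.records_in != report.records_out + report.records_dropped:
            return [
                f"C6 conservation violated: {report.records_in} != "
                f"{report.records_out} + {report.records_dropped}"
            ]
        return []

    return ConnectorSpec(
        id="C6",
        blocks={
            "data_input_processing": data_input,
            "lifting": lifting,
            "lowering": lowering,
            "data_output_processing": data_output,
        },
        equivalence_table=load_equivalence_table("C6"),
        access_policy=access_policy or AccessPolicy(),
        consumes=("htself_path", "out_path"),
        produces=("genes",),
        check_report=check,
    )
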