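"""Deterministic fixture generators emulating the three integration
scenarios' input shapes.

Each generator writes real files in exactly the dialects the format
readers accept (SOFT sample tables, SAM, GFF, HTself tables, platform
mappings) plus a ``truth.json`` sidecar recording the planted ground
truth, so every connector can be tested end to end without any download.
All randomness flows from a single seed through one ``numpy`` generator
stream, and regenerating with the same seed reproduces byte-identical
files.

Default scales are tiny (tens of genes, a handful of conditions, a few
hundred reads): the shapes of the real studies, not their volumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats import SoftSampleTable, ValidationError, format_number, write_soft_sample

__all__ = [
    "FixtureBundle",
    "gen_two_color_soft",
    "gen_rnaseq_fixture",
    "gen_one_color_fixture",
    "gen_htself_fixture",
    "gen_platform_mapping_fixture",
]


@dataclass
class FixtureBundle:
    """Generated input files plus their planted ground truth."""

    files: dict[str, Path]
    truth: dict
    seed: int

    def write_truth(self, out_dir: Path, name: str = "truth.json") -> Path:
        path = Path(out_dir) / name
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        self.files["truth"] = path
        return path


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def gen_two_color_soft(
    n_genes: int,
    n_conditions: int,
    seed: int,
    out_dir: str | Path,
    omit_fraction: float = 0.1,
    sd: float = 1.0,
) -> FixtureBundle:
    """Scenario-1 inputs: one two-color SOFT sample file per condition.

    Values are zero-centered log2 ratios drawn from Normal(0, ``sd``),
    rounded to 4 decimals as printed. A fraction ``omit_fraction`` of
    (gene, condition) cells is omitted from the corresponding file to
    exercise the NA-filling union merge.
    """
    if n_genes < 1 or n_conditions < 1:
        raise ValidationError("n_genes and n_conditions must be >= 1")
    if not 0 <= omit_fraction < 1:
        raise ValidationError("omit_fraction must be in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    conditions = [f"cond{j + 1}" for j in range(n_conditions)]
    files: dict[str, Path] = {}
    truth_values: dict[str, dict[str, float | None]] = {g: {} for g in genes}
    for cond in conditions:
        raw = rng.normal(0.0, sd, size=n_genes)
        omit = rng.random(n_genes) < omit_fraction
        rows: list[tuple[str, float | None]] = []
        for gid, value, skip in zip(genes, raw, omit):
            if skip:
                truth_values[gid][cond] = None
                continue
            printed = float(f"{value:.4f}")
            truth_values[gid][cond] = printed
            rows.append((gid, printed))
        path = out_dir / f"{cond}.soft"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            write_soft_sample(SoftSampleTable(sample_id=cond, rows=rows), fh)
        files[cond] = path
    bundle = FixtureBundle(
        files=files,
        truth={
            "kind": "two_color",
            "genes": genes,
            "conditions": conditions,
            "sd": sd,
            "omit_fraction": omit_fraction,
            "values": truth_values,
        },
        seed=seed,
    )
    bundle.write_truth(out_dir)
    return bundle


def gen_rnaseq_fixture(
    out_dir: str | Path,
    seed: int,
    n_genes: int = 8,
    gene_length: int = 300,
    spacing: int = 100,
    counts: Mapping[str, Mapping[str, int]] | None = None,
    intergenic_reads: int = 5,
    read_length: int = 50,
    n_conditions: int = 2,
    mean_count: float = 6.0,
) -> FixtureBundle:
    """Scenario-2 inputs: a GFF of non-overlapping genes plus per-condition
    SAM files with planted per-gene read counts.

    Genes are laid out on a single prokaryote-like reference sequence,
    ``gene_length`` bases each, separated (and flanked) by ``spacing``
    intergenic bases. Each SAM contains exactly ``counts[gene][condition]``
    reads placed uniformly, fully inside the gene, plus
    ``intergenic_reads`` reads placed wholly between genes (these are the
    reads the annotation step must remove). When ``counts`` is omitted a
    Poisson(``mean_count``) table over ``n_conditions`` conditions is
    planted. The truth sidecar records planted counts, per-condition
    totals and removed-read counts.
    """
    if gene_length < read_length or spacing < read_length:
        raise ValidationError(
            "infeasible geometry: gene_length and spacing must both be >= read_length"
        )
    if n_genes < 1:
        raise ValidationError("n_genes must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    if counts is None:
        conditions = [f"cond{j + 1}" for j in range(n_conditions)]
        counts = {
            g: {c: int(rng.poisson(mean_count)) for c in conditions} for g in genes
        }
    else:
        counts = {g: dict(cmap) for g, cmap in counts.items()}
        genes = list(counts)
        conditions = list(next(iter(counts.values())))
    for g, cmap in counts.items():
        for c, n in cmap.items():
            if n < 0 or n != int(n):
                raise ValidationError(f"planted count for ({g}, {c}) must be a non-negative integer")

    seqid = "chr"
    gene_spans: dict[str, tuple[int, int]] = {}
    cursor = spacing + 1  # leave an intergenic gap before the first gene
    for g in genes:
        gene_spans[g] = (cursor, cursor + gene_length - 1)
        cursor += gene_length + spacing
    genome_length = cursor - 1
    gaps = [(1, spacing)]
    for g in genes:
        start, end = gene_spans[g]
        gaps.append((end + 1, end + spacing))

    gff_path = out_dir / "genes.gff"
    with open(gff_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = gene_spans[g]
            fh.write(f"{seqid}\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={g}\n")

    files: dict[str, Path] = {"gff": gff_path}
    totals: dict[str, int] = {}
    read_serial = 0
    for cond in conditions:
        records: list[str] = []
        for g in genes:
            start, end = gene_spans[g]
            n = counts[g][cond]
            if n:
                starts = rng.integers(start, end - read_length + 2, size=n)
                for pos in starts:
                    read_serial += 1
                    records.append(
                        f"r{read_serial:05d}\t0\t{seqid}\t{int(pos)}\t60\t{read_length}M"
                        f"\t*\t0\t0\t{'A' * read_length}\t{'I' * read_length}"
                    )
        for _ in range(intergenic_reads):
            gap_start, gap_end = gaps[int(rng.integers(0, len(gaps)))]
            pos = int(rng.integers(gap_start, gap_end - read_length + 2))
            read_serial += 1
            records.append(
                f"x{read_serial:05d}\t0\t{seqid}\t{pos}\t60\t{read_length}M"
                f"\t*\t0\t0\t{'A' * read_length}\t{'I' * read_length}"
            )
        path = out_dir / f"{cond}.sam"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{seqid}\tLN:{genome_length}\n")
            for rec in records:
                fh.write(rec + "\n")
        files[cond] = path
        totals[cond] = sum(counts[g][cond] for g in genes)

    bundle = FixtureBundle(
        files=files,
        truth={
            "kind": "rnaseq",
            "genes": genes,
            "conditions": conditions,
            "counts": {g: dict(counts[g]) for g in genes},
            "totals": totals,
            "removed": {c: intergenic_reads for c in conditions},
            "gene_spans": {g: list(gene_spans[g]) for g in genes},
            "read_length": read_length,
        },
        seed=seed,
    )
    bundle.write_truth(out_dir)
    return bundle


def gen_one_color_fixture(
    out_dir: str | Path,
    seed: int,
    n_genes: int = 20,
    category_sizes: Mapping[str, int] | None = None,
    log2_mean: float = 8.0,
    log2_sd: float = 1.5,
) -> FixtureBundle:
    """Scenario-3 inputs: one-color SOFT intensity files in categories.

    Intensities are log-normal (2 ** Normal(``log2_mean``, ``log2_sd``)),
    strictly positive, printed to 4 decimals. Defaults emulate a
    normal-vs-tumor design with 2 and 3 biological replicates.
    """
    category_sizes = dict(category_sizes or {"normal": 2, "tumor": 3})
    if not category_sizes or any(n < 1 for n in category_sizes.values()):
        raise ValidationError("every category needs at least one sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    files: dict[str, Path] = {}
    intensities: dict[str, dict[str, float]] = {}
    categories: dict[str, list[str]] = {}
    for cat, size in category_sizes.items():
        categories[cat] = []
        for k in range(size):
            sample_id = f"{cat}{k + 1}"
            categories[cat].append(sample_id)
            values = 2.0 ** rng.normal(log2_mean, log2_sd, size=n_genes)
            printed = [float(f"{v:.4f}") for v in values]
            intensities[sample_id] = dict(zip(genes, printed))
            path = out_dir / f"{sample_id}.soft"
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                write_soft_sample(
                    SoftSampleTable(sample_id=sample_id, rows=list(zip(genes, printed))),
                    fh,
                )
            files[sample_id] = path
    bundle = FixtureBundle(
        files=files,
        truth={
            "kind": "one_color",
            "genes": genes,
            "categories": categories,
            "intensities": intensities,
        },
        seed=seed,
    )
    bundle.write_truth(out_dir)
    return bundle


def gen_htself_fixture(
    out_dir: str | Path,
    seed: int,
    n_genes: int = 20,
    planted_significant: Sequence[str] | None = None,
    stat_threshold: float = 0.8,
    p_threshold: float = 0.05,
) -> FixtureBundle:
    """An HTself result table with a planted significant gene set.

    Planted genes get a statistic at or above ``stat_threshold`` and a
    p-value at or below ``p_threshold``; every other gene fails at least
    one of the two criteria, so filtering at the generator's thresholds
    recovers the planted set exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    if planted_significant is None:
        k = max(1, n_genes // 5)
        planted_significant = sorted(rng.choice(genes, size=k, replace=False).tolist())
    planted = list(planted_significant)
    if not set(planted) <= set(genes):
        raise ValidationError(
            f"planted significant genes {sorted(set(planted) - set(genes))} "
            "are not among the generated genes"
        )
    path = out_dir / "htself.tsv"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\thtself\tp_value\n")
        for g in genes:
            if g in planted:
                stat = stat_threshold + 0.1 + 0.8 * rng.random()
                p = p_threshold * (0.1 + 0.8 * rng.random())
            else:
                # fail the statistic, the p-value, or both
                mode = int(rng.integers(0, 3))
                fail_stat = mode in (0, 2)
                fail_p = mode in (1, 2)
                stat = (
                    stat_threshold * 0.9 * rng.random()
                    if fail_stat
                    else stat_threshold + 0.1 + 0.8 * rng.random()
                )
                p = (
                    min(1.0, p_threshold + 0.01 + (1 - p_threshold) * rng.random())
                    if fail_p
                    else p_threshold * (0.1 + 0.8 * rng.random())
                )
            fh.write(f"{g}\t{stat:.4f}\t{p:.6f}\n")
    bundle = FixtureBundle(
        files={"htself": path},
        truth={
            "kind": "htself",
            "genes": genes,
            "planted_significant": planted,
            "stat_threshold": stat_threshold,
            "p_threshold": p_threshold,
        },
        seed=seed,
    )
    bundle.write_truth(out_dir)
    return bundle


def gen_platform_mapping_fixture(
    out_dir: str | Path,
    gene_ids: Sequence[str],
    seed: int,
    mappable_fraction: float = 0.8,
    kegg_prefix: str = "PVX_",
) -> FixtureBundle:
    """A two-column platform mapping covering a fraction of the genes.

    The mapped genes get KEGG-style identifiers in which the KEGG id
    doubles as the official id (two-column dialect); the rest are simply
    absent from the file, emulating probes with no pathway-database entry.
    """
    if not 0 <= mappable_fraction <= 1:
        raise ValidationError("mappable_fraction must be in [0, 1]")
    if not gene_ids:
        raise ValidationError("gene_ids must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_mapped = int(round(mappable_fraction * len(gene_ids)))
    mapped = sorted(
        rng.choice(list(gene_ids), size=n_mapped, replace=False).tolist()
    )
    mapping = {g: f"{kegg_prefix}{i + 1:06d}" for i, g in enumerate(mapped)}
    path = Path(out_dir) / "platform_mapping.tsv"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("ID\tKEGG\n")
        for g in mapped:
            fh.write(f"{g}\t{mapping[g]}\n")
    bundle = FixtureBundle(
        files={"mapping": path},
        truth={
            "kind": "platform_mapping",
            "mappable_fraction": mappable_fraction,
            "mapping": mapping,
            "unmapped": sorted(set(gene_ids) - set(mapped)),
        },
        seed=seed,
    )
    bundle.write_truth(out_dir, name="mapping_truth.json")
    return bundle
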