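"""Scenario-2 connectors: read-to-gene assignment, counting, normalization."""

import io
import math

import numpy as np
import pytest

from gexpo_connect.core import run_composite
from gexpo_connect.formats import (
    GffFeature,
    SamAlignment,
    ValidationError,
    read_matrix,
)
from gexpo_connect.rnaseq import (
    AnnotatedReadSet,
    ConditionTotals,
    GeneIndex,
    assign_read_to_gene,
    build_c3_plan,
    c3_1_annotate,
    c3_2_total,
    c3_3_count,
    c4_normalize,
    read_totals,
    write_totals,
)
from gexpo_connect.simdata import gen_rnaseq_fixture


def _aln(start, end, rname="chr", flag=0):
    return SamAlignment(
        qname="r",
        flag=flag,
        rname=rname,
        pos=start,
        cigar=f"{end - start + 1}M",
        aligned_span=(start, end),
    )


def _gene(gene_id, start, end, seqid="chr", strand="+"):
    return GffFeature(seqid, "gene", start, end, strand, gene_id)


# ---------------------------------------------------------------------------
# assignment


def test_assignment_containment_intergenic_and_largest_overlap():
    index = GeneIndex([_gene("g1", 50, 200), _gene("g2", 210, 400)])
    assert assign_read_to_gene(_aln(100, 149), index) == "g1"
    assert assign_read_to_gene(_aln(500, 550), index) is None
    # overlap 11 with g1 vs overlap 30 with g2 -> g2
    assert assign_read_to_gene(_aln(190, 239), index) == "g2"


def test_assignment_exact_tie_breaks_lexicographically():
    # read [96,115] overlaps gB by [96,105] and gA by [106,115]: 10 bases each
    index = GeneIndex([_gene("gB", 50, 105), _gene("gA", 106, 160)])
    aln = _aln(96, 115)
    assert min(115, 105) - max(96, 50) + 1 == min(115, 160) - max(96, 106) + 1 == 10
    assert assign_read_to_gene(aln, index) == "gA"


def test_assignment_requires_same_reference_sequence():
    index = GeneIndex([_gene("g1", 50, 200, seqid="chr2")])
    assert assign_read_to_gene(_aln(100, 149, rname="chr1"), index) is None


def test_assignment_stranded_mode_filters_by_strand():
    index = GeneIndex([_gene("g1", 50, 200, strand="-")], stranded=True)
    assert assign_read_to_gene(_aln(100, 149, flag=0), index) is None
    assert assign_read_to_gene(_aln(100, 149, flag=16), index) == "g1"


def _brute_force_assign(aln, features):
    """Independent all-pairs overlap scan with the same tie rules."""
    best = None
    for f in features:
        if f.seqid != aln.rname:
            continue
        start, end = aln.aligned_span
        overlap = min(end, f.end) - max(start, f.start) + 1
        if overlap < 1:
            continue
        if best is None or overlap > best[0] or (overlap == best[0] and f.gene_id < best[1]):
            best = (overlap, f.gene_id)
    return best[1] if best else None


def test_assignment_agrees_with_brute_force_on_random_instances():
    rng = np.random.default_rng(2024)
    for trial in range(100):
        n_genes = int(rng.integers(1, 21))
        genes = []
        for i in range(n_genes):
            start = int(rng.integers(1, 2000))
            length = int(rng.integers(1, 150))
            genes.append(_gene(f"g{i:02d}", start, start + length))
        # deliberately duplicate some intervals to force exact ties
        for i in range(min(3, n_genes)):
            src = genes[int(rng.integers(0, n_genes))]
            genes.append(_gene(f"t{i}", src.start, src.end))
        index = GeneIndex(genes)
        for _ in range(int(rng.integers(1, 201))):
            start = int(rng.integers(1, 2200))
            end = start + int(rng.integers(0, 120))
            aln = _aln(start, end)
            assert assign_read_to_gene(aln, index) == _brute_force_assign(aln, genes)


# ---------------------------------------------------------------------------
# C3.1 / C3.2 / C3.3


SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr\tLN:1000\n"


def _sam_body(spans):
    lines = [
        f"r{i}\t0\tchr\t{start}\t60\t{end - start + 1}M\t*\t0\t0\tA\tI"
        for i, (start, end) in enumerate(spans)
    ]
    return SAM_HEADER + "\n".join(lines) + ("\n" if lines else "")


def test_c3_1_annotates_in_read_order_and_counts_removed():
    features = [_gene("g1", 50, 200), _gene("g2", 300, 500)]
    spans = [(60, 109), (310, 359), (700, 749), (100, 149)]
    result = c3_1_annotate(io.StringIO(_sam_body(spans)), features, "c1")
    assert result.gene_hits == ["g1", "g2", "g1"]
    assert result.removed == 1
    assert result.mapped_reads == 4


def test_c3_1_empty_and_all_intergenic():
    features = [_gene("g1", 50, 200)]
    empty = c3_1_annotate(io.StringIO(SAM_HEADER), features, "c1")
    assert empty.gene_hits == [] and empty.removed == 0
    lost = c3_1_annotate(io.StringIO(_sam_body([(700, 749), (800, 849)])), features, "c1")
    assert lost.gene_hits == [] and lost.removed == 2


def test_c3_2_totals_are_annotated_read_counts():
    sets = [
        AnnotatedReadSet("c1", ["g1"] * 8),
        AnnotatedReadSet("c2", ["g1"] * 6 + ["g2"] * 6),
    ]
    totals = c3_2_total(sets)
    assert totals.totals == {"c1": 8, "c2": 12}
    assert c3_2_total([]).totals == {}


def test_c3_2_distinct_genes_mode():
    sets = [AnnotatedReadSet("c1", ["g1", "g1", "g2"])]
    assert c3_2_total(sets, mode="distinct-genes").totals == {"c1": 2}


def test_c3_2_duplicate_condition_rejected():
    sets = [AnnotatedReadSet("c1", ["g1"]), AnnotatedReadSet("c1", ["g2"])]
    with pytest.raises(ValidationError, match="duplicate"):
        c3_2_total(sets)


def test_c3_3_tally_and_zero_fill():
    sets = [
        AnnotatedReadSet("c1", ["g1", "g1", "g2"]),
        AnnotatedReadSet("c2", ["g2"]),
    ]
    m = c3_3_count(sets)
    assert m.concept_tag == "absolute_cdna_reads_counting_based_value"
    assert m.row_ids == ["g1", "g2"]
    assert m.values.tolist() == [[2.0, 0.0], [1.0, 1.0]]
    single = c3_3_count([AnnotatedReadSet("c", ["g1"])])
    assert single.values.tolist() == [[1.0]]


def test_c3_count_conservation_totals_equal_column_sums():
    rng = np.random.default_rng(7)
    sets = [
        AnnotatedReadSet(
            f"c{j}", [f"g{int(rng.integers(0, 5))}" for _ in range(int(rng.integers(0, 40)))]
        )
        for j in range(3)
    ]
    totals = c3_2_total(sets)
    m = c3_3_count(sets)
    for j, cond in enumerate(m.col_ids):
        assert m.values[:, j].sum() == totals.totals[cond]


# ---------------------------------------------------------------------------
# C4


def test_c4_division_and_column_sums():
    sets = [
        AnnotatedReadSet("c1", ["g1"] * 5 + ["g2"] * 5),
        AnnotatedReadSet("c2", ["g1"] * 3 + ["g2"] * 9),
    ]
    counts = c3_3_count(sets)
    totals = c3_2_total(sets)
    rel = c4_normalize(counts, totals)
    assert rel.concept_tag == "relative_cdna_reads_counting_based_value"
    assert rel.values[0, 0] == 0.5
    assert np.allclose(rel.values.sum(axis=0), 1.0, atol=1e-12)


def test_c4_zero_count_yields_zero():
    counts = c3_3_count([AnnotatedReadSet("c1", ["g1", "g2"]), AnnotatedReadSet("c2", ["g1"])])
    rel = c4_normalize(counts, ConditionTotals({"c1": 2, "c2": 1}))
    assert rel.values[counts.row_ids.index("g2"), 1] == 0.0


def test_c4_zero_total_rejected_naming_condition():
    counts = c3_3_count([AnnotatedReadSet("c1", ["g1"])])
    with pytest.raises(ValidationError, match="c1"):
        c4_normalize(counts, ConditionTotals({"c1": 0}))


def test_totals_round_trip():
    totals = ConditionTotals({"c1": 8, "c2": 12})
    buf = io.StringIO()
    write_totals(totals, buf)
    buf.seek(0)
    assert read_totals(buf).totals == totals.totals


# ---------------------------------------------------------------------------
# ground truth recovery and composite equivalence


def test_c3_recovers_planted_counts_exactly(tmp_path):
    bundle = gen_rnaseq_fixture(
        tmp_path,
        seed=11,
        counts={"g1": {"c1": 2, "c2": 0}, "g2": {"c1": 1, "c2": 1}},
        intergenic_reads=1,
    )
    plan = build_c3_plan()
    outputs, report = run_composite(
        plan,
        {
            "sam_paths": {c: bundle.files[c] for c in bundle.truth["conditions"]},
            "gff_path": bundle.files["gff"],
            "out_dir": tmp_path / "out",
        },
    )
    counts = outputs["C3.3.counts"]
    truth = bundle.truth["counts"]
    expected_genes = sorted(g for g in truth if any(truth[g].values()))
    assert counts.row_ids == expected_genes
    for i, g in enumerate(counts.row_ids):
        for j, c in enumerate(counts.col_ids):
            assert counts.values[i, j] == truth[g][c]
    assert outputs["C3.2.totals"].totals == bundle.truth["totals"]
    child = dict(report.children)["C3.1"]
    assert child.dropped["no_gene_overlap"] == sum(bundle.truth["removed"].values())


def test_c3_composite_equals_manual_chaining_byte_identical(tmp_path):
    bundle = gen_rnaseq_fixture(tmp_path / "fx", seed=5)
    sam_paths = {c: bundle.files[c] for c in bundle.truth["conditions"]}

    plan = build_c3_plan()
    run_composite(
        plan,
        {"sam_paths": sam_paths, "gff_path": bundle.files["gff"], "out_dir": tmp_path / "auto"},
    )

    from gexpo_connect.core import run_connector
    from gexpo_connect.rnaseq import build_c3_1_spec, build_c3_2_spec, build_c3_3_spec

    manual = tmp_path / "manual"
    out1, _ = run_connector(
        build_c3_1_spec(),
        {"sam_paths": sam_paths, "gff_path": bundle.files["gff"], "out_dir": manual},
    )
    # hand the annotated gene-list FILES (not objects) to the next stages
    run_connector(
        build_c3_2_spec(), {"annotated_sets": out1["annotated_paths"], "out_dir": manual}
    )
    run_connector(
        build_c3_3_spec(), {"annotated_sets": out1["annotated_paths"], "out_dir": manual}
    )
    for name in ["totals.tsv", "counts.tsv"]:
        assert (tmp_path / "auto" / name).read_bytes() == (manual / name).read_bytes()
    for cond in sam_paths:
        name = f"annotated_{cond}.txt"
        assert (tmp_path / "auto" / name).read_bytes() == (manual / name).read_bytes()


def test_c3_plan_out_of_order_is_wiring_error(tmp_path):
    from gexpo_connect.core import CompositePlan
    from gexpo_connect.rnaseq import build_c3_1_spec, build_c3_3_spec

    plan = CompositePlan(
        id="C3",
        children=(build_c3_3_spec(), build_c3_1_spec()),
        wiring={"C3.3": {"annotated_sets": "C3.1.annotated_sets"}},
    )
    with pytest.raises(ValidationError, match="C3.1.annotated_sets"):
        run_composite(
            plan,
            {"sam_paths": {}, "gff_path": "x", "out_dir": tmp_path},
        )
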