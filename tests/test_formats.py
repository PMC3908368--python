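"""Format readers/writers: SOFT, SAM, GFF, matrices, mappings, color lists."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gexpo_connect.formats import (
    DelimitedMatrix,
    FormatError,
    HtselfResultRow,
    KeggColorEntry,
    ValidationError,
    cigar_reference_span,
    format_number,
    read_gff_genes,
    read_htself,
    read_matrix,
    read_platform_mapping,
    read_sam,
    read_soft_sample,
    write_kegg_colors,
    write_matrix,
)

# ---------------------------------------------------------------------------
# SOFT sample tables

SOFT_FIXTURE = """\
^SAMPLE = GSM1
!Sample_title = condition one
!sample_table_begin
ID_REF\tVALUE
g1\t1.5
g2\t-0.2
g3\t0.0
!sample_table_end
"""


def test_soft_reads_rows_in_order():
    table = read_soft_sample(io.StringIO(SOFT_FIXTURE))
    assert table.sample_id == "GSM1"
    assert table.rows == [("g1", 1.5), ("g2", -0.2), ("g3", 0.0)]


def test_soft_unparsable_value_becomes_missing():
    text = SOFT_FIXTURE.replace("g2\t-0.2", "g2\tnull")
    table = read_soft_sample(io.StringIO(text))
    assert table.rows[1] == ("g2", None)
    assert table.rows[0] == ("g1", 1.5) and table.rows[2] == ("g3", 0.0)


def test_soft_missing_sentinels_is_format_error():
    with pytest.raises(FormatError, match="sentinel"):
        read_soft_sample(io.StringIO("ID_REF\tVALUE\ng1\t1.0\n"))


def test_soft_header_without_id_value_is_format_error():
    text = "!sample_table_begin\nPROBE\tSIGNAL\ng1\t1.0\n!sample_table_end\n"
    with pytest.raises(FormatError, match="PROBE"):
        read_soft_sample(io.StringIO(text))


def test_soft_extra_columns_ignored():
    text = (
        "!sample_table_begin\nID_REF\tFLAG\tVALUE\ng1\tA\t2.5\n!sample_table_end\n"
    )
    table = read_soft_sample(io.StringIO(text))
    assert table.rows == [("g1", 2.5)]


# ---------------------------------------------------------------------------
# SAM


def _sam_line(pos, cigar, flag=0, rname="chr"):
    return f"read1\t{flag}\t{rname}\t{pos}\t60\t{cigar}\t*\t0\t0\tAAAA\tIIII"


@pytest.mark.parametrize(
    "pos,cigar,expected_span",
    [
        (100, "50M", (100, 149)),
        (10, "10M5N10M", (10, 34)),
        (7, "5S20M3I10M", (7, 36)),  # S and I do not consume reference
        (1, "10M2D5M", (1, 17)),
    ],
)
def test_sam_aligned_span(pos, cigar, expected_span):
    records = list(read_sam(io.StringIO(_sam_line(pos, cigar) + "\n")))
    assert len(records) == 1
    assert records[0].aligned_span == expected_span


def test_sam_skips_header_and_unmapped():
    text = "@HD\tVN:1.6\n" + _sam_line(100, "10M", flag=4) + "\n" + _sam_line(5, "10M") + "\n"
    records = list(read_sam(io.StringIO(text)))
    assert [r.pos for r in records] == [5]


def test_sam_too_few_columns_is_format_error():
    with pytest.raises(FormatError, match="line 1"):
        list(read_sam(io.StringIO("read1\t0\tchr\t100\t60\n")))


def test_sam_non_numeric_pos_is_format_error():
    with pytest.raises(FormatError, match="pos"):
        list(read_sam(io.StringIO("read1\t0\tchr\tabc\t60\t10M\n")))


_cigar_ops = st.lists(
    st.tuples(st.integers(1, 30), st.sampled_from("MIDNS=X")), min_size=1, max_size=6
)


@given(_cigar_ops)
def test_cigar_span_matches_per_base_walk(ops):
    """Reference span equals a brute-force per-base walk over the CIGAR."""
    cigar = "".join(f"{n}{op}" for n, op in ops)
    walked = 0
    for n, op in ops:
        for _ in range(n):
            if op in "MDN=X":
                walked += 1
    assert cigar_reference_span(cigar) == walked


# ---------------------------------------------------------------------------
# GFF

GFF_FIXTURE = """\
##gff-version 3
chr1\t.\tgene\t50\t200\t.\t+\t.\tID=g1
chr1\t.\tCDS\t60\t190\t.\t+\t.\tID=c1
chr1\t.\tgene\t300\t400\t.\t-\t.\tlocus_tag=g2;note=x
"""


def test_gff_type_filter_and_id_extraction():
    feats = read_gff_genes(io.StringIO(GFF_FIXTURE))
    assert [(f.gene_id, f.start, f.end, f.strand) for f in feats] == [
        ("g1", 50, 200, "+"),
        ("g2", 300, 400, "-"),
    ]


def test_gff_inverted_interval_is_format_error():
    text = "chr1\t.\tgene\t300\t250\t.\t+\t.\tID=g1\n"
    with pytest.raises(FormatError, match="start 300 > end 250"):
        read_gff_genes(io.StringIO(text))


def test_gff_record_without_id_key_skipped():
    text = "chr1\t.\tgene\t50\t200\t.\t+\t.\tnote=hello\n"
    assert read_gff_genes(io.StringIO(text)) == []


def test_gff_gtf_style_attributes():
    text = 'chr1\t.\tgene\t5\t25\t.\t+\t.\tgene_id "g9"; gene_name "x"\n'
    feats = read_gff_genes(io.StringIO(text))
    assert feats[0].gene_id == "g9"


def test_gff_empty_feature_types_rejected():
    with pytest.raises(ValidationError):
        read_gff_genes(io.StringIO(GFF_FIXTURE), feature_types=set())


# ---------------------------------------------------------------------------
# Matrices


def test_matrix_shape_and_na_round_trip():
    m = DelimitedMatrix(
        row_ids=["g1", "g2"],
        col_ids=["c1", "c2", "c3"],
        values=np.array([[1.5, math.nan, 0.0], [-2.25, 3.0, 1e-9]]),
        concept_tag="ratio_intensity_based_value",
    )
    buf = io.StringIO()
    write_matrix(m, buf)
    lines = buf.getvalue().splitlines()
    assert len(lines) == 3 and all(len(l.split("\t")) == 4 for l in lines)
    assert lines[1].split("\t")[2] == "NA"
    buf.seek(0)
    again = read_matrix(buf)
    assert again.row_ids == m.row_ids and again.col_ids == m.col_ids
    assert np.array_equal(again.values, m.values, equal_nan=True)


@given(
    st.integers(1, 20),
    st.integers(1, 5),
    st.integers(0, 2**31 - 1),
)
def test_matrix_round_trip_random(n_rows, n_cols, seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_rows, n_cols))
    values[rng.random(values.shape) < 0.2] = math.nan
    m = DelimitedMatrix(
        row_ids=[f"g{i}" for i in range(n_rows)],
        col_ids=[f"c{j}" for j in range(n_cols)],
        values=values,
    )
    buf = io.StringIO()
    write_matrix(m, buf)
    buf.seek(0)
    again = read_matrix(buf)
    assert again.row_ids == m.row_ids and again.col_ids == m.col_ids
    assert np.array_equal(again.values, m.values, equal_nan=True)


def test_matrix_ragged_row_is_format_error():
    text = "gene_id\tc1\tc2\ng1\t1.0\n"
    with pytest.raises(FormatError, match="row 2"):
        read_matrix(io.StringIO(text))


def test_matrix_duplicate_ids_rejected():
    with pytest.raises(ValidationError):
        DelimitedMatrix(["g1", "g1"], ["c1"], np.zeros((2, 1)))


def test_format_number_shortest_round_trip():
    for v in [0.1, 1 / 3, -2.5, 1e-12, 123456.789]:
        assert float(format_number(v)) == v


# ---------------------------------------------------------------------------
# Platform mapping / HTself / KEGG colors / gene lists


def test_platform_mapping_two_column_collapses_official_and_kegg():
    mapping = read_platform_mapping(io.StringIO("probe7\tPVX_000100\n"))
    assert mapping.entries["probe7"] == ("PVX_000100", "PVX_000100")
    assert mapping.kegg_id("probe7") == "PVX_000100"


def test_platform_mapping_three_column_and_duplicates():
    text = "probe1\tgeneX\tkegg:123\nprobe1\tgeneY\tkegg:999\nprobe2\tgeneZ\t\n"
    mapping = read_platform_mapping(io.StringIO(text))
    assert mapping.entries["probe1"] == ("geneX", "kegg:123")  # first wins
    assert mapping.kegg_id("probe2") is None


def test_platform_mapping_soft_wrapped_metadata_skipped():
    text = "^PLATFORM = GPL1\n!platform_table_begin\nID\tKEGG\np1\tk1\n"
    mapping = read_platform_mapping(io.StringIO(text))
    assert mapping.kegg_id("p1") == "k1"


def test_platform_mapping_empty_is_validation_error():
    with pytest.raises(ValidationError):
        read_platform_mapping(io.StringIO("# nothing\n"))


def test_htself_reader_parses_rows_and_header():
    text = "gene_id\thtself\tp_value\ng1\t0.9\t0.01\ng2\t0.7\t0.2\n"
    rows = read_htself(io.StringIO(text))
    assert rows == [HtselfResultRow("g1", 0.9, 0.01), HtselfResultRow("g2", 0.7, 0.2)]


def test_htself_p_value_outside_unit_interval_rejected():
    with pytest.raises(ValidationError):
        HtselfResultRow("g1", 0.5, 1.5)


def test_kegg_colors_rendering_and_order():
    entries = [
        KeggColorEntry("PVX_000100", "red"),
        KeggColorEntry("PVX_000200", "green"),
        KeggColorEntry("PVX_000300", "yellow"),
    ]
    buf = io.StringIO()
    write_kegg_colors(entries, buf)
    assert buf.getvalue() == "PVX_000100 red\nPVX_000200 green\nPVX_000300 yellow\n"
    empty = io.StringIO()
    write_kegg_colors([], empty)
    assert empty.getvalue() == ""


def test_kegg_color_outside_set_rejected():
    with pytest.raises(ValidationError):
        KeggColorEntry("PVX_000100", "blue")


def test_sam_span_agrees_with_pysam(tmp_path):
    """Cross-check aligned spans against pysam on a round-trippable file."""
    pysam = pytest.importorskip("pysam")
    cigars = ["50M", "10M5N10M", "5S20M3I10M", "10M2D5M", "8M1I8M2D4M"]
    path = tmp_path / "mini.sam"
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\n@SQ\tSN:chr\tLN:10000\n")
        for i, cigar in enumerate(cigars):
            fh.write(
                f"r{i}\t0\tchr\t{100 * (i + 1)}\t60\t{cigar}\t*\t0\t0\t*\t*\n"
            )
    with open(path) as fh:
        ours = list(read_sam(fh))
    with pysam.AlignmentFile(str(path), "r") as af:
        theirs = list(af)
    assert len(ours) == len(theirs)
    for mine, ref in zip(ours, theirs):
        assert mine.pos == ref.reference_start + 1
        assert mine.aligned_span == (ref.reference_start + 1, ref.reference_end)
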