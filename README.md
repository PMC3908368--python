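# gexpo-connect

Ontology-grounded software connectors for gene-expression analysis
pipelines.

Gene-expression studies rarely end with a single tool: raw measurements
are normalized in one environment, tested for differential expression in
another, and the results pushed into pathway, clustering or functional
annotation services. Every hand-off risks silently changing what the
numbers *mean* — a log2 ratio is not an absolute intensity, a raw read
count is not a library-size-normalized abundance. `gexpo-connect` makes
these hand-offs explicit and machine-checked: each transformation is a
**connector** whose consumed and produced data items are mapped, through
a bundled reference gene-expression ontology, to concepts with a single
agreed meaning.

It is aimed at bioinformaticians gluing together microarray and RNA-Seq
analyses who want the glue to be auditable rather than ad hoc.

## The model

Every connector is structured as four functional blocks executed
strictly in order:

1. **Data input processing** — parse the source syntax (GEO SOFT sample
   tables, SAM alignments, GFF features, TSV matrices, …);
2. **Lifting** — interpret the parsed records as canonical instances
   tagged with reference-ontology concepts (`gene`,
   `experimental_condition`, `ratio_intensity_based_value`, …), applying
   any semantic transformation rules;
3. **Lowering** — render canonical instances into output-ready records;
4. **Data output processing** — write the target syntax and, under an
   *automatic* access policy, hand control to the target tool afterwards.

Each connector ships a declarative **equivalence table** whose rows link
consumed concepts ↔ reference concept ↔ produced concepts, with
transformation-rule tokens wherever the mapping is not an identity (the
partial-mapping cases: unused inputs; several inputs combining into one
output; outputs derived from inputs). Tables are validated against the
ontology at startup, turning the integration design into checkable data.

Six connectors cover three scenarios:

| Connector | Transformation |
|---|---|
| C1 | per-condition two-color SOFT files → one gene × condition log2-ratio matrix |
| C2 | differential-expression matrix → KEGG Mapper gene/color list, with `x ≥ t` → red (up), `x ≤ −t` → green (down), otherwise yellow, plus experiment-specific → KEGG id mapping |
| C3 = C3.1→C3.2→C3.3 | SAM + GFF → read-to-gene annotation (largest-overlap assignment, unmatched reads removed) → per-condition library sizes → gene × condition count matrix |
| C4 | count matrix → relative abundances, `count(g, c) / library_size(c)` |
| C5 = C5.1→C5.2 | one-color intensity samples → virtual two-color log2-ratio matrices: within-category self-self pairs (i < j), then all cross-category pairs — the input HTself needs |
| C6 | HTself result table → gene list with `statistic ≥ t_stat` and `p ≤ t_p` |

C3 and C5 are composite connectors: ordered compositions of simple
connectors with wiring that is validated before anything runs, and whose
outputs are byte-identical to chaining the children by hand.

## Worked example

Generate a tiny synthetic RNA-Seq scenario (8 genes on a
prokaryote-like reference, 2 conditions, planted per-gene read counts
plus a few intergenic reads), run the composite C3, then normalize:

```sh
$ gexpo-connect simdata scenario2 --seed 11 --out-dir fx
$ gexpo-connect run C3 --sam cond1=fx/cond1.sam --sam cond2=fx/cond2.sam \
      --gff fx/genes.gff --out-dir c3out
connector C3: in=0 out=0 dropped=0
  connector C3.1: in=88 out=78 dropped=10
    dropped[no_gene_overlap] = 10
  connector C3.2: in=78 out=2 dropped=0
  connector C3.3: in=78 out=8 dropped=0
$ gexpo-connect run C4 --counts c3out/counts.tsv --totals c3out/totals.tsv \
      --out relative.tsv
connector C4: in=8 out=8 dropped=0
```

The C3.1 section reports the read-conservation identity: 88 mapped reads
in, 78 annotated to genes, 10 removed because they overlap no gene
(these are exactly the 5 intergenic reads planted per condition). The
composite header stays at zero because children count different record
granularities (reads vs conditions vs genes) and are reported
separately. The outputs:

```sh
$ cat c3out/totals.tsv
cond1	cond2
35	43
$ head -3 c3out/counts.tsv
gene_id	cond1	cond2
g01	3.0	3.0
g02	7.0	9.0
$ head -3 relative.tsv
gene_id	cond1	cond2
g01	0.08571428571428572	0.06976744186046512
g02	0.2	0.20930232558139536
```

Totals equal the count-matrix column sums (35 and 43), and each column
of `relative.tsv` sums to 1 — e.g. `3/35 = 0.0857…` for g01 in cond1.
The fixture's `truth.json` records the planted counts; C3 recovers them
exactly.

`gexpo-connect validate all` checks every bundled equivalence table
against the reference ontology, and `gexpo-connect list` names the
connectors.

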