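# Methods

This note documents the procedures, conventions and design choices
behind `gexpo-connect`: what each component computes, the parameters
that matter, what the synthetic data emulates, and where the edges of
the approach are.

## Reference ontology

The bundled gene-expression ontology is a hand-transcribed, plain-text
edge list (`src/gexpo_connect/data/gexpo_edges.tsv`) of 49 concepts and
103 typed edges covering the expression process (transcription, RNA
processing, translation, protein maturation and the molecules they
produce), the measurement processes (one-/two-color microarray and
RNA-Seq with their subprocesses) and the expression-value hierarchy
(fluorescence intensity-based vs sequence counting-based values, each
with absolute/ratio or absolute/relative specializations). Concepts
reused from the Gene Ontology (processes) and the Sequence Ontology
(sequence entities) are flagged by a `source` attribute; everything else
is marked `introduced`, including the three relations that are not part
of the OBO Relation Ontology vocabulary: `produced_by` (process →
entity it produces), `affected_by` (experimental process → condition)
and `quantifies` (value → biopolymer).

Structural guarantees enforced at load time: the `is_a` sub-graph is
acyclic and every concept reaches the root `thing` along `is_a` edges.
Subsumption (`is_subconcept`) is the reflexive-transitive closure of
`is_a`; `relation_holds` checks declared edges exactly, with an opt-in
`inherit` flag that also accepts an edge declared between sub-concepts
of the queried pair. Decisions taken where the design was open:

* `preceded_by` is treated as **non-transitive** — only explicitly
  declared precedence edges hold. Process precedence chains here are
  short and the declared edges are the ones that carry meaning.
* The two alternative RNA-Seq preparations (alignment to a reference vs
  de novo assembly) are both encoded as ordinary `preceded_by` edges of
  the profiling step, with the mutual exclusivity recorded in the
  `CHOICE_GROUPS` annotation rather than a bespoke edge type.
* No OWL/RDF serialization and no description-logic reasoning: the
  graph is small, the needed queries are subsumption and edge lookup,
  and a flat TSV keeps the resource diffable and hand-auditable.

## Connector engine

`run_connector` executes the four blocks serially and records a block
trace; a failing block aborts the run naming the block. The canonical
instances passed between lifting and lowering are plain tagged values
(`SemanticInstance`: value + concept id + provenance identifiers) — the
concept-per-class idea without prescribing a class hierarchy.

Equivalence tables are shipped as TSV resources, one per connector, and
validated at startup: a present reference concept must resolve in the
ontology, a non-unused row without a reference concept must carry a
transformation rule, and no concept may appear in two rows (rows must be
merged). Unused consumed items (e.g. the SAM read name in C3.1) are
legitimate rows with no produced concepts.

Access policies are `manual` (the default; the user moves the output
onward) or `automatic`, which requires a post-output hook fired only
after data output completes; a hook failure is downgraded to a warning
and the outputs are kept, since the data products are already sound. A
no-op hook and a shell-command hook ship; a live R-session control
channel is exposed only as this hook interface.

Composite connectors (`CompositePlan`) validate their wiring — every
slot a child consumes must be an external input or a prior child's
output — before any child runs, then execute children serially. The
aggregate report keeps per-child sections instead of summing counts,
because children count different record granularities (reads vs genes vs
conditions).

## Connector semantics and parameters

**C1 (merge two-color samples).** Row set is the union of gene ids
across input tables, ordered by first appearance, with `NA` for a gene
absent from a condition. Union rather than intersection avoids data loss
ahead of normalization. Duplicate probe ids within one table keep the
first occurrence with a warning. Values are carried bit-exactly.

**C2 (regulation coloring).** Classification operates on log2 ratios
with a single symmetric, user-supplied threshold `t > 0` and closed
boundaries: `x ≥ t` up (red), `x ≤ −t` down (green), otherwise
undefined (yellow). Closed boundaries make the classification total for
any positive `t`. Two-color VALUE columns are conventionally log
ratios; a `linear` scale option classifies on log2 of the stored value,
dropping non-positive cells. Id mapping uses a platform table in either
the two-column dialect (KEGG id doubles as official id) or the
three-column experiment → official → KEGG form; genes without a mapping
are dropped and tallied, never errors. Emission follows matrix row
order for reproducible diffs.

**C3.1 (read annotation).** A read is assigned to the gene on the same
reference sequence whose interval overlaps the read's aligned span by at
least one base; the largest overlap wins and exact ties go to the
lexicographically smallest gene id — a deterministic rule that a
brute-force all-pairs scan can verify independently (the interval-tree
index is an optimization, never the definition). Aligned spans come from
the SAM position plus the reference-consuming CIGAR operations (M, D,
N, =, X). Strand is ignored by default (`stranded` option available)
and each occurrence of a multi-mapped read name counts independently;
each read contributes to at most one gene. Reads with no overlap are
removed and counted, so annotated + removed = mapped reads always.

**C3.2 (library sizes).** The per-condition total is the number of
*annotated reads* (default), which is the quantity that normalizes
library size; counting *distinct genes* is available as an explicit
`distinct-genes` mode since the phrase "total of annotated genes" admits
both readings, but distinct-gene counts would not correct for sequencing
depth.

**C3.3 (count matrix).** Genes hit in any condition, sorted
lexicographically; cells are occurrence counts with 0 fill. Column sums
equal the C3.2 read totals by construction, and the identity is asserted
after every run.

**C4 (normalization).** `relative(g, c) = count(g, c) / total(c)`; a
zero or missing total is rejected naming the condition. When totals are
the column sums, every output column sums to 1 to within 1e-12 (the
only arithmetic is one division per cell).

**C5 (virtual two-color).** Within-category pairing emits unordered
pairs `(s_i, s_j)` with `i < j` — dye-swap duplicates are excluded, so a
category of n samples yields C(n, 2) columns. Cross-category pairing is
ordered with the first-named category as numerator, n_a × n_b columns;
only one orientation is emitted (the reverse is its negation). Ratios
are log2 quotients because the downstream self-self statistic operates
on log ratios; a `linear` option emits raw quotients. Missing or
non-positive intensities (background-subtracted one-color data can go
negative) yield `NA` cells rather than errors.

**C6 (result filtering).** Keep gene `g` iff
`statistic(g) ≥ t_stat` and `p(g) ≤ t_p`, input order preserved.
Boundaries are non-strict by default with a strict mode available;
output is always a subset of the input genes and shrinks monotonically
as `t_stat` rises or `t_p` falls.

## Synthetic data

The generators emulate the *shapes* of the three study designs — 
multi-condition two-color ratio samples, per-condition SAM alignments
over a small prokaryote-like genome with GFF genes, one-color intensity
samples in two biological categories, and an HTself-style result table
— at desk scale, writing real files in the exact dialects the readers
parse. Defaults, chosen once as realistic for these designs:

* two-color: 20 genes × 3 conditions, log2 ratios ~ Normal(0, 1), 10 %
  of cells omitted to exercise `NA` merging, values printed to 4
  decimals and recorded in the truth sidecar as printed;
* RNA-Seq: 8 non-overlapping 300 bp genes separated and flanked by
  100 bp intergenic gaps on one reference sequence; planted counts ~
  Poisson(6) per gene and condition (2 conditions); 50 bp fully
  contained reads at uniform positions; 5 intergenic reads per condition
  placed wholly between genes (the geometry is validated so both genes
  and gaps can hold a read);
* one-color: 20 genes, categories `normal` (2 samples) and `tumor` (3),
  intensities 2^Normal(8, 1.5) — strictly positive, log-normal;
* HTself: planted significant genes (1 in 5 by default) receive a
  statistic above and a p-value below the generator's thresholds
  (0.8, 0.05); every other gene fails at least one criterion, so
  filtering at those thresholds recovers the planted set exactly;
* platform mapping: 80 % of genes mappable by default, two-column
  dialect.

All randomness flows from one seed through a single `numpy` generator
stream per bundle, and regeneration with the same seed is byte-identical
— file content, not just values. What the generators do **not**
emulate: sequencing error and quality strings (placeholders only),
dye bias, spatial artifacts, overlapping or nested gene models,
spliced alignments in the planted reads (though the SAM reader handles
N operations), and any real biological covariance between conditions.
Passing tests therefore demonstrate the correctness of the
transformations and their conservation laws on well-formed inputs, not
robustness to pathological real-world files beyond the error cases the
readers check explicitly.

## Numerical and I/O conventions

All coordinates are 1-based inclusive end to end (SAM and GFF native);
no conversion happens anywhere. Numbers are written in their shortest
round-trippable decimal form (`repr` of the float) with `NA` for
missing, so matrix write → read is an identity on ids and values
including NaN positions. Readers accept Unix or Windows line endings and
emit Unix. The SOFT parser consumes only the sample-table block between
its begin/end sentinels, requiring an ID (or ID_REF) and a VALUE column
and ignoring any extra columns — only the id/value pairs feed the
connectors. Unparsable SOFT values become missing with a logged
warning rather than aborting a whole sample.

## Problem sizes

The test suite and the acceptance script run everything at the
generator defaults: 20-seed sweeps for conservation and recovery
checks, 100 randomized instances (≤ 220 reads × ≤ 25 gene intervals,
duplicated intervals forcing exact ties) for the assignment oracle,
exhaustive category-size grids 1..6 for the pair-count laws, and a
6-point threshold grid over 60 genes for the coloring partition. The
full suite completes in a few seconds; the acceptance script in well
under a minute.

## Known limitations

* The ontology is the transcription of the documented concept set, not
  a parse of a full OWL artifact; SAGE-related concepts are excluded
  because no bundled connector consumes them, and there is no term
  accession cross-referencing into GO/SO.
* The SAM subset reads mandatory columns 1–6 of text SAM only (no
  BAM/CRAM, no mate resolution); the GFF reader extracts flat gene
  features, not feature hierarchies.
* Bidirectional integration scenarios are not built in; they are
  expressible as two composed unidirectional runs.
* The wrapped analysis tools themselves (normalization, the HTself
  statistic, pathway and functional-annotation services) are out of
  scope: the connectors build their inputs and consume their outputs.
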