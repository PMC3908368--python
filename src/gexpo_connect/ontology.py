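"""Reference gene-expression ontology (GEXPO) as a queryable in-memory graph.

The ontology covers the gene-expression process (transcription through
protein maturation), the measurement processes (one-/two-color microarray
and RNA-Seq), and the hierarchy of expression values (fluorescence
intensity-based and sequence counting-based). It is shipped as a
plain-text edge list bundled with the package and loaded into a typed
graph supporting subsumption (``is_a``) queries and exact / inherited
relation lookups. Connectors use it to tag values semantically and to
validate their equivalence tables at startup.

Relations other than ``produced_by``, ``affected_by`` and ``quantifies``
follow the OBO Relation Ontology reading (``is_a``, ``part_of``,
``has_part``, ``preceded_by``, ``has_participant``, ``derives_from``).
``preceded_by`` is treated as *non-transitive* here: only the explicitly
declared precedence edges hold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "RELATIONS",
    "ROOT_CONCEPT",
    "CHOICE_GROUPS",
    "Concept",
    "RelationEdge",
    "OntologyGraph",
    "OntologyError",
    "OntologyLoadError",
    "UnknownConceptError",
    "UnknownRelationError",
    "normalize_label",
    "parse_edge_list",
    "load_reference_ontology",
]

#: Closed relation vocabulary.
RELATIONS = frozenset(
    {
        "is_a",
        "part_of",
        "has_part",
        "preceded_by",
        "produced_by",
        "has_participant",
        "affected_by",
        "quantifies",
        "derives_from",
    }
)

#: All concepts are (transitive) sub-concepts of the root.
ROOT_CONCEPT = "thing"

#: Mutually exclusive process alternatives, keyed by the dependent process.
#: The bundled graph encodes both branches as ordinary ``preceded_by``
#: edges; this annotation records that exactly one of them applies per run.
CHOICE_GROUPS: dict[str, tuple[str, ...]] = {
    "rna_seq_gene_expression_profiling": (
        "alignment_of_cdna_read_to_a_reference_genome",
        "de_novo_assembly_of_cdna_reads",
    ),
}

# Concepts reused from external ontologies; everything else is introduced.
_GENE_ONTOLOGY_CONCEPTS = frozenset(
    {
        "biological_process",
        "gene_expression",
        "transcription",
        "rna_processing",
        "translation",
        "protein_maturation",
        "reverse_transcription",
        "hybridization",
    }
)
_SEQUENCE_ONTOLOGY_CONCEPTS = frozenset(
    {
        "dna",
        "gene",
        "primary_transcript",
        "mature_transcript",
        "ncrna",
        "mrna",
        "protein",
        "cdna",
        "probe",
    }
)

# Labels whose capitalization/punctuation is not recoverable from the id.
_SPECIAL_LABELS = {
    "dna": "DNA",
    "cdna": "cDNA",
    "ncrna": "ncRNA",
    "mrna": "mRNA",
    "rna_processing": "RNA processing",
    "rna_extraction": "RNA extraction",
    "dna_microarray_experimental_process": "DNA microarray experimental process",
    "rna_seq_experimental_process": "RNA-Seq experimental process",
    "rna_seq_gene_expression_profiling": "RNA-Seq gene expression profiling",
    "cdna_read": "cDNA read",
    "cdna_labeling": "cDNA labeling",
    "cdna_library_with_adaptors_preparation": "cDNA library with adaptors preparation",
    "cdna_next_generation_sequencing": "cDNA next-generation sequencing",
    "alignment_of_cdna_read_to_a_reference_genome": "alignment of cDNA read to a reference genome",
    "de_novo_assembly_of_cdna_reads": "de novo assembly of cDNA reads",
    "fluorescence_intensity_based_value": "fluorescence intensity-based value",
    "absolute_intensity_based_value": "absolute intensity-based value",
    "ratio_intensity_based_value": "ratio intensity-based value",
    "sequence_counting_based_value": "sequence counting-based value",
    "cdna_reads_counting_based_value": "cDNA reads counting-based value",
    "absolute_cdna_reads_counting_based_value": "absolute cDNA reads counting-based value",
    "relative_cdna_reads_counting_based_value": "relative cDNA reads counting-based value",
    "one_color_microarray_experimental_process": "one-color microarray experimental process",
    "two_color_microarray_experimental_process": "two-color microarray experimental process",
    "hybridization_based_gene_expression_measurement": "hybridization-based gene expression measurement",
    "sequencing_based_gene_expression_measurement": "sequencing-based gene expression measurement",
}


class OntologyError(Exception):
    """Base class for ontology failures."""


class OntologyLoadError(OntologyError):
    """The bundled or supplied edge list is malformed."""


class UnknownConceptError(OntologyError, KeyError):
    """A concept id does not resolve in the graph."""

    def __init__(self, concept_id: str):
        super().__init__(f"unknown concept: {concept_id!r}")
        self.concept_id = concept_id


class UnknownRelationError(OntologyError, ValueError):
    """A relation token is outside the closed vocabulary."""

    def __init__(self, relation: str):
        super().__init__(
            f"unknown relation: {relation!r}; expected one of {sorted(RELATIONS)}"
        )
        self.relation = relation


def normalize_label(label: str) -> str:
    """Normalize a human-readable concept label into a stable id token.

    Lowercases and maps spaces and hyphens to underscores, e.g.
    ``"ratio intensity-based value"`` -> ``"ratio_intensity_based_value"``.
    """
    return label.strip().lower().replace("-", " ").replace(" ", "_").replace("__", "_")


def _concept_source(concept_id: str) -> str:
    if concept_id in _GENE_ONTOLOGY_CONCEPTS:
        return "gene_ontology"
    if concept_id in _SEQUENCE_ONTOLOGY_CONCEPTS:
        return "sequence_ontology"
    return "introduced"


def _concept_label(concept_id: str) -> str:
    return _SPECIAL_LABELS.get(concept_id, concept_id.replace("_", " "))


@dataclass(frozen=True)
class Concept:
    """A node of the reference ontology."""

    id: str
    label: str
    source: str = "introduced"  # introduced | gene_ontology | sequence_ontology

    def __post_init__(self) -> None:
        if normalize_label(self.label) != self.id:
            raise OntologyError(
                f"concept id {self.id!r} is not the normalization of label {self.label!r}"
            )
        if self.source not in {"introduced", "gene_ontology", "sequence_ontology"}:
            raise OntologyError(f"bad concept source: {self.source!r}")


@dataclass(frozen=True)
class RelationEdge:
    """A typed, directed relationship between two concepts."""

    subject: str
    relation: str
    object: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise UnknownRelationError(self.relation)


class OntologyGraph:
    """Concepts plus typed relation edges, with subsumption queries.

    The ``is_a`` sub-graph must be acyclic and every concept must reach the
    root ``thing`` along ``is_a`` edges; both are enforced at construction.
    """

    def __init__(self, edges: Iterable[RelationEdge]):
        self.edges: tuple[RelationEdge, ...] = tuple(edges)
        ids = {ROOT_CONCEPT}
        for e in self.edges:
            ids.add(e.subject)
            ids.add(e.object)
        self.concepts: dict[str, Concept] = {
            cid: Concept(cid, _concept_label(cid), _concept_source(cid))
            for cid in sorted(ids)
        }
        # child -> parent along is_a
        self._isa = nx.DiGraph()
        self._isa.add_nodes_from(self.concepts)
        self._isa.add_edges_from(
            (e.subject, e.object) for e in self.edges if e.relation == "is_a"
        )
        if not nx.is_directed_acyclic_graph(self._isa):
            cycle = nx.find_cycle(self._isa)
            raise OntologyError(f"is_a sub-graph contains a cycle: {cycle}")
        for cid in self.concepts:
            if cid != ROOT_CONCEPT and not nx.has_path(self._isa, cid, ROOT_CONCEPT):
                raise OntologyError(
                    f"concept {cid!r} is not connected to {ROOT_CONCEPT!r} via is_a"
                )
        self._edge_set = {(e.subject, e.relation, e.object) for e in self.edges}

    # -- queries ---------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def _require(self, concept_id: str) -> None:
        if concept_id not in self.concepts:
            raise UnknownConceptError(concept_id)

    def superconcepts(self, concept_id: str) -> set[str]:
        """All concepts reachable from ``concept_id`` via is_a, plus itself."""
        self._require(concept_id)
        return {concept_id} | nx.descendants(self._isa, concept_id)

    def subconcepts(self, concept_id: str) -> set[str]:
        """All concepts from which ``concept_id`` is reachable, plus itself."""
        self._require(concept_id)
        return {concept_id} | nx.ancestors(self._isa, concept_id)

    def is_subconcept(self, a: str, b: str) -> bool:
        """True iff ``a`` equals ``b`` or reaches it via one or more is_a edges."""
        self._require(a)
        self._require(b)
        return b in self.superconcepts(a)

    def relation_holds(
        self, a: str, relation: str, b: str, *, inherit: bool = False
    ) -> bool:
        """True iff the edge ``(a, relation, b)`` is declared.

        With ``inherit=True`` and no exact edge, the edge may instead be
        declared between any sub-concepts of ``a`` and ``b`` (inheritance
        along is_a).
        """
        if relation not in RELATIONS:
            raise UnknownRelationError(relation)
        self._require(a)
        self._require(b)
        if (a, relation, b) in self._edge_set:
            return True
        if not inherit:
            return False
        subs_a = self.subconcepts(a)
        subs_b = self.subconcepts(b)
        return any(
            s in subs_a and o in subs_b
            for (s, r, o) in self._edge_set
            if r == relation
        )

    # -- serialization ---------------------------------------------------

    def export(self, stream: io.TextIOBase) -> None:
        """Write the graph as a tab-separated edge list (the bundled format)."""
        for e in self.edges:
            stream.write(f"{e.subject}\t{e.relation}\t{e.object}\n")


def parse_edge_list(
    lines: Iterable[str], origin: str = "<edge list>"
) -> OntologyGraph:
    """Parse `subject<TAB>relation<TAB>object` lines into an :class:`OntologyGraph`.

    Blank lines and ``#`` comments are skipped. A malformed line raises
    :class:`OntologyLoadError` naming the offending line.
    """

    def gen() -> Iterator[RelationEdge]:
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                raise OntologyLoadError(
                    f"{origin}, line {lineno}: expected "
                    f"'subject<TAB>relation<TAB>object', got {line!r}"
                )
            subject, relation, obj = (p.strip() for p in parts)
            if relation not in RELATIONS:
                raise OntologyLoadError(
                    f"{origin}, line {lineno}: unknown relation {relation!r}"
                )
            yield RelationEdge(subject, relation, obj)

    try:
        return OntologyGraph(gen())
    except OntologyError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise OntologyLoadError(f"{origin}: {exc}") from exc


def load_reference_ontology() -> OntologyGraph:
    """Load the bundled reference ontology edge list."""
    resource = resources.files("gexpo_connect").joinpath("data/gexpo_edges.tsv")
    with resource.open("r", encoding="utf-8") as fh:
        return parse_edge_list(fh, origin="gexpo_edges.tsv")
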