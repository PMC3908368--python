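"""Connector execution engine: equivalence tables, grounding and the
four-functional-block run model.

A connector turns data consumed from one tool's concrete syntax into data
another tool can use, passing through a semantically tagged canonical form.
Its work is structured into four blocks executed strictly in order:

1. ``data_input_processing`` - parse the input syntax into raw records;
2. ``lifting`` - interpret the records as canonical semantic instances,
   applying any semantic transformation rules;
3. ``lowering`` - render canonical instances into output-ready records;
4. ``data_output_processing`` - write the output syntax and, under an
   automatic access policy, hand control to the target tool afterwards.

Each connector carries a declarative *equivalence table* mapping its
consumed and produced concepts to reference-ontology concepts, with
transformation-rule tokens for the rows where the mapping is not a plain
identity. Tables are validated against the loaded ontology at startup.
Composite connectors are ordered plans of simple connectors whose wiring
is validated before anything runs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Callable, Iterable, Sequence

from .formats import ValidationError
from .ontology import OntologyGraph

__all__ = [
    "BLOCK_ORDER",
    "SemanticInstance",
    "EquivalenceRow",
    "EquivalenceTable",
    "AccessPolicy",
    "ConnectorSpec",
    "CompositePlan",
    "RunReport",
    "BlockExecutionError",
    "load_equivalence_table",
    "validate_equivalence_table",
    "run_connector",
    "run_composite",
    "noop_hook",
    "shell_command_hook",
]

#: The four functional blocks, in their fixed execution order.
BLOCK_ORDER = (
    "data_input_processing",
    "lifting",
    "lowering",
    "data_output_processing",
)


@dataclass(frozen=True)
class SemanticInstance:
    """A canonical value tagged with its reference-ontology concept.

    ``provenance`` carries the identifiers (gene, condition, sample pair,
    ...) the value is about, so lowering can regroup instances without
    re-reading the inputs.
    """

    value: Any
    concept: str
    provenance: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Equivalence tables


@dataclass(frozen=True)
class EquivalenceRow:
    """One row linking consumed concepts, a reference concept and produced
    concepts.

    Partial mappings: an ``unused`` row (case 1: the consumed item does not
    contribute to any output) has no produced concepts and no rule; a
    non-unused row lacking a reference concept must carry a ``rule_id``
    (cases 2-3: the output is derived from several inputs, or vice versa).
    """

    consumed: tuple[str, ...] = ()
    reference: str | None = None
    produced: tuple[str, ...] = ()
    rule_id: str | None = None
    unused: bool = False

    def __post_init__(self) -> None:
        if self.unused and (self.produced or self.rule_id):
            raise ValidationError(
                "an unused equivalence row must have no produced concepts and no rule"
            )
        if not self.unused and self.reference is None and self.rule_id is None:
            raise ValidationError(
                "a non-unused equivalence row without a reference concept "
                "requires a transformation rule (partial-mapping cases 2-3)"
            )


@dataclass(frozen=True)
class EquivalenceTable:
    connector_id: str
    rows: tuple[EquivalenceRow, ...]


def _split_cell(cell: str) -> tuple[str, ...]:
    cell = cell.strip()
    if cell in {"", "-"}:
        return ()
    return tuple(tok.strip() for tok in cell.split(";") if tok.strip())


def load_equivalence_table(connector_id: str) -> EquivalenceTable:
    """Load the bundled equivalence table for a connector (e.g. ``"C3.1"``)."""
    resource = resources.files("gexpo_connect").joinpath(
        f"data/equivalence/{connector_id}.tsv"
    )
    rows: list[EquivalenceRow] = []
    with resource.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 5:
                raise ValidationError(
                    f"{connector_id}.tsv line {lineno}: expected 5 columns, got {len(cells)}"
                )
            consumed, reference, produced, rule_id, unused = (c.strip() for c in cells)
            rows.append(
                EquivalenceRow(
                    consumed=_split_cell(consumed),
                    reference=None if reference in {"", "-"} else reference,
                    produced=_split_cell(produced),
                    rule_id=None if rule_id in {"", "-"} else rule_id,
                    unused=unused == "1",
                )
            )
    return EquivalenceTable(connector_id=connector_id, rows=tuple(rows))


def validate_equivalence_table(
    table: EquivalenceTable, graph: OntologyGraph
) -> list[str]:
    """Check a table against the reference ontology.

    Returns a list of violation messages (empty iff the table is sound):
    every present reference concept must resolve in the graph, every
    non-unused row without a reference concept must carry a rule, and no
    consumed or produced concept may appear in more than one row.
    """
    violations: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(table.rows):
        if row.reference is not None and row.reference not in graph:
            violations.append(
                f"{table.connector_id} row {i}: reference concept "
                f"{row.reference!r} does not resolve in the ontology"
            )
        if not row.unused and row.reference is None and row.rule_id is None:
            violations.append(
                f"{table.connector_id} row {i}: no reference concept and no "
                "transformation rule (partial-mapping cases 2-3 require a rule)"
            )
        for concept in (*row.consumed, *row.produced):
            if concept in seen and seen[concept] != i:
                violations.append(
                    f"{table.connector_id}: concept {concept!r} appears in "
                    f"rows {seen[concept]} and {i}; rows must be merged"
                )
            else:
                seen[concept] = i
    return violations


# ---------------------------------------------------------------------------
# Access policies and reports


def noop_hook(outputs: dict[str, Any], report: "RunReport") -> None:
    """Reference post-output hook that transfers no control anywhere."""


def shell_command_hook(command: Sequence[str]) -> Callable[[dict[str, Any], "RunReport"], None]:
    """Build a hook that launches a shell command after data output.

    Stands in for a live tool-control channel: the command receives the
    output file paths as extra arguments.
    """

    def hook(outputs: dict[str, Any], report: "RunReport") -> None:
        import subprocess

        paths = [str(v) for v in outputs.values() if isinstance(v, (str,)) or hasattr(v, "__fspath__")]
        subprocess.run([*command, *paths], check=True)

    return hook


@dataclass
class AccessPolicy:
    """How and where the integration target is reached.

    ``manual`` mode means the user moves the output onward themselves;
    ``automatic`` mode fires ``post_output_hook`` once data output has
    completed successfully.
    """

    transfer_mode: str = "manual"  # manual | automatic
    location: str | None = None
    post_output_hook: Callable[[dict[str, Any], "RunReport"], None] | None = None

    def __post_init__(self) -> None:
        if self.transfer_mode not in {"manual", "automatic"}:
            raise ValidationError(f"bad transfer mode: {self.transfer_mode!r}")
        if self.transfer_mode == "automatic" and self.post_output_hook is None:
            raise ValidationError("automatic transfer mode requires a post-output hook")


@dataclass
class RunReport:
    """Record-level accounting for one connector run."""

    connector_id: str = ""
    records_in: int = 0
    records_out: int = 0
    dropped: Counter = field(default_factory=Counter)
    warnings: list[str] = field(default_factory=list)
    block_trace: list[str] = field(default_factory=list)
    children: list[tuple[str, "RunReport"]] = field(default_factory=list)

    @property
    def records_dropped(self) -> int:
        return sum(self.dropped.values())

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] += n

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def summary_lines(self) -> list[str]:
        lines = [
            f"connector {self.connector_id}: in={self.records_in} "
            f"out={self.records_out} dropped={self.records_dropped}"
        ]
        for reason, n in sorted(self.dropped.items()):
            lines.append(f"  dropped[{reason}] = {n}")
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        for child_id, child in self.children:
            lines.extend("  " + l for l in child.summary_lines())
        return lines


class BlockExecutionError(RuntimeError):
    """A functional block failed; the run was aborted."""

    def __init__(self, connector_id: str, block: str, cause: BaseException):
        super().__init__(f"connector {connector_id}: block {block!r} failed: {cause}")
        self.connector_id = connector_id
        self.block = block
        self.cause = cause


# ---------------------------------------------------------------------------
# Connector specs and execution

BlockFn = Callable[[Any, dict[str, Any], dict[str, Any], RunReport], Any]


@dataclass
class ConnectorSpec:
    """A simple connector: four ordered blocks plus its design artifacts.

    ``consumes`` / ``produces`` name the logical input and output slots
    used for composite wiring. ``check_report`` may assert per-connector
    conservation identities after the run (return a list of violation
    messages, empty when sound).
    """

    id: str
    blocks: dict[str, BlockFn]
    equivalence_table: EquivalenceTable | None = None
    access_policy: AccessPolicy = field(default_factory=AccessPolicy)
    consumes: tuple[str, ...] = ()
    produces: tuple[str, ...] = ()
    check_report: Callable[[RunReport], list[str]] | None = None

    def __post_init__(self) -> None:
        missing = [b for b in BLOCK_ORDER if b not in self.blocks]
        if missing:
            raise ValidationError(
                f"connector {self.id}: missing functional blocks {missing}"
            )


def run_connector(
    spec: ConnectorSpec,
    inputs: dict[str, Any],
    config: dict[str, Any] | None = None,
) -> tuple[dict[str, Any], RunReport]:
    """Execute a simple connector's four blocks strictly in order.

    The payload produced by each block feeds the next; the data-output
    block returns the ``outputs`` mapping (slot name -> file path or
    in-memory object). Under an automatic access policy the post-output
    hook fires only after output succeeds; a hook failure is downgraded to
    a warning and the outputs are retained.
    """
    config = dict(config or {})
    report = RunReport(connector_id=spec.id)
    payload: Any = None
    for block_name in BLOCK_ORDER:
        try:
            payload = spec.blocks[block_name](payload, inputs, config, report)
        except Exception as exc:
            raise BlockExecutionError(spec.id, block_name, exc) from exc
        report.block_trace.append(block_name)
    outputs: dict[str, Any] = payload if isinstance(payload, dict) else {"out": payload}
    if spec.check_report is not None:
        problems = spec.check_report(report)
        if problems:
            raise BlockExecutionError(
                spec.id,
                "data_output_processing",
                RuntimeError("; ".join(problems)),
            )
    policy = spec.access_policy
    if policy.transfer_mode == "automatic":
        try:
            policy.post_output_hook(outputs, report)  # type: ignore[misc]
        except Exception as exc:
            report.warn(f"post-output hook failed (outputs retained): {exc}")
    return outputs, report


@dataclass
class CompositePlan:
    """An ordered composition of simple connectors with explicit wiring.

    ``wiring`` maps, per child, its input slot names to either external
    input slots or ``"<child id>.<slot>"`` references to a prior child's
    output.
    """

    id: str
    children: tuple[ConnectorSpec, ...]
    wiring: dict[str, dict[str, str]] = field(default_factory=dict)
    access_policy: AccessPolicy = field(default_factory=AccessPolicy)

    def validate(self, external_inputs: Iterable[str]) -> None:
        available = set(external_inputs)
        for child in self.children:
            child_wiring = self.wiring.get(child.id, {})
            for slot in child.consumes:
                source = child_wiring.get(slot, slot)
                if source not in available:
                    raise ValidationError(
                        f"composite {self.id}: child {child.id} consumes "
                        f"{source!r} which no prior child produces and no "
                        "external input supplies"
                    )
            for slot in child.produces:
                available.add(f"{child.id}.{slot}")


def run_composite(
    plan: CompositePlan,
    inputs: dict[str, Any],
    config: dict[str, Any] | None = None,
) -> tuple[dict[str, Any], RunReport]:
    """Run a composite connector: children serially, in plan order.

    The aggregate report keeps a per-child section rather than summing
    counts across children, since children may count different record
    granularities (reads vs genes). The composite's own post-output hook,
    if automatic, fires after the last child completes.
    """
    plan.validate(inputs)
    report = RunReport(connector_id=plan.id)
    pool: dict[str, Any] = dict(inputs)
    outputs: dict[str, Any] = {}
    for child in plan.children:
        child_wiring = plan.wiring.get(child.id, {})
        child_inputs = {
            slot: pool[child_wiring.get(slot, slot)] for slot in child.consumes
        }
        child_outputs, child_report = run_connector(child, child_inputs, config)
        report.children.append((child.id, child_report))
        for slot, value in child_outputs.items():
            pool[f"{child.id}.{slot}"] = value
            outputs[f"{child.id}.{slot}"] = value
    if plan.access_policy.transfer_mode == "automatic":
        try:
            plan.access_policy.post_output_hook(outputs, report)  # type: ignore[misc]
        except Exception as exc:
            report.warn(f"post-output hook failed (outputs retained): {exc}")
    return outputs, report
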