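"""Tool annotations: typed, possibly disjunctive I/O slots plus operations.

The JSON layout mirrors the functional part of a registry entry::

    {"functions": [
        {"id": "comet",
         "label": "Comet",
         "operation": ["Peptide_database_search"],
         "inputs":  [{"Type": ["Mass_spectrum"], "Format": ["mzML", "mzXML"]}],
         "outputs": [{"Type": ["Peptide_identification"], "Format": ["pepXML"]}],
         "implementation": {"shell_command": "cat {in1} > {out1}"}}
    ]}

Slot mappings are keyed by data-dimension id; the value is a non-empty list
of term references interpreted as a disjunction within that dimension.
Term references may be full IRIs, IRI fragments, or labels, resolved in the
context of their dimension.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple, Union

from ..errors import AnnotationSchemaError, UnresolvedTermError
from .taxonomy import DomainTaxonomy


@dataclass(frozen=True)
class DataSignature:
    """Per-dimension acceptable term sets for one data instance or slot.

    Values are disjunctions within a dimension.  A signature is *concrete*
    when every dimension carries exactly one term (an instance); slot
    requirements are typically disjunctive.
    """

    terms: Tuple[Tuple[str, FrozenSet[str]], ...]

    @staticmethod
    def of(mapping: Mapping[str, object]) -> "DataSignature":
        items = []
        for dim in sorted(mapping):
            value = mapping[dim]
            ids = (value,) if isinstance(value, str) else tuple(value)  # type: ignore[arg-type]
            if not ids:
                raise AnnotationSchemaError(
                    f"empty term set for dimension {dim!r}"
                )
            items.append((dim, frozenset(ids)))
        return DataSignature(terms=tuple(items))

    @property
    def dimensions(self) -> Tuple[str, ...]:
        return tuple(dim for dim, _ in self.terms)

    def terms_in(self, dimension: str) -> FrozenSet[str]:
        for dim, ids in self.terms:
            if dim == dimension:
                return ids
        raise KeyError(dimension)

    @property
    def is_concrete(self) -> bool:
        return all(len(ids) == 1 for _, ids in self.terms)

    def concrete_term(self, dimension: str) -> str:
        ids = self.terms_in(dimension)
        if len(ids) != 1:
            raise ValueError(f"dimension {dimension!r} is disjunctive: {ids}")
        return next(iter(ids))

    def covers(self, taxonomy: DomainTaxonomy) -> bool:
        return set(self.dimensions) == set(taxonomy.data_dimensions)

    def as_dict(self) -> Dict[str, List[str]]:
        return {dim: sorted(ids) for dim, ids in self.terms}

    def __str__(self) -> str:
        parts = []
        for dim, ids in self.terms:
            parts.append(f"{dim}={'|'.join(sorted(ids))}")
        return ", ".join(parts)


@dataclass(frozen=True)
class ToolAnnotation:
    """A tool with its operations and ordered, typed I/O slots."""

    id: str
    label: str
    operations: FrozenSet[str]
    inputs: Tuple[DataSignature, ...]
    outputs: Tuple[DataSignature, ...]
    command: Optional[str] = None


@dataclass(frozen=True)
class ToolMode:
    """One concrete resolution of a tool's disjunctive output annotation.

    Inputs stay disjunctive; each output slot carries exactly one term per
    dimension.  Modes of a tool are indexed in lexicographic term-id order,
    so mode ids are deterministic.
    """

    tool: ToolAnnotation
    index: int
    outputs: Tuple[DataSignature, ...] = field(default_factory=tuple)

    @property
    def id(self) -> str:
        return f"{self.tool.id}@{self.index}"

    @property
    def sort_key(self) -> Tuple[str, int]:
        return (self.tool.id, self.index)

    def __str__(self) -> str:
        outs = "; ".join(str(o) for o in self.outputs)
        return f"{self.id}[{outs}]"


def expand_modes(tool: ToolAnnotation) -> List[ToolMode]:
    """Cross-product of the output-slot disjunctions, deterministically
    ordered (lexicographic by the chosen term-id tuples)."""
    per_slot: List[List[DataSignature]] = []
    for sig in tool.outputs:
        choices = [sorted(ids) for _, ids in sig.terms]
        dims = sig.dimensions
        slot_options = [
            DataSignature.of(dict(zip(dims, combo)))
            for combo in itertools.product(*choices)
        ]
        per_slot.append(slot_options)
    modes = []
    for index, combo in enumerate(itertools.product(*per_slot)):
        modes.append(ToolMode(tool=tool, index=index, outputs=tuple(combo)))
    return modes


def _resolve_signature(
    raw: Mapping[str, object],
    taxonomy: DomainTaxonomy,
    context: str,
) -> DataSignature:
    if not isinstance(raw, dict):
        raise AnnotationSchemaError(f"{context}: slot must be an object")
    resolved: Dict[str, List[str]] = {}
    for dim_ref, value in raw.items():
        if dim_ref not in taxonomy.data_dimensions:
            raise AnnotationSchemaError(
                f"{context}: unknown data dimension {dim_ref!r} "
                f"(declared: {taxonomy.data_dimensions})"
            )
        refs = (value,) if isinstance(value, str) else value
        if not isinstance(refs, (list, tuple)) or not refs:
            raise AnnotationSchemaError(
                f"{context}: dimension {dim_ref!r} needs a non-empty term list"
            )
        try:
            resolved[dim_ref] = [
                taxonomy.resolve(r, dimension=dim_ref) for r in refs
            ]
        except UnresolvedTermError as exc:
            raise UnresolvedTermError(f"{context}: {exc}") from exc
    return DataSignature.of(resolved)


def parse_tool_annotations(
    json_document: Union[str, Path, Mapping],
    taxonomy: DomainTaxonomy,
) -> List[ToolAnnotation]:
    """Parse and resolve a tool-annotation document against the taxonomy.

    Accepts a file path, a JSON string, or an already-parsed mapping.
    Unknown terms raise :class:`UnresolvedTermError` naming the tool and
    slot; structural problems raise :class:`AnnotationSchemaError`.
    """
    doc = _as_document(json_document)
    if not isinstance(doc, dict) or "functions" not in doc:
        raise AnnotationSchemaError("document must contain a 'functions' list")
    entries = doc["functions"]
    if not isinstance(entries, list):
        raise AnnotationSchemaError("'functions' must be a list")
    tools: List[ToolAnnotation] = []
    seen_ids = set()
    for pos, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise AnnotationSchemaError(f"functions[{pos}] must be an object")
        tool_id = entry.get("id")
        if not tool_id or not isinstance(tool_id, str):
            raise AnnotationSchemaError(
                f"functions[{pos}]: missing required field 'id'"
            )
        if tool_id in seen_ids:
            raise AnnotationSchemaError(f"duplicate tool id {tool_id!r}")
        seen_ids.add(tool_id)
        ops_raw = entry.get("operation")
        if not isinstance(ops_raw, list) or not ops_raw:
            raise AnnotationSchemaError(
                f"tool {tool_id!r}: 'operation' must be a non-empty list"
            )
        try:
            operations = frozenset(
                taxonomy.resolve(r, dimension=taxonomy.operation_dimension)
                for r in ops_raw
            )
        except UnresolvedTermError as exc:
            raise UnresolvedTermError(f"tool {tool_id!r}: {exc}") from exc
        for key in ("inputs", "outputs"):
            if key not in entry or not isinstance(entry[key], list):
                raise AnnotationSchemaError(
                    f"tool {tool_id!r}: missing required field {key!r}"
                )
        inputs = tuple(
            _resolve_signature(
                raw, taxonomy, f"tool {tool_id!r} input slot {k + 1}"
            )
            for k, raw in enumerate(entry["inputs"])
        )
        outputs = tuple(
            _resolve_signature(
                raw, taxonomy, f"tool {tool_id!r} output slot {k + 1}"
            )
            for k, raw in enumerate(entry["outputs"])
        )
        impl = entry.get("implementation") or {}
        command = impl.get("shell_command") if isinstance(impl, dict) else None
        tools.append(
            ToolAnnotation(
                id=tool_id,
                label=entry.get("label", tool_id),
                operations=operations,
                inputs=inputs,
                outputs=outputs,
                command=command,
            )
        )
    return tools


def tools_to_json(tools: List[ToolAnnotation]) -> Dict:
    """Inverse of :func:`parse_tool_annotations` (ids stay fully qualified)."""
    functions = []
    for tool in tools:
        entry: Dict[str, object] = {
            "id": tool.id,
            "label": tool.label,
            "operation": sorted(tool.operations),
            "inputs": [sig.as_dict() for sig in tool.inputs],
            "outputs": [sig.as_dict() for sig in tool.outputs],
        }
        if tool.command is not None:
            entry["implementation"] = {"shell_command": tool.command}
        functions.append(entry)
    return {"functions": functions}


def _as_document(source: Union[str, Path, Mapping]) -> Mapping:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    try:
        exists = path.exists()
    except OSError:
        exists = False
    text = path.read_text() if exists else str(source)
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise AnnotationSchemaError(f"invalid JSON: {exc}") from exc
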