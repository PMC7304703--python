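"""Bundle of taxonomy plus annotated tools, with derived mode tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .annotations import ToolAnnotation, ToolMode, expand_modes
from .taxonomy import DomainTaxonomy


@dataclass
class Domain:
    """Validated semantic domain model used by the synthesis engine."""

    taxonomy: DomainTaxonomy
    tools: Sequence[ToolAnnotation]
    _modes: List[ToolMode] = field(init=False, repr=False)
    _mode_by_id: Dict[str, ToolMode] = field(init=False, repr=False)
    _tool_by_id: Dict[str, ToolAnnotation] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tools = sorted(self.tools, key=lambda t: t.id)
        self._modes = [m for t in self.tools for m in expand_modes(t)]
        self._modes.sort(key=lambda m: m.sort_key)
        self._mode_by_id = {m.id: m for m in self._modes}
        self._tool_by_id = {t.id: t for t in self.tools}

    @property
    def modes(self) -> List[ToolMode]:
        """All tool modes in canonical (tool id, mode index) order."""
        return list(self._modes)

    def mode(self, mode_id: str) -> ToolMode:
        return self._mode_by_id[mode_id]

    def tool(self, tool_id: str) -> ToolAnnotation:
        return self._tool_by_id[tool_id]

    def has_tool(self, tool_id: str) -> bool:
        return tool_id in self._tool_by_id

    def mode_performs(self, mode: ToolMode, operation_term: str) -> bool:
        """Descendant-closed operation test: the mode's tool is annotated
        with ``operation_term`` or any of its descendants."""
        closure = self.taxonomy.descendant_closure(operation_term)
        return bool(mode.tool.operations & closure)

    def mode_can_consume(self, mode: ToolMode, data_term: str) -> bool:
        """True iff some input slot of the mode's tool accepts an instance
        of ``data_term`` (or one of its descendants) in that dimension."""
        dim = self.taxonomy.terms[data_term].dimension
        wanted = self.taxonomy.descendant_closure(data_term)
        for sig in mode.tool.inputs:
            if dim not in sig.dimensions:
                continue
            acceptable = self.taxonomy.closure_of(sig.terms_in(dim))
            if wanted & acceptable:
                return True
        return False
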