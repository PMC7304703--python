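"""Domain-model well-formedness report."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .annotations import ToolAnnotation, expand_modes
from .taxonomy import DomainTaxonomy

ISSUE_KINDS = (
    "unresolved-term",
    "coverage",
    "empty-dimension",
    "cycle",
    "unreachable-tool",
    "dimension-mismatch",
)


@dataclass(frozen=True)
class ValidationIssue:
    kind: str
    subject: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.subject}: {self.detail}"


@dataclass
class ValidationReport:
    issues: List[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, kind: str, subject: str, detail: str) -> None:
        assert kind in ISSUE_KINDS, kind
        self.issues.append(ValidationIssue(kind, subject, detail))

    def __str__(self) -> str:
        if self.ok:
            return "domain model OK"
        return "\n".join(str(i) for i in self.issues)


def _find_cycle(taxonomy: DomainTaxonomy) -> Optional[str]:
    """Return a term that participates in a parent cycle, if any."""
    state = {}  # 0 visiting, 1 done

    for start in taxonomy.terms:
        if start in state:
            continue
        stack = [(start, iter(taxonomy.terms[start].parents))]
        state[start] = 0
        while stack:
            node, parents = stack[-1]
            advanced = False
            for parent in parents:
                if state.get(parent) == 0:
                    return parent
                if parent not in state:
                    state[parent] = 0
                    stack.append(
                        (parent, iter(taxonomy.terms[parent].parents))
                    )
                    advanced = True
                    break
            if not advanced:
                state[node] = 1
                stack.pop()
    return None


def validate_domain(
    taxonomy: DomainTaxonomy, tools: List[ToolAnnotation]
) -> ValidationReport:
    """Check the taxonomy and annotations; problems become report entries,
    never exceptions.  An empty report means the model is well-formed."""
    report = ValidationReport()

    cyclic = _find_cycle(taxonomy)
    if cyclic is not None:
        report.add("cycle", cyclic, "parent links form a cycle")

    for dim in taxonomy.dimensions:
        if not taxonomy.terms_in(dim):
            report.add("empty-dimension", dim, "dimension has no terms")

    produced = set()
    if cyclic is None:
        for tool in tools:
            for mode in expand_modes(tool):
                for sig in mode.outputs:
                    for dim, ids in sig.terms:
                        produced.update((dim, t) for t in ids)

    for tool in tools:
        for op in sorted(tool.operations):
            if op not in taxonomy.terms:
                report.add("unresolved-term", tool.id, f"operation {op!r}")
            elif taxonomy.terms[op].dimension != taxonomy.operation_dimension:
                report.add(
                    "dimension-mismatch",
                    tool.id,
                    f"operation {op!r} lives in dimension "
                    f"{taxonomy.terms[op].dimension!r}",
                )
        for role, slots in (("input", tool.inputs), ("output", tool.outputs)):
            for pos, sig in enumerate(slots, start=1):
                missing = set(taxonomy.data_dimensions) - set(sig.dimensions)
                for dim in sorted(missing):
                    report.add(
                        "coverage",
                        tool.id,
                        f"{role} slot {pos} omits dimension {dim!r}",
                    )
                for dim, ids in sig.terms:
                    if dim not in taxonomy.data_dimensions:
                        report.add(
                            "dimension-mismatch",
                            tool.id,
                            f"{role} slot {pos} uses unknown dimension {dim!r}",
                        )
                        continue
                    for tid in sorted(ids):
                        if tid not in taxonomy.terms:
                            report.add(
                                "unresolved-term",
                                tool.id,
                                f"{role} slot {pos} term {tid!r}",
                            )
                        elif taxonomy.terms[tid].dimension != dim:
                            report.add(
                                "dimension-mismatch",
                                tool.id,
                                f"{role} slot {pos} term {tid!r} is not in "
                                f"dimension {dim!r}",
                            )
        # a slot no workflow input nor tool output could ever satisfy
        if cyclic is None and not any(
            issue.subject == tool.id for issue in report.issues
        ):
            for pos, sig in enumerate(tool.inputs, start=1):
                for dim, ids in sig.terms:
                    closure = taxonomy.closure_of(ids)
                    if not closure:
                        report.add(
                            "unreachable-tool",
                            tool.id,
                            f"input slot {pos} accepts no term in {dim!r}",
                        )
    return report
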