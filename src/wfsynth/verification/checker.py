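"""Independent semantics checker for solution workflows.

This is the reference oracle: it interprets the data-flow graph directly —
walking steps in execution order, maintaining the cumulative memory of
available instances — and shares none of the encoder's clause machinery.
Only the domain primitives (taxonomy subsumption, tool annotations, the
constraint trace predicates) are common ground.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

from ..domain_model import DataSignature, Domain
from ..solution_export.graph import SolutionWorkflow
from ..specification import WorkflowSpec, constraint_holds

VIOLATION_KINDS = (
    "unbound-input",
    "subsumption-failure",
    "unmet-output",
    "constraint-failure",
)


@dataclass(frozen=True)
class Violation:
    kind: str
    step: Optional[int]
    detail: str

    def __post_init__(self) -> None:
        assert self.kind in VIOLATION_KINDS, self.kind

    def __str__(self) -> str:
        where = f"step {self.step}" if self.step is not None else "workflow"
        return f"[{self.kind}] {where}: {self.detail}"


def signature_satisfies(
    domain: Domain, instance: DataSignature, requirement: DataSignature
) -> bool:
    """Concrete instance vs (possibly disjunctive) requirement: every
    dimension's term must be subsumed by some acceptable term."""
    taxonomy = domain.taxonomy
    return all(
        any(
            taxonomy.subsumes(acceptable, instance.concrete_term(dim))
            for acceptable in requirement.terms_in(dim)
        )
        for dim in taxonomy.data_dimensions
    )


def check_solution(
    solution: SolutionWorkflow, domain: Domain, spec: WorkflowSpec
) -> List[Violation]:
    """Empty list iff the workflow is executable, meets every requested
    output and satisfies every constraint."""
    violations: List[Violation] = []
    memory: Dict[str, DataSignature] = {
        node.id: node.signature for node in solution.workflow_inputs
    }
    for step in solution.steps:
        tool = step.mode.tool
        for slot, node in enumerate(step.inputs, start=1):
            if node.id not in memory:
                violations.append(
                    Violation(
                        "unbound-input",
                        step.index,
                        f"slot {slot} bound to {node.id!r}, which is not "
                        f"available before step {step.index}",
                    )
                )
                continue
            requirement = tool.inputs[slot - 1]
            if not signature_satisfies(domain, memory[node.id], requirement):
                violations.append(
                    Violation(
                        "subsumption-failure",
                        step.index,
                        f"slot {slot} requires {requirement}, got "
                        f"{memory[node.id]} ({node.id})",
                    )
                )
        for node in step.outputs:
            memory[node.id] = node.signature
    for r, requirement in enumerate(spec.outputs):
        if not any(
            signature_satisfies(domain, sig, requirement)
            for sig in memory.values()
        ):
            violations.append(
                Violation(
                    "unmet-output",
                    None,
                    f"requested output {r} ({requirement}) is not matched "
                    f"by any available instance",
                )
            )
    sequence = [step.mode for step in solution.steps]
    for constraint in spec.constraints:
        if not constraint_holds(constraint, sequence, domain):
            violations.append(
                Violation(
                    "constraint-failure",
                    None,
                    f"constraint not satisfied: {constraint.human_text}",
                )
            )
    return violations
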