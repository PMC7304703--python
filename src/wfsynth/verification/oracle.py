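"""Exhaustive workflow enumeration — the engine's completeness oracle.

Depth-first search over all tool-mode sequences up to the length bound,
with an executability test per prefix (greedy-any binding: a slot is
satisfiable iff *some* available instance satisfies it, slots being
independent because memory is cumulative and instances are reusable).
Deliberately simple and independent of the CNF encoder.
"""

from __future__ import annotations

from typing import List, Set, Tuple

from ..domain_model import DataSignature, Domain, ToolMode
from ..errors import OracleSizeError
from ..specification import WorkflowSpec, constraint_holds
from .checker import signature_satisfies

MAX_SEQUENCE_SPACE = 10**6


def _executable(
    domain: Domain, mode: ToolMode, memory: List[DataSignature]
) -> bool:
    return all(
        any(signature_satisfies(domain, sig, slot) for sig in memory)
        for slot in mode.tool.inputs
    )


def _outputs_met(
    domain: Domain, spec: WorkflowSpec, memory: List[DataSignature]
) -> bool:
    return all(
        any(signature_satisfies(domain, sig, req) for sig in memory)
        for req in spec.outputs
    )


def brute_force_enumerate(
    domain: Domain, spec: WorkflowSpec, max_length: int
) -> Set[Tuple[str, ...]]:
    """All satisfying tool-mode id sequences with length between the
    specification's ``min_length`` and ``max_length``."""
    modes = domain.modes
    space = sum(
        len(modes) ** n for n in range(1, max_length + 1)
    )
    if space > MAX_SEQUENCE_SPACE:
        raise OracleSizeError(
            f"mode-sequence space {space} exceeds guard {MAX_SEQUENCE_SPACE}"
        )
    results: Set[Tuple[str, ...]] = set()
    if not modes:
        return results

    def recurse(prefix: List[ToolMode], memory: List[DataSignature]) -> None:
        depth = len(prefix)
        if depth >= spec.min_length:
            if _outputs_met(domain, spec, memory) and all(
                constraint_holds(c, prefix, domain)
                for c in spec.constraints
            ):
                results.add(tuple(m.id for m in prefix))
        if depth >= max_length:
            return
        for mode in modes:
            if _executable(domain, mode, memory):
                recurse(prefix + [mode], memory + list(mode.outputs))

    recurse([], list(spec.inputs))
    return results
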