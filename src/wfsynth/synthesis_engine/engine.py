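"""Model enumeration and decoding; the top-level synthesis loop."""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence

from ..domain_model import Domain
from ..errors import EngineError
from ..solution_export.graph import SolutionWorkflow, build_workflow
from ..specification import WorkflowSpec
from .encode import CNFProblem, encode
from .sat import SATSolver

logger = logging.getLogger(__name__)


class SolverModel:
    """A total truth assignment over the registered variables."""

    def __init__(self, values: Sequence[bool]) -> None:
        self._values = list(values)  # index 0 unused

    def __getitem__(self, var: int) -> bool:
        return self._values[var]


def enumerate_models(cnf: CNFProblem, limit: int) -> List[SolverModel]:
    """Up to ``limit`` models, one per distinct step-wise tool-mode
    sequence, in canonical (lexicographic) order.

    After each model a blocking clause forbidding its tool-mode projection
    is added, so no two returned models share a sequence.  Canonical order
    falls out of the solver's static decision order: tool variables are
    decided first, in step-major canonical mode order, trying True first.
    """
    if limit < 0:
        raise EngineError("limit must be >= 0")
    solver = SATSolver(num_vars=len(cnf.registry))
    for clause in cnf.clauses:
        solver.add_clause(clause)
    order = cnf.tool_vars
    models: List[SolverModel] = []
    while len(models) < limit:
        assignment = solver.solve(decision_order=order)
        if assignment is None:
            break
        models.append(SolverModel(assignment))
        blocking = []
        for step in cnf.step_modes:
            for _, var in step:
                if assignment[var]:
                    blocking.append(-var)
        solver.add_clause(blocking)
    return models


def decode_model(
    model: SolverModel,
    cnf: CNFProblem,
    domain: Domain,
    spec: WorkflowSpec,
) -> SolutionWorkflow:
    """Interpret a satisfying assignment as a data-flow graph."""
    sequence = []
    for i, step in enumerate(cnf.step_modes, start=1):
        chosen = [mode for mode, var in step if model[var]]
        if len(chosen) != 1:
            raise EngineError(
                f"model selects {len(chosen)} modes at step {i}"
            )
        sequence.append(chosen[0])

    registry = cnf.registry
    bindings: List[List[str]] = []
    for i, mode in enumerate(sequence, start=1):
        row = []
        for s in range(1, len(mode.tool.inputs) + 1):
            bound: Optional[str] = None
            for inst in cnf.instances:
                tag = ("bind", i, s, inst)
                if tag in registry and model[registry.var(tag)]:
                    bound = inst
                    break
            if bound is None:
                raise EngineError(f"no binding for step {i} slot {s}")
            row.append(bound)
        bindings.append(row)

    # prune phantom instances (slots beyond the chosen mode's output count)
    real = {f"in{k}" for k in range(1, len(spec.inputs) + 1)}
    for i, mode in enumerate(sequence, start=1):
        real.update(f"s{i}.o{o}" for o in range(1, len(mode.outputs) + 1))

    output_ids = []
    for r in range(len(spec.outputs)):
        matched = None
        for inst in cnf.instances:
            tag = ("match", r, inst)
            if inst in real and tag in registry and model[registry.var(tag)]:
                matched = inst
                break
        if matched is None:
            raise EngineError(f"requested output {r} unmatched in model")
        output_ids.append(matched)

    return build_workflow(
        mode_sequence=sequence,
        input_signatures=spec.inputs,
        bindings=bindings,
        output_ids=output_ids,
    )


def synthesize(domain: Domain, spec: WorkflowSpec) -> List[SolutionWorkflow]:
    """All bounded-length workflows satisfying the specification.

    Iterates the length bound from ``min_length`` to ``max_length``,
    enumerating canonical models per bound until ``max_solutions`` have
    been collected.  The result is ordered by length, then canonically; no
    two solutions share a tool-mode sequence.  An empty domain or an
    unsatisfiable specification yields an empty list.
    """
    if not domain.modes:
        return []
    solutions: List[SolutionWorkflow] = []
    for length in range(spec.min_length, spec.max_length + 1):
        remaining = spec.max_solutions - len(solutions)
        if remaining <= 0:
            break
        cnf = encode(domain, spec, length)
        models = enumerate_models(cnf, remaining)
        logger.info(
            "length %d: %d variables, %d clauses, %d solution(s)",
            length,
            len(cnf.registry),
            len(cnf.clauses),
            len(models),
        )
        for model in models:
            solutions.append(decode_model(model, cnf, domain, spec))
    return solutions
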