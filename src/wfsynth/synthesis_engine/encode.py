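"""Propositional encoding of bounded workflow composition.

For a length bound ``n`` the CNF's models correspond (up to binding
symmetry) to executable length-``n`` workflows:

* exactly one tool mode per step;
* every input slot of a step's tool binds exactly one *available* memory
  instance (a workflow input or the output of a strictly earlier step)
  whose term in every dimension is subsumed by an acceptable slot term —
  memory is cumulative and instances may be consumed repeatedly;
* each produced instance's per-dimension attributes are forced by (and
  support) the chosen mode;
* every requested output of the specification is matched, by subsumption,
  by some memory instance at the end;
* all compiled constraint clauses hold.

Variables are registered with semantic tags so that models can be decoded
and the CNF dumped with a human-readable legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Hashable, List, Optional, Tuple

from ..domain_model import DataSignature, Domain, ToolMode
from ..errors import EncodingError
from ..specification import CompilationContext, WorkflowSpec, compile_constraint


class VariableRegistry:
    """Bidirectional map between semantic tags and DIMACS variables."""

    def __init__(self) -> None:
        self._by_tag: Dict[Hashable, int] = {}
        self._by_var: Dict[int, Hashable] = {}

    def new(self, tag: Hashable) -> int:
        if tag in self._by_tag:
            raise EncodingError(f"duplicate variable tag {tag!r}")
        var = len(self._by_tag) + 1
        self._by_tag[tag] = var
        self._by_var[var] = tag
        return var

    def var(self, tag: Hashable) -> int:
        return self._by_tag[tag]

    def tag(self, var: int) -> Hashable:
        return self._by_var[var]

    def __contains__(self, tag: Hashable) -> bool:
        return tag in self._by_tag

    def __len__(self) -> int:
        return len(self._by_tag)


@dataclass
class CNFProblem:
    """Tagged CNF for one length bound, plus the decode tables."""

    length: int
    registry: VariableRegistry
    clauses: List[List[int]] = field(default_factory=list)
    # decode tables
    step_modes: List[List[Tuple[ToolMode, int]]] = field(default_factory=list)
    instances: List[str] = field(default_factory=list)  # canonical order
    max_slots: int = 0

    def add(self, clause: List[int]) -> None:
        self.clauses.append(clause)

    @property
    def tool_vars(self) -> List[int]:
        return [var for step in self.step_modes for _, var in step]

    def to_dimacs(self) -> str:
        """DIMACS text with a comment-line variable legend."""
        lines = [f"p cnf {len(self.registry)} {len(self.clauses)}"]
        legend = [
            f"c {var} {self.registry.tag(var)}"
            for var in range(1, len(self.registry) + 1)
        ]
        body = [" ".join(map(str, cl)) + " 0" for cl in self.clauses]
        return "\n".join(legend + lines + body) + "\n"


def _compatible_concrete(
    domain: Domain, instance: DataSignature, slot: DataSignature
) -> bool:
    """A concrete instance satisfies a (possibly disjunctive) slot iff in
    every dimension its term is subsumed by some acceptable term."""
    taxonomy = domain.taxonomy
    for dim in taxonomy.data_dimensions:
        term = instance.concrete_term(dim)
        if not any(
            taxonomy.subsumes(acc, term) for acc in slot.terms_in(dim)
        ):
            return False
    return True


def encode(domain: Domain, spec: WorkflowSpec, length: int) -> CNFProblem:
    if length < 1:
        raise EncodingError(f"length bound must be >= 1, got {length}")
    modes = domain.modes
    if not modes:
        raise EncodingError("domain has no tool modes")
    taxonomy = domain.taxonomy
    registry = VariableRegistry()
    cnf = CNFProblem(length=length, registry=registry)

    # 1. tool-mode choice variables, canonical order (decision priority)
    for i in range(1, length + 1):
        row = [(mode, registry.new(("tool", i, mode.id))) for mode in modes]
        cnf.step_modes.append(row)
    for i in range(1, length + 1):
        row_vars = [var for _, var in cnf.step_modes[i - 1]]
        cnf.add(list(row_vars))  # at least one
        for a in range(len(row_vars)):
            for b in range(a + 1, len(row_vars)):
                cnf.add([-row_vars[a], -row_vars[b]])  # at most one

    # 2. instance bookkeeping
    input_ids = [f"in{k}" for k in range(1, len(spec.inputs) + 1)]
    input_sig = dict(zip(input_ids, spec.inputs))
    max_out = max(len(m.outputs) for m in modes)
    cnf.max_slots = max(len(m.tool.inputs) for m in modes)
    produced_ids = {
        (i, o): f"s{i}.o{o}"
        for i in range(1, length + 1)
        for o in range(1, max_out + 1)
    }
    cnf.instances = list(input_ids) + [
        produced_ids[(i, o)]
        for i in range(1, length + 1)
        for o in range(1, max_out + 1)
    ]

    # producible(i, o, dim) -> {term: [mode vars that put it there]}
    producible: Dict[Tuple[int, int, str], Dict[str, List[int]]] = {}
    for i in range(1, length + 1):
        for mode, var in cnf.step_modes[i - 1]:
            for o, sig in enumerate(mode.outputs, start=1):
                for dim in taxonomy.data_dimensions:
                    term = sig.concrete_term(dim)
                    producible.setdefault((i, o, dim), {}).setdefault(
                        term, []
                    ).append(var)

    # 3. attribute variables, forced by and supporting the chosen mode
    attr_var: Dict[Tuple[int, int, str, str], int] = {}
    for (i, o, dim), by_term in sorted(producible.items()):
        for term in sorted(by_term):
            attr_var[(i, o, dim, term)] = registry.new(
                ("attr", produced_ids[(i, o)], dim, term)
            )
    for (i, o, dim), by_term in sorted(producible.items()):
        for term, supporters in sorted(by_term.items()):
            av = attr_var[(i, o, dim, term)]
            cnf.add([-av, *supporters])  # support: attr only if some producer
            for mv in supporters:
                cnf.add([-mv, av])  # forcing: producer implies attr

    # 4. binding variables and constraints
    closure_cache: Dict[FrozenSet[str], FrozenSet[str]] = {}

    def closure(ids: FrozenSet[str]) -> FrozenSet[str]:
        if ids not in closure_cache:
            closure_cache[ids] = taxonomy.closure_of(ids)
        return closure_cache[ids]

    def available(i: int) -> List[str]:
        out = list(input_ids)
        for j in range(1, i):
            for o in range(1, max_out + 1):
                out.append(produced_ids[(j, o)])
        return out

    bind_var: Dict[Tuple[int, int, str], int] = {}
    for i in range(1, length + 1):
        for s in range(1, cnf.max_slots + 1):
            for inst in available(i):
                bind_var[(i, s, inst)] = registry.new(("bind", i, s, inst))

    for i in range(1, length + 1):
        avail = available(i)
        # at most one binding per slot, regardless of the chosen mode
        for s in range(1, cnf.max_slots + 1):
            row = [bind_var[(i, s, inst)] for inst in avail]
            for a in range(len(row)):
                for b in range(a + 1, len(row)):
                    cnf.add([-row[a], -row[b]])
        for mode, mvar in cnf.step_modes[i - 1]:
            slots = mode.tool.inputs
            for s in range(1, cnf.max_slots + 1):
                if s > len(slots):
                    for inst in avail:
                        cnf.add([-mvar, -bind_var[(i, s, inst)]])
                    continue
                slot_sig = slots[s - 1]
                cnf.add(
                    [-mvar] + [bind_var[(i, s, inst)] for inst in avail]
                )  # at least one binding for an active slot
                for inst in avail:
                    bv = bind_var[(i, s, inst)]
                    if inst in input_sig:
                        if not _compatible_concrete(
                            domain, input_sig[inst], slot_sig
                        ):
                            cnf.add([-mvar, -bv])
                        continue
                    j, o = _parse_instance(inst)
                    for dim in taxonomy.data_dimensions:
                        acceptable = closure(slot_sig.terms_in(dim))
                        options = [
                            attr_var[(j, o, dim, t)]
                            for t in sorted(
                                acceptable
                                & set(producible.get((j, o, dim), ()))
                            )
                        ]
                        if not options:
                            cnf.add([-mvar, -bv])
                            break
                        cnf.add([-mvar, -bv, *options])

    # 5. requested outputs matched by some memory instance at the end
    all_insts = cnf.instances
    for r, req in enumerate(spec.outputs):
        mvars = {
            inst: registry.new(("match", r, inst)) for inst in all_insts
        }
        cnf.add(list(mvars.values()))
        for inst, mv in mvars.items():
            if inst in input_sig:
                if not _compatible_concrete(domain, input_sig[inst], req):
                    cnf.add([-mv])
                continue
            j, o = _parse_instance(inst)
            for dim in taxonomy.data_dimensions:
                acceptable = closure(req.terms_in(dim))
                options = [
                    attr_var[(j, o, dim, t)]
                    for t in sorted(
                        acceptable & set(producible.get((j, o, dim), ()))
                    )
                ]
                if not options:
                    cnf.add([-mv])
                    break
                cnf.add([-mv, *options])

    # 6. constraints
    ctx = CompilationContext(domain, length, cnf.step_modes)
    for constraint in spec.constraints:
        for clause in compile_constraint(constraint, ctx):
            cnf.add(clause)
    return cnf


def _parse_instance(inst: str) -> Tuple[int, int]:
    step_part, out_part = inst[1:].split(".o")
    return int(step_part), int(out_part)
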