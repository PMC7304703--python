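"""Workflow specifications and the constraint-template catalog.

A specification names the available workflow inputs, the requested outputs
and a list of template-based constraints, plus the synthesis parameters
(length bounds, number of solutions).  Each constraint template carries two
synchronized semantics:

* a *trace predicate* over tool-mode sequences (the reference meaning, used
  by the independent checker/oracle), and
* a *compiler* producing step-indexed CNF clauses over the per-step
  tool-mode variables, equivalent to the predicate on every decoded
  sequence.

Catalog semantics (``X``, ``Y`` are operation terms, descendant-closed;
``T`` a tool id; ``D`` a data term):

``use_operation(X)``
    some step performs ``X``.
``avoid_operation(X)``
    no step performs ``X``.
``use_tool(T)``
    some step runs tool ``T``.
``last_operation(X)``
    the final step performs ``X``.
``operation_before(X, Y)``
    if ``X`` occurs, some step strictly after its *first* occurrence
    performs ``Y`` (with ``X = Y``: ``X`` occurs at least twice or never).
``use_type(D)``
    some step runs a tool with an input slot that accepts data matching
    ``D`` (non-empty intersection of descendant closures).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import (
    Callable,
    Dict,
    List,
    Mapping,
    Optional,
    Sequence,
    Tuple,
    Union,
)

from .domain_model import DataSignature, Domain, DomainTaxonomy, ToolMode
from .errors import (
    CatalogError,
    SpecificationError,
    TemplateSignatureError,
    UnresolvedTermError,
)

# ---------------------------------------------------------------------------
# data classes


@dataclass(frozen=True)
class Constraint:
    template_id: str
    arguments: Tuple[str, ...]
    human_text: str


@dataclass(frozen=True)
class WorkflowSpec:
    inputs: Tuple[DataSignature, ...]
    outputs: Tuple[DataSignature, ...]
    constraints: Tuple[Constraint, ...] = ()
    min_length: int = 1
    max_length: int = 10
    max_solutions: int = 100

    def __post_init__(self) -> None:
        if not (1 <= self.min_length <= self.max_length):
            raise SpecificationError(
                f"need 1 <= min_length <= max_length, got "
                f"{self.min_length}..{self.max_length}"
            )
        if self.max_solutions < 1:
            raise SpecificationError("max_solutions must be >= 1")
        for sig in self.inputs:
            if not sig.is_concrete:
                raise SpecificationError(
                    f"workflow inputs must be concrete, got {sig}"
                )


class CompilationContext:
    """What a template compiler may see: per-step tool-mode variables."""

    def __init__(
        self,
        domain: Domain,
        length: int,
        step_mode_vars: Sequence[Sequence[Tuple[ToolMode, int]]],
    ) -> None:
        self.domain = domain
        self.length = length
        # step_mode_vars[i-1] lists (mode, variable) in canonical mode order
        self.step_mode_vars = step_mode_vars


Predicate = Callable[[Sequence[ToolMode], Domain, Tuple[str, ...]], bool]
Compiler = Callable[[CompilationContext, Tuple[str, ...]], List[List[int]]]

# parameter kinds: which vocabulary an argument is resolved against
PARAM_OPERATION = "operation"
PARAM_DATA = "data"
PARAM_TOOL = "tool"


@dataclass(frozen=True)
class ConstraintTemplate:
    id: str
    params: Tuple[str, ...]
    pattern: str  # .format()-able with positional argument display names
    holds: Predicate = field(repr=False)
    compile: Compiler = field(repr=False)

    def render(self, display_args: Sequence[str]) -> str:
        return self.pattern.format(*display_args)


# ---------------------------------------------------------------------------
# trace predicates


def _performs(mode: ToolMode, op: str, domain: Domain) -> bool:
    return domain.mode_performs(mode, op)


def _holds_use_operation(seq, domain, args):
    return any(_performs(m, args[0], domain) for m in seq)


def _holds_avoid_operation(seq, domain, args):
    return not any(_performs(m, args[0], domain) for m in seq)


def _holds_use_tool(seq, domain, args):
    return any(m.tool.id == args[0] for m in seq)


def _holds_last_operation(seq, domain, args):
    return bool(seq) and _performs(seq[-1], args[0], domain)


def _holds_operation_before(seq, domain, args):
    x, y = args
    for i, mode in enumerate(seq):
        if _performs(mode, x, domain):
            return any(_performs(m, y, domain) for m in seq[i + 1 :])
    return True


def _holds_use_type(seq, domain, args):
    return any(domain.mode_can_consume(m, args[0]) for m in seq)


# ---------------------------------------------------------------------------
# CNF compilers (clauses over the per-step tool-mode variables)


def _step_vars(ctx: CompilationContext, i: int, pred) -> List[int]:
    return [var for mode, var in ctx.step_mode_vars[i] if pred(mode)]


def _compile_use_operation(ctx: CompilationContext, args) -> List[List[int]]:
    lits = [
        var
        for i in range(ctx.length)
        for var in _step_vars(
            ctx, i, lambda m: _performs(m, args[0], ctx.domain)
        )
    ]
    return [lits]  # empty disjunction == unsatisfiable, intentionally


def _compile_avoid_operation(ctx: CompilationContext, args) -> List[List[int]]:
    return [
        [-var]
        for i in range(ctx.length)
        for var in _step_vars(
            ctx, i, lambda m: _performs(m, args[0], ctx.domain)
        )
    ]


def _compile_use_tool(ctx: CompilationContext, args) -> List[List[int]]:
    lits = [
        var
        for i in range(ctx.length)
        for var in _step_vars(ctx, i, lambda m: m.tool.id == args[0])
    ]
    return [lits]


def _compile_last_operation(ctx: CompilationContext, args) -> List[List[int]]:
    return [
        _step_vars(
            ctx, ctx.length - 1, lambda m: _performs(m, args[0], ctx.domain)
        )
    ]


def _compile_operation_before(ctx: CompilationContext, args) -> List[List[int]]:
    x, y = args
    clauses = []
    for i in range(ctx.length):
        x_here = _step_vars(ctx, i, lambda m: _performs(m, x, ctx.domain))
        earlier_x = [
            var
            for j in range(i)
            for var in _step_vars(
                ctx, j, lambda m: _performs(m, x, ctx.domain)
            )
        ]
        later_y = [
            var
            for j in range(i + 1, ctx.length)
            for var in _step_vars(
                ctx, j, lambda m: _performs(m, y, ctx.domain)
            )
        ]
        for var in x_here:
            clauses.append([-var, *earlier_x, *later_y])
    return clauses


def _compile_use_type(ctx: CompilationContext, args) -> List[List[int]]:
    lits = [
        var
        for i in range(ctx.length)
        for var in _step_vars(
            ctx, i, lambda m: ctx.domain.mode_can_consume(m, args[0])
        )
    ]
    return [lits]


# ---------------------------------------------------------------------------
# catalog

_TEMPLATES: Dict[str, ConstraintTemplate] = {}


def _register(template: ConstraintTemplate) -> None:
    assert template.id not in _TEMPLATES
    _TEMPLATES[template.id] = template


_register(
    ConstraintTemplate(
        id="use_operation",
        params=(PARAM_OPERATION,),
        pattern="Use a tool performing operation {0}.",
        holds=_holds_use_operation,
        compile=_compile_use_operation,
    )
)
_register(
    ConstraintTemplate(
        id="avoid_operation",
        params=(PARAM_OPERATION,),
        pattern="Never use a tool performing operation {0}.",
        holds=_holds_avoid_operation,
        compile=_compile_avoid_operation,
    )
)
_register(
    ConstraintTemplate(
        id="use_tool",
        params=(PARAM_TOOL,),
        pattern="Use tool {0}.",
        holds=_holds_use_tool,
        compile=_compile_use_tool,
    )
)
_register(
    ConstraintTemplate(
        id="last_operation",
        params=(PARAM_OPERATION,),
        pattern="The last step must perform operation {0}.",
        holds=_holds_last_operation,
        compile=_compile_last_operation,
    )
)
_register(
    ConstraintTemplate(
        id="operation_before",
        params=(PARAM_OPERATION, PARAM_OPERATION),
        pattern=(
            "If operation {0} is used, a later step must perform "
            "operation {1}."
        ),
        holds=_holds_operation_before,
        compile=_compile_operation_before,
    )
)
_register(
    ConstraintTemplate(
        id="use_type",
        params=(PARAM_DATA,),
        pattern="Use a tool that accepts data matching {0}.",
        holds=_holds_use_type,
        compile=_compile_use_type,
    )
)


def list_templates() -> Dict[str, ConstraintTemplate]:
    """The fixed constraint-template catalog, keyed by template id."""
    return dict(_TEMPLATES)


def get_template(template_id: str) -> ConstraintTemplate:
    try:
        return _TEMPLATES[template_id]
    except KeyError:
        raise CatalogError(
            f"unknown constraint template {template_id!r}; "
            f"known: {sorted(_TEMPLATES)}"
        ) from None


# ---------------------------------------------------------------------------
# instantiation and rendering


def _display(arg: str, kind: str, taxonomy: DomainTaxonomy) -> str:
    if kind == PARAM_TOOL:
        return f"'{arg}'"
    return f"'{taxonomy.label(arg)}' [{arg}]"


def instantiate_template(
    template_id: str,
    arguments: Sequence[str],
    taxonomy: DomainTaxonomy,
) -> Constraint:
    """Resolve arguments against the template signature and render the
    natural-language form."""
    template = get_template(template_id)
    if len(arguments) != len(template.params):
        raise TemplateSignatureError(
            f"{template_id} expects {len(template.params)} argument(s), "
            f"got {len(arguments)}"
        )
    resolved: List[str] = []
    for arg, kind in zip(arguments, template.params):
        if kind == PARAM_TOOL:
            resolved.append(arg)
            continue
        if kind == PARAM_OPERATION:
            try:
                term = taxonomy.resolve(
                    arg, dimension=taxonomy.operation_dimension
                )
            except UnresolvedTermError:
                # distinguish "wrong dimension" from "unknown term"
                try:
                    taxonomy.resolve(arg)
                except UnresolvedTermError:
                    raise
                raise TemplateSignatureError(
                    f"{template_id}: argument {arg!r} must be an "
                    f"operation term"
                ) from None
        else:  # data term: any data dimension
            candidates = []
            for dim in taxonomy.data_dimensions:
                try:
                    candidates.append(taxonomy.resolve(arg, dimension=dim))
                except UnresolvedTermError:
                    pass
            if len(candidates) != 1:
                raise TemplateSignatureError(
                    f"{template_id}: cannot resolve data term {arg!r} "
                    f"uniquely (candidates: {sorted(set(candidates))})"
                )
            term = candidates[0]
        dim = taxonomy.terms[term].dimension
        if kind == PARAM_OPERATION and dim != taxonomy.operation_dimension:
            raise TemplateSignatureError(
                f"{template_id}: argument {arg!r} must be an operation term"
            )
        if kind == PARAM_DATA and dim == taxonomy.operation_dimension:
            raise TemplateSignatureError(
                f"{template_id}: argument {arg!r} must be a data term"
            )
        resolved.append(term)
    display = [
        _display(a, k, taxonomy) for a, k in zip(resolved, template.params)
    ]
    return Constraint(
        template_id=template_id,
        arguments=tuple(resolved),
        human_text=template.render(display),
    )


_TERM_RE = re.compile(r"'(?:[^']*)' \[([^\]]+)\]")
_TOOL_RE = re.compile(r"'([^']+)'")


def parse_constraint_text(
    text: str, taxonomy: DomainTaxonomy
) -> Constraint:
    """Recover (template, arguments) from a rendered ``human_text``."""
    for template in _TEMPLATES.values():
        regex = re.escape(template.pattern)
        for pos in range(len(template.params)):
            regex = regex.replace(re.escape(f"{{{pos}}}"), r"(.+?)", 1)
        match = re.fullmatch(regex, text)
        if match is None:
            continue
        args = []
        ok = True
        for group, kind in zip(match.groups(), template.params):
            sub = _TERM_RE.fullmatch(group) if kind != PARAM_TOOL else None
            if kind != PARAM_TOOL:
                if sub is None:
                    ok = False
                    break
                args.append(sub.group(1))
            else:
                sub = _TOOL_RE.fullmatch(group)
                if sub is None:
                    ok = False
                    break
                args.append(sub.group(1))
        if ok:
            return instantiate_template(template.id, args, taxonomy)
    raise SpecificationError(f"cannot parse constraint text {text!r}")


def compile_constraint(
    constraint: Constraint, ctx: CompilationContext
) -> List[List[int]]:
    """Clauses equivalent to the template's trace semantics at the context's
    length bound."""
    template = get_template(constraint.template_id)
    return template.compile(ctx, constraint.arguments)


def constraint_holds(
    constraint: Constraint, sequence: Sequence[ToolMode], domain: Domain
) -> bool:
    """Evaluate the reference trace predicate on a decoded mode sequence."""
    template = get_template(constraint.template_id)
    return template.holds(sequence, domain, constraint.arguments)


# ---------------------------------------------------------------------------
# spec parsing

_DEFAULTS = {"min_length": 1, "max_length": 10, "max_solutions": 100}


def _resolve_spec_signature(
    raw: Mapping[str, object],
    taxonomy: DomainTaxonomy,
    path: str,
    concrete: bool,
) -> DataSignature:
    if not isinstance(raw, Mapping):
        raise SpecificationError(f"{path}: must be an object")
    resolved: Dict[str, List[str]] = {}
    for dim in taxonomy.data_dimensions:
        if dim not in raw:
            # omitted dimension == the dimension root (any term)
            resolved[dim] = [taxonomy.root(dim)]
            continue
        value = raw[dim]
        refs = (value,) if isinstance(value, str) else value
        if not isinstance(refs, (list, tuple)) or not refs:
            raise SpecificationError(
                f"{path}.{dim}: needs a term or non-empty term list"
            )
        try:
            resolved[dim] = [taxonomy.resolve(r, dimension=dim) for r in refs]
        except UnresolvedTermError as exc:
            raise SpecificationError(f"{path}.{dim}: {exc}") from exc
    unknown = set(raw) - set(taxonomy.data_dimensions)
    if unknown:
        raise SpecificationError(
            f"{path}: unknown dimension(s) {sorted(unknown)}"
        )
    sig = DataSignature.of(resolved)
    if concrete and not sig.is_concrete:
        raise SpecificationError(f"{path}: workflow inputs must be concrete")
    return sig


def parse_spec(
    document: Union[Mapping, str],
    taxonomy: DomainTaxonomy,
) -> WorkflowSpec:
    """Parse a specification document (mapping or JSON string) and resolve
    every term reference.  Errors carry the JSON path of the offender."""
    import json

    doc = json.loads(document) if isinstance(document, str) else document
    if not isinstance(doc, Mapping):
        raise SpecificationError("specification must be a JSON object")
    inputs = tuple(
        _resolve_spec_signature(raw, taxonomy, f"inputs[{k}]", concrete=True)
        for k, raw in enumerate(doc.get("inputs", []))
    )
    outputs = tuple(
        _resolve_spec_signature(raw, taxonomy, f"outputs[{k}]", concrete=False)
        for k, raw in enumerate(doc.get("outputs", []))
    )
    constraints: List[Constraint] = []
    for k, raw in enumerate(doc.get("constraints", [])):
        path = f"constraints[{k}]"
        if not isinstance(raw, Mapping) or "template" not in raw:
            raise SpecificationError(f"{path}: needs a 'template' key")
        args = raw.get("args", [])
        if not isinstance(args, list):
            raise SpecificationError(f"{path}.args: must be a list")
        try:
            constraints.append(
                instantiate_template(raw["template"], args, taxonomy)
            )
        except (CatalogError, TemplateSignatureError, UnresolvedTermError) as exc:
            raise SpecificationError(f"{path}: {exc}") from exc
    params = {}
    for key, default in _DEFAULTS.items():
        value = doc.get(key, default)
        if not isinstance(value, int):
            raise SpecificationError(f"{key}: must be an integer")
        params[key] = value
    return WorkflowSpec(
        inputs=inputs,
        outputs=outputs,
        constraints=tuple(constraints),
        **params,
    )


def spec_to_json(spec: WorkflowSpec) -> Dict:
    return {
        "inputs": [sig.as_dict() for sig in spec.inputs],
        "outputs": [sig.as_dict() for sig in spec.outputs],
        "constraints": [
            {"template": c.template_id, "args": list(c.arguments)}
            for c in spec.constraints
        ],
        "min_length": spec.min_length,
        "max_length": spec.max_length,
        "max_solutions": spec.max_solutions,
    }
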