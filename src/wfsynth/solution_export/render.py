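"""Text, DOT and shell-script renderings of a solution workflow.

All renderers are pure functions of their inputs: the same solution always
produces byte-identical output.
"""

from __future__ import annotations

import re
from typing import List, Optional

from ..domain_model import Domain, iri_fragment
from ..errors import ExportError
from .graph import SolutionWorkflow, TypeNode


def _sig_text(node: TypeNode) -> str:
    parts = [
        iri_fragment(node.signature.concrete_term(dim))
        for dim, _ in node.signature.terms
    ]
    return "/".join(parts)


def to_text(solution: SolutionWorkflow) -> str:
    """One header pair plus one line per step."""
    lines = [
        "Workflow inputs: "
        + ", ".join(
            f"{n.id} ({_sig_text(n)})" for n in solution.workflow_inputs
        ),
        "Workflow outputs: "
        + ", ".join(
            f"{n.id} ({_sig_text(n)})" for n in solution.workflow_outputs
        ),
    ]
    for step in solution.steps:
        ins = ",".join(n.id for n in step.inputs)
        outs = ",".join(n.id for n in step.outputs)
        lines.append(
            f"{step.index}. {step.mode.tool.label} ({step.mode.id}) "
            f"| in: {ins} | out: {outs}"
        )
    return "\n".join(lines) + "\n"


def to_dot(solution: SolutionWorkflow, flavor: str = "dataflow") -> str:
    """Graphviz DOT text.

    ``dataflow``: ellipse nodes for data instances, box nodes for steps;
    edges into a step carry the 1-based argument position as label.
    ``controlflow``: the steps chained in execution order.
    """
    if flavor not in ("dataflow", "controlflow"):
        raise ExportError(f"unknown DOT flavor {flavor!r}")
    lines = ["digraph workflow {"]
    if flavor == "controlflow":
        for step in solution.steps:
            lines.append(
                f'  "step{step.index}" [shape=box, '
                f'label="{step.index}. {step.mode.tool.label}"];'
            )
        for a, b in zip(solution.steps, solution.steps[1:]):
            lines.append(f'  "step{a.index}" -> "step{b.index}";')
        lines.append("}")
        return "\n".join(lines) + "\n"
    for node in solution.type_nodes:
        lines.append(
            f'  "{node.id}" [shape=ellipse, '
            f'label="{node.id}\\n{_sig_text(node)}"];'
        )
    for step in solution.steps:
        lines.append(
            f'  "step{step.index}" [shape=box, '
            f'label="{step.index}. {step.mode.tool.label}"];'
        )
    for step in solution.steps:
        for slot, node in enumerate(step.inputs, start=1):
            lines.append(
                f'  "{node.id}" -> "step{step.index}" [label="{slot}"];'
            )
        for node in step.outputs:
            lines.append(f'  "step{step.index}" -> "{node.id}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


_PLACEHOLDER_RE = re.compile(r"\{([a-z]+)([0-9]+)\}")
_BRACE_RE = re.compile(r"\{[^}]*\}")


def instance_filename(node: TypeNode, domain: Domain) -> str:
    """Deterministic per-instance filename ``<instance-id>.<format-label>``.

    The format label is taken from the last data dimension (the convention
    of this package's domain models: format-like dimensions come last).
    """
    fmt_dim = domain.taxonomy.data_dimensions[-1]
    term = node.signature.concrete_term(fmt_dim)
    label = re.sub(r"[^A-Za-z0-9]+", "_", iri_fragment(term)).strip("_")
    return f"{node.id}.{label}"


def to_shell(solution: SolutionWorkflow, domain: Domain) -> Optional[str]:
    """POSIX shell script implementing the workflow, or ``None`` when any
    step's tool lacks a command template (never a partial script)."""
    commands = {
        step.index: domain.tool(step.mode.tool.id).command
        for step in solution.steps
    }
    if any(command is None for command in commands.values()):
        return None
    lines = [
        "#!/bin/sh",
        "# auto-generated workflow script",
        "set -e",
        "",
    ]
    for node in solution.workflow_inputs:
        lines.append(
            f"# workflow input {node.id}: expected at "
            f"{instance_filename(node, domain)}"
        )
    for step in solution.steps:
        command = commands[step.index]
        assert command is not None
        substitutions = {}
        for k, node in enumerate(step.inputs, start=1):
            substitutions[f"in{k}"] = instance_filename(node, domain)
        for k, node in enumerate(step.outputs, start=1):
            substitutions[f"out{k}"] = instance_filename(node, domain)

        def replace(match: "re.Match[str]") -> str:
            key = match.group(1) + match.group(2)
            if key not in substitutions:
                raise ExportError(
                    f"tool {step.mode.tool.id!r}: unknown placeholder "
                    f"{{{key}}} in command template"
                )
            return substitutions[key]

        rendered = _PLACEHOLDER_RE.sub(replace, command)
        leftover = _BRACE_RE.search(rendered)
        if leftover:
            raise ExportError(
                f"tool {step.mode.tool.id!r}: unknown placeholder "
                f"{leftover.group(0)} in command template"
            )
        lines.append(f"# step {step.index}: {step.mode.tool.label}")
        lines.append(rendered)
    for node in solution.workflow_outputs:
        lines.append(
            f"# workflow output {node.id}: {instance_filename(node, domain)}"
        )
    return "\n".join(lines) + "\n"


def parse_text(document: str) -> List[str]:
    """Recover the tool-mode id sequence from a :func:`to_text` document."""
    sequence = []
    for line in document.splitlines():
        match = re.match(r"^\d+\. .* \(([^)]+)\) \| in: ", line)
        if match:
            sequence.append(match.group(1))
    return sequence
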