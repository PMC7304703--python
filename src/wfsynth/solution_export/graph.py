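"""Directed data-flow graph representation of one synthesized workflow.

TypeNodes are data instances; ModuleNodes are tool executions.  Binding
edges carry the 1-based argument position of the consuming slot.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

from ..domain_model import DataSignature, ToolMode


class TypeNode:
    """A concrete data instance: a workflow input or a produced output."""

    def __init__(self, node_id: str, signature: DataSignature) -> None:
        if not signature.is_concrete:
            raise ValueError(f"TypeNode {node_id!r} needs a concrete signature")
        self.id = node_id
        self.signature = signature
        self.producer: Optional["ModuleNode"] = None
        self.consumers: List[Tuple["ModuleNode", int]] = []

    @property
    def is_workflow_input(self) -> bool:
        return self.producer is None

    def __repr__(self) -> str:
        return f"TypeNode({self.id}, {self.signature})"


class ModuleNode:
    """One tool execution at a fixed step index (1-based)."""

    def __init__(self, index: int, mode: ToolMode) -> None:
        self.index = index
        self.mode = mode
        self.inputs: List[TypeNode] = []
        self.outputs: List[TypeNode] = []
        self.previous: Optional["ModuleNode"] = None
        self.next: Optional["ModuleNode"] = None

    @property
    def tool_id(self) -> str:
        return self.mode.tool.id

    def __repr__(self) -> str:
        return f"ModuleNode({self.index}, {self.mode.id})"


class SolutionWorkflow:
    """Ordered module nodes plus every data instance they touch."""

    def __init__(
        self,
        steps: Sequence[ModuleNode],
        type_nodes: Sequence[TypeNode],
        workflow_inputs: Sequence[TypeNode],
        workflow_outputs: Sequence[TypeNode],
    ) -> None:
        self.steps = list(steps)
        self.type_nodes = list(type_nodes)
        self.workflow_inputs = list(workflow_inputs)
        self.workflow_outputs = list(workflow_outputs)
        for prev, nxt in zip(self.steps, self.steps[1:]):
            prev.next = nxt
            nxt.previous = prev
        self._check_structure()

    def _check_structure(self) -> None:
        for pos, step in enumerate(self.steps, start=1):
            if step.index != pos:
                raise ValueError(
                    f"step indices must be contiguous from 1, got "
                    f"{step.index} at position {pos}"
                )
            if len(step.inputs) != len(step.mode.tool.inputs):
                raise ValueError(
                    f"step {pos}: {len(step.inputs)} bindings for "
                    f"{len(step.mode.tool.inputs)} slots"
                )
        known = {node.id for node in self.type_nodes}
        for node in [*self.workflow_inputs, *self.workflow_outputs]:
            if node.id not in known:
                raise ValueError(f"dangling workflow I/O node {node.id!r}")

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def mode_ids(self) -> Tuple[str, ...]:
        """The step-wise tool-mode id sequence — the solution's identity."""
        return tuple(step.mode.id for step in self.steps)

    @property
    def sort_key(self) -> Tuple:
        return (self.length, tuple(s.mode.sort_key for s in self.steps))

    def node(self, node_id: str) -> TypeNode:
        for node in self.type_nodes:
            if node.id == node_id:
                return node
        raise KeyError(node_id)

    def __repr__(self) -> str:
        return f"SolutionWorkflow({' -> '.join(self.mode_ids)})"


def build_workflow(
    mode_sequence: Sequence[ToolMode],
    input_signatures: Sequence[DataSignature],
    bindings: Sequence[Sequence[str]],
    output_ids: Sequence[str],
) -> SolutionWorkflow:
    """Assemble a graph from a mode sequence plus per-step binding ids.

    ``bindings[i][s]`` names the instance bound to slot ``s+1`` of step
    ``i+1``; instance ids are ``in<k>`` for workflow inputs and
    ``s<i>.o<k>`` for step outputs.  ``output_ids`` selects the instances
    reported as workflow outputs.
    """
    nodes: Dict[str, TypeNode] = {}
    inputs = []
    for k, sig in enumerate(input_signatures, start=1):
        node = TypeNode(f"in{k}", sig)
        nodes[node.id] = node
        inputs.append(node)
    steps: List[ModuleNode] = []
    for i, mode in enumerate(mode_sequence, start=1):
        step = ModuleNode(i, mode)
        for slot, inst_id in enumerate(bindings[i - 1], start=1):
            node = nodes[inst_id]
            step.inputs.append(node)
            node.consumers.append((step, slot))
        for k, sig in enumerate(mode.outputs, start=1):
            node = TypeNode(f"s{i}.o{k}", sig)
            node.producer = step
            step.outputs.append(node)
            nodes[node.id] = node
        steps.append(step)
    ordered = [*inputs] + [n for s in steps for n in s.outputs]
    outputs = [nodes[oid] for oid in output_ids]
    return SolutionWorkflow(
        steps=steps,
        type_nodes=ordered,
        workflow_inputs=inputs,
        workflow_outputs=outputs,
    )
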