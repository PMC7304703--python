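"""Abstract CWL v1.2 export.

Steps are descriptive ``Operation`` containers carrying the tool's
operation term IRIs in their ``intent`` field; no commands and no container
hints are emitted — turning the document into an executable workflow is
deliberately left to the user.  Workflow inputs are annotated with their
format IRI only (the type dimension is dropped on purpose: the format is
what execution needs).  YAML is emitted with sorted keys and fixed
indentation so the export is byte-stable; step ids are zero-padded to keep
sorted order equal to execution order.
"""

from __future__ import annotations

import re
from typing import Dict

import yaml

from ..domain_model import Domain
from .graph import ModuleNode, SolutionWorkflow, TypeNode


def _sanitize(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9_]+", "_", text).strip("_")


def _step_id(step: ModuleNode) -> str:
    return f"step_{step.index:02d}_{_sanitize(step.mode.tool.id)}"


def _input_id(node: TypeNode) -> str:
    return f"workflow_in_{_sanitize(node.id)}"


def _format_iri(node: TypeNode, domain: Domain) -> str:
    fmt_dim = domain.taxonomy.data_dimensions[-1]
    return node.signature.concrete_term(fmt_dim)


def to_cwl(solution: SolutionWorkflow, domain: Domain) -> str:
    """Serialize the solution as an abstract CWL v1.2 Workflow document."""
    source: Dict[str, str] = {}  # TypeNode id -> CWL reference
    inputs: Dict[str, Dict] = {}
    for node in solution.workflow_inputs:
        cwl_id = _input_id(node)
        source[node.id] = cwl_id
        inputs[cwl_id] = {
            "type": "File",
            "format": _format_iri(node, domain),
        }

    steps: Dict[str, Dict] = {}
    for step in solution.steps:
        step_id = _step_id(step)
        run_inputs: Dict[str, Dict] = {}
        step_in: Dict[str, str] = {}
        for slot, node in enumerate(step.inputs, start=1):
            param = f"in{slot}"
            run_inputs[param] = {"type": "File"}
            step_in[param] = source[node.id]
        run_outputs: Dict[str, Dict] = {}
        out_ids = []
        for k, node in enumerate(step.outputs, start=1):
            param = f"out{k}"
            run_outputs[param] = {
                "type": "File",
                "format": _format_iri(node, domain),
            }
            out_ids.append(param)
            source[node.id] = f"{step_id}/{param}"
        steps[step_id] = {
            "in": step_in,
            "out": out_ids,
            "run": {
                "class": "Operation",
                "doc": step.mode.tool.label,
                "intent": sorted(step.mode.tool.operations),
                "inputs": run_inputs,
                "outputs": run_outputs,
            },
        }

    outputs: Dict[str, Dict] = {}
    for k, node in enumerate(solution.workflow_outputs, start=1):
        outputs[f"workflow_out_{k}"] = {
            "type": "File",
            "format": _format_iri(node, domain),
            "outputSource": source[node.id],
        }

    document = {
        "cwlVersion": "v1.2",
        "class": "Workflow",
        "inputs": inputs,
        "steps": steps,
        "outputs": outputs,
    }
    return yaml.safe_dump(
        document, sort_keys=True, indent=2, default_flow_style=False
    )
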