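"""Structural validators for exported artifacts.

Offline stand-ins for external toolchains: a small DOT grammar checker for
the Graphviz dialect this package emits, and a CWL v1.2 structural
validator covering the abstract-Workflow subset (required fields, class
names, and step-source referential integrity).
"""

from __future__ import annotations

import re
from typing import Dict, List, Set, Tuple

import yaml

_NODE_RE = re.compile(r'^"(?P<id>[^"]+)"\s*(\[(?P<attrs>.*)\])?;$')
_EDGE_RE = re.compile(
    r'^"(?P<src>[^"]+)"\s*->\s*"(?P<dst>[^"]+)"\s*(\[(?P<attrs>.*)\])?;$'
)
_ATTR_RE = re.compile(r'(\w+)=("(?:[^"\\]|\\.)*"|\w+)')


def parse_dot(
    text: str,
) -> Tuple[Set[str], List[Tuple[str, str, Dict[str, str]]]]:
    """Parse a digraph document; returns (node ids, edges with attrs).

    Raises ``ValueError`` on any statement outside the supported grammar —
    this is the "does it parse" oracle for the DOT exporter.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines or not re.fullmatch(r"digraph \w+ \{", lines[0]):
        raise ValueError("expected 'digraph <name> {' header")
    if lines[-1] != "}":
        raise ValueError("expected closing '}'")
    nodes: Set[str] = set()
    edges: List[Tuple[str, str, Dict[str, str]]] = []
    for line in lines[1:-1]:
        edge = _EDGE_RE.match(line)
        if edge:
            attrs = _parse_attrs(edge.group("attrs"))
            edges.append((edge.group("src"), edge.group("dst"), attrs))
            continue
        node = _NODE_RE.match(line)
        if node:
            nodes.add(node.group("id"))
            _parse_attrs(node.group("attrs"))
            continue
        raise ValueError(f"unparseable DOT statement: {line!r}")
    for src, dst, _ in edges:
        for endpoint in (src, dst):
            if endpoint not in nodes:
                raise ValueError(f"edge endpoint {endpoint!r} undeclared")
    return nodes, edges


def _parse_attrs(attrs: str) -> Dict[str, str]:
    if not attrs:
        return {}
    out = {}
    for key, value in _ATTR_RE.findall(attrs):
        out[key] = value.strip('"')
    return out


def validate_cwl(document: str) -> List[str]:
    """Problems found in an abstract CWL v1.2 Workflow document; empty list
    means the document is accepted."""
    problems: List[str] = []
    try:
        doc = yaml.safe_load(document)
    except yaml.YAMLError as exc:
        return [f"not valid YAML: {exc}"]
    if not isinstance(doc, dict):
        return ["document root must be a mapping"]
    if doc.get("cwlVersion") != "v1.2":
        problems.append("cwlVersion must be 'v1.2'")
    if doc.get("class") != "Workflow":
        problems.append("class must be 'Workflow'")
    for key in ("inputs", "steps", "outputs"):
        if not isinstance(doc.get(key), dict):
            problems.append(f"'{key}' must be a mapping")
    if problems:
        return problems

    valid_sources = set(doc["inputs"])
    for step_id, step in doc["steps"].items():
        if not isinstance(step, dict):
            problems.append(f"step {step_id!r} must be a mapping")
            continue
        out = step.get("out")
        if not isinstance(out, list) or not all(
            isinstance(o, str) for o in out
        ):
            problems.append(f"step {step_id!r}: 'out' must be a string list")
            continue
        valid_sources.update(f"{step_id}/{o}" for o in out)
        run = step.get("run")
        if not isinstance(run, dict) or run.get("class") != "Operation":
            problems.append(f"step {step_id!r}: 'run' must be an Operation")
        else:
            intent = run.get("intent")
            if not isinstance(intent, list) or not intent:
                problems.append(
                    f"step {step_id!r}: 'intent' must be a non-empty list"
                )
    for step_id, step in doc["steps"].items():
        if not isinstance(step, dict):
            continue
        inputs = step.get("in", {})
        if not isinstance(inputs, dict):
            problems.append(f"step {step_id!r}: 'in' must be a mapping")
            continue
        for param, src in inputs.items():
            if src not in valid_sources:
                problems.append(
                    f"step {step_id!r}: input {param!r} references unknown "
                    f"source {src!r}"
                )
    for out_id, out in doc["outputs"].items():
        if not isinstance(out, dict) or "outputSource" not in out:
            problems.append(f"output {out_id!r}: missing 'outputSource'")
        elif out["outputSource"] not in valid_sources:
            problems.append(
                f"output {out_id!r}: unknown source {out['outputSource']!r}"
            )
    return problems
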