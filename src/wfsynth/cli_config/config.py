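"""Run configuration: one self-contained JSON file.

Documented keys::

    ontology_path           path to the OWL ontology            (required)
    tool_annotations_path   path to the tool-annotation JSON    (required)
    dimension_roots         root class IRIs, operation first    (required)
    inputs / outputs / constraints / min_length / max_length /
    max_solutions           the workflow specification (or put them in a
                            separate file referenced by "spec_path")
    output_dir              where solution files are written (default "out")
    exports                 {"text": bool, "dot": bool, "shell": bool,
                             "cwl": bool}; text and dot default on
    log_level               python logging level name (default "INFO")

Term resolution needs the loaded taxonomy, so the specification is kept as
a raw document here and resolved by the runner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Union

from ..errors import ConfigurationError

_SPEC_KEYS = (
    "inputs",
    "outputs",
    "constraints",
    "min_length",
    "max_length",
    "max_solutions",
)
_EXPORT_DEFAULTS = {"text": True, "dot": True, "shell": False, "cwl": False}


@dataclass
class RunConfig:
    ontology_path: Path
    tool_annotations_path: Path
    dimension_roots: List[str]
    spec_doc: Dict
    output_dir: Path = Path("out")
    exports: Dict[str, bool] = field(
        default_factory=lambda: dict(_EXPORT_DEFAULTS)
    )
    log_level: str = "INFO"

    @property
    def operation_root(self) -> str:
        return self.dimension_roots[0]

    @property
    def data_dimension_roots(self) -> List[str]:
        return self.dimension_roots[1:]


def load_config(source: Union[str, Path, Mapping]) -> RunConfig:
    """Load and sanity-check a configuration; referenced files must exist."""
    if isinstance(source, Mapping):
        doc = dict(source)
        base = Path(".")
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"config is not valid JSON: {exc}")
        base = path.parent
    if not isinstance(doc, dict):
        raise ConfigurationError("config must be a JSON object")

    def require(key: str):
        if key not in doc:
            raise ConfigurationError(f"missing required config key {key!r}")
        return doc[key]

    ontology = base / str(require("ontology_path"))
    tools = base / str(require("tool_annotations_path"))
    for key, p in (("ontology_path", ontology), ("tool_annotations_path", tools)):
        if not p.exists():
            raise ConfigurationError(f"{key}: file not found: {p}")
    roots = require("dimension_roots")
    if (
        not isinstance(roots, list)
        or len(roots) < 2
        or not all(isinstance(r, str) for r in roots)
    ):
        raise ConfigurationError(
            "dimension_roots: need a list of IRIs, operation root first, "
            "then at least one data dimension root"
        )

    if "spec_path" in doc:
        spec_file = base / str(doc["spec_path"])
        if not spec_file.exists():
            raise ConfigurationError(f"spec_path: file not found: {spec_file}")
        try:
            spec_doc = json.loads(spec_file.read_text())
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"spec_path: not valid JSON: {exc}")
    else:
        spec_doc = {k: doc[k] for k in _SPEC_KEYS if k in doc}
    if "inputs" not in spec_doc or "outputs" not in spec_doc:
        raise ConfigurationError(
            "the specification needs 'inputs' and 'outputs'"
        )

    exports = dict(_EXPORT_DEFAULTS)
    raw_exports = doc.get("exports", {})
    if not isinstance(raw_exports, dict):
        raise ConfigurationError("exports: must be an object of booleans")
    for key, value in raw_exports.items():
        if key not in _EXPORT_DEFAULTS or not isinstance(value, bool):
            raise ConfigurationError(f"exports.{key}: unknown key or non-bool")
        exports[key] = value

    return RunConfig(
        ontology_path=ontology,
        tool_annotations_path=tools,
        dimension_roots=list(roots),
        spec_doc=spec_doc,
        output_dir=base / str(doc.get("output_dir", "out")),
        exports=exports,
        log_level=str(doc.get("log_level", "INFO")),
    )
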