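"""Execute a full synthesis run from a configuration."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import List, Tuple

from ..domain_model import (
    Domain,
    load_taxonomy,
    parse_tool_annotations,
    validate_domain,
)
from ..solution_export import to_cwl, to_dot, to_shell, to_text
from ..solution_export.graph import SolutionWorkflow
from ..specification import parse_spec
from ..synthesis_engine import synthesize
from ..verification import check_solution
from .config import RunConfig

logger = logging.getLogger("wfsynth")

EXIT_OK = 0
EXIT_ERROR = 1
EXIT_NO_SOLUTIONS = 2


def load_domain(config: RunConfig) -> Domain:
    taxonomy = load_taxonomy(config.ontology_path, config.dimension_roots)
    tools = parse_tool_annotations(config.tool_annotations_path, taxonomy)
    for dim in taxonomy.dimensions:
        logger.info(
            "dimension %s: %d terms", dim, len(taxonomy.terms_in(dim))
        )
    domain = Domain(taxonomy=taxonomy, tools=tools)
    logger.info(
        "domain: %d tools, %d modes", len(domain.tools), len(domain.modes)
    )
    return domain


def run(config: RunConfig) -> Tuple[int, List[SolutionWorkflow]]:
    """Synthesize, cross-check, and write one file set per solution.

    Returns the exit status (0 when at least one solution was found, 2 when
    none) plus the solutions; errors propagate to the caller (the CLI maps
    them to exit status 1).
    """
    logging.basicConfig(level=config.log_level)
    domain = load_domain(config)
    report = validate_domain(domain.taxonomy, list(domain.tools))
    if not report.ok:
        for issue in report.issues:
            logger.warning("domain issue: %s", issue)
    spec = parse_spec(config.spec_doc, domain.taxonomy)
    solutions = synthesize(domain, spec)
    for solution in solutions:  # defense in depth: re-check every solution
        violations = check_solution(solution, domain, spec)
        if violations:
            raise AssertionError(
                f"synthesized workflow failed verification: "
                f"{[str(v) for v in violations]}"
            )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = []
    for k, solution in enumerate(solutions, start=1):
        files = {}
        if config.exports.get("text", True):
            path = out_dir / f"solution_{k}.txt"
            path.write_text(to_text(solution))
            files["text"] = path.name
        if config.exports.get("dot", True):
            path = out_dir / f"solution_{k}.dot"
            path.write_text(to_dot(solution, flavor="dataflow"))
            files["dot"] = path.name
        if config.exports.get("shell", False):
            script = to_shell(solution, domain)
            if script is not None:
                path = out_dir / f"solution_{k}.sh"
                path.write_text(script)
                files["shell"] = path.name
        if config.exports.get("cwl", False):
            path = out_dir / f"solution_{k}.cwl"
            path.write_text(to_cwl(solution, domain))
            files["cwl"] = path.name
        summary.append(
            {
                "index": k,
                "length": solution.length,
                "tools": list(solution.mode_ids),
                "files": files,
            }
        )
    (out_dir / "solutions.json").write_text(
        json.dumps({"solutions": summary}, indent=2, sort_keys=True) + "\n"
    )
    logger.info("%d solution(s) written to %s", len(solutions), out_dir)
    return (EXIT_OK if solutions else EXIT_NO_SOLUTIONS), solutions
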