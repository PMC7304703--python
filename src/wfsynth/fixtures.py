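"""Packaged proteomics example domain (a six-tool fragment).

The fixture mirrors a published proteomics tool-annotation fragment: a
three-dimension vocabulary (operations, data types, data formats) and six
annotated tools (Comet, msconvert, Peptide Prophet, rt4, SSRCalc,
xml2tsv).  It is used by the test suite and handy for demos::

    from wfsynth.fixtures import proteomics_domain
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .domain_model import Domain, load_taxonomy, parse_tool_annotations

PROTEOMICS_ROOTS = [
    "http://example.org/proteomics/operation#Operation",
    "http://example.org/proteomics/data#Type",
    "http://example.org/proteomics/format#Format",
]


def proteomics_path(name: str) -> Path:
    """Path of a packaged proteomics data file (e.g. ``ontology.owl``)."""
    return Path(
        resources.files("wfsynth").joinpath(f"data/proteomics/{name}")  # type: ignore[arg-type]
    )


def proteomics_domain() -> Domain:
    taxonomy = load_taxonomy(
        proteomics_path("ontology.owl"), PROTEOMICS_ROOTS
    )
    tools = parse_tool_annotations(proteomics_path("tools.json"), taxonomy)
    return Domain(taxonomy=taxonomy, tools=tools)
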