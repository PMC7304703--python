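"""OWL reading and writing for the subclass fragment the engine needs.

The ontology is treated as a controlled vocabulary: only named classes,
``rdfs:subClassOf`` axioms between named classes, and ``rdfs:label``
annotations are read; every other axiom is ignored.  Two concrete syntaxes
are supported, RDF/XML and a pragmatic Turtle subset (prefixed names,
IRIREFs, plain string literals, ``;``/``,`` lists), which covers the files
this package itself writes plus typical hand-authored vocabularies.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Set, Tuple, Union

from ..errors import ConfigurationError, DisjointnessError, OntologyFormatError
from .taxonomy import DomainTaxonomy, TaxonomyTerm, iri_fragment

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"

_SubclassGraph = Tuple[Set[str], Dict[str, str], Dict[str, Set[str]]]


def _parse_rdfxml(text: str) -> _SubclassGraph:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise OntologyFormatError(f"not well-formed RDF/XML: {exc}") from exc
    classes: Set[str] = set()
    labels: Dict[str, str] = {}
    parents: Dict[str, Set[str]] = {}
    class_tag = f"{{{OWL_NS}}}Class"
    descr_tag = f"{{{RDF_NS}}}Description"
    type_tag = f"{{{RDF_NS}}}type"
    sub_tag = f"{{{RDFS_NS}}}subClassOf"
    label_tag = f"{{{RDFS_NS}}}label"
    about_attr = f"{{{RDF_NS}}}about"
    id_attr = f"{{{RDF_NS}}}ID"
    resource_attr = f"{{{RDF_NS}}}resource"

    for el in root.iter():
        if el.tag == class_tag:
            is_class = True
        elif el.tag == descr_tag:
            is_class = any(
                child.tag == type_tag
                and child.get(resource_attr) == f"{OWL_NS}Class"
                for child in el
            )
        else:
            continue
        iri = el.get(about_attr) or el.get(id_attr)
        if iri is None:  # anonymous class expression — ignored
            continue
        if not is_class:
            continue
        classes.add(iri)
        for child in el:
            if child.tag == sub_tag:
                res = child.get(resource_attr)
                if res:  # bnode superclasses (restrictions) are ignored
                    parents.setdefault(iri, set()).add(res)
            elif child.tag == label_tag and child.text:
                labels.setdefault(iri, child.text.strip())
    return classes, labels, parents


def _tokenize_turtle(text: str) -> List[str]:
    tokens: List[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch in " \t\r\n":
            i += 1
        elif ch == "#":
            while i < n and text[i] != "\n":
                i += 1
        elif ch == "<":
            j = text.find(">", i)
            if j < 0:
                raise OntologyFormatError("unterminated IRIREF in Turtle input")
            tokens.append(text[i : j + 1])
            i = j + 1
        elif ch == '"':
            j = i + 1
            while j < n and text[j] != '"':
                j += 2 if text[j] == "\\" else 1
            if j >= n:
                raise OntologyFormatError("unterminated string in Turtle input")
            tokens.append(text[i : j + 1])
            i = j + 1
        elif ch in ".;,":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and text[j] not in ' \t\r\n<>".;,#':
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def _parse_turtle(text: str) -> _SubclassGraph:
    tokens = _tokenize_turtle(text)
    prefixes: Dict[str, str] = {}

    def expand(tok: str) -> str:
        if tok.startswith("<") and tok.endswith(">"):
            return tok[1:-1]
        if tok == "a":
            return f"{RDF_NS}type"
        if ":" in tok:
            pfx, local = tok.split(":", 1)
            if pfx in prefixes:
                return prefixes[pfx] + local
        raise OntologyFormatError(f"cannot expand Turtle token {tok!r}")

    classes: Set[str] = set()
    labels: Dict[str, str] = {}
    parents: Dict[str, Set[str]] = {}

    def record(subj: str, pred: str, obj_tok: str) -> None:
        if pred == f"{RDF_NS}type" and expand(obj_tok) == f"{OWL_NS}Class":
            classes.add(subj)
        elif pred == f"{RDFS_NS}subClassOf":
            obj = expand(obj_tok)
            classes.add(subj)
            classes.add(obj)
            parents.setdefault(subj, set()).add(obj)
        elif pred == f"{RDFS_NS}label" and obj_tok.startswith('"'):
            labels.setdefault(subj, obj_tok[1:-1])

    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok in ("@prefix", "PREFIX"):
            pfx = tokens[i + 1].rstrip(":")
            prefixes[pfx] = expand(tokens[i + 2])
            i += 3
            if i < len(tokens) and tokens[i] == ".":
                i += 1
            continue
        subj = expand(tok)
        i += 1
        while True:
            pred = expand(tokens[i])
            i += 1
            while True:
                record(subj, pred, tokens[i])
                i += 1
                if i < len(tokens) and tokens[i] == ",":
                    i += 1
                    continue
                break
            if i < len(tokens) and tokens[i] == ";":
                i += 1
                if i < len(tokens) and tokens[i] in (".",):
                    break
                continue
            break
        if i < len(tokens) and tokens[i] == ".":
            i += 1
        else:
            raise OntologyFormatError("missing '.' terminator in Turtle input")
    return classes, labels, parents


def read_subclass_graph(document: Union[str, Path]) -> _SubclassGraph:
    """Read (classes, labels, parent-edges) from an OWL file or string."""
    path = Path(document)
    try:
        exists = path.exists()
    except OSError:  # document passed inline and too long for a path
        exists = False
    text = path.read_text() if exists else str(document)
    stripped = text.lstrip()
    if stripped.startswith("<?xml") or stripped.startswith("<rdf:RDF"):
        return _parse_rdfxml(text)
    if stripped.startswith("<") and "rdf" in stripped[:200].lower():
        return _parse_rdfxml(text)
    return _parse_turtle(text)


def load_taxonomy(
    owl_document: Union[str, Path], dimension_roots: List[str]
) -> DomainTaxonomy:
    """Build a :class:`DomainTaxonomy` from an OWL document.

    ``dimension_roots`` lists the root class IRIs, operation dimension
    first, followed by the data dimensions in their declared order.  Every
    named class reachable downward from a root via subclass axioms becomes a
    term of that root's dimension; a class reachable from two roots is a
    disjointness violation.  Labels default to the IRI fragment.
    """
    if len(dimension_roots) < 2:
        raise ConfigurationError(
            "need an operation root and at least one data dimension root"
        )
    classes, labels, parents = read_subclass_graph(owl_document)
    for root_iri in dimension_roots:
        if root_iri not in classes:
            raise ConfigurationError(
                f"dimension root {root_iri!r} is not a class in the ontology"
            )
    children: Dict[str, Set[str]] = {}
    for child, supers in parents.items():
        for sup in supers:
            children.setdefault(sup, set()).add(child)

    dim_ids = [iri_fragment(r) for r in dimension_roots]
    if len(set(dim_ids)) != len(dim_ids):
        raise ConfigurationError(
            f"dimension root fragments must be unique, got {dim_ids}"
        )
    assignment: Dict[str, str] = {}
    for dim_id, root_iri in zip(dim_ids, dimension_roots):
        stack = [root_iri]
        while stack:
            cur = stack.pop()
            prev = assignment.get(cur)
            if prev == dim_id:
                continue
            if prev is not None:
                raise DisjointnessError(
                    f"class {cur!r} is reachable from roots of both "
                    f"{prev!r} and {dim_id!r}"
                )
            assignment[cur] = dim_id
            stack.extend(children.get(cur, ()))

    terms: Dict[str, TaxonomyTerm] = {}
    for iri, dim_id in assignment.items():
        in_dim_parents = frozenset(
            p for p in parents.get(iri, ()) if assignment.get(p) == dim_id
        )
        terms[iri] = TaxonomyTerm(
            id=iri,
            label=labels.get(iri, iri_fragment(iri)),
            dimension=dim_id,
            parents=in_dim_parents,
        )
    roots = dict(zip(dim_ids, dimension_roots))
    return DomainTaxonomy(
        operation_dimension=dim_ids[0],
        data_dimensions=dim_ids[1:],
        terms=terms,
        roots=roots,
    )


def taxonomy_to_owl(taxonomy: DomainTaxonomy) -> str:
    """Serialize a taxonomy back to RDF/XML (sorted, byte-stable)."""
    lines = [
        '<?xml version="1.0"?>',
        f'<rdf:RDF xmlns:rdf="{RDF_NS}" xmlns:rdfs="{RDFS_NS}" '
        f'xmlns:owl="{OWL_NS}">',
    ]
    for tid in sorted(taxonomy.terms):
        term = taxonomy.terms[tid]
        lines.append(f'  <owl:Class rdf:about="{tid}">')
        lines.append(f"    <rdfs:label>{_xml_escape(term.label)}</rdfs:label>")
        for parent in sorted(term.parents):
            lines.append(f'    <rdfs:subClassOf rdf:resource="{parent}"/>')
        lines.append("  </owl:Class>")
    lines.append("</rdf:RDF>")
    return "\n".join(lines) + "\n"


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )
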