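# wfsynth

Automated composition of bounded-length scientific workflows. Given a
**semantic domain model** — an OWL ontology holding an operation taxonomy
plus one or more disjoint data-characterization taxonomies (e.g. data type
and data format), and JSON tool annotations with typed, possibly
disjunctive input/output slots — and a **loose workflow specification**
(available inputs, requested outputs, natural-language constraint
templates), `wfsynth` enumerates *every* workflow up to a length bound that
satisfies the specification by construction, and exports each solution as
text, Graphviz DOT (data-flow and control-flow), an executable POSIX shell
script, and an abstract CWL v1.2 document.

Internally the bounded composition problem is compiled to propositional
CNF (one tool mode per step, slot-to-instance bindings with taxonomy
subsumption, step-indexed constraint clauses) and solved with a small
built-in DPLL solver whose static decision order makes model enumeration
canonical and fully deterministic. An independent verification module — a
graph-interpreting checker and an exhaustive brute-force enumerator that
share no code with the encoder — cross-checks every result, and a seeded
synthetic-domain generator with planted solution chains drives the
property-based test suite without any downloads.

## Command-line usage

```sh
wfsynth synthesize --config config.json [--max-solutions N] [--output-dir D]
wfsynth validate-domain --config config.json
wfsynth templates
```

`synthesize` exits 0 when at least one workflow was found, 2 when the
specification is unsatisfiable within the bounds, and 1 on any error. Per
solution *i* it writes `solution_i.txt`, `solution_i.dot` and — per the
`exports` toggles and command availability — `solution_i.sh` and
`solution_i.cwl`, plus a `solutions.json` run summary. Re-running the same
configuration produces byte-identical files.

A complete example configuration (the packaged six-tool proteomics
fragment) lives at `src/wfsynth/data/proteomics/config.json`:

```json
{
  "ontology_path": "ontology.owl",
  "tool_annotations_path": "tools.json",
  "dimension_roots": ["...#Operation", "...#Type", "...#Format"],
  "inputs":  [{"Type": "Mass_spectrum", "Format": "mzML"}],
  "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
  "constraints": [
    {"template": "use_operation", "args": ["Peptide_identification"]},
    {"template": "use_operation", "args": ["Retention_time_prediction"]}
  ],
  "min_length": 1, "max_length": 3, "max_solutions": 100
}
```

Constraint templates: `use_operation(X)`, `avoid_operation(X)`,
`use_tool(T)`, `last_operation(X)`, `operation_before(X, Y)` and
`use_type(D)`; operation arguments are descendant-closed (an abstract
ontology term matches any tool annotated with it or any of its
descendants). See `wfsynth templates` and the docstring of
`wfsynth/specification.py` for the exact trace semantics.

## Python API

```python
from wfsynth import Domain, load_taxonomy, parse_tool_annotations, parse_spec, synthesize
from wfsynth.solution_export import to_text, to_cwl

taxonomy = load_taxonomy("ontology.owl", [op_root_iri, type_root_iri, format_root_iri])
domain = Domain(taxonomy=taxonomy, tools=parse_tool_annotations("tools.json", taxonomy))
spec = parse_spec({"inputs": [...], "outputs": [...], "max_length": 4}, taxonomy)
for solution in synthesize(domain, spec):
    print(to_text(solution))
```

Each solution is a directed data-flow graph of `TypeNode`s (data
instances, with producer and consumer links) and `ModuleNode`s (tool
executions in order, with argument-position-labelled bindings).

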