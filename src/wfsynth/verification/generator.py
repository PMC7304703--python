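"""Seeded synthetic domain generator with a planted solution chain.

Every generated instance is guaranteed satisfiable: a chain of
``planted_chain_length`` tools is constructed to be executable from the
generated workflow inputs through to the requested outputs.  All
randomness flows through one ``random.Random(seed)``, so identical
parameters yield identical domains.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Tuple

from ..domain_model import (
    DataSignature,
    Domain,
    DomainTaxonomy,
    TaxonomyTerm,
    ToolAnnotation,
    taxonomy_to_owl,
    tools_to_json,
)
from ..specification import WorkflowSpec

_NS = "http://example.org/generated"


@dataclass(frozen=True)
class GeneratorParams:
    seed: int
    data_dimensions: int = 2
    terms_per_dimension: int = 6
    depth: int = 3
    tool_count: int = 4
    max_slots: int = 2
    output_disjunction_prob: float = 0.2
    planted_chain_length: int = 2

    def __post_init__(self) -> None:
        assert self.data_dimensions >= 1
        assert self.terms_per_dimension >= 1
        assert self.depth >= 1
        assert self.tool_count >= self.planted_chain_length >= 1
        assert self.max_slots >= 1


def _build_dimension(
    rng: random.Random, dim: str, size: int, depth: int
) -> Tuple[Dict[str, TaxonomyTerm], str]:
    root = f"{_NS}/{dim}#{dim}"
    terms = {root: TaxonomyTerm(root, dim, dim, frozenset())}
    depths = {root: 0}
    pool = [root]
    for k in range(1, size + 1):
        parent = rng.choice([t for t in pool if depths[t] < depth])
        tid = f"{_NS}/{dim}#{dim}_T{k}"
        terms[tid] = TaxonomyTerm(tid, f"{dim}_T{k}", dim, frozenset([parent]))
        depths[tid] = depths[parent] + 1
        pool.append(tid)
    return terms, root


def _ancestors(taxonomy: DomainTaxonomy, term: str) -> List[str]:
    out = [term]
    seen = {term}
    stack = [term]
    while stack:
        for parent in taxonomy.terms[stack.pop()].parents:
            if parent not in seen:
                seen.add(parent)
                out.append(parent)
                stack.append(parent)
    return sorted(out)


def _stub_command(n_inputs: int, n_outputs: int) -> str:
    ins = " ".join(f"{{in{k}}}" for k in range(1, n_inputs + 1))
    parts = [f"cat {ins} > {{out1}}" if ins else "printf 'x' > {out1}"]
    for k in range(2, n_outputs + 1):
        parts.append(f"cp {{out1}} {{out{k}}}")
    return " && ".join(parts)


def generate_domain(
    params: GeneratorParams,
) -> Tuple[DomainTaxonomy, List[ToolAnnotation], WorkflowSpec]:
    rng = random.Random(params.seed)
    dims = ["Op"] + [f"D{i}" for i in range(1, params.data_dimensions + 1)]
    terms: Dict[str, TaxonomyTerm] = {}
    roots: Dict[str, str] = {}
    for dim in dims:
        dim_terms, root = _build_dimension(
            rng, dim, params.terms_per_dimension, params.depth
        )
        terms.update(dim_terms)
        roots[dim] = root
    taxonomy = DomainTaxonomy(
        operation_dimension="Op",
        data_dimensions=dims[1:],
        terms=terms,
        roots=roots,
    )
    data_dims = taxonomy.data_dimensions
    op_terms = [t.id for t in taxonomy.terms_in("Op") if t.id != roots["Op"]]
    op_terms = op_terms or [roots["Op"]]

    def random_concrete() -> DataSignature:
        return DataSignature.of(
            {
                dim: [rng.choice([t.id for t in taxonomy.terms_in(dim)])]
                for dim in data_dims
            }
        )

    tools: List[ToolAnnotation] = []

    # planted, guaranteed-executable chain
    current = random_concrete()
    spec_inputs = (current,)
    for j in range(1, params.planted_chain_length + 1):
        slot = DataSignature.of(
            {
                dim: [
                    rng.choice(
                        _ancestors(taxonomy, current.concrete_term(dim))
                    )
                ]
                for dim in data_dims
            }
        )
        produced = random_concrete()
        tools.append(
            ToolAnnotation(
                id=f"planted{j}",
                label=f"Planted step {j}",
                operations=frozenset([rng.choice(op_terms)]),
                inputs=(slot,),
                outputs=(produced,),
                command=_stub_command(1, 1),
            )
        )
        current = produced
    spec_outputs = (
        DataSignature.of(
            {
                dim: [
                    rng.choice(_ancestors(taxonomy, current.concrete_term(dim)))
                ]
                for dim in data_dims
            }
        ),
    )

    # random filler tools
    for j in range(params.tool_count - params.planted_chain_length):
        n_in = rng.randint(1, params.max_slots)
        n_out = rng.randint(1, 2)
        inputs = []
        for _ in range(n_in):
            inputs.append(
                DataSignature.of(
                    {
                        dim: sorted(
                            rng.sample(
                                [t.id for t in taxonomy.terms_in(dim)],
                                rng.randint(1, 2),
                            )
                        )
                        for dim in data_dims
                    }
                )
            )
        outputs = []
        for _ in range(n_out):
            outputs.append(
                DataSignature.of(
                    {
                        dim: sorted(
                            rng.sample(
                                [t.id for t in taxonomy.terms_in(dim)],
                                2
                                if rng.random()
                                < params.output_disjunction_prob
                                else 1,
                            )
                        )
                        for dim in data_dims
                    }
                )
            )
        tools.append(
            ToolAnnotation(
                id=f"tool{j + 1}",
                label=f"Random tool {j + 1}",
                operations=frozenset(
                    rng.sample(op_terms, min(len(op_terms), rng.randint(1, 2)))
                ),
                inputs=tuple(inputs),
                outputs=tuple(outputs),
                command=_stub_command(n_in, n_out),
            )
        )

    spec = WorkflowSpec(
        inputs=spec_inputs,
        outputs=spec_outputs,
        min_length=1,
        max_length=max(params.planted_chain_length, 1),
        max_solutions=100,
    )
    return taxonomy, tools, spec


def planted_sequence(params: GeneratorParams) -> Tuple[str, ...]:
    """Mode-id sequence of the planted chain (each planted tool has exactly
    one mode)."""
    return tuple(
        f"planted{j}@0" for j in range(1, params.planted_chain_length + 1)
    )


def write_domain(
    directory: Path,
    taxonomy: DomainTaxonomy,
    tools: List[ToolAnnotation],
    spec: WorkflowSpec = None,
) -> Dict[str, Path]:
    """Write the domain as OWL + annotation JSON (+ a full run config when
    a spec is given), so generated fixtures exercise the real file readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": directory / "ontology.owl",
        "tools": directory / "tools.json",
    }
    paths["ontology"].write_text(taxonomy_to_owl(taxonomy))
    paths["tools"].write_text(
        json.dumps(tools_to_json(tools), indent=2, sort_keys=True) + "\n"
    )
    if spec is not None:
        from ..specification import spec_to_json

        config = {
            "ontology_path": "ontology.owl",
            "tool_annotations_path": "tools.json",
            "dimension_roots": [
                taxonomy.roots[d] for d in taxonomy.dimensions
            ],
            "output_dir": "out",
            **spec_to_json(spec),
        }
        paths["config"] = directory / "config.json"
        paths["config"].write_text(
            json.dumps(config, indent=2, sort_keys=True) + "\n"
        )
    return paths


def generated_domain(params: GeneratorParams) -> Tuple[Domain, WorkflowSpec]:
    """Convenience wrapper returning a ready :class:`Domain`."""
    taxonomy, tools, spec = generate_domain(params)
    return Domain(taxonomy=taxonomy, tools=tools), spec
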