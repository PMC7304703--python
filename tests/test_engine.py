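"""Encoding, model enumeration, decoding and the synthesis loop."""

import dataclasses

import pytest

from wfsynth.domain_model import Domain, ToolAnnotation
from wfsynth.errors import EncodingError
from wfsynth.specification import WorkflowSpec, instantiate_template, parse_spec
from wfsynth.synthesis_engine import (
    decode_model,
    encode,
    enumerate_models,
    synthesize,
)
from wfsynth.verification import (
    GeneratorParams,
    brute_force_enumerate,
    check_solution,
    generated_domain,
    planted_sequence,
)

from .conftest import sig


@pytest.fixture()
def toy_spec(toy_domain):
    return WorkflowSpec(
        inputs=(sig(T="X1"),),
        outputs=(sig(T="Y"),),
        max_length=1,
    )


class TestEncode:
    def test_single_feasible_assignment(self, toy_domain, toy_spec):
        cnf = encode(toy_domain, toy_spec, 1)
        models = enumerate_models(cnf, 10)
        assert len(models) == 1
        solution = decode_model(models[0], cnf, toy_domain, toy_spec)
        assert solution.mode_ids == ("a2y@0",)

    def test_unproducible_output_unsat_at_every_length(self, toy_domain):
        # restrict the domain to a2y (X -> Y): nothing can ever produce an
        # X instance, and the workflow input is a Y
        only_a2y = Domain(
            taxonomy=toy_domain.taxonomy,
            tools=[t for t in toy_domain.tools if t.id == "a2y"],
        )
        spec = WorkflowSpec(
            inputs=(sig(T="Y"),),
            outputs=(sig(T="X"),),
            min_length=1,
            max_length=3,
        )
        for n in (1, 2, 3):
            cnf = encode(only_a2y, spec, n)
            assert enumerate_models(cnf, 10) == []

    def test_fixture_matches_brute_force_at_length_3(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "min_length": 3,
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        cnf = encode(proteomics, spec, 3)
        models = enumerate_models(cnf, 10_000)
        engine_set = {
            decode_model(m, cnf, proteomics, spec).mode_ids for m in models
        }
        oracle_set = {
            seq
            for seq in brute_force_enumerate(proteomics, spec, 3)
            if len(seq) == 3
        }
        assert engine_set == oracle_set

    def test_zero_length_rejected(self, toy_domain, toy_spec):
        with pytest.raises(EncodingError):
            encode(toy_domain, toy_spec, 0)

    def test_empty_domain_rejected(self, toy_taxonomy, toy_spec):
        with pytest.raises(EncodingError):
            encode(Domain(taxonomy=toy_taxonomy, tools=[]), toy_spec, 1)

    def test_dimacs_dump(self, toy_domain, toy_spec):
        cnf = encode(toy_domain, toy_spec, 1)
        text = cnf.to_dimacs()
        header = [l for l in text.splitlines() if l.startswith("p cnf")]
        assert header == [f"p cnf {len(cnf.registry)} {len(cnf.clauses)}"]
        legend = [l for l in text.splitlines() if l.startswith("c ")]
        assert len(legend) == len(cnf.registry)


class TestEnumerateModels:
    def test_unsat_gives_empty_list(self, toy_domain):
        spec = WorkflowSpec(
            inputs=(sig(T="Y"),), outputs=(sig(T="X"),), max_length=1
        )
        only_a2y = Domain(
            taxonomy=toy_domain.taxonomy,
            tools=[t for t in toy_domain.tools if t.id == "a2y"],
        )
        cnf = encode(only_a2y, spec, 1)
        assert enumerate_models(cnf, 10) == []

    def test_exactly_two_sequences(self, toy_domain):
        # from X1: step1 must be a2y (X1 matches X); step2 either tool can
        # run (a2y re-reads X1, y2x reads the fresh Y)
        spec = WorkflowSpec(
            inputs=(sig(T="X1"),),
            outputs=(sig(T="Y"),),
            min_length=2,
            max_length=2,
        )
        cnf = encode(toy_domain, spec, 2)
        models = enumerate_models(cnf, 10)
        sequences = {
            decode_model(m, cnf, toy_domain, spec).mode_ids for m in models
        }
        assert sequences == {("a2y@0", "a2y@0"), ("a2y@0", "y2x@0")}

    def test_limit_one(self, toy_domain):
        spec = WorkflowSpec(
            inputs=(sig(T="X1"),),
            outputs=(sig(T="Y"),),
            min_length=2,
            max_length=2,
        )
        cnf = encode(toy_domain, spec, 2)
        assert len(enumerate_models(cnf, 1)) == 1

    def test_canonical_order(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "min_length": 3,
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        cnf = encode(proteomics, spec, 3)
        models = enumerate_models(cnf, 10_000)
        keys = [
            tuple(
                m.sort_key
                for m in (
                    decode_model(model, cnf, proteomics, spec).steps[k].mode
                    for k in range(3)
                )
            )
            for model in models
        ]
        assert keys == sorted(keys)


class TestDecode:
    def test_single_step_graph(self, toy_domain, toy_spec):
        cnf = encode(toy_domain, toy_spec, 1)
        (model,) = enumerate_models(cnf, 1)
        solution = decode_model(model, cnf, toy_domain, toy_spec)
        assert len(solution.steps) == 1
        assert [n.id for n in solution.workflow_inputs] == ["in1"]
        assert solution.steps[0].outputs[0].id == "s1.o1"
        assert solution.workflow_outputs[0].id == "s1.o1"
        assert solution.steps[0].outputs[0].producer is solution.steps[0]

    def test_unused_input_kept_with_empty_consumers(self, toy_domain):
        spec = WorkflowSpec(
            inputs=(sig(T="X1"), sig(T="Y")),  # the Y input goes unused
            outputs=(sig(T="Y"),),
            max_length=1,
        )
        cnf = encode(toy_domain, spec, 1)
        models = enumerate_models(cnf, 10)
        for model in models:
            solution = decode_model(model, cnf, toy_domain, spec)
            in2 = solution.node("in2")
            assert in2.is_workflow_input
            # binding symmetry collapsing keeps only one model per sequence,
            # but the unused input node must survive in every decoded graph
            if all(n.id != "in2" for s in solution.steps for n in s.inputs):
                assert in2.consumers == []

    def test_decoded_graphs_pass_independent_checker(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        for solution in synthesize(proteomics, spec):
            assert check_solution(solution, proteomics, spec) == []


class TestSynthesize:
    def test_max_solutions_one_returns_shortest_canonical(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "max_length": 3,
                "max_solutions": 1,
            },
            proteomics.taxonomy,
        )
        (solution,) = synthesize(proteomics, spec)
        assert solution.mode_ids == ("comet@0", "rt4@0")

    def test_planted_domain_returns_exactly_the_chain(self):
        for seed in (0, 1, 2):
            params = GeneratorParams(
                seed=seed,
                tool_count=3,
                planted_chain_length=3,
                terms_per_dimension=5,
            )
            domain, spec = generated_domain(params)
            spec = dataclasses.replace(spec, min_length=3, max_length=3)
            sequences = {s.mode_ids for s in synthesize(domain, spec)}
            oracle = brute_force_enumerate(domain, spec, 3)
            assert sequences == oracle
            assert planted_sequence(params) in sequences

    def test_constrained_fixture_requires_both_operations(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "constraints": [
                    {"template": "use_operation", "args": ["Peptide_identification"]},
                    {"template": "use_operation", "args": ["Retention_time_prediction"]},
                ],
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        tax = proteomics.taxonomy
        pep = tax.resolve("Peptide_identification", dimension="Operation")
        ret = tax.resolve("Retention_time_prediction", dimension="Operation")
        solutions = synthesize(proteomics, spec)
        assert solutions
        for solution in solutions:
            modes = [s.mode for s in solution.steps]
            assert any(proteomics.mode_performs(m, pep) for m in modes)
            assert any(proteomics.mode_performs(m, ret) for m in modes)

    def test_ordering_and_no_duplicate_sequences(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        solutions = synthesize(proteomics, spec)
        keys = [s.sort_key for s in solutions]
        assert keys == sorted(keys)
        assert len({s.mode_ids for s in solutions}) == len(solutions)

    def test_empty_domain_returns_empty_list(self, toy_taxonomy):
        domain = Domain(taxonomy=toy_taxonomy, tools=[])
        spec = WorkflowSpec(inputs=(sig(T="X1"),), outputs=(sig(T="Y"),))
        assert synthesize(domain, spec) == []

    def test_determinism(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "mzML"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "max_length": 3,
            },
            proteomics.taxonomy,
        )
        first = [s.mode_ids for s in synthesize(proteomics, spec)]
        second = [s.mode_ids for s in synthesize(proteomics, spec)]
        assert first == second


class TestAntiMonotonicity:
    @pytest.mark.parametrize("seed", range(8))
    def test_removing_tool_never_adds_solutions(self, seed):
        domain, spec = generated_domain(
            GeneratorParams(seed=seed, tool_count=4, planted_chain_length=2)
        )
        spec = dataclasses.replace(spec, max_length=3, max_solutions=10**6)
        full = {s.mode_ids for s in synthesize(domain, spec)}
        for removed in domain.tools:
            smaller = Domain(
                taxonomy=domain.taxonomy,
                tools=[t for t in domain.tools if t.id != removed.id],
            )
            reduced = {s.mode_ids for s in synthesize(smaller, spec)}
            assert reduced <= full

    @pytest.mark.parametrize("seed", range(8))
    def test_adding_constraint_never_adds_solutions(self, seed):
        import random

        domain, spec = generated_domain(
            GeneratorParams(seed=seed, tool_count=4, planted_chain_length=2)
        )
        spec = dataclasses.replace(spec, max_length=3, max_solutions=10**6)
        base = {s.mode_ids for s in synthesize(domain, spec)}
        rng = random.Random(seed)
        tax = domain.taxonomy
        ops = [t.id for t in tax.terms_in(tax.operation_dimension)]
        constraint = instantiate_template(
            "use_operation", [rng.choice(ops)], tax
        )
        constrained = dataclasses.replace(
            spec, constraints=(*spec.constraints, constraint)
        )
        assert {s.mode_ids for s in synthesize(domain, constrained)} <= base
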