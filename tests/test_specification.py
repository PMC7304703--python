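"""Constraint catalog, template semantics, compilation, spec parsing."""

import itertools
import random

import pytest

from wfsynth.errors import (
    CatalogError,
    SpecificationError,
    TemplateSignatureError,
)
from wfsynth.specification import (
    CompilationContext,
    WorkflowSpec,
    compile_constraint,
    constraint_holds,
    get_template,
    instantiate_template,
    list_templates,
    parse_constraint_text,
    parse_spec,
)
from wfsynth.synthesis_engine.sat import SATSolver
from wfsynth.verification import GeneratorParams, generated_domain


class TestCatalog:
    def test_expected_templates_present(self):
        catalog = list_templates()
        assert set(catalog) == {
            "use_operation",
            "avoid_operation",
            "use_tool",
            "last_operation",
            "operation_before",
            "use_type",
        }

    def test_ids_unique_and_consistent(self):
        for template_id, template in list_templates().items():
            assert template.id == template_id

    def test_each_template_renders_with_placeholders(self):
        for template in list_templates().values():
            text = template.render([f"<{p}>" for p in template.params])
            for p in template.params:
                assert f"<{p}>" in text

    def test_unknown_template(self):
        with pytest.raises(CatalogError):
            get_template("use_magic")


class TestInstantiate:
    def test_valid_operation_constraint(self, proteomics):
        c = instantiate_template(
            "use_operation", ["Peptide identification"], proteomics.taxonomy
        )
        assert c.arguments[0].endswith("operation#Peptide_identification")
        assert "Peptide identification" in c.human_text

    def test_wrong_dimension_rejected(self, proteomics):
        with pytest.raises(TemplateSignatureError):
            instantiate_template(
                "use_operation", ["mzML"], proteomics.taxonomy
            )

    def test_wrong_arity_rejected(self, proteomics):
        with pytest.raises(TemplateSignatureError):
            instantiate_template(
                "operation_before", ["Conversion"], proteomics.taxonomy
            )

    def test_human_text_round_trips(self, proteomics):
        tax = proteomics.taxonomy
        examples = [
            ("use_operation", ["Conversion"]),
            ("avoid_operation", ["Filtering"]),
            ("use_tool", ["comet"]),
            ("last_operation", ["Retention time prediction"]),
            ("operation_before", ["Conversion", "Filtering"]),
            ("use_type", ["mzML"]),
        ]
        for template_id, args in examples:
            constraint = instantiate_template(template_id, args, tax)
            again = parse_constraint_text(constraint.human_text, tax)
            assert again == constraint


class TestOperationBeforeSelfOrdering:
    def test_x_equals_y_semantics_by_enumeration(self, toy_domain):
        """operation_before(X, X) holds iff X occurs >= 2 times or never —
        verified by hand enumeration of every trace of length <= 3."""
        tax = toy_domain.taxonomy
        constraint = instantiate_template(
            "operation_before", ["DoA", "DoA"], tax
        )
        modes = toy_domain.modes
        for n in (1, 2, 3):
            for seq in itertools.product(modes, repeat=n):
                count = sum(
                    1 for m in seq if toy_domain.mode_performs(m, "DoA")
                )
                expected = count == 0 or count >= 2
                assert (
                    constraint_holds(constraint, list(seq), toy_domain)
                    == expected
                ), [m.id for m in seq]


def _enumerate_constrained_sequences(domain, constraint, n):
    """SAT route: exactly-one mode per step + compiled constraint clauses,
    models projected to mode-id sequences."""
    solver = SATSolver()
    step_mode_vars = []
    for _ in range(n):
        row = [(mode, solver.new_var()) for mode in domain.modes]
        step_mode_vars.append(row)
    for row in step_mode_vars:
        solver.add_clause([var for _, var in row])
        for a in range(len(row)):
            for b in range(a + 1, len(row)):
                solver.add_clause([-row[a][1], -row[b][1]])
    ctx = CompilationContext(domain, n, step_mode_vars)
    for clause in compile_constraint(constraint, ctx):
        solver.add_clause(clause)
    order = [var for row in step_mode_vars for _, var in row]
    found = set()
    while True:
        model = solver.solve(decision_order=order)
        if model is None:
            return found
        seq = tuple(
            next(mode.id for mode, var in row if model[var])
            for row in step_mode_vars
        )
        found.add(seq)
        solver.add_clause(
            [-var for row in step_mode_vars for _, var in row if model[var]]
        )


def _random_constraint(rng, domain):
    tax = domain.taxonomy
    ops = [t.id for t in tax.terms_in(tax.operation_dimension)]
    data_terms = [
        t.id for d in tax.data_dimensions for t in tax.terms_in(d)
    ]
    tools = [t.id for t in domain.tools]
    template_id = rng.choice(sorted(list_templates()))
    args = {
        "use_operation": lambda: [rng.choice(ops)],
        "avoid_operation": lambda: [rng.choice(ops)],
        "use_tool": lambda: [rng.choice(tools)],
        "last_operation": lambda: [rng.choice(ops)],
        "operation_before": lambda: [rng.choice(ops), rng.choice(ops)],
        "use_type": lambda: [rng.choice(data_terms)],
    }[template_id]()
    return instantiate_template(template_id, args, tax)


class TestCompilationVsTracePredicate:
    @pytest.mark.parametrize("seed", range(20))
    def test_sat_models_equal_brute_force_filter(self, seed):
        """For random (domain, constraint, n <= 4) triples the SAT route and
        direct predicate evaluation over all mode sequences agree exactly.

        100 triples overall: 20 seeds x 5 constraint/length draws.
        """
        rng = random.Random(seed)
        domain, _ = generated_domain(
            GeneratorParams(
                seed=seed,
                data_dimensions=1,
                terms_per_dimension=4,
                tool_count=3,
                planted_chain_length=1,
            )
        )
        for _ in range(5):
            n = rng.randint(1, 4)
            constraint = _random_constraint(rng, domain)
            sat_set = _enumerate_constrained_sequences(domain, constraint, n)
            brute = {
                tuple(m.id for m in seq)
                for seq in itertools.product(domain.modes, repeat=n)
                if constraint_holds(constraint, list(seq), domain)
            }
            assert sat_set == brute, (constraint.human_text, n)

    def test_avoid_operation_forced_unit_clause(self, toy_domain):
        constraint = instantiate_template(
            "avoid_operation", ["DoA"], toy_domain.taxonomy
        )
        row = [(mode, k + 1) for k, mode in enumerate(toy_domain.modes)]
        ctx = CompilationContext(toy_domain, 1, [row])
        clauses = compile_constraint(constraint, ctx)
        doa_vars = [
            var
            for mode, var in row
            if toy_domain.mode_performs(mode, "DoA")
        ]
        assert len(doa_vars) == 1  # exactly one DoA-performing mode
        assert clauses == [[-doa_vars[0]]]

    def test_unperformable_use_operation_is_unsat_clause(self, toy_domain):
        # no tool performs the root operation's sibling-free leaf "DoC"
        tax = toy_domain.taxonomy
        constraint = instantiate_template(
            "use_operation", ["Run"], tax
        )  # both tools match Run (descendant-closed): non-empty
        row = [(mode, k + 1) for k, mode in enumerate(toy_domain.modes)]
        ctx = CompilationContext(toy_domain, 1, [row])
        assert compile_constraint(constraint, ctx)[0]  # non-empty clause

        # restrict to a domain slice where nothing performs DoB's descendants
        from wfsynth.domain_model import Domain

        only_a = Domain(
            taxonomy=tax,
            tools=[t for t in toy_domain.tools if "DoB" not in t.operations],
        )
        row = [(mode, k + 1) for k, mode in enumerate(only_a.modes)]
        ctx = CompilationContext(only_a, 1, [row])
        constraint = instantiate_template("use_operation", ["DoB"], tax)
        assert compile_constraint(constraint, ctx) == [[]]  # unsatisfiable


class TestParseSpec:
    def test_proteomics_spec(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [{"Type": "Mass_spectrum", "Format": "Thermo_RAW_format"}],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
                "constraints": [
                    {"template": "use_operation", "args": ["Peptide_identification"]},
                    {"template": "use_operation", "args": ["Validation of peptide spectrum matches"]},
                    {"template": "use_operation", "args": ["Retention_time_prediction"]},
                ],
            },
            proteomics.taxonomy,
        )
        assert len(spec.inputs) == 1
        assert len(spec.outputs) == 1
        assert len(spec.constraints) == 3
        assert spec.min_length == 1
        assert spec.max_length == 10
        assert spec.max_solutions == 100

    def test_no_constraints_is_valid(self, proteomics):
        spec = parse_spec(
            {"inputs": [], "outputs": []}, proteomics.taxonomy
        )
        assert spec.constraints == ()

    def test_omitted_dimension_becomes_root(self, proteomics):
        spec = parse_spec(
            {
                "inputs": [],
                "outputs": [{"Type": "Amino_acid_index_hydropathy"}],
            },
            proteomics.taxonomy,
        )
        assert spec.outputs[0].terms_in("Format") == frozenset(
            ["http://example.org/proteomics/format#Format"]
        )

    def test_error_carries_json_path(self, proteomics):
        with pytest.raises(SpecificationError, match=r"inputs\[0\].Format"):
            parse_spec(
                {
                    "inputs": [{"Type": "Mass_spectrum", "Format": "RAWX"}],
                    "outputs": [],
                },
                proteomics.taxonomy,
            )

    def test_disjunctive_input_rejected(self, proteomics):
        with pytest.raises(SpecificationError, match="concrete"):
            parse_spec(
                {
                    "inputs": [{"Type": "Mass_spectrum", "Format": ["mzML", "mzXML"]}],
                    "outputs": [],
                },
                proteomics.taxonomy,
            )

    def test_zero_max_solutions_rejected(self, proteomics):
        with pytest.raises(SpecificationError):
            parse_spec(
                {"inputs": [], "outputs": [], "max_solutions": 0},
                proteomics.taxonomy,
            )

    def test_bad_length_bounds_rejected(self):
        with pytest.raises(SpecificationError):
            WorkflowSpec(
                inputs=(), outputs=(), min_length=3, max_length=2
            )
        with pytest.raises(SpecificationError):
            WorkflowSpec(inputs=(), outputs=(), min_length=0)

    def test_constraint_with_unknown_template(self, proteomics):
        with pytest.raises(SpecificationError, match=r"constraints\[0\]"):
            parse_spec(
                {
                    "inputs": [],
                    "outputs": [],
                    "constraints": [{"template": "use_magic", "args": []}],
                },
                proteomics.taxonomy,
            )
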