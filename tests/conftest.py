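import json
from pathlib import Path

import pytest

from wfsynth.domain_model import (
    DataSignature,
    Domain,
    DomainTaxonomy,
    TaxonomyTerm,
    ToolAnnotation,
)
from wfsynth.fixtures import PROTEOMICS_ROOTS, proteomics_domain, proteomics_path

DATA_DIR = Path(__file__).parent / "data"


def make_taxonomy(edges_by_dim, operation_dimension="Op"):
    """Build a taxonomy from {dim: {child: parent-or-None}} dicts; term ids
    are plain strings (no IRIs) for readability in tests."""
    terms = {}
    roots = {}
    for dim, edges in edges_by_dim.items():
        for child, parent in edges.items():
            parents = frozenset() if parent is None else frozenset([parent])
            terms[child] = TaxonomyTerm(child, child, dim, parents)
            if parent is None:
                roots[dim] = child
    dims = list(edges_by_dim)
    return DomainTaxonomy(
        operation_dimension=operation_dimension,
        data_dimensions=[d for d in dims if d != operation_dimension],
        terms=terms,
        roots=roots,
    )


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Op: Run > {DoA, DoB}; one data dimension T: T > {X > {X1, X2}, Y}.

    X2 is deliberately produced by no tool (useful for unmet-output cases).
    """
    return make_taxonomy(
        {
            "Op": {"Run": None, "DoA": "Run", "DoB": "Run"},
            "T": {"T": None, "X": "T", "X1": "X", "X2": "X", "Y": "T"},
        }
    )


def sig(**dims):
    return DataSignature.of({k: v if isinstance(v, list) else [v] for k, v in dims.items()})


@pytest.fixture(scope="session")
def toy_domain(toy_taxonomy):
    """Two tools over the toy taxonomy: a X1->Y producer and a Y->X chain."""
    t1 = ToolAnnotation(
        id="a2y",
        label="A to Y",
        operations=frozenset(["DoA"]),
        inputs=(sig(T="X"),),
        outputs=(sig(T="Y"),),
        command="cat {in1} > {out1}",
    )
    t2 = ToolAnnotation(
        id="y2x",
        label="Y to X",
        operations=frozenset(["DoB"]),
        inputs=(sig(T="Y"),),
        outputs=(sig(T=["X1"]),),
        command="cat {in1} > {out1}",
    )
    return Domain(taxonomy=toy_taxonomy, tools=[t1, t2])


@pytest.fixture(scope="session")
def proteomics():
    return proteomics_domain()


@pytest.fixture(scope="session")
def proteomics_ontology_text():
    return proteomics_path("ontology.owl").read_text()


@pytest.fixture(scope="session")
def snapshots():
    return json.loads((DATA_DIR / "proteomics_snapshots.json").read_text())


@pytest.fixture()
def proteomics_workdir(tmp_path):
    """Copy the packaged proteomics files into a scratch dir so CLI runs
    can resolve relative paths."""
    for name in (
        "ontology.owl",
        "tools.json",
        "config.json",
        "config_raw_input.json",
    ):
        (tmp_path / name).write_text(proteomics_path(name).read_text())
    return tmp_path


__all__ = ["PROTEOMICS_ROOTS", "make_taxonomy", "sig"]
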