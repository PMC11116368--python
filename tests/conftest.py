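"""Shared fixtures: small hand-built networks and generated communities."""

import pytest

from comgem.core import DEFAULT_BOUND, Metabolite, Model, Reaction
from comgem.synth import generate_truth_network


def make_model(mid="m", reactions=(), metabolites=(), objective=None, tool="synthetic"):
    """Convenience constructor: metabolites as ids or Metabolite objects,
    reactions as (id, stoich, lb, ub, kind) tuples or Reaction objects."""
    model = Model(id=mid, tool=tool)
    for met in metabolites:
        model.add_metabolite(met if isinstance(met, Metabolite) else Metabolite(id=met))
    for rxn in reactions:
        if not isinstance(rxn, Reaction):
            rid, stoich, lb, ub, kind = rxn
            rxn = Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                           upper_bound=ub, kind=kind)
        for mmid in rxn.stoichiometry:
            if mmid not in model.metabolites:
                model.add_metabolite(Metabolite(id=mmid))
        model.add_reaction(rxn)
    model.objective = objective
    return model


@pytest.fixture
def chain_model():
    """EX_A <-> A, A -> B, B -> C, no consumer of C (C is a dead end)."""
    return make_model(
        "chain",
        reactions=[
            ("EX_A", {"A@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
            ("R1", {"A@e": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ("R2", {"B@c": -1.0, "C@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
        ],
    )


@pytest.fixture
def two_path_model():
    """Two parallel routes with capacities 4 and 6 feeding one biomass."""
    return make_model(
        "twopath",
        reactions=[
            ("EX_S", {"S@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
            ("P1", {"S@e": -1.0, "X@c": 1.0}, 0.0, 4.0, "internal"),
            ("P2", {"S@e": -1.0, "X@c": 1.0}, 0.0, 6.0, "internal"),
            ("BIO", {"X@c": -1.0}, 0.0, DEFAULT_BOUND, "biomass"),
        ],
        objective="BIO",
    )


@pytest.fixture(scope="session")
def truth_fixture():
    return generate_truth_network(n_branch_pathways=3, branch_length=3, seed=11)


@pytest.fixture
def rich_medium(truth_fixture):
    return truth_fixture.rich_medium
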