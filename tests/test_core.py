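"""Structural diagnostics: dead ends, balance checks, stats, GPR algebra."""

import numpy as np
import pytest

from comgem.core import (
    DEFAULT_BOUND,
    Metabolite,
    Model,
    Reaction,
    check_mass_charge_balance,
    find_dead_end_metabolites,
    gpr_genes,
    gpr_or,
    gprs_equivalent,
    infer_reaction_kind,
    model_stats,
    parse_formula,
)
from comgem.errors import FormulaError, ValidationError

from conftest import make_model


class TestGPR:
    def test_genes_of_nested_rule(self):
        assert gpr_genes("(g1 and g2) or g3") == {"g1", "g2", "g3"}
        assert gpr_genes("") == frozenset()

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("g1 and g2", "g2 and g1", True),
            ("(g1 and g2) or g3", "g3 or (g2 and g1)", True),
            ("g1 or g2", "g1 and g2", False),
            ("", "", True),
            ("g1", "", False),
        ],
    )
    def test_truth_table_equivalence(self, a, b, expected):
        assert gprs_equivalent(a, b) is expected

    def test_or_keeps_annotated_rule_over_empty(self):
        assert gpr_or("g1", "") == "g1"
        assert gpr_or("", "g2") == "g2"
        combined = gpr_or("g1", "g2")
        assert gprs_equivalent(combined, "g1 or g2")


class TestDeadEnds:
    def test_chain_terminal_metabolite_is_dead_end(self, chain_model):
        assert find_dead_end_metabolites(chain_model) == {"C@c"}

    def test_reversible_isolated_pair_has_no_dead_ends(self):
        # A <-> B: forward produces B / consumes A, reverse produces A /
        # consumes B, so each metabolite has both a producer and a consumer
        model = make_model(
            "pair",
            reactions=[("R", {"A@c": -1.0, "B@c": 1.0}, -DEFAULT_BOUND, DEFAULT_BOUND, "internal")],
        )
        assert find_dead_end_metabolites(model) == set()

    def test_irreversible_isolated_pair_both_dead(self):
        model = make_model(
            "pair",
            reactions=[("R", {"A@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal")],
        )
        assert find_dead_end_metabolites(model) == {"A@c", "B@c"}

    def test_empty_model(self):
        assert find_dead_end_metabolites(Model(id="empty")) == set()

    def test_adding_reactions_never_creates_dead_ends_on_existing_metabolites(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_mets = int(rng.integers(3, 8))
            mets = [f"M{i}@c" for i in range(n_mets)]
            model = make_model("rand", metabolites=mets)
            for j in range(int(rng.integers(1, 6))):
                picks = rng.choice(n_mets, size=2, replace=False)
                model.add_reaction(
                    Reaction(
                        id=f"R{j}",
                        stoichiometry={mets[picks[0]]: -1.0, mets[picks[1]]: 1.0},
                        lower_bound=float(rng.choice([-DEFAULT_BOUND, 0.0])),
                        upper_bound=DEFAULT_BOUND,
                    )
                )
            before = find_dead_end_metabolites(model)
            picks = rng.choice(n_mets, size=2, replace=False)
            model.add_reaction(
                Reaction(id="extra", stoichiometry={mets[picks[0]]: -1.0, mets[picks[1]]: 1.0},
                         lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND)
            )
            after = find_dead_end_metabolites(model)
            assert after & set(mets) <= before


class TestBalance:
    def _table(self, **formulas):
        return {mid: Metabolite(id=mid, formula=f, charge=0) for mid, f in formulas.items()}

    def test_water_splitting_is_balanced(self):
        rxn = Reaction(id="R", stoichiometry={"h2o@c": -2.0, "h2@c": 2.0, "o2@c": 1.0})
        rep = check_mass_charge_balance(
            rxn, self._table(**{"h2o@c": "H2O", "h2@c": "H2", "o2@c": "O2"})
        )
        assert rep.verdict == "balanced"

    def test_hydrogen_imbalance_reported(self):
        rxn = Reaction(id="R", stoichiometry={"a@c": -1.0, "b@c": 1.0})
        rep = check_mass_charge_balance(rxn, self._table(**{"a@c": "CH4", "b@c": "CH3"}))
        assert rep.verdict == "imbalanced"
        assert rep.element_imbalance == {"H": -1.0}

    def test_missing_formula_is_undetermined(self):
        rxn = Reaction(id="R", stoichiometry={"a@c": -1.0, "b@c": 1.0})
        table = self._table(**{"a@c": "CH4", "b@c": ""})
        assert check_mass_charge_balance(rxn, table).verdict == "undetermined"

    def test_boundary_reactions_exempt(self):
        rxn = Reaction(id="EX_a", stoichiometry={"a@e": -1.0}, kind="exchange")
        assert check_mass_charge_balance(rxn, self._table(**{"a@e": "CH4"})).verdict == "exempt"

    def test_unparsable_formula(self):
        with pytest.raises(FormulaError):
            parse_formula("C6(H2O)n")
        rxn = Reaction(id="R", stoichiometry={"a@c": -1.0, "b@c": 1.0})
        rep = check_mass_charge_balance(rxn, self._table(**{"a@c": "C6(H2O)n", "b@c": "C"}))
        assert rep.verdict == "undetermined"

    def test_agrees_with_integer_arithmetic_on_random_stoichiometries(self):
        rng = np.random.default_rng(7)
        elements = ["C", "H", "O", "N"]
        for _ in range(10):
            n = int(rng.integers(2, 5))
            comp = {}
            table = {}
            for i in range(n):
                counts = {e: int(rng.integers(0, 5)) for e in elements}
                counts["C"] = max(counts["C"], 1)
                formula = "".join(f"{e}{c}" for e, c in counts.items() if c)
                mid = f"m{i}@c"
                table[mid] = Metabolite(id=mid, formula=formula, charge=0)
                comp[mid] = counts
            stoich = {mid: float(rng.integers(-3, 4)) or 1.0 for mid in table}
            expected = {
                e: sum(stoich[mid] * comp[mid][e] for mid in table) for e in elements
            }
            expected = {e: v for e, v in expected.items() if v != 0}
            rep = check_mass_charge_balance(Reaction(id="R", stoichiometry=stoich), table)
            assert rep.element_imbalance == expected
            assert rep.balanced is (not expected)


class TestStatsAndValidation:
    def test_stats_counts(self, chain_model):
        s = model_stats(chain_model)
        assert s.n_metabolites == 3
        assert s.n_reactions == 3
        assert s.n_dead_ends == 1

    def test_frac_without_gpr_over_internal_reactions(self):
        model = make_model(
            "g",
            reactions=[
                Reaction(id=f"R{i}", stoichiometry={"a@c": -1.0, "b@c": 1.0},
                         gpr="g1" if i else "")
                for i in range(4)
            ]
            + [Reaction(id="EX_a", stoichiometry={"a@e": -1.0}, kind="exchange")],
        )
        assert model_stats(model).frac_reactions_without_gpr == 0.25

    def test_empty_model_stats(self):
        s = model_stats(Model(id="empty"))
        assert (s.n_reactions, s.n_metabolites, s.n_genes, s.n_dead_ends) == (0, 0, 0, 0)

    def test_undeclared_metabolite_fails_validation(self):
        model = Model(id="bad")
        model.add_reaction(Reaction(id="R", stoichiometry={"ghost@c": -1.0, "b@c": 1.0}))
        with pytest.raises(ValidationError, match="ghost"):
            model.validate()

    def test_exchange_with_two_metabolites_fails_validation(self):
        model = make_model(
            "bad2",
            reactions=[("EX_x", {"a@e": -1.0, "b@e": 1.0}, -10.0, 10.0, "exchange")],
        )
        with pytest.raises(ValidationError, match="exactly one"):
            model.validate()


class TestKindInference:
    @pytest.mark.parametrize(
        "rid,stoich,expected",
        [
            ("EX_glc", {"glc@e": -1.0}, "exchange"),
            ("SK_ac", {"ac@e": -1.0}, "sink"),
            ("T_glc", {"glc@e": -1.0, "glc@c": 1.0}, "transport"),
            ("R_pgi", {"g6p@c": -1.0, "f6p@c": 1.0}, "internal"),
            ("biomass_core", {"atp@c": -1.0}, "biomass"),
        ],
    )
    def test_prefix_and_structure_rules(self, rid, stoich, expected):
        assert infer_reaction_kind(Reaction(id=rid, stoichiometry=stoich)) == expected

    def test_objective_wins(self):
        rxn = Reaction(id="R_growth", stoichiometry={"a@c": -1.0})
        assert infer_reaction_kind(rxn, objective="R_growth") == "biomass"
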