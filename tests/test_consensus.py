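"""Consensus merging: stripping, duplicate detection, merge invariants."""

import pytest

from comgem.consensus import (
    canonical_stoichiometry,
    consensus_dead_end_audit,
    direction_free_digest,
    merge_models,
    reactions_equivalent,
    strip_boundary_and_biomass,
)
from comgem.core import (
    DEFAULT_BOUND,
    Model,
    Reaction,
    find_dead_end_metabolites,
    gprs_equivalent,
)
from comgem.namespace import translate_model
from comgem.namespace import NamespaceMap
from comgem.synth import (
    default_profiles,
    derive_complementary_views,
    generate_truth_network,
)

from conftest import make_model


def R(rid, stoich, lb=0.0, ub=DEFAULT_BOUND, gpr="", kind="internal"):
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    gpr=gpr, kind=kind)


class TestStrip:
    def test_boundary_and_biomass_removed(self):
        model = make_model(
            "m",
            reactions=[
                ("EX_A", {"A@e": -1.0}, -10.0, 10.0, "exchange"),
                ("SK_B", {"B@e": -1.0}, 0.0, 10.0, "sink"),
                ("bio", {"A@e": -1.0}, 0.0, 10.0, "biomass"),
                ("R1", {"A@e": -1.0, "B@e": 1.0}, 0.0, 10.0, "internal"),
            ],
            objective="bio",
        )
        stripped = strip_boundary_and_biomass(model)
        assert set(stripped.reactions) == {"R1"}
        assert stripped.objective is None

    def test_idempotent_on_clean_model(self):
        model = make_model("m", reactions=[("R1", {"A@c": -1.0, "B@c": 1.0}, 0.0, 10.0, "internal")])
        assert set(strip_boundary_and_biomass(model).reactions) == {"R1"}

    def test_empty_model(self):
        assert strip_boundary_and_biomass(Model(id="e")).reactions == {}


class TestEquivalence:
    def test_same_composition_different_ids(self):
        r1 = R("x", {"A@c": -1.0, "B@c": -1.0, "C@c": 1.0})
        r2 = R("y", {"A@c": -1.0, "B@c": -1.0, "C@c": 1.0})
        assert reactions_equivalent(r1, r2) == "duplicate"

    def test_scaled_coefficients_are_duplicates(self):
        r1 = R("x", {"A@c": -2.0, "B@c": 2.0})
        r2 = R("y", {"A@c": -1.0, "B@c": 1.0})
        assert reactions_equivalent(r1, r2) == "duplicate"

    def test_reversed(self):
        r1 = R("x", {"A@c": -1.0, "B@c": 1.0})
        r2 = R("y", {"B@c": -1.0, "A@c": 1.0})
        assert reactions_equivalent(r1, r2) == "duplicate_reversed"

    def test_distinct(self):
        r1 = R("x", {"A@c": -1.0, "B@c": 1.0})
        r2 = R("y", {"A@c": -1.0, "C@c": 1.0})
        assert reactions_equivalent(r1, r2) == "distinct"

    def test_canonical_handles_fractional_coefficients(self):
        c1 = canonical_stoichiometry({"A@c": -0.5, "B@c": 1.5})
        c2 = canonical_stoichiometry({"A@c": -1.0, "B@c": 3.0})
        assert c1 == c2


class TestMerge:
    def test_merge_with_itself_is_idempotent(self):
        m = make_model(
            "m", tool="carveme",
            reactions=[
                R("R1", {"A@c": -1.0, "B@c": 1.0}, gpr="g1"),
                R("R2", {"B@c": -1.0, "C@c": 1.0}, gpr="g2 and g3"),
            ],
        )
        merged, _ = merge_models([m, m.copy()])
        assert set(merged.reactions) == set(m.reactions)
        for rid in m.reactions:
            assert merged.reactions[rid].stoichiometry == m.reactions[rid].stoichiometry
            assert gprs_equivalent(merged.reactions[rid].gpr, m.reactions[rid].gpr)
        assert merged.genes == m.genes

    def test_disjoint_views_sum_reactions(self):
        m1 = make_model("m", tool="carveme", reactions=[R("R1", {"A@c": -1.0, "B@c": 1.0})])
        m2 = make_model("m", tool="gapseq", reactions=[R("R2", {"C@c": -1.0, "D@c": 1.0})])
        merged, report = merge_models([m1, m2])
        assert len(merged.reactions) == 2
        assert report.per_view["gapseq"]["added"] == 1

    def test_direction_union_and_gpr_or(self):
        m1 = make_model(
            "m", tool="carveme",
            reactions=[R("R1", {"A@c": -1.0, "B@c": 1.0}, lb=0.0, gpr="g1")],
        )
        m2 = make_model(
            "m", tool="gapseq",
            reactions=[R("Rother", {"A@c": -1.0, "B@c": 1.0}, lb=-DEFAULT_BOUND, gpr="g2")],
        )
        merged, _ = merge_models([m1, m2])
        (rxn,) = merged.reactions.values()
        assert rxn.lower_bound == -DEFAULT_BOUND and rxn.upper_bound == DEFAULT_BOUND
        assert gprs_equivalent(rxn.gpr, "g1 or g2")
        assert rxn.source_tools == {"carveme", "gapseq"}

    def test_reversed_duplicate_merged_as_reversible(self):
        m1 = make_model("m", tool="carveme", reactions=[R("fwd", {"A@c": -1.0, "B@c": 1.0})])
        m2 = make_model("m", tool="kbase", reactions=[R("bwd", {"B@c": -1.0, "A@c": 1.0})])
        merged, report = merge_models([m1, m2])
        (rxn,) = merged.reactions.values()
        assert rxn.id == "fwd"
        assert rxn.lower_bound < 0 < rxn.upper_bound
        assert report.per_view["kbase"]["merged_reversed"] == 1

    def test_gene_union_exact(self):
        m1 = make_model("m", tool="a", reactions=[R("R1", {"A@c": -1.0, "B@c": 1.0}, gpr="g1")])
        m2 = make_model("m", tool="b", reactions=[R("R2", {"B@c": -1.0, "C@c": 1.0}, gpr="g2 or g3")])
        merged, _ = merge_models([m1, m2])
        assert merged.genes == {"g1", "g2", "g3"}

    def test_empty_view_list_raises(self):
        with pytest.raises(ValueError):
            merge_models([])

    def test_content_digest_order_insensitive(self):
        views = []
        for tool, rxns in (
            ("a", [R("R1", {"A@c": -1.0, "B@c": 1.0}), R("R2", {"B@c": -1.0, "C@c": 1.0})]),
            ("b", [R("R3", {"B@c": 1.0, "A@c": -1.0}), R("R4", {"C@c": -1.0, "D@c": 1.0})]),
            ("c", [R("R5", {"C@c": 1.0, "B@c": -1.0})]),
        ):
            views.append(make_model("m", tool=tool, reactions=rxns))
        digests = []
        for order in ([0, 1, 2], [2, 1, 0], [1, 0, 2]):
            merged, _ = merge_models([views[i].copy() for i in order])
            digests.append(
                frozenset(direction_free_digest(r.stoichiometry) for r in merged.reactions.values())
            )
        assert digests[0] == digests[1] == digests[2]


class TestAudit:
    def test_dead_end_healed_by_second_view(self):
        # view1: B -> C with no consumer of C; view2 consumes C
        v1 = make_model("m", tool="a", reactions=[R("R1", {"B@c": -1.0, "C@c": 1.0})])
        v2 = make_model("m", tool="b", reactions=[R("R2", {"C@c": -1.0, "D@c": 1.0})])
        assert "C@c" in find_dead_end_metabolites(v1)
        merged, _ = merge_models([v1, v2])
        assert "C@c" not in find_dead_end_metabolites(merged)
        audit = consensus_dead_end_audit([v1, v2], merged)
        assert audit.passed

    def test_single_view_merge_keeps_dead_ends(self):
        v1 = make_model("m", tool="a", reactions=[R("R1", {"B@c": -1.0, "C@c": 1.0})])
        merged, _ = merge_models([v1])
        assert find_dead_end_metabolites(merged) == find_dead_end_metabolites(v1)
        assert consensus_dead_end_audit([v1], merged).passed

    def test_audit_detects_missing_genes(self):
        v1 = make_model("m", tool="a", reactions=[R("R1", {"A@c": -1.0, "B@c": 1.0}, gpr="g1")])
        merged, _ = merge_models([v1])
        merged.genes.discard("g1")
        assert not consensus_dead_end_audit([v1], merged).passed


class TestSeededTriples:
    """Merge invariants on generated tool-view triples."""

    @pytest.mark.parametrize("seed", range(5))
    def test_invariants_hold(self, seed):
        fx = generate_truth_network(n_branch_pathways=3, branch_length=3, seed=seed)
        per_tool = derive_complementary_views(
            fx.truth, default_profiles(), seed=seed, core_reaction_ids=fx.core_reaction_ids
        )
        views = []
        for tool, (view, table) in sorted(per_tool.items()):
            ns = NamespaceMap(
                met_map=dict(zip(
                    table[table["kind"] == "metabolite"]["source_id"],
                    table[table["kind"] == "metabolite"]["common_id"],
                )),
                rxn_map=dict(zip(
                    table[table["kind"] == "reaction"]["source_id"],
                    table[table["kind"] == "reaction"]["common_id"],
                )),
            )
            translated, _ = translate_model(view, ns)
            views.append(strip_boundary_and_biomass(translated))
        consensus, _ = merge_models(views)
        audit = consensus_dead_end_audit(views, consensus)
        assert audit.passed
        assert consensus.genes == set().union(*(v.genes for v in views))
        # complementary dropout: the consensus interior is complete, each view
        # carries at least one dropout-induced dead end the others heal
        n_consensus = len(find_dead_end_metabolites(consensus))
        for view in views:
            assert n_consensus < len(find_dead_end_metabolites(view))
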