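"""Gap-filling: MILP minimality, permeability prediction, iterative medium
augmentation, and abundance correlation."""

import itertools

import numpy as np
import pytest

from comgem.core import DEFAULT_BOUND, Metabolite, Model, Reaction
from comgem.errors import (
    GapfillInfeasibleError,
    InfeasibleError,
    UndefinedStatisticError,
)
from comgem.fluxes import Medium, fba, fva
from comgem.gapfill import (
    Community,
    GapfillResult,
    add_universal_biomass,
    correlate_abundance_with_gapfill,
    gapfill_model,
    iterative_community_gapfill,
    predict_permeable_metabolites,
)
from comgem.synth import cross_feeding_pair, random_gapfill_instance

from conftest import make_model


def exhaustive_min_gapfill(model, db, medium, epsilon):
    """Independent oracle: smallest feasible candidate subset by brute-force
    enumeration in order of increasing size, feasibility checked by LP."""
    cand_ids = sorted(set(db.reactions) - set(model.reactions))
    for size in range(len(cand_ids) + 1):
        for subset in itertools.combinations(cand_ids, size):
            trial = model.copy()
            for rid in subset:
                rxn = db.reactions[rid]
                for mid in rxn.stoichiometry:
                    if mid not in trial.metabolites:
                        met = db.metabolites.get(mid)
                        trial.add_metabolite(met.copy() if met else Metabolite(id=mid))
                trial.add_reaction(rxn.copy())
            _open_boundaries(trial, medium)
            try:
                if fba(trial, medium).objective_value >= epsilon - 1e-9:
                    return set(subset)
            except InfeasibleError:
                continue
    return None


def _open_boundaries(model, medium):
    """Mirror the gap-filler's environment: free medium exchanges and free
    secretion valves for otherwise boundary-less extracellular metabolites."""
    from comgem.core import split_compartment

    for mid in medium.uptake:
        if mid not in model.metabolites:
            continue
        rid = f"EX_{split_compartment(mid)[0]}"
        if rid not in model.reactions:
            model.add_reaction(
                Reaction(id=rid, stoichiometry={mid: -1.0},
                         lower_bound=-medium.uptake[mid], upper_bound=DEFAULT_BOUND,
                         kind="exchange")
            )
    drained = set()
    for rxn in model.reactions.values():
        if rxn.kind in ("exchange", "sink") and rxn.upper_bound > 0:
            drained |= set(rxn.stoichiometry)
    for mid in sorted(model.extracellular_metabolites() - drained):
        model.add_reaction(
            Reaction(id=f"SK_{split_compartment(mid)[0]}", stoichiometry={mid: -1.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="sink")
        )


class TestUniversalBiomass:
    def test_sets_objective(self):
        model = make_model("m", metabolites=["ATP@c", "ADP@c"])
        out = add_universal_biomass(model, {"ATP@c": -1.0, "ADP@c": 1.0, "BIOM@c": 1.0})
        assert out.objective == "bio_universal"
        assert "BIOM@c" in out.metabolites

    def test_replaces_existing_biomass(self):
        model = make_model(
            "m", reactions=[("old_bio", {"X@c": -1.0}, 0.0, 10.0, "biomass")],
            objective="old_bio",
        )
        out = add_universal_biomass(model, {"X@c": -1.0})
        assert "old_bio" not in out.reactions
        assert len(out.reactions_of_kind("biomass")) == 1

    def test_empty_spec_raises(self):
        with pytest.raises(ValueError):
            add_universal_biomass(Model(id="m"), {})


class TestGapfillModel:
    def _missing_link_setup(self):
        model = make_model(
            "m",
            reactions=[
                ("T_glc", {"glc@e": -1.0, "glc@c": 1.0}, 0.0, DEFAULT_BOUND, "transport"),
            ],
        )
        model = add_universal_biomass(model, {"B@c": -1.0})
        db = make_model(
            "db",
            reactions=[
                ("R_fix", {"glc@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_irrelevant", {"junk@c": -1.0, "junk2@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ],
        )
        return model, db, Medium({"glc@e": 10.0})

    def test_unique_feasible_singleton(self):
        model, db, medium = self._missing_link_setup()
        augmented, result = gapfill_model(model, db, medium)
        assert result.added_reactions == {"R_fix"}
        assert result.growth >= 0.05
        assert fba(augmented, medium).objective_value >= 0.05

    def test_added_reactions_have_empty_gpr(self):
        model, db, medium = self._missing_link_setup()
        db.reactions["R_fix"].gpr = "gX"  # genetic support must not leak in
        augmented, result = gapfill_model(model, db, medium)
        for rid in result.added_reactions:
            assert augmented.reactions[rid].gpr == ""

    def test_shorter_path_preferred(self):
        # db offers a 1-reaction route and a 2-reaction route to B
        model = make_model(
            "m",
            reactions=[("T", {"glc@e": -1.0, "glc@c": 1.0}, 0.0, DEFAULT_BOUND, "transport")],
        )
        model = add_universal_biomass(model, {"B@c": -1.0})
        db = make_model(
            "db",
            reactions=[
                ("R_direct", {"glc@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_step1", {"glc@c": -1.0, "I@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_step2", {"I@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_junk1", {"I@c": -1.0, "J@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_junk2", {"J@c": -1.0, "K@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ],
        )
        medium = Medium({"glc@e": 10.0})
        _, result = gapfill_model(model, db, medium)
        assert result.added_reactions == {"R_direct"}
        oracle = exhaustive_min_gapfill(model, db, medium, 0.05)
        assert len(result.added_reactions) == len(oracle)

    def test_infeasible_names_blocked_precursor(self):
        model = make_model(
            "m",
            reactions=[("T", {"glc@e": -1.0, "glc@c": 1.0}, 0.0, DEFAULT_BOUND, "transport")],
        )
        model = add_universal_biomass(model, {"B@c": -1.0, "unreachable@c": -1.0})
        db = make_model(
            "db",
            reactions=[("R_fix", {"glc@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal")],
        )
        with pytest.raises(GapfillInfeasibleError) as err:
            gapfill_model(model, db, Medium({"glc@e": 10.0}))
        assert "unreachable@c" in err.value.blocked_precursors
        assert "B@c" not in err.value.blocked_precursors

    def test_lexicographic_tie_break(self):
        # two interchangeable singleton solutions: the smaller id wins
        model = make_model(
            "m",
            reactions=[("T", {"glc@e": -1.0, "glc@c": 1.0}, 0.0, DEFAULT_BOUND, "transport")],
        )
        model = add_universal_biomass(model, {"B@c": -1.0})
        db = make_model(
            "db",
            reactions=[
                ("R_zz", {"glc@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("R_aa", {"glc@c": -1.0, "B@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ],
        )
        _, result = gapfill_model(model, db, Medium({"glc@e": 10.0}))
        assert result.added_reactions == {"R_aa"}

    @pytest.mark.parametrize("seed", range(8))
    def test_milp_weight_matches_exhaustive_minimum(self, seed):
        model, db, medium, epsilon = random_gapfill_instance(seed)
        _, result = gapfill_model(model, db, medium, epsilon=epsilon)
        oracle = exhaustive_min_gapfill(model, db, medium, epsilon)
        assert oracle is not None
        assert len(result.added_reactions) == len(oracle)


class TestPermeable:
    def test_obligate_byproduct_is_permeable(self):
        model = make_model(
            "m",
            reactions=[
                ("EX_S", {"S@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
                ("T", {"S@e": -1.0, "X@c": 1.0, "D@e": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
                ("SK_D", {"D@e": -1.0}, 0.0, DEFAULT_BOUND, "sink"),
            ],
        )
        model = add_universal_biomass(model, {"X@c": -1.0})
        assert "D@e" in predict_permeable_metabolites(model, Medium({"S@e": 10.0}))

    def test_unconnected_metabolite_not_permeable(self):
        model = make_model(
            "m",
            metabolites=["orphan@e"],
            reactions=[
                ("EX_S", {"S@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
                ("T", {"S@e": -1.0, "X@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ],
        )
        model = add_universal_biomass(model, {"X@c": -1.0})
        assert "orphan@e" not in predict_permeable_metabolites(model, Medium({"S@e": 10.0}))

    def test_medium_component_passthrough_not_counted(self):
        model = make_model(
            "m",
            reactions=[
                ("EX_S", {"S@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
                ("T", {"S@e": -1.0, "X@c": 1.0}, 0.0, DEFAULT_BOUND, "internal"),
            ],
        )
        model = add_universal_biomass(model, {"X@c": -1.0})
        assert "S@e" not in predict_permeable_metabolites(model, Medium({"S@e": 10.0}))

    def test_tolerance_excludes_capped_secretion(self):
        # secretion capacity exists but is capped below tol by the sink bound
        model = make_model(
            "m",
            reactions=[
                ("EX_S", {"S@e": -1.0}, -10.0, DEFAULT_BOUND, "exchange"),
                ("T", {"S@e": -1.0, "X@c": 1.0, "D@e": 0.5}, 0.0, DEFAULT_BOUND, "internal"),
                ("SK_D", {"D@e": -1.0}, 0.0, DEFAULT_BOUND, "sink"),
            ],
        )
        model = add_universal_biomass(model, {"X@c": -1.0})
        medium = Medium({"S@e": 10.0})
        hi = fva(model, medium, reactions=["SK_D"])["SK_D"][1]  # independent LP maximum
        assert "D@e" in predict_permeable_metabolites(model, medium, tol=hi / 2)
        assert "D@e" not in predict_permeable_metabolites(model, medium, tol=hi * 2)

    def test_non_growing_model_raises(self):
        model = make_model(
            "m",
            reactions=[("T", {"S@e": -1.0, "X@c": 1.0}, 0.0, DEFAULT_BOUND, "transport")],
        )
        model = add_universal_biomass(model, {"X@c": -1.0})
        with pytest.raises(InfeasibleError):
            predict_permeable_metabolites(model, Medium({"other@e": 1.0}))


class TestIterative:
    def test_cross_feeding_cheaper_in_descending_order(self):
        base, donor, recipient = cross_feeding_pair(seed=0)
        abundance = {"donor": 10.0, "recipient": 1.0}
        added = {}
        for order in ("descending", "ascending"):
            community = Community(
                members=[("donor", donor.copy()), ("recipient", recipient.copy())],
                abundance=abundance, order=order,
            )
            results, final, _ = iterative_community_gapfill(
                community, base.rich_medium, base.minimal_medium, base.universal_db
            )
            by_mag = {r.mag_id: r for r in results}
            assert all(r.feasible for r in results)
            added[order] = len(by_mag["recipient"].added_reactions)
            # medium monotonicity: the final medium contains the base medium
            assert set(base.minimal_medium.uptake) <= set(final.uptake)
        assert added["descending"] < added["ascending"]

    def test_cross_fed_metabolite_imported_by_dependent_member(self):
        base, donor, recipient = cross_feeding_pair(seed=0)
        community = Community(
            members=[("donor", donor), ("recipient", recipient)],
            abundance={"donor": 10.0, "recipient": 1.0}, order="descending",
        )
        results, final, models = iterative_community_gapfill(
            community, base.rich_medium, base.minimal_medium, base.universal_db
        )
        recipient_res = [r for r in results if r.mag_id == "recipient"][0]
        assert recipient_res.imported & set(base.byproducts.values())
        assert set(base.byproducts.values()) <= set(final.uptake)

    def test_single_member_reduces_to_plain_gapfill(self):
        base, donor, _ = cross_feeding_pair(seed=0)
        community = Community(members=[("donor", donor.copy())],
                              abundance={"donor": 1.0}, order="descending")
        results, _, _ = iterative_community_gapfill(
            community, base.rich_medium, base.minimal_medium, base.universal_db
        )
        _, direct = gapfill_model(donor.copy(), base.universal_db, base.rich_medium)
        assert results[0].added_reactions == direct.added_reactions

    def test_infeasible_member_recorded_not_fatal(self):
        base, donor, recipient = cross_feeding_pair(seed=0)
        doomed = donor.copy()
        doomed.id = "doomed"
        biomass = doomed.reactions[doomed.objective]
        doomed.add_metabolite(Metabolite(id="nowhere@c"))
        biomass.stoichiometry["nowhere@c"] = -1.0
        community = Community(
            members=[("doomed", doomed), ("recipient", recipient)],
            abundance={"doomed": 10.0, "recipient": 1.0}, order="descending",
        )
        results, _, _ = iterative_community_gapfill(
            community, base.rich_medium, base.minimal_medium, base.universal_db
        )
        by_mag = {r.mag_id: r for r in results}
        assert not by_mag["doomed"].feasible
        assert by_mag["recipient"].feasible  # pipeline continued


class TestCorrelation:
    def _results(self, counts):
        return [
            GapfillResult(mag_id=f"m{i}", added_reactions={f"r{j}" for j in range(c)})
            for i, c in enumerate(counts)
        ]

    def test_proportional_counts_give_r_one(self):
        abundance = {f"m{i}": float(i + 1) for i in range(4)}
        r, p = correlate_abundance_with_gapfill(self._results([2, 4, 6, 8]), abundance)
        assert r == pytest.approx(1.0)

    def test_constant_counts_raise(self):
        abundance = {f"m{i}": float(i + 1) for i in range(4)}
        with pytest.raises(UndefinedStatisticError):
            correlate_abundance_with_gapfill(self._results([3, 3, 3, 3]), abundance)

    def test_matches_closed_form_on_hand_dataset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        abundance = {f"m{i}": x[i] for i in range(5)}
        r, _ = correlate_abundance_with_gapfill(self._results(y.astype(int)), abundance)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)
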