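"""Synthetic ground-truth networks and reconstruction-tool degradations.

The generator builds small but fully functional metabolic networks with the
structural signatures seen when one genome is reconstructed by several
automated tools: a shared true network, per-tool "views" that differ in
identifier namespace, reaction/gene content, GPR associations, and dead-end
metabolite counts, plus the surrounding artefacts a community analysis
needs (universal reaction database, rich/minimal media, abundance vector,
namespace cross-reference tables, universal biomass composition).

Truth-network layout (all element-balanced C/H/O/N/Mg bookkeeping):

    glc@e --EX/T--> glc@c --core chain--> hub
    hub --branch j--> prec_j@c  (+ byproduct byp_j@c --T--> byp_j@e --SK-->)
    biomass: sum_j prec_j + nh4 + mg

Every branch emits a secretable byproduct, and the universal database
contains, besides the true reactions and decoys, an uptake transporter and
a salvage reaction per byproduct (2 byp_j -> prec_j), so a member whose
branch j was deleted can be repaired either de novo (branch_length
reactions) or — more cheaply — by cross-feeding on another member's
byproduct. Tool-view profiles default to the qualitative ordering reported
for real reconstructions: the gapseq-like profile keeps the most reactions
but gains the most spurious dead ends, the carveme-like profile retains the
most gene associations, the kbase-like profile loses the most reactions.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .core import DEFAULT_BOUND, Metabolite, Model, Reaction
from .fluxes import Medium
from .io import write_model

#: EC subclass alphabet and sampling weights used for reaction annotation.
EC_SUBCLASSES = ("1.1", "2.3", "2.7", "4.2", "3.1")
EC_WEIGHTS = (0.3, 0.25, 0.2, 0.15, 0.1)


@dataclass
class ToolProfile:
    """Degradation profile emulating one reconstruction tool."""

    namespace_label: str
    reaction_dropout_prob: float = 0.1
    gene_dropout_prob: float = 0.1
    extra_deadend_reactions: int = 2
    gpr_rewire_prob: float = 0.05

    def __post_init__(self):
        for p in (self.reaction_dropout_prob, self.gene_dropout_prob, self.gpr_rewire_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.extra_deadend_reactions < 0:
            raise ValueError("extra_deadend_reactions must be non-negative")


def default_profiles() -> Dict[str, ToolProfile]:
    """Profiles reproducing the qualitative inter-tool signatures:
    gapseq-like has most reactions and most dead ends, carveme-like has the
    most genes, kbase-like drops the most reactions."""
    return {
        "carveme": ToolProfile(
            "bigg", reaction_dropout_prob=0.18, gene_dropout_prob=0.03,
            extra_deadend_reactions=2, gpr_rewire_prob=0.02,
        ),
        "gapseq": ToolProfile(
            "modelseed", reaction_dropout_prob=0.04, gene_dropout_prob=0.30,
            extra_deadend_reactions=12, gpr_rewire_prob=0.05,
        ),
        "kbase": ToolProfile(
            "seed", reaction_dropout_prob=0.30, gene_dropout_prob=0.15,
            extra_deadend_reactions=2, gpr_rewire_prob=0.05,
        ),
    }


@dataclass
class TruthFixture:
    """A ground-truth network plus everything needed to run the pipeline."""

    truth: Model
    biomass_spec: Dict[str, float]
    universal_db: Model
    rich_medium: Medium
    minimal_medium: Medium
    core_reaction_ids: Set[str] = field(default_factory=set)
    branch_reaction_ids: Dict[int, List[str]] = field(default_factory=dict)
    byproducts: Dict[int, str] = field(default_factory=dict)


def _sample_ec(rng) -> str:
    sub = rng.choice(EC_SUBCLASSES, p=EC_WEIGHTS)
    return f"{sub}.{rng.integers(1, 20)}.{rng.integers(1, 99)}"


def _fresh_gpr(rng, counter: List[int]) -> str:
    def gene():
        counter[0] += 1
        return f"g{counter[0]:03d}"

    pattern = rng.random()
    if pattern < 0.5:
        return gene()
    if pattern < 0.8:
        return f"{gene()} and {gene()}"
    return f"({gene()} and {gene()}) or {gene()}"


def generate_truth_network(
    n_branch_pathways: int = 4,
    branch_length: int = 4,
    seed: int = 0,
) -> TruthFixture:
    """Build a connected, growth-capable, dead-end-free truth network.

    ``n_branch_pathways`` biosynthetic branches of ``branch_length``
    reactions each hang off a linear core pathway; every branch yields one
    biomass precursor and one secretable byproduct. Deterministic for a
    fixed seed.
    """
    if n_branch_pathways < 1 or branch_length < 1:
        raise ValueError("n_branch_pathways and branch_length must be >= 1")
    rng = np.random.default_rng(seed)
    gene_counter = [0]
    model = Model(id="truth", tool="synthetic")

    def met(mid, formula="", charge=0):
        if mid not in model.metabolites:
            model.add_metabolite(Metabolite(id=mid, formula=formula, charge=charge))
        return mid

    def rxn(rid, stoich, lb, ub, kind, with_gpr=True, with_ec=True):
        r = Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub, kind=kind,
            gpr=_fresh_gpr(rng, gene_counter) if with_gpr else "",
            ec_numbers=(_sample_ec(rng),) if with_ec else (),
        )
        model.add_reaction(r)
        return rid

    core_ids: Set[str] = set()
    # nutrients: glucose (carbon), ammonium-like nitrogen, magnesium
    for base, formula in (("glc", "C6H12O6"), ("nh4", "H3N"), ("mg", "Mg")):
        met(f"{base}@e", formula)
        met(f"{base}@c", formula)
        core_ids.add(rxn(f"EX_{base}", {f"{base}@e": -1.0}, -10.0, DEFAULT_BOUND,
                         "exchange", with_gpr=False, with_ec=False))
        core_ids.add(rxn(f"T_{base}", {f"{base}@e": -1.0, f"{base}@c": 1.0},
                         0.0, DEFAULT_BOUND, "transport", with_ec=False))
    # linear core pathway glc@c -> core_1 -> ... -> hub
    prev = "glc@c"
    for i in range(1, branch_length + 1):
        cur = met(f"core_{i}@c", "C6H12O6")
        core_ids.add(rxn(f"R_core_{i}", {prev: -1.0, cur: 1.0}, 0.0, DEFAULT_BOUND, "internal"))
        prev = cur
    hub = prev
    # branches: hub -> ... -> prec_j, splitting off byproduct byp_j
    branch_ids: Dict[int, List[str]] = {}
    byproducts: Dict[int, str] = {}
    biomass_spec: Dict[str, float] = {"nh4@c": -1.0, "mg@c": -0.1}
    for j in range(1, n_branch_pathways + 1):
        byp_c = met(f"byp_{j}@c", "C2H4O2")
        byp_e = met(f"byp_{j}@e", "C2H4O2")
        prec = met(f"prec_{j}@c", "C4H8O4")
        ids = []
        if branch_length == 1:
            ids.append(rxn(f"R_b{j}_split", {hub: -1.0, prec: 1.0, byp_c: 1.0},
                           0.0, DEFAULT_BOUND, "internal"))
        else:
            first = met(f"b{j}_1@c", "C4H8O4")
            ids.append(rxn(f"R_b{j}_split", {hub: -1.0, first: 1.0, byp_c: 1.0},
                           0.0, DEFAULT_BOUND, "internal"))
            prev_b = first
            for i in range(2, branch_length):
                cur_b = met(f"b{j}_{i}@c", "C4H8O4")
                ids.append(rxn(f"R_b{j}_{i}", {prev_b: -1.0, cur_b: 1.0},
                               0.0, DEFAULT_BOUND, "internal"))
                prev_b = cur_b
            ids.append(rxn(f"R_b{j}_final", {prev_b: -1.0, prec: 1.0},
                           0.0, DEFAULT_BOUND, "internal"))
        # byproduct secretion machinery
        ids_t = rxn(f"T_byp_{j}", {byp_c: -1.0, byp_e: 1.0}, 0.0, DEFAULT_BOUND,
                    "transport", with_ec=False)
        rxn(f"SK_byp_{j}", {byp_e: -1.0}, 0.0, DEFAULT_BOUND, "sink",
            with_gpr=False, with_ec=False)
        ids.append(ids_t)
        branch_ids[j] = ids
        byproducts[j] = f"byp_{j}@e"
        biomass_spec[prec] = -1.0
    biomass_id = rxn("bio_truth", dict(biomass_spec), 0.0, DEFAULT_BOUND, "biomass",
                     with_gpr=False, with_ec=False)
    model.objective = biomass_id
    core_ids.add(biomass_id)

    db = _build_universal_db(model, n_branch_pathways, rng)
    rich = Medium({"glc@e": 20.0, "nh4@e": 20.0, "mg@e": 20.0})
    minimal = Medium({"glc@e": 10.0, "nh4@e": 10.0, "mg@e": 10.0})
    return TruthFixture(
        truth=model,
        biomass_spec=dict(biomass_spec),
        universal_db=db,
        rich_medium=rich,
        minimal_medium=minimal,
        core_reaction_ids=core_ids,
        branch_reaction_ids=branch_ids,
        byproducts=byproducts,
    )


def _build_universal_db(truth: Model, n_branches: int, rng) -> Model:
    """Universal reaction database: the true internal/transport reactions
    (GPR-stripped), per-byproduct salvage routes, and connected decoys."""
    db = Model(id="universal_db", tool="synthetic")
    for met_ in truth.metabolites.values():
        db.add_metabolite(met_.copy())
    for rxn_ in truth.reactions_of_kind("internal", "transport"):
        cand = rxn_.copy()
        cand.gpr = ""
        db.add_reaction(cand)
    for j in range(1, n_branches + 1):
        db.add_reaction(
            Reaction(id=f"T_byp_{j}_in", stoichiometry={f"byp_{j}@e": -1.0, f"byp_{j}@c": 1.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport")
        )
        db.add_reaction(
            Reaction(id=f"R_salvage_{j}", stoichiometry={f"byp_{j}@c": -2.0, f"prec_{j}@c": 1.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal",
                     ec_numbers=(_sample_ec(rng),))
        )
    # decoys: carbon drains and db-only chains that never help biomass
    for k in range(1, n_branches + 3):
        dmet = f"dmet_{k}@c"
        db.add_metabolite(Metabolite(id=dmet, formula="C3H6O3"))
        db.add_reaction(
            Reaction(id=f"R_decoy_{k}", stoichiometry={"core_1@c": -1.0, dmet: 2.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal",
                     ec_numbers=(_sample_ec(rng),))
        )
    return db


# ---------------------------------------------------------------------------
# Tool views
# ---------------------------------------------------------------------------

def build_namespace_rename(truth: Model, label: str, seed: int) -> Dict[str, Dict[str, str]]:
    """Deterministic common-id -> tool-source-id rename maps for one tool."""
    rng = np.random.default_rng(seed)
    met_bases = sorted({m.base_id for m in truth.metabolites.values()})
    rxn_ids = sorted(truth.reactions)
    met_order = rng.permutation(len(met_bases))
    rxn_order = rng.permutation(len(rxn_ids))
    return {
        "metabolite": {b: f"{label}_m{met_order[i]:05d}" for i, b in enumerate(met_bases)},
        "reaction": {r: f"{label}_r{rxn_order[i]:05d}" for i, r in enumerate(rxn_ids)},
    }


def namespace_table(rename: Dict[str, Dict[str, str]], label: str) -> pd.DataFrame:
    rows = [
        {"source_namespace": label, "source_id": src, "common_id": common, "kind": kind}
        for kind in ("metabolite", "reaction")
        for common, src in sorted(rename[kind].items())
    ]
    return pd.DataFrame(rows, columns=["source_namespace", "source_id", "common_id", "kind"])


def derive_tool_view(
    truth: Model,
    profile: ToolProfile,
    seed: int,
    protected_reactions: Optional[Set[str]] = None,
    rename: Optional[Dict[str, Dict[str, str]]] = None,
    drop_exactly: Optional[Set[str]] = None,
) -> Tuple[Model, pd.DataFrame]:
    """Degrade a truth network into one tool's view of it.

    Non-protected reactions are dropped i.i.d. with the profile's dropout
    probability (or exactly the ``drop_exactly`` set, for complementary
    designs); GPRs are cleared or rewired per profile; extra reactions
    producing tool-specific dead-end metabolites are appended; finally all
    metabolite and reaction ids are relabelled into the tool namespace.
    Returns the view and its namespace cross-reference table (the appended
    dead-end artefacts are deliberately absent from the table — they have
    no counterpart in the common namespace).
    """
    rng = np.random.default_rng(seed)
    protected = set(protected_reactions or set())
    protected |= {r.id for r in truth.reactions_of_kind("exchange", "sink", "biomass")}
    if rename is None:
        rename = build_namespace_rename(truth, profile.namespace_label, seed)
    view = Model(id=truth.id, tool=profile.namespace_label)

    kept: List[Reaction] = []
    for rid in sorted(truth.reactions):
        rxn = truth.reactions[rid]
        if drop_exactly is not None:
            dropped = rid in drop_exactly
        else:
            dropped = rid not in protected and rng.random() < profile.reaction_dropout_prob
        if not dropped:
            kept.append(rxn.copy())
    gene_pool = sorted(truth.genes)
    for rxn in kept:
        if rxn.kind in ("internal", "transport") and rxn.gpr:
            u = rng.random()
            if u < profile.gene_dropout_prob:
                rxn.gpr = ""
            elif u < profile.gene_dropout_prob + profile.gpr_rewire_prob and gene_pool:
                rxn.gpr = gene_pool[rng.integers(0, len(gene_pool))]
    # tool-specific spurious reactions feeding dead-end metabolites
    internal_mets = sorted(
        m for m in truth.metabolites if truth.metabolites[m].compartment == "c"
    )
    extras: List[Reaction] = []
    for i in range(profile.extra_deadend_reactions):
        src = internal_mets[rng.integers(0, len(internal_mets))]
        gpr = gene_pool[rng.integers(0, len(gene_pool))] if gene_pool else ""
        extras.append(
            Reaction(
                id=f"R_dd_{profile.namespace_label}_{i}",
                stoichiometry={src: -1.0, f"dd_{profile.namespace_label}_{i}@c": 1.0},
                lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal",
                gpr=gpr, ec_numbers=(_sample_ec(rng),),
            )
        )

    met_map, rxn_map = rename["metabolite"], rename["reaction"]

    def view_met_id(mid: str) -> str:
        met = truth.metabolites.get(mid)
        base = met.base_id if met else mid.rsplit("@", 1)[0]
        comp = (met.compartment if met else mid.rsplit("@", 1)[1]) or "c"
        return f"{met_map.get(base, base)}@{comp}"

    needed: Set[str] = set()
    for rxn in kept + extras:
        needed |= set(rxn.stoichiometry)
    for mid in sorted(needed):
        src = truth.metabolites.get(mid)
        new = src.copy() if src else Metabolite(id=mid)
        new.id = view_met_id(mid)
        view.add_metabolite(new)
    objective = None
    for rxn in kept + extras:
        rxn.stoichiometry = {view_met_id(m): c for m, c in rxn.stoichiometry.items()}
        new_id = rxn_map.get(rxn.id, rxn.id)
        if truth.objective == rxn.id:
            objective = new_id
        rxn.id = new_id
        view.add_reaction(rxn)
    view.objective = objective
    return view, namespace_table(rename, profile.namespace_label)


def derive_complementary_views(
    truth: Model,
    profiles: Dict[str, ToolProfile],
    seed: int,
    core_reaction_ids: Set[str],
    renames: Optional[Dict[str, Dict[str, Dict[str, str]]]] = None,
) -> Dict[str, Tuple[Model, pd.DataFrame]]:
    """Views that drop pairwise-disjoint reaction subsets (and add no
    spurious dead-end reactions), so the consensus of the views recovers the
    complete interior of the truth network."""
    rng = np.random.default_rng(seed)
    protected = set(core_reaction_ids)
    protected |= {r.id for r in truth.reactions_of_kind("exchange", "sink", "biomass")}
    droppable = sorted(set(truth.reactions) - protected)
    order = list(rng.permutation(len(droppable)))
    tools = sorted(profiles)
    shares: Dict[str, Set[str]] = {t: set() for t in tools}
    for pos, idx in enumerate(order):
        shares[tools[pos % len(tools)]].add(droppable[idx])
    out = {}
    for i, tool in enumerate(tools):
        profile = replace(profiles[tool], extra_deadend_reactions=0)
        out[tool] = derive_tool_view(
            truth,
            profile,
            seed=seed + 101 * (i + 1),
            protected_reactions=protected,
            rename=renames.get(tool) if renames else None,
            drop_exactly=shares[tool],
        )
    return out


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

@dataclass
class CommunityFixture:
    """A full synthetic community: per-member truths and tool views,
    abundances, media, database, biomass spec and namespace tables."""

    member_truths: Dict[str, Model]
    views: Dict[str, Dict[str, Model]]  # tool -> mag_id -> view
    namespace_tables: Dict[str, pd.DataFrame]
    abundance: Dict[str, float]
    biomass_spec: Dict[str, float]
    universal_db: Model
    rich_medium: Medium
    minimal_medium: Medium
    core_reaction_ids: Set[str]
    seed: int


def _relabel_genes(model: Model, prefix: str) -> None:
    """Give a member its own gene namespace (genes are MAG-specific)."""
    sub = re.compile(r"\bg(\d+)\b")
    for rxn in model.reactions.values():
        if rxn.gpr:
            rxn.gpr = sub.sub(rf"{prefix}_g\1", rxn.gpr)
    model.genes = set()
    for rxn in model.reactions.values():
        model.genes |= rxn.genes


def generate_community(
    n_members: int = 4,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.0,
    profiles: Optional[Dict[str, ToolProfile]] = None,
    seed: int = 0,
    n_branch_pathways: int = 4,
    branch_length: int = 4,
    complementary: bool = False,
) -> CommunityFixture:
    """Generate a community of seeded truth variants sharing one metabolite
    universe, each viewed through every tool profile.

    Member 1 carries the complete network; every later member is an
    auxotroph missing one randomly chosen biosynthetic branch, so its
    biomass precursor must be gap-filled — de novo, or by cross-feeding on
    byproducts accumulated in the community medium. Abundances are
    log-normal (the typical shape of MAG coverage sums).
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed)
    base = generate_truth_network(n_branch_pathways, branch_length, seed=int(rng.integers(2**31)))
    mag_ids = [f"MAG{k + 1:03d}" for k in range(n_members)]
    abundance = {
        mag: float(a)
        for mag, a in zip(mag_ids, rng.lognormal(abundance_mu, abundance_sigma, n_members))
    }
    renames = {
        tool: build_namespace_rename(base.truth, profiles[tool].namespace_label,
                                     seed=int(rng.integers(2**31)))
        for tool in sorted(profiles)
    }
    member_truths: Dict[str, Model] = {}
    views: Dict[str, Dict[str, Model]] = {tool: {} for tool in profiles}
    tables: Dict[str, pd.DataFrame] = {}
    for k, mag in enumerate(mag_ids):
        truth_k = base.truth.copy()
        truth_k.id = mag
        if k > 0:
            missing = int(rng.integers(1, n_branch_pathways + 1))
            for rid in base.branch_reaction_ids[missing]:
                truth_k.remove_reaction(rid)
        _relabel_genes(truth_k, mag)
        member_truths[mag] = truth_k
        if complementary:
            per_tool = derive_complementary_views(
                truth_k, profiles, seed=int(rng.integers(2**31)),
                core_reaction_ids=base.core_reaction_ids,
                renames=renames,
            )
            for tool, (view, table) in per_tool.items():
                view.id = mag
                views[tool][mag] = view
                tables.setdefault(tool, table)
        else:
            for tool in sorted(profiles):
                view, table = derive_tool_view(
                    truth_k, profiles[tool], seed=int(rng.integers(2**31)),
                    protected_reactions=base.core_reaction_ids,
                    rename=renames[tool],
                )
                view.id = mag
                views[tool][mag] = view
                tables.setdefault(tool, table)
    return CommunityFixture(
        member_truths=member_truths,
        views=views,
        namespace_tables=tables,
        abundance=abundance,
        biomass_spec=base.biomass_spec,
        universal_db=base.universal_db,
        rich_medium=base.rich_medium,
        minimal_medium=base.minimal_medium,
        core_reaction_ids=base.core_reaction_ids,
        seed=seed,
    )


def write_fixture(fixture: CommunityFixture, out_dir) -> Path:
    """Write a community fixture as a self-contained directory of SBML
    models, TSV tables, media and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tool, by_mag in sorted(fixture.views.items()):
        tool_dir = out / "models" / tool
        tool_dir.mkdir(parents=True, exist_ok=True)
        for mag, view in sorted(by_mag.items()):
            write_model(view, tool_dir / f"{mag}.xml")
    ns_dir = out / "namespace"
    ns_dir.mkdir(exist_ok=True)
    for tool, table in sorted(fixture.namespace_tables.items()):
        table.to_csv(ns_dir / f"{tool}.tsv", sep="\t", index=False)
    media_dir = out / "media"
    media_dir.mkdir(exist_ok=True)
    fixture.rich_medium.to_tsv(media_dir / "lb.tsv")
    fixture.minimal_medium.to_tsv(media_dir / "m9.tsv")
    write_model(fixture.universal_db, out / "universal_db.xml")
    pd.DataFrame(
        sorted(fixture.abundance.items()), columns=["mag_id", "abundance"]
    ).to_csv(out / "abundance.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "biomass.json").write_text(
        json.dumps(fixture.biomass_spec, indent=2, sort_keys=True)
    )
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "seed": fixture.seed,
                "n_members": len(fixture.member_truths),
                "tools": sorted(fixture.views),
                "core_reaction_ids": sorted(fixture.core_reaction_ids),
            },
            indent=2,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Purpose-built small fixtures
# ---------------------------------------------------------------------------

def cross_feeding_pair(seed: int = 0):
    """Two-member community where the low-abundance member depends on the
    high-abundance member's byproduct.

    The donor carries the complete network; the recipient lacks branch 1,
    whose precursor can be restored either de novo (``branch_length``
    database reactions) or via uptake + salvage of the donor's byproduct
    (3 reactions) once that byproduct is in the community medium. Returns
    (fixture, donor_model, recipient_model) with biomass already attached
    and boundaries stripped, ready for iterative gap-filling.
    """
    from .consensus import strip_boundary_and_biomass
    from .gapfill import add_universal_biomass

    base = generate_truth_network(n_branch_pathways=2, branch_length=4, seed=seed)
    donor = base.truth.copy()
    donor.id = "donor"
    recipient = base.truth.copy()
    recipient.id = "recipient"
    for rid in base.branch_reaction_ids[1]:
        recipient.remove_reaction(rid)
    _relabel_genes(donor, "donor")
    _relabel_genes(recipient, "recipient")
    donor = add_universal_biomass(strip_boundary_and_biomass(donor), base.biomass_spec)
    recipient = add_universal_biomass(strip_boundary_and_biomass(recipient), base.biomass_spec)
    return base, donor, recipient


def random_gapfill_instance(seed: int):
    """A random small gap-filling problem with a known-feasible database.

    A linear pathway from a single carbon source to biomass has 1-3 of its
    reactions removed into the candidate database, which also contains
    decoy reactions (some touching pathway metabolites, some isolated).
    Candidate count stays <= 12 so exhaustive enumeration is tractable.
    Returns (model, db, medium, epsilon).
    """
    from .gapfill import add_universal_biomass

    rng = np.random.default_rng(seed)
    n_chain = int(rng.integers(4, 7))
    model = Model(id=f"toy{seed}", tool="synthetic")
    model.add_metabolite(Metabolite(id="S@e"))
    chain_mets = ["S@c"] + [f"M{i}@c" for i in range(1, n_chain)] + ["P@c"]
    for mid in chain_mets:
        model.add_metabolite(Metabolite(id=mid))
    reactions = [
        Reaction(id="T_S", stoichiometry={"S@e": -1.0, "S@c": 1.0},
                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport")
    ]
    for i in range(len(chain_mets) - 1):
        reactions.append(
            Reaction(id=f"R{i}", stoichiometry={chain_mets[i]: -1.0, chain_mets[i + 1]: 1.0},
                     lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal")
        )
    n_missing = int(rng.integers(1, 4))
    missing_idx = set(rng.choice(len(reactions), size=n_missing, replace=False).tolist())
    db = Model(id="db", tool="synthetic")
    for met_ in model.metabolites.values():
        db.add_metabolite(met_.copy())
    kept_model = Model(id=model.id, tool="synthetic")
    for met_ in model.metabolites.values():
        kept_model.add_metabolite(met_.copy())
    for idx, rxn in enumerate(reactions):
        if idx in missing_idx:
            db.add_reaction(rxn)
        else:
            kept_model.add_reaction(rxn)
    # occasionally a 2-reaction bypass competing with one missing reaction
    if rng.random() < 0.5 and n_chain >= 5:
        db.add_metabolite(Metabolite(id="bypass@c"))
        db.add_reaction(Reaction(id="R_bypass_a", stoichiometry={"S@c": -1.0, "bypass@c": 1.0},
                                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal"))
        db.add_reaction(Reaction(id="R_bypass_b", stoichiometry={"bypass@c": -1.0, "P@c": 1.0},
                                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal"))
    n_decoys = int(rng.integers(2, 1 + max(3, 10 - n_missing)))
    for k in range(n_decoys):
        if len(db.reactions) >= 12:
            break
        src = chain_mets[int(rng.integers(0, len(chain_mets)))]
        dmet = f"junk{k}@c"
        db.add_metabolite(Metabolite(id=dmet))
        db.add_reaction(Reaction(id=f"R_junk{k}", stoichiometry={src: -1.0, dmet: 1.0},
                                 lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal"))
    kept_model = add_universal_biomass(kept_model, {"P@c": -1.0})
    medium = Medium({"S@e": 10.0})
    return kept_model, db, medium, 0.05
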