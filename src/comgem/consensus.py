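"""Consensus model construction by iterative folding of tool views.

For one MAG, the draft models produced by different reconstruction tools
(CarveMe first, then gapseq, then KBase, by convention) are stripped of
boundary and biomass reactions, translated to the common namespace, and
folded into a single consensus model: gene sets are unioned, duplicate
reactions (same common id, or identical canonical stoichiometry, possibly
reversed) are collapsed into one reaction with direction-union bounds and
OR-combined GPRs, and duplicate metabolites are fused.

Canonical stoichiometry: coefficients are converted to exact rationals,
divided by the gcd of their absolute values, and listed in sorted metabolite
order, giving an exact composition fingerprint; the negated fingerprint
identifies reversed duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from functools import reduce
from math import gcd
from typing import Dict, List, Sequence, Set, Tuple

from .core import (
    Model,
    Reaction,
    check_mass_charge_balance,
    find_dead_end_metabolites,
    gpr_or,
    gprs_equivalent,
)

logger = logging.getLogger(__name__)

Canonical = Tuple[Tuple[str, Fraction], ...]


def strip_boundary_and_biomass(model: Model) -> Model:
    """Remove exchange, sink, and biomass reactions; everything else untouched."""
    out = model.copy()
    for rid in [r.id for r in out.reactions_of_kind("exchange", "sink", "biomass")]:
        out.remove_reaction(rid)
    return out


def canonical_stoichiometry(stoich: Dict[str, float], max_denominator: int = 10**6) -> Canonical:
    """Exact composition fingerprint of a stoichiometry map.

    Coefficients are taken as rationals and normalised by the gcd of their
    absolute values, so 2A -> 2B and A -> B share one fingerprint while
    direction (sign) is preserved.
    """
    fracs = {
        m: Fraction(c).limit_denominator(max_denominator)
        for m, c in stoich.items()
        if c != 0
    }
    if not fracs:
        return ()
    denom_lcm = reduce(lambda a, b: a * b // gcd(a, b), (f.denominator for f in fracs.values()), 1)
    ints = {m: int(f * denom_lcm) for m, f in fracs.items()}
    g = reduce(gcd, (abs(v) for v in ints.values()))
    return tuple((m, Fraction(v, g)) for m, v in sorted(ints.items()))


def negate_canonical(canon: Canonical) -> Canonical:
    return tuple((m, -c) for m, c in canon)


def direction_free_digest(stoich: Dict[str, float]) -> Canonical:
    """Canonical form that ignores direction: the lexicographically smaller
    of the fingerprint and its negation. Used for order-insensitivity checks."""
    canon = canonical_stoichiometry(stoich)
    neg = negate_canonical(canon)
    return min(canon, neg, key=lambda t: tuple((m, str(c)) for m, c in t))


def reactions_equivalent(r1: Reaction, r2: Reaction) -> str:
    """Classify a reaction pair as 'distinct', 'duplicate', or 'duplicate_reversed'."""
    if r1.id == r2.id:
        return "duplicate"
    c1 = canonical_stoichiometry(r1.stoichiometry)
    c2 = canonical_stoichiometry(r2.stoichiometry)
    if c1 == c2:
        return "duplicate"
    if c1 == negate_canonical(c2):
        return "duplicate_reversed"
    return "distinct"


@dataclass
class MergeReport:
    """Per-view bookkeeping of a consensus merge."""

    per_view: Dict[str, Dict[str, int]] = field(default_factory=dict)
    conflicts: List[str] = field(default_factory=list)

    def count(self, view_label: str, what: str) -> None:
        self.per_view.setdefault(
            view_label, {"added": 0, "merged_duplicate": 0, "merged_reversed": 0}
        )[what] += 1


def _merge_into(kept: Reaction, incoming: Reaction, reversed_: bool, report: MergeReport) -> None:
    """Fold ``incoming`` (a duplicate of ``kept``) into ``kept`` in place."""
    lo, hi = incoming.lower_bound, incoming.upper_bound
    if reversed_:
        lo, hi = -hi, -lo
    kept.lower_bound = min(kept.lower_bound, lo)
    kept.upper_bound = max(kept.upper_bound, hi)
    if not gprs_equivalent(kept.gpr, incoming.gpr):
        kept.gpr = gpr_or(kept.gpr, incoming.gpr)
    kept.ec_numbers = tuple(dict.fromkeys(kept.ec_numbers + incoming.ec_numbers))
    kept.source_tools = kept.source_tools | incoming.source_tools


def merge_models(views: Sequence[Model], mag_id: str = None) -> Tuple[Model, MergeReport]:
    """Fold an ordered list of stripped, translated views into one consensus.

    The consensus gene set is exactly the union of the view gene sets. Each
    incoming reaction is matched against the consensus by common id and by
    canonical stoichiometry (direct and negated); duplicates widen the kept
    reaction's bounds to the union of allowed directions and OR its GPR.
    Metabolite attribute conflicts resolve first-seen-wins and are logged;
    when duplicate reactions disagree on mass balance, the balanced
    variant's metabolite formulas are kept.
    """
    if not views:
        raise ValueError("merge_models requires at least one view")
    report = MergeReport()
    consensus = Model(id=mag_id or views[0].id, tool="consensus")
    by_canon: Dict[Canonical, str] = {}

    for view in views:
        label = view.tool
        consensus.genes |= view.genes
        for met in view.metabolites.values():
            if met.id not in consensus.metabolites:
                consensus.add_metabolite(met.copy())
            else:
                kept = consensus.metabolites[met.id]
                for attr in ("name", "formula"):
                    new = getattr(met, attr)
                    old = getattr(kept, attr)
                    if new and old and new != old:
                        report.conflicts.append(
                            f"metabolite {met.id}: {attr} {old!r} (kept) vs {new!r} ({label})"
                        )
                    elif new and not old:
                        setattr(kept, attr, new)
                if met.charge is not None and kept.charge is None:
                    kept.charge = met.charge
                elif met.charge is not None and kept.charge is not None and met.charge != kept.charge:
                    report.conflicts.append(
                        f"metabolite {met.id}: charge {kept.charge} (kept) vs {met.charge} ({label})"
                    )
        for rxn in view.reactions.values():
            canon = canonical_stoichiometry(rxn.stoichiometry)
            match_id = None
            reversed_ = False
            if rxn.id in consensus.reactions:
                match_id = rxn.id
                existing = consensus.reactions[match_id]
                if canonical_stoichiometry(existing.stoichiometry) != canon:
                    report.conflicts.append(
                        f"reaction {rxn.id}: same id, different stoichiometry "
                        f"({label}); keeping first-seen composition"
                    )
            elif canon in by_canon:
                match_id = by_canon[canon]
            elif negate_canonical(canon) in by_canon:
                match_id = by_canon[negate_canonical(canon)]
                reversed_ = True
            if match_id is None:
                new = rxn.copy()
                new.source_tools = new.source_tools | {label}
                consensus.add_reaction(new)
                by_canon.setdefault(canon, new.id)
                report.count(label, "added")
            else:
                kept = consensus.reactions[match_id]
                _resolve_balance_annotations(kept, rxn, consensus, view, report)
                _merge_into(kept, rxn, reversed_, report)
                kept.source_tools = kept.source_tools | {label}
                report.count(label, "merged_reversed" if reversed_ else "merged_duplicate")
    return consensus, report


def _resolve_balance_annotations(kept, incoming, consensus, view, report) -> None:
    """When duplicates disagree on mass balance, prefer the balanced
    variant's metabolite formula annotations."""
    kept_rep = check_mass_charge_balance(kept, consensus.metabolites)
    inc_rep = check_mass_charge_balance(incoming, view.metabolites)
    if inc_rep.balanced and not kept_rep.balanced:
        for mid in incoming.stoichiometry:
            src = view.metabolites.get(mid)
            if src is not None and src.formula:
                consensus.metabolites[mid].formula = src.formula
                if src.charge is not None:
                    consensus.metabolites[mid].charge = src.charge
        report.conflicts.append(
            f"reaction {kept.id}: adopted balanced formula annotations from {view.tool}"
        )


@dataclass
class DeadEndAudit:
    """Consistency audit of a consensus against its source views."""

    gene_union_ok: bool
    dead_end_subset_ok: bool
    missing_genes: Set[str] = field(default_factory=set)
    extra_genes: Set[str] = field(default_factory=set)
    violating_dead_ends: Set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return self.gene_union_ok and self.dead_end_subset_ok


def consensus_dead_end_audit(views: Sequence[Model], consensus: Model) -> DeadEndAudit:
    """Verify the two structural guarantees of a merge.

    (a) the consensus gene set equals the union of view gene sets exactly;
    (b) every consensus dead-end metabolite is a dead end in every view that
    contains the metabolite (merging only ever adds producers/consumers).
    """
    union_genes = set().union(*(v.genes for v in views))
    missing = union_genes - consensus.genes
    extra = consensus.genes - union_genes
    consensus_dead = find_dead_end_metabolites(consensus)
    view_dead = [(v, find_dead_end_metabolites(v)) for v in views]
    violating = set()
    for met in consensus_dead:
        for view, dead in view_dead:
            if met in view.metabolites and met not in dead:
                violating.add(met)
    return DeadEndAudit(
        gene_union_ok=not missing and not extra,
        dead_end_subset_ok=not violating,
        missing_genes=missing,
        extra_genes=extra,
        violating_dead_ends=violating,
    )
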