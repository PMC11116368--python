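"""Core representation of genome-scale metabolic models (GEMs).

A :class:`Model` is a single organism's metabolic network: metabolites with
chemical annotations, reactions with stoichiometry, flux bounds and
gene-protein-reaction (GPR) rules, a gene set, and an optional biomass
objective. Metabolite identifiers are namespace-qualified and carry their
compartment as an ``@<code>`` suffix (e.g. ``MNXM2@c`` for cytosolic water),
with one cytosolic (``c``) and one extracellular (``e``) compartment per
organism model.

Structural diagnostics used throughout the comparison pipeline live here as
well: dead-end metabolite detection, per-reaction mass/charge balance checks,
and the structural summary counts (reactions, metabolites, genes, dead ends,
fraction of reactions lacking a GPR).
"""

from __future__ import annotations

import copy
import itertools
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set

from cobra.core.gene import GPR as _CobraGPR

from .errors import FormulaError, ValidationError

REACTION_KINDS = ("internal", "transport", "exchange", "sink", "biomass")
TOOL_LABELS = ("carveme", "gapseq", "kbase", "consensus", "synthetic")

#: Default flux bound magnitude (mmol gDW^-1 h^-1) when a source omits bounds.
DEFAULT_BOUND = 1000.0

EXCHANGE_PREFIXES = ("EX_",)
SINK_PREFIXES = ("SK_", "DM_")


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split ``base@comp`` into ``(base, comp)``; comp is '' when absent."""
    base, sep, comp = met_id.rpartition("@")
    if not sep:
        return met_id, ""
    return base, comp


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

def gpr_genes(gpr: str) -> frozenset:
    """Genes referenced by a boolean GPR string ('' -> empty set)."""
    if not gpr:
        return frozenset()
    return frozenset(_CobraGPR.from_string(gpr).genes)


def gpr_eval(gpr: str, active_genes: Iterable[str]) -> bool:
    """Evaluate a GPR with the given genes present (all others absent).

    An empty GPR evaluates to True: a reaction without genetic requirements
    is always available.
    """
    if not gpr:
        return True
    tree = _CobraGPR.from_string(gpr)
    knockouts = set(tree.genes) - set(active_genes)
    return bool(tree.eval(knockouts))


def gprs_equivalent(a: str, b: str, max_genes: int = 12) -> bool:
    """True iff two GPR strings have identical truth tables.

    Compared by exhaustive enumeration over the union gene set; beyond
    ``max_genes`` genes a normalized string comparison is used instead
    (sufficient for the automatically generated rules handled here).
    """
    if not a and not b:
        return True
    if bool(a) != bool(b):
        return False
    genes = sorted(gpr_genes(a) | gpr_genes(b))
    if len(genes) > max_genes:
        return _normalize_gpr(a) == _normalize_gpr(b)
    for mask in itertools.product((False, True), repeat=len(genes)):
        active = {g for g, on in zip(genes, mask) if on}
        if gpr_eval(a, active) != gpr_eval(b, active):
            return False
    return True


def gpr_or(a: str, b: str) -> str:
    """Combine two GPRs by OR (union-of-evidence semantics).

    An empty GPR means "no genetic evidence recorded", not "always
    catalysed", so combining with an empty rule keeps the annotated one.
    """
    if not a:
        return b
    if not b:
        return a
    if gprs_equivalent(a, b):
        return a
    return f"({a}) or ({b})"


def _normalize_gpr(gpr: str) -> str:
    return re.sub(r"\s+", " ", gpr.strip().lower())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``id`` is namespace-qualified with an ``@<compartment>`` suffix; the
    ``compartment`` field is derived from the id when not given explicitly.
    ``charge`` is ``None`` when unknown; ``formula`` is '' when unknown.
    """

    id: str
    name: str = ""
    formula: str = ""
    charge: Optional[int] = None
    compartment: str = ""

    def __post_init__(self):
        if not self.compartment:
            self.compartment = split_compartment(self.id)[1]

    @property
    def base_id(self) -> str:
        return split_compartment(self.id)[0]

    def copy(self) -> "Metabolite":
        return copy.copy(self)


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds and gene associations.

    ``stoichiometry`` maps metabolite id to a signed coefficient (negative =
    substrate). ``kind`` is one of :data:`REACTION_KINDS`; exchange and sink
    reactions touch exactly one metabolite. ``source_tools`` records which
    reconstruction views contributed the reaction (relevant after merging).
    """

    id: str
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    ec_numbers: tuple = ()
    kind: str = "internal"
    source_tools: frozenset = frozenset()

    def __post_init__(self):
        self.ec_numbers = tuple(self.ec_numbers)
        self.source_tools = frozenset(self.source_tools)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def metabolite_ids(self) -> Set[str]:
        return set(self.stoichiometry)

    @property
    def genes(self) -> frozenset:
        return gpr_genes(self.gpr)

    def copy(self) -> "Reaction":
        r = copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


@dataclass
class Model:
    """One organism's metabolic network (one MAG, one reconstruction view)."""

    id: str
    tool: str = "synthetic"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: Set[str] = field(default_factory=set)
    objective: Optional[str] = None

    # -- construction -------------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, infer_kind: bool = False) -> None:
        if infer_kind:
            rxn.kind = infer_reaction_kind(rxn, objective=self.objective)
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.genes

    def remove_reaction(self, rxn_id: str) -> None:
        self.reactions.pop(rxn_id, None)
        if self.objective == rxn_id:
            self.objective = None

    def copy(self) -> "Model":
        return Model(
            id=self.id,
            tool=self.tool,
            metabolites={k: m.copy() for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            genes=set(self.genes),
            objective=self.objective,
        )

    # -- queries ------------------------------------------------------------
    def reactions_of_kind(self, *kinds: str):
        return [r for r in self.reactions.values() if r.kind in kinds]

    def extracellular_metabolites(self) -> Set[str]:
        return {m for m, met in self.metabolites.items() if met.compartment == "e"}

    # -- invariants ---------------------------------------------------------
    def validation_errors(self) -> list:
        problems = []
        for mid, met in self.metabolites.items():
            if not met.compartment:
                problems.append(f"metabolite {mid}: empty compartment")
        for rid, rxn in self.reactions.items():
            if rxn.lower_bound > rxn.upper_bound:
                problems.append(
                    f"reaction {rid}: lower_bound {rxn.lower_bound} > "
                    f"upper_bound {rxn.upper_bound}"
                )
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    problems.append(f"reaction {rid}: undeclared metabolite {mid}")
            if rxn.kind in ("exchange", "sink"):
                if len(rxn.stoichiometry) != 1:
                    problems.append(
                        f"reaction {rid}: {rxn.kind} reaction must touch exactly "
                        f"one metabolite, has {len(rxn.stoichiometry)}"
                    )
            elif not rxn.stoichiometry:
                problems.append(f"reaction {rid}: empty stoichiometry")
            if rxn.kind not in REACTION_KINDS:
                problems.append(f"reaction {rid}: unknown kind {rxn.kind!r}")
            missing = rxn.genes - self.genes
            if missing:
                problems.append(
                    f"reaction {rid}: GPR genes not in model gene set: {sorted(missing)}"
                )
        if self.objective is not None and self.objective not in self.reactions:
            problems.append(f"objective {self.objective} is not a reaction")
        return problems

    def validate(self) -> None:
        problems = self.validation_errors()
        if problems:
            raise ValidationError(problems)


@dataclass
class StatRecord:
    """Structural summary of one model."""

    n_reactions: int
    n_metabolites: int
    n_genes: int
    n_dead_ends: int
    frac_reactions_without_gpr: float


# ---------------------------------------------------------------------------
# Reaction kind inference
# ---------------------------------------------------------------------------

def infer_reaction_kind(rxn: Reaction, objective: Optional[str] = None) -> str:
    """Classify a reaction as internal/transport/exchange/sink/biomass.

    Heuristics: the objective reaction (or an id containing "biomass") is
    biomass; single-metabolite reactions are boundary reactions, split into
    exchange vs sink by id prefix (``EX_`` vs ``SK_``/``DM_``) and, failing
    that, by compartment (extracellular -> exchange); a reaction moving one
    base species between compartments is a transport.
    """
    if objective is not None and rxn.id == objective:
        return "biomass"
    if "biomass" in rxn.id.lower():
        return "biomass"
    if len(rxn.stoichiometry) == 1:
        if rxn.id.startswith(EXCHANGE_PREFIXES):
            return "exchange"
        if rxn.id.startswith(SINK_PREFIXES):
            return "sink"
        (mid,) = rxn.stoichiometry
        return "exchange" if split_compartment(mid)[1] == "e" else "sink"
    comps_by_base: Dict[str, set] = {}
    for mid in rxn.stoichiometry:
        base, comp = split_compartment(mid)
        comps_by_base.setdefault(base, set()).add(comp)
    if any(len(comps) > 1 for comps in comps_by_base.values()):
        return "transport"
    return "internal"


# ---------------------------------------------------------------------------
# Dead-end metabolites
# ---------------------------------------------------------------------------

def find_dead_end_metabolites(model: Model) -> Set[str]:
    """Metabolites lacking any producer or any consumer.

    A reaction produces metabolite m if it can run in a direction that
    generates m (positive coefficient with upper bound > 0, or negative
    coefficient with lower bound < 0), and symmetrically for consumption.
    Boundary (exchange/sink) reactions count as producers/consumers, so an
    extracellular nutrient with an open uptake exchange is not a dead end.
    """
    producers: Set[str] = set()
    consumers: Set[str] = set()
    for rxn in model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for mid, coef in rxn.stoichiometry.items():
            if coef == 0:
                continue
            if (coef > 0 and fwd) or (coef < 0 and rev):
                producers.add(mid)
            if (coef < 0 and fwd) or (coef > 0 and rev):
                consumers.add(mid)
    return {
        m for m in model.metabolites if m not in producers or m not in consumers
    }


# ---------------------------------------------------------------------------
# Mass/charge balance
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-style chemical formula into element counts.

    Raises :class:`FormulaError` on anything but plain element/count pairs
    (no parentheses, no polymer 'n' suffixes).
    """
    counts: Counter = Counter()
    pos = 0
    for match in _ELEMENT.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparsable formula {formula!r}")
        element, digits = match.groups()
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula) or not counts:
        raise FormulaError(f"unparsable formula {formula!r}")
    return dict(counts)


@dataclass
class BalanceReport:
    """Per-reaction mass/charge balance verdict.

    ``verdict`` is one of ``balanced``, ``imbalanced``, ``undetermined``
    (missing or unparsable formula), or ``exempt`` (boundary/biomass
    reactions, which are unbalanced by design).
    """

    reaction_id: str
    verdict: str
    element_imbalance: Dict[str, float] = field(default_factory=dict)
    charge_imbalance: Optional[float] = None
    reason: str = ""

    @property
    def balanced(self) -> bool:
        return self.verdict == "balanced"


def check_mass_charge_balance(
    rxn: Reaction, metabolite_table: Mapping[str, Metabolite]
) -> BalanceReport:
    """Signed element/charge sums of coefficient x count over a reaction."""
    if rxn.kind in ("exchange", "sink", "biomass"):
        return BalanceReport(rxn.id, "exempt", reason=f"{rxn.kind} reaction")
    elements: Counter = Counter()
    charge = 0.0
    charge_known = True
    for mid, coef in rxn.stoichiometry.items():
        met = metabolite_table[mid]
        if not met.formula:
            return BalanceReport(
                rxn.id, "undetermined", reason=f"metabolite {mid} has no formula"
            )
        try:
            counts = parse_formula(met.formula)
        except FormulaError as exc:
            return BalanceReport(rxn.id, "undetermined", reason=str(exc))
        for element, n in counts.items():
            elements[element] += coef * n
        if met.charge is None:
            charge_known = False
        else:
            charge += coef * met.charge
    imbalance = {e: v for e, v in elements.items() if abs(v) > 1e-9}
    charge_imbalance = charge if charge_known else None
    balanced = not imbalance and (not charge_known or abs(charge) < 1e-9)
    return BalanceReport(
        rxn.id,
        "balanced" if balanced else "imbalanced",
        element_imbalance=imbalance,
        charge_imbalance=charge_imbalance,
        reason="" if charge_known else "charge unknown for some metabolites",
    )


# ---------------------------------------------------------------------------
# Structural statistics
# ---------------------------------------------------------------------------

def model_stats(model: Model) -> StatRecord:
    """Counts of reactions, metabolites, genes and dead ends, plus the
    fraction of internal/transport reactions lacking a GPR."""
    gpr_eligible = model.reactions_of_kind("internal", "transport")
    without = sum(1 for r in gpr_eligible if not r.gpr)
    frac = without / len(gpr_eligible) if gpr_eligible else 0.0
    return StatRecord(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_genes=len(model.genes),
        n_dead_ends=len(find_dead_end_metabolites(model)),
        frac_reactions_without_gpr=frac,
    )
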