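"""Community-aware gap-filling with abundance-ordered medium augmentation.

Each draft model receives a universal biomass reaction and is then
gap-filled against a universal reaction database: a minimum-weight set of
database reactions is added so that biomass flux >= epsilon becomes feasible
on the given medium. The selection is a mixed-integer program (one binary
per candidate reaction, objective sum of weights, default weight 1) solved
with HiGHS; an LP relaxation is available as a faster, non-exact switch.

At the community level, members are processed in descending (or ascending)
abundance order. The first member is gap-filled on a rich initial medium
(LB-like); every later member on a minimal base medium (adjusted-M9-like)
plus the *permeable* metabolites of the members processed before it —
metabolites a growing model can secrete — offered as additional uptake
candidates in the gap-filling database. The shared medium therefore only
grows along the iteration, and cross-feeding becomes cheaper than de-novo
pathway completion for later members.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import lil_matrix

from .core import DEFAULT_BOUND, Metabolite, Model, Reaction, split_compartment
from .errors import (
    GapfillInfeasibleError,
    InfeasibleError,
    UndefinedStatisticError,
)
from .fluxes import FLUX_TOL, Medium, fba

logger = logging.getLogger(__name__)

#: Minimum biomass flux a gap-filled model must reach.
DEFAULT_EPSILON = 0.05
#: Uptake rate granted to pool metabolites added during the iteration.
DEFAULT_POOL_UPTAKE = 10.0
#: Largest candidate count for which the exact lexicographic tie-break runs.
TIE_BREAK_CAP = 64


@dataclass
class Community:
    """Ordered collection of per-MAG models sharing a medium."""

    members: List[Tuple[str, Model]]
    abundance: Dict[str, float]
    order: str = "descending"

    def __post_init__(self):
        if self.order not in ("descending", "ascending"):
            raise ValueError(f"unknown order {self.order!r}")
        missing = [m for m, _ in self.members if m not in self.abundance]
        if missing:
            raise ValueError(f"abundance missing for members: {missing}")
        bad = {m: a for m, a in self.abundance.items() if not a > 0}
        if bad:
            raise ValueError(f"abundances must be positive: {bad}")

    def sorted_members(self) -> List[Tuple[str, Model]]:
        sign = -1.0 if self.order == "descending" else 1.0
        return sorted(self.members, key=lambda kv: (sign * self.abundance[kv[0]], kv[0]))


@dataclass
class GapfillResult:
    """Outcome of gap-filling one member."""

    mag_id: str
    added_reactions: Set[str] = field(default_factory=set)
    imported: Set[str] = field(default_factory=set)
    exported: Set[str] = field(default_factory=set)
    growth: float = 0.0
    error: Optional[str] = None
    #: the medium the member actually grows on: the one it was gap-filled
    #: against plus any uptake candidates selected from the community pool
    effective_medium: Optional[Medium] = None

    @property
    def feasible(self) -> bool:
        return self.error is None


# ---------------------------------------------------------------------------
# Universal biomass
# ---------------------------------------------------------------------------

def add_universal_biomass(
    model: Model, biomass_spec: Dict[str, float], reaction_id: str = "bio_universal"
) -> Model:
    """Insert (or replace) the universal biomass reaction and set it as objective.

    ``biomass_spec`` maps metabolite ids to signed coefficients (negative =
    precursor). Metabolites absent from the model are added; the model may
    be unable to produce them until gap-filled.
    """
    if not biomass_spec:
        raise ValueError("empty biomass specification")
    out = model.copy()
    for rid in [r.id for r in out.reactions_of_kind("biomass")]:
        logger.info("model %s: replacing existing biomass reaction %s", out.id, rid)
        out.remove_reaction(rid)
    for mid in biomass_spec:
        if mid not in out.metabolites:
            out.add_metabolite(Metabolite(id=mid))
    out.add_reaction(
        Reaction(
            id=reaction_id,
            stoichiometry=dict(biomass_spec),
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            kind="biomass",
        )
    )
    out.objective = reaction_id
    return out


# ---------------------------------------------------------------------------
# Single-model gap-filling (MILP)
# ---------------------------------------------------------------------------

def _workspace(model: Model, universal_db: Model, medium: Medium,
               extra_uptake_candidates: Sequence[str] = ()):
    """Assemble the fixed part (model + free boundaries) and the candidate
    list (db reactions + pool-uptake exchanges) of the gap-fill program."""
    work = model.copy()
    candidates: List[Reaction] = []
    for rxn in universal_db.reactions.values():
        if rxn.id in work.reactions:
            continue
        cand = rxn.copy()
        cand.gpr = ""  # gap-filled reactions carry no genetic support
        candidates.append(cand)
        for mid in cand.stoichiometry:
            if mid not in work.metabolites:
                met = universal_db.metabolites.get(mid)
                work.add_metabolite(met.copy() if met else Metabolite(id=mid))
    for mid in extra_uptake_candidates:
        rid = f"EX_{split_compartment(mid)[0]}"
        if rid in work.reactions or any(c.id == rid for c in candidates):
            continue
        if mid not in work.metabolites:
            work.add_metabolite(Metabolite(id=mid))
        candidates.append(
            Reaction(
                id=rid,
                stoichiometry={mid: -1.0},
                lower_bound=-DEFAULT_POOL_UPTAKE,
                upper_bound=DEFAULT_BOUND,
                kind="exchange",
            )
        )
    # free exchanges for medium metabolites present in the universe
    for mid, rate in medium.uptake.items():
        if mid not in work.metabolites:
            continue
        rid = f"EX_{split_compartment(mid)[0]}"
        if rid in work.reactions:
            work.reactions[rid].lower_bound = min(work.reactions[rid].lower_bound, -rate)
        else:
            work.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={mid: -1.0},
                    lower_bound=-rate,
                    upper_bound=DEFAULT_BOUND,
                    kind="exchange",
                )
            )
            candidates = [c for c in candidates if c.id != rid]
    # free secretion valves for extracellular metabolites lacking a zero-cost
    # boundary (candidate exchanges cost weight, so they do not count)
    drained = set()
    for rxn in work.reactions.values():
        if rxn.kind in ("exchange", "sink") and rxn.upper_bound > 0:
            drained |= set(rxn.stoichiometry)
    for mid in sorted(work.extracellular_metabolites() - drained):
        work.add_reaction(
            Reaction(
                id=f"SK_{split_compartment(mid)[0]}",
                stoichiometry={mid: -1.0},
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                kind="sink",
            )
        )
    return work, candidates


class _GapfillProgram:
    """MILP: min sum(w_i y_i) s.t. S v = 0, bounds, v_bio >= eps,
    lb_i y_i <= v_i <= ub_i y_i for candidates."""

    def __init__(self, work: Model, candidates: Sequence[Reaction], medium: Medium,
                 epsilon: float, weights: Optional[Dict[str, float]]):
        self.work = work
        self.candidates = list(candidates)
        self.epsilon = epsilon
        self.rxn_ids = list(work.reactions)
        self.cand_ids = [c.id for c in self.candidates]
        self.weights = {cid: (weights or {}).get(cid, 1.0) for cid in self.cand_ids}
        mets = set()
        for rxn in list(work.reactions.values()) + self.candidates:
            mets |= set(rxn.stoichiometry)
        self.met_ids = sorted(mets)
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        self.n_fix = len(self.rxn_ids)
        self.n_cand = len(self.candidates)
        n = self.n_fix + self.n_cand
        S = lil_matrix((len(self.met_ids), n))
        lb = np.empty(n)
        ub = np.empty(n)
        for j, rid in enumerate(self.rxn_ids):
            rxn = work.reactions[rid]
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if rxn.kind == "exchange":
                (mid,) = rxn.stoichiometry
                lo = -medium.uptake[mid] if mid in medium.uptake else max(lo, 0.0)
            lb[j], ub[j] = lo, hi
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        for k, cand in enumerate(self.candidates):
            j = self.n_fix + k
            lb[j], ub[j] = cand.lower_bound, cand.upper_bound
            for mid, coef in cand.stoichiometry.items():
                S[met_index[mid], j] = coef
        self.S = S.tocsr()
        self.v_lb, self.v_ub = lb, ub
        self.bio_col = self.rxn_ids.index(work.objective)

    def solve(self, relaxed: bool = False, forced: Optional[Dict[str, int]] = None,
              max_weight: Optional[float] = None):
        """Returns (weight, selected ids, v) or raises InfeasibleError."""
        n = self.n_fix + self.n_cand
        nvar = n + self.n_cand
        c = np.zeros(nvar)
        for k, cid in enumerate(self.cand_ids):
            c[n + k] = self.weights[cid]
        lb = np.concatenate([self.v_lb, np.zeros(self.n_cand)])
        ub = np.concatenate([self.v_ub, np.ones(self.n_cand)])
        if forced:
            for cid, val in forced.items():
                k = self.cand_ids.index(cid)
                lb[n + k] = ub[n + k] = float(val)
        constraints = []
        A_eq = lil_matrix((self.S.shape[0], nvar))
        A_eq[:, :n] = self.S
        constraints.append(LinearConstraint(A_eq.tocsr(), 0.0, 0.0))
        # candidate gating: v_k - ub_k y_k <= 0 ; v_k - lb_k y_k >= 0
        if self.n_cand:
            A_gate = lil_matrix((2 * self.n_cand, nvar))
            glo = np.empty(2 * self.n_cand)
            ghi = np.empty(2 * self.n_cand)
            for k, cand in enumerate(self.candidates):
                j = self.n_fix + k
                A_gate[2 * k, j] = 1.0
                A_gate[2 * k, n + k] = -cand.upper_bound
                glo[2 * k], ghi[2 * k] = -np.inf, 0.0
                A_gate[2 * k + 1, j] = 1.0
                A_gate[2 * k + 1, n + k] = -cand.lower_bound
                glo[2 * k + 1], ghi[2 * k + 1] = 0.0, np.inf
            constraints.append(LinearConstraint(A_gate.tocsr(), glo, ghi))
        A_bio = np.zeros((1, nvar))
        A_bio[0, self.bio_col] = 1.0
        constraints.append(LinearConstraint(A_bio, self.epsilon, np.inf))
        if max_weight is not None:
            constraints.append(LinearConstraint(c.reshape(1, -1), -np.inf, max_weight))
        integrality = np.zeros(nvar)
        if not relaxed:
            integrality[n:] = 1
        res = milp(
            c=c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lb, ub),
        )
        if res.status != 0 or res.x is None:
            raise InfeasibleError(f"gap-fill program infeasible ({res.message})")
        y = res.x[n:]
        v = dict(zip(self.rxn_ids + self.cand_ids, res.x[:n]))
        selected = {
            cid for k, cid in enumerate(self.cand_ids)
            if (y[k] > 0.5 if not relaxed else y[k] > 1e-6)
        }
        weight = sum(self.weights[cid] for cid in selected)
        return weight, selected, v

    def lexicographic_tiebreak(self, weight: float):
        """Among minimum-weight solutions, fix candidates in sorted-id order,
        keeping each one iff an optimum-weight solution containing it exists;
        yields the lexicographically smallest selected id set."""
        forced: Dict[str, int] = {}
        tol = 1e-6
        for cid in sorted(self.cand_ids):
            try:
                self.solve(forced={**forced, cid: 1}, max_weight=weight + tol)
                forced[cid] = 1
            except InfeasibleError:
                forced[cid] = 0
        _, selected, v = self.solve(forced=forced, max_weight=weight + tol)
        return selected, v


def gapfill_model(
    model: Model,
    universal_db: Model,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
    weights: Optional[Dict[str, float]] = None,
    extra_uptake_candidates: Sequence[str] = (),
    relaxed: bool = False,
    tie_break: bool = True,
) -> Tuple[Model, GapfillResult]:
    """Add a minimum-weight reaction set so the model grows on the medium.

    Returns the augmented model (original + selected database reactions +
    the boundary reactions opened to support the solution) and a
    :class:`GapfillResult`. Raises :class:`GapfillInfeasibleError` naming
    the unreachable biomass precursors when even the full database cannot
    support growth.
    """
    if model.objective is None:
        raise ValueError(f"model {model.id} has no biomass objective; add one first")
    work, candidates = _workspace(model, universal_db, medium, extra_uptake_candidates)
    program = _GapfillProgram(work, candidates, medium, epsilon, weights)
    try:
        weight, selected, v = program.solve(relaxed=relaxed)
    except InfeasibleError:
        raise GapfillInfeasibleError(
            model.id, _blocked_precursors(work, candidates, medium, epsilon)
        )
    if not relaxed and tie_break and program.n_cand <= TIE_BREAK_CAP:
        selected, v = program.lexicographic_tiebreak(weight)
    augmented = _assemble_augmented(model, work, candidates, selected, v)
    effective = medium
    pool_uptakes = {
        mid: -cand.lower_bound
        for cand in candidates
        if cand.id in selected and cand.kind == "exchange" and cand.lower_bound < 0
        for mid in cand.stoichiometry
        if mid not in medium
    }
    if pool_uptakes:
        effective = medium.union(Medium(pool_uptakes))
    result = GapfillResult(
        mag_id=model.id,
        added_reactions=set(selected),
        imported=imported_from_bounds(augmented),
        exported=exported_from_bounds(augmented),
        growth=fba(augmented, effective).objective_value,
        effective_medium=effective,
    )
    return augmented, result


def _assemble_augmented(model, work, candidates, selected, v) -> Model:
    augmented = model.copy()
    by_id = {c.id: c for c in candidates}
    used_mets = set()
    chosen = [by_id[cid] for cid in sorted(selected)]
    for rxn in chosen:
        used_mets |= set(rxn.stoichiometry)
    # free boundaries actually exercised by the MILP solution stay open
    opened = [
        work.reactions[rid]
        for rid, flux in v.items()
        if rid in work.reactions
        and rid not in model.reactions
        and (work.reactions[rid].kind in ("exchange", "sink"))
        and (abs(flux) > FLUX_TOL)
    ]
    for rxn in chosen + opened:
        for mid in rxn.stoichiometry:
            if mid not in augmented.metabolites:
                met = work.metabolites.get(mid)
                augmented.add_metabolite(met.copy() if met else Metabolite(id=mid))
        if rxn.id not in augmented.reactions:
            augmented.add_reaction(rxn.copy())
    # medium exchanges opened on the workspace copy of pre-existing reactions
    for rid, rxn in work.reactions.items():
        if rid in augmented.reactions and rxn.kind == "exchange":
            augmented.reactions[rid].lower_bound = min(
                augmented.reactions[rid].lower_bound, rxn.lower_bound
            )
    return augmented


def _blocked_precursors(work, candidates, medium, epsilon) -> List[str]:
    """Biomass precursors unreachable even with every candidate enabled,
    found by maximising a per-precursor demand with all else relaxed."""
    relaxed_model = work.copy()
    for cand in candidates:
        if cand.id not in relaxed_model.reactions:
            for mid in cand.stoichiometry:
                if mid not in relaxed_model.metabolites:
                    relaxed_model.add_metabolite(Metabolite(id=mid))
            relaxed_model.add_reaction(cand.copy())
    biomass = relaxed_model.reactions[relaxed_model.objective]
    blocked = []
    for mid, coef in sorted(biomass.stoichiometry.items()):
        if coef >= 0:
            continue
        probe = relaxed_model.copy()
        probe.remove_reaction(biomass.id)
        demand_id = f"demand_probe_{mid}"
        probe.add_reaction(
            Reaction(id=demand_id, stoichiometry={mid: -1.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, kind="sink")
        )
        probe.objective = demand_id
        try:
            cap = fba(probe, medium).objective_value
        except InfeasibleError:
            cap = 0.0
        if cap < abs(coef) * epsilon - FLUX_TOL:
            blocked.append(mid)
    return blocked


# ---------------------------------------------------------------------------
# Permeable metabolites
# ---------------------------------------------------------------------------

def predict_permeable_metabolites(
    model: Model,
    medium: Medium,
    epsilon: float = DEFAULT_EPSILON,
    tol: float = FLUX_TOL,
) -> Set[str]:
    """Extracellular metabolites the model can secrete while growing.

    For each extracellular metabolite, its secretion (sink) flux is
    maximised subject to biomass >= epsilon; metabolites whose maximum
    exceeds ``tol`` are permeable. Raises :class:`InfeasibleError` if the
    model cannot reach epsilon at all.
    """
    from .fluxes import _LinearProblem  # shared LP machinery

    work = model.copy()
    sink_of = {}
    for rxn in work.reactions.values():
        if rxn.kind == "sink" and rxn.upper_bound > 0:
            (mid,) = rxn.stoichiometry
            sink_of[mid] = rxn.id
    for mid in sorted(work.extracellular_metabolites() - set(sink_of)):
        rid = f"SK_probe_{split_compartment(mid)[0]}"
        work.add_reaction(
            Reaction(id=rid, stoichiometry={mid: -1.0}, lower_bound=0.0,
                     upper_bound=DEFAULT_BOUND, kind="sink")
        )
        sink_of[mid] = rid
    exchange_of = {}
    for rxn in work.reactions.values():
        if rxn.kind == "exchange":
            (mid,) = rxn.stoichiometry
            exchange_of[mid] = rxn.id
    try:
        growth = fba(work, medium).objective_value
    except InfeasibleError:
        growth = 0.0
    if growth < epsilon - tol:
        raise InfeasibleError(
            f"model {model.id} cannot reach biomass {epsilon} on the given medium"
        )
    lp = _LinearProblem(work, medium)
    lp.add_row({work.objective: 1.0}, epsilon, np.inf)
    permeable = set()
    for mid, rid in sorted(sink_of.items()):
        if rid not in lp._index:
            continue  # sink on a metabolite untouched by any reaction
        # close the metabolite's own uptake so that re-export of a medium
        # component does not count as secretion capability
        ex_col = lp._index.get(exchange_of.get(mid))
        saved = None
        if ex_col is not None:
            saved = lp.lb[ex_col]
            lp.lb[ex_col] = max(saved, 0.0)
        try:
            hi, _ = lp.optimize({rid: 1.0}, sense="max")
        except InfeasibleError:
            hi = 0.0  # growth requires this metabolite's uptake: not permeable
        finally:
            if ex_col is not None:
                lp.lb[ex_col] = saved
        if hi > tol:
            permeable.add(mid)
    return permeable


# ---------------------------------------------------------------------------
# Iterative community gap-filling
# ---------------------------------------------------------------------------

def iterative_community_gapfill(
    community: Community,
    init_medium: Medium,
    base_medium: Medium,
    universal_db: Model,
    epsilon: float = DEFAULT_EPSILON,
    pool_uptake: float = DEFAULT_POOL_UPTAKE,
    fail_fast: bool = False,
    relaxed: bool = False,
) -> Tuple[List[GapfillResult], Medium, Dict[str, Model]]:
    """Gap-fill every member in abundance order with medium augmentation.

    The first member uses the rich initial medium; all later members use the
    minimal base medium, with the accumulated permeable metabolites of
    earlier members offered as extra uptake candidates in the database.
    Returns the per-member results (processing order), the final community
    medium (base plus everything exported), and the augmented models.
    """
    results: List[GapfillResult] = []
    augmented_models: Dict[str, Model] = {}
    pool: Set[str] = set()
    for idx, (mag_id, model) in enumerate(community.sorted_members()):
        medium = init_medium if idx == 0 else base_medium
        extra = sorted(pool - set(medium.uptake)) if idx > 0 else []
        try:
            augmented, result = gapfill_model(
                model,
                universal_db,
                medium,
                epsilon=epsilon,
                extra_uptake_candidates=extra,
                relaxed=relaxed,
            )
            permeable = predict_permeable_metabolites(
                augmented, result.effective_medium, epsilon
            )
            for mid in sorted(permeable):
                rid = f"SK_{split_compartment(mid)[0]}"
                if rid not in augmented.reactions:
                    augmented.add_reaction(
                        Reaction(id=rid, stoichiometry={mid: -1.0}, lower_bound=0.0,
                                 upper_bound=DEFAULT_BOUND, kind="sink")
                    )
            result.exported |= permeable
            pool |= result.exported
            augmented_models[mag_id] = augmented
            logger.info(
                "gap-filled %s: %d added, growth %.4f",
                mag_id, len(result.added_reactions), result.growth,
            )
        except GapfillInfeasibleError as exc:
            if fail_fast:
                raise
            result = GapfillResult(mag_id=mag_id, error=str(exc))
            augmented_models[mag_id] = model.copy()
            logger.warning("gap-fill infeasible for %s: %s", mag_id, exc)
        results.append(result)
    final = base_medium.union(Medium({m: pool_uptake for m in pool})) if pool else base_medium
    return results, final, augmented_models


def correlate_abundance_with_gapfill(
    results: Sequence[GapfillResult],
    abundance: Dict[str, float],
    metric: str = "added",
) -> Tuple[float, float]:
    """Pearson correlation between MAG abundance and a gap-fill count.

    ``metric`` selects added reactions, imported metabolites, or exported
    metabolites. Requires >= 3 feasible members; constant vectors raise
    :class:`UndefinedStatisticError`.
    """
    attr = {"added": "added_reactions", "imported": "imported", "exported": "exported"}
    if metric not in attr:
        raise ValueError(f"unknown metric {metric!r}")
    pairs = [
        (abundance[r.mag_id], len(getattr(r, attr[metric])))
        for r in results
        if r.feasible
    ]
    if len(pairs) < 3:
        raise UndefinedStatisticError("need >= 3 feasible members for correlation")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance in correlation input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Bound-based import/export membership (shared with exchange analysis)
# ---------------------------------------------------------------------------

def imported_from_bounds(model: Model) -> Set[str]:
    """Metabolites of exchange reactions whose bounds permit uptake."""
    out = set()
    for rxn in model.reactions_of_kind("exchange"):
        if rxn.lower_bound < 0:
            out |= set(rxn.stoichiometry)
    return out


def exported_from_bounds(model: Model) -> Set[str]:
    """Metabolites of sink reactions whose bounds permit secretion."""
    out = set()
    for rxn in model.reactions_of_kind("sink"):
        if rxn.upper_bound > 0:
            out |= set(rxn.stoichiometry)
    return out
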