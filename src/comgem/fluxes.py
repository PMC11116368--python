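"""Constraint-based flux computations: FBA, FVA, blocked reactions, export ranges.

All linear programs are solved with HiGHS through :func:`scipy.optimize.linprog`,
which is deterministic for a fixed input. A growth medium is applied by
overriding exchange-reaction lower bounds: an exchange with metabolite *m*
gets uptake capacity ``-medium[m]`` if *m* is in the medium and 0 otherwise
(uptake = negative exchange flux; secretion = positive flux). Sink reactions
model secretion only (positive flux) and are untouched by media.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .core import Model
from .errors import FluxError, InfeasibleError, UnboundedError

#: Numerical tolerance for treating a flux as zero.
FLUX_TOL = 1e-6


@dataclass
class Medium:
    """Growth medium: extracellular metabolite id -> maximum uptake rate (>0)."""

    uptake: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        bad = {m: r for m, r in self.uptake.items() if not r > 0}
        if bad:
            raise ValueError(f"medium uptake rates must be positive: {bad}")

    def __contains__(self, met_id):
        return met_id in self.uptake

    def __iter__(self):
        return iter(self.uptake)

    def union(self, other: "Medium") -> "Medium":
        merged = dict(self.uptake)
        for m, r in other.uptake.items():
            merged[m] = max(merged.get(m, 0.0), r)
        return Medium(merged)

    @classmethod
    def from_tsv(cls, path) -> "Medium":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(dict(zip(df["metabolite"], df["max_uptake"].astype(float))))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [{"metabolite": m, "max_uptake": f"{r:.10g}"} for m, r in sorted(self.uptake.items())],
            columns=["metabolite", "max_uptake"],
        ).to_csv(path, sep="\t", index=False)


class _LinearProblem:
    """Stoichiometric LP S.v = 0 with per-reaction bounds, built once and
    re-optimised under different objectives (FVA-style)."""

    def __init__(self, model: Model, medium: Optional[Medium] = None):
        self.rxn_ids = list(model.reactions)
        self.met_ids = [m for m in model.metabolites if self._referenced(model, m)]
        met_index = {m: i for i, m in enumerate(self.met_ids)}
        n, m = len(self.rxn_ids), len(self.met_ids)
        S = lil_matrix((m, n))
        lb = np.empty(n)
        ub = np.empty(n)
        for j, rid in enumerate(self.rxn_ids):
            rxn = model.reactions[rid]
            lo, hi = rxn.lower_bound, rxn.upper_bound
            if medium is not None and rxn.kind == "exchange":
                # medium sets the uptake capacity outright (cobra convention);
                # exchanges of non-medium metabolites lose uptake entirely
                (mid,) = rxn.stoichiometry
                lo = -medium.uptake[mid] if mid in medium.uptake else max(lo, 0.0)
            lb[j], ub[j] = lo, hi
            for mid, coef in rxn.stoichiometry.items():
                S[met_index[mid], j] = coef
        self.S = S.tocsr()
        self.lb, self.ub = lb, ub
        self.extra_rows: list = []  # (coeffs dict rxn_id->w, lower, upper)
        self._index = {r: j for j, r in enumerate(self.rxn_ids)}

    @staticmethod
    def _referenced(model, met_id):
        return any(met_id in r.stoichiometry for r in model.reactions.values())

    def add_row(self, coeffs: Mapping[str, float], lower: float, upper: float) -> None:
        self.extra_rows.append((dict(coeffs), lower, upper))

    def optimize(self, objective: Mapping[str, float], sense: str = "max"):
        n = len(self.rxn_ids)
        c = np.zeros(n)
        for rid, w in objective.items():
            c[self._index[rid]] += w
        if sense == "max":
            c = -c
        A_ub, b_ub = [], []
        for coeffs, lower, upper in self.extra_rows:
            row = np.zeros(n)
            for rid, w in coeffs.items():
                row[self._index[rid]] = w
            if np.isfinite(upper):
                A_ub.append(row)
                b_ub.append(upper)
            if np.isfinite(lower):
                A_ub.append(-row)
                b_ub.append(-lower)
        res = linprog(
            c,
            A_ub=np.array(A_ub) if A_ub else None,
            b_ub=np.array(b_ub) if b_ub else None,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=list(zip(self.lb, self.ub)),
            method="highs",
        )
        if res.status == 2:
            raise InfeasibleError("LP infeasible")
        if res.status == 3:
            raise UnboundedError("LP unbounded")
        if res.status != 0:
            raise FluxError(f"LP solver failure: {res.message}")
        value = -res.fun if sense == "max" else res.fun
        return value, dict(zip(self.rxn_ids, res.x))


@dataclass
class FBAResult:
    objective_value: float
    fluxes: Dict[str, float]


def fba(model: Model, medium: Optional[Medium] = None) -> FBAResult:
    """Flux balance analysis: maximise the model objective at steady state."""
    if model.objective is None:
        raise FluxError(f"model {model.id} has no objective reaction")
    lp = _LinearProblem(model, medium)
    value, fluxes = lp.optimize({model.objective: 1.0}, sense="max")
    return FBAResult(objective_value=value, fluxes=fluxes)


def fva(
    model: Model,
    medium: Optional[Medium] = None,
    reactions: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 0.0,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux minima/maxima, optionally constrained to a fraction
    of the optimal objective value."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    lp = _LinearProblem(model, medium)
    if fraction_of_optimum > 0.0:
        opt = fba(model, medium).objective_value
        # tiny slack keeps fraction=1 feasible under solver round-off
        lp.add_row({model.objective: 1.0}, fraction_of_optimum * opt - 1e-9, np.inf)
    targets = list(reactions) if reactions is not None else list(model.reactions)
    ranges = {}
    for rid in targets:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid}")
        lo, _ = lp.optimize({rid: 1.0}, sense="min")
        hi, _ = lp.optimize({rid: 1.0}, sense="max")
        ranges[rid] = (lo, hi)
    return ranges


def blocked_reactions(model: Model, medium: Optional[Medium] = None, tol: float = FLUX_TOL):
    """Reactions that cannot carry flux in any feasible steady state.

    Computed from FVA with no growth requirement (fraction_of_optimum = 0):
    the filter targets structural capability, not optimal-state activity.
    """
    ranges = fva(model, medium, fraction_of_optimum=0.0)
    return {r for r, (lo, hi) in ranges.items() if abs(lo) < tol and abs(hi) < tol}


def export_flux_ranges(
    model: Model,
    medium: Optional[Medium],
    exported_metabolites: Iterable[str],
) -> Dict[str, dict]:
    """Min/max secretion flux of each exported metabolite at optimal growth.

    The objective is fixed at its FBA optimum (fraction 1) and the sink
    reaction of each listed metabolite is min/maximised. Metabolites without
    a sink reaction yield a per-entry error record rather than aborting.
    """
    sinks = {}
    for rxn in model.reactions.values():
        if rxn.kind == "sink":
            (mid,) = rxn.stoichiometry
            sinks[mid] = rxn.id
    result: Dict[str, dict] = {}
    wanted = [m for m in exported_metabolites]
    with_sink = [m for m in wanted if m in sinks]
    ranges = fva(model, medium, reactions=[sinks[m] for m in with_sink], fraction_of_optimum=1.0)
    for met in wanted:
        if met not in sinks:
            result[met] = {"error": "no sink reaction for metabolite"}
        else:
            lo, hi = ranges[sinks[met]]
            result[met] = {"min": lo, "max": hi, "reaction": sinks[met]}
    return result
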