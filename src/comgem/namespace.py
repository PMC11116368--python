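"""Identifier harmonization across reconstruction-tool namespaces.

Automated reconstruction tools emit models in different identifier
namespaces (BiGG-like, ModelSEED-like, ...). Before models of the same
organism can be compared or merged, their metabolite and reaction ids are
mapped to a common reference namespace (MNXref-style) using static TSV
cross-reference tables with columns ``source_namespace``, ``source_id``,
``common_id``.

Identifiers without a mapping are retained with an ``unmapped:<tool>:``
provenance prefix rather than dropped, so that set comparisons between tool
views penalise namespace gaps instead of silently hiding them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable

import pandas as pd

from .core import Model, split_compartment
from .errors import NamespaceConflictError

logger = logging.getLogger(__name__)

UNMAPPED_PREFIX = "unmapped:"


@dataclass
class NamespaceMap:
    """source-id -> common-id dictionaries for metabolites and reactions."""

    met_map: Dict[str, str] = field(default_factory=dict)
    rxn_map: Dict[str, str] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        empty = [s for s, c in list(self.met_map.items()) + list(self.rxn_map.items()) if not c]
        if empty:
            raise ValueError(f"empty common ids for source ids: {empty}")

    @property
    def common_met_ids(self):
        return set(self.met_map.values())

    @property
    def common_rxn_ids(self):
        return set(self.rxn_map.values())


@dataclass
class CoverageReport:
    """Mapping coverage of one translated model."""

    model_id: str
    tool: str
    n_metabolites: int
    n_metabolites_mapped: int
    n_reactions: int
    n_reactions_mapped: int
    removed_reactions: list = field(default_factory=list)

    @property
    def frac_metabolites_mapped(self) -> float:
        return self.n_metabolites_mapped / self.n_metabolites if self.n_metabolites else 1.0

    @property
    def frac_reactions_mapped(self) -> float:
        return self.n_reactions_mapped / self.n_reactions if self.n_reactions else 1.0


def load_reference_tables(paths: Iterable, kind_column: str = "kind") -> NamespaceMap:
    """Build a :class:`NamespaceMap` from one or more reference TSVs.

    Each table needs columns ``source_namespace``, ``source_id``,
    ``common_id`` and a ``kind`` column distinguishing ``metabolite`` from
    ``reaction`` rows ('#' comment lines allowed). Duplicate rows collapse
    when consistent; the same source id mapped to different common ids is a
    hard error listing every conflict.
    """
    frames = [pd.read_csv(p, sep="\t", dtype=str, comment="#") for p in paths]
    table = pd.concat(frames, ignore_index=True)
    required = {"source_namespace", "source_id", "common_id", kind_column}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    ns = NamespaceMap()
    conflicts: Dict[tuple, set] = {}
    for row in table.itertuples(index=False):
        kind = getattr(row, kind_column)
        target = ns.met_map if kind == "metabolite" else ns.rxn_map
        key = (kind, row.source_id)
        existing = target.get(row.source_id)
        if existing is not None and existing != row.common_id:
            conflicts.setdefault(key, {existing}).add(row.common_id)
            continue
        target[row.source_id] = row.common_id
        ns.provenance[row.source_id] = row.source_namespace
    if conflicts:
        raise NamespaceConflictError(
            [(f"{kind}:{sid}", targets) for (kind, sid), targets in sorted(conflicts.items())]
        )
    return ns


def _translate_met_id(met_id: str, ns: NamespaceMap, tool: str) -> str:
    base, comp = split_compartment(met_id)
    if base.startswith(UNMAPPED_PREFIX) or base in ns.common_met_ids:
        return met_id  # already in the common namespace: idempotence
    common = ns.met_map.get(base)
    if common is None:
        common = f"{UNMAPPED_PREFIX}{tool}:{base}"
    return f"{common}@{comp}" if comp else common


def translate_model(model: Model, ns: NamespaceMap):
    """Rewrite a model into the common namespace.

    Returns ``(translated_model, CoverageReport)``. Compartment suffixes are
    preserved. When two source metabolites in the same compartment map to
    one common id they are fused and every stoichiometry rewritten; terms
    that cancel to zero are dropped, and reactions left with an empty
    stoichiometry are removed and logged in the report. Gene sets are never
    touched.
    """
    out = Model(id=model.id, tool=model.tool, genes=set(model.genes), objective=None)
    met_rename: Dict[str, str] = {}
    n_met_mapped = 0
    for met in model.metabolites.values():
        new_id = _translate_met_id(met.id, ns, model.tool)
        if not split_compartment(new_id)[0].startswith(UNMAPPED_PREFIX):
            n_met_mapped += 1
        met_rename[met.id] = new_id
        if new_id in out.metabolites:
            logger.info(
                "model %s: fusing %s into %s (same common id)", model.id, met.id, new_id
            )
            continue  # first-seen metabolite attributes win
        new_met = met.copy()
        new_met.id = new_id
        out.add_metabolite(new_met)
    n_rxn_mapped = 0
    removed = []
    rxn_rename: Dict[str, str] = {}
    for rxn in model.reactions.values():
        new_rxn = rxn.copy()
        if rxn.id in ns.common_rxn_ids or rxn.id.startswith(UNMAPPED_PREFIX):
            n_rxn_mapped += rxn.id in ns.common_rxn_ids
        elif rxn.id in ns.rxn_map:
            new_rxn.id = ns.rxn_map[rxn.id]
            n_rxn_mapped += 1
        else:
            new_rxn.id = f"{UNMAPPED_PREFIX}{model.tool}:{rxn.id}"
        stoich: Dict[str, float] = {}
        for mid, coef in rxn.stoichiometry.items():
            new_mid = met_rename[mid]
            stoich[new_mid] = stoich.get(new_mid, 0.0) + coef
        stoich = {m: c for m, c in stoich.items() if not math.isclose(c, 0.0, abs_tol=1e-12)}
        if rxn.stoichiometry and not stoich:
            removed.append(rxn.id)
            logger.warning(
                "model %s: reaction %s removed (stoichiometry cancelled under fusion)",
                model.id,
                rxn.id,
            )
            continue
        new_rxn.stoichiometry = stoich
        if new_rxn.id in out.reactions:
            # two source reactions share one common id; keep the first, the
            # consensus stage handles any remaining duplication
            logger.warning(
                "model %s: reaction %s collapses onto already-translated %s",
                model.id,
                rxn.id,
                new_rxn.id,
            )
            removed.append(rxn.id)
            continue
        rxn_rename[rxn.id] = new_rxn.id
        out.add_reaction(new_rxn)
    out.objective = rxn_rename.get(model.objective) if model.objective else None
    report = CoverageReport(
        model_id=model.id,
        tool=model.tool,
        n_metabolites=len(model.metabolites),
        n_metabolites_mapped=n_met_mapped,
        n_reactions=len(model.reactions),
        n_reactions_mapped=n_rxn_mapped,
        removed_reactions=removed,
    )
    return out, report


def coverage_table(reports: Iterable[CoverageReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_id": r.model_id,
                "tool": r.tool,
                "frac_metabolites_mapped": round(r.frac_metabolites_mapped, 6),
                "frac_reactions_mapped": round(r.frac_reactions_mapped, 6),
                "removed_reactions": ";".join(r.removed_reactions),
            }
            for r in reports
        ],
        columns=[
            "model_id",
            "tool",
            "frac_metabolites_mapped",
            "frac_reactions_mapped",
            "removed_reactions",
        ],
    )
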