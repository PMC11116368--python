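"""Model I/O: SBML Level 3 + fbc, and a plain-text TSV triplet dialect.

SBML reading/writing is delegated to COBRApy; this module converts between
:class:`comgem.core.Model` and :class:`cobra.Model`. Internal metabolite ids
carry their compartment as an ``@<code>`` suffix, which is not a legal SBML
SId character, so ids are escaped on write (``__<ord>__`` per character) and
unescaped on read.

The TSV triplet dialect stores a model as a directory with three files —
``metabolites.tsv``, ``reactions.tsv``, ``gprs.tsv`` — and exists for
human-editable fixtures and reports.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional

import cobra
import pandas as pd

from .core import (
    DEFAULT_BOUND,
    Metabolite,
    Model,
    Reaction,
    infer_reaction_kind,
    split_compartment,
)
from .errors import ParseError

_UNSAFE = re.compile(r"[^A-Za-z0-9_]")
_ESCAPE = re.compile(r"__(\d+)__")


def sanitize_sbml_id(raw: str) -> str:
    """Escape characters outside [A-Za-z0-9_] as ``__<ord>__``."""
    out = _UNSAFE.sub(lambda m: f"__{ord(m.group(0))}__", raw)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def desanitize_sbml_id(raw: str) -> str:
    return _ESCAPE.sub(lambda m: chr(int(m.group(1))), raw)


# ---------------------------------------------------------------------------
# cobra conversion
# ---------------------------------------------------------------------------

def to_cobra(model: Model) -> cobra.Model:
    cm = cobra.Model(sanitize_sbml_id(model.id) or "model")
    compartments = sorted({m.compartment for m in model.metabolites.values()})
    cm.compartments = {c: c for c in compartments}
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(
            sanitize_sbml_id(met.id),
            name=met.name or met.base_id,
            formula=met.formula or None,
            charge=met.charge,
            compartment=met.compartment,
        )
        cm.add_metabolites([cmet])
    rxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            sanitize_sbml_id(rxn.id),
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        rxns.append((cr, rxn))
    cm.add_reactions([cr for cr, _ in rxns])
    for cr, rxn in rxns:
        cr.add_metabolites(
            {
                cm.metabolites.get_by_id(sanitize_sbml_id(mid)): coef
                for mid, coef in rxn.stoichiometry.items()
            }
        )
        if rxn.gpr:
            cr.gene_reaction_rule = rxn.gpr
        if rxn.ec_numbers:
            cr.annotation["ec-code"] = list(rxn.ec_numbers)
        if rxn.source_tools:
            cr.notes["source_tools"] = ",".join(sorted(rxn.source_tools))
    # genes that survive in the model's gene set without appearing in any
    # kept GPR (possible after merging) are preserved as orphan geneProducts
    orphan = model.genes - {g.id for g in cm.genes}
    for gid in sorted(orphan):
        cm.genes.append(cobra.Gene(gid))
    if model.objective is not None:
        cm.objective = cm.reactions.get_by_id(sanitize_sbml_id(model.objective))
    return cm


def from_cobra(cm: cobra.Model, tool: str = "synthetic", model_id: Optional[str] = None) -> Model:
    model = Model(id=model_id or desanitize_sbml_id(cm.id), tool=tool)
    for cmet in cm.metabolites:
        mid = desanitize_sbml_id(cmet.id)
        comp = cmet.compartment or split_compartment(mid)[1] or "c"
        if "@" not in mid:
            mid = f"{mid}@{comp}"
        model.add_metabolite(
            Metabolite(
                id=mid,
                name=cmet.name or "",
                formula=cmet.formula or "",
                charge=cmet.charge,
                compartment=comp,
            )
        )
    objective_id = None
    for cr in cm.reactions:
        if cr.objective_coefficient:
            objective_id = desanitize_sbml_id(cr.id)
            break
    for cr in cm.reactions:
        rid = desanitize_sbml_id(cr.id)
        stoich = {}
        for cmet, coef in cr.metabolites.items():
            mid = desanitize_sbml_id(cmet.id)
            if "@" not in mid:
                mid = f"{mid}@{cmet.compartment or 'c'}"
            stoich[mid] = float(coef)
        ec = cr.annotation.get("ec-code", ())
        if isinstance(ec, str):
            ec = (ec,)
        tools = cr.notes.get("source_tools", "")
        rxn = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=cr.lower_bound if cr.lower_bound is not None else -DEFAULT_BOUND,
            upper_bound=cr.upper_bound if cr.upper_bound is not None else DEFAULT_BOUND,
            gpr=cr.gene_reaction_rule or "",
            ec_numbers=tuple(ec),
            source_tools=frozenset(t for t in tools.split(",") if t),
        )
        rxn.kind = infer_reaction_kind(rxn, objective=objective_id)
        model.add_reaction(rxn)
    model.genes |= {g.id for g in cm.genes}
    model.objective = objective_id
    return model


# ---------------------------------------------------------------------------
# public read/write
# ---------------------------------------------------------------------------

def read_model(path, dialect: str = "sbml-fbc", tool: str = "synthetic") -> Model:
    """Read a model from ``path`` in the named dialect and validate it.

    ``sbml-fbc``: a single SBML L3 file. ``tsv-triplet``: a directory with
    metabolites.tsv / reactions.tsv / gprs.tsv.
    """
    path = Path(path)
    if dialect == "sbml-fbc":
        try:
            # objective-less files (e.g. universal databases) are legitimate;
            # silence cobra's error-level complaint about them
            sbml_logger = logging.getLogger("cobra.io.sbml")
            level = sbml_logger.level
            sbml_logger.setLevel(logging.CRITICAL)
            try:
                cm = cobra.io.read_sbml_model(str(path))
            finally:
                sbml_logger.setLevel(level)
        except Exception as exc:  # cobra raises several libsbml-backed types
            raise ParseError(f"cannot parse SBML file {path}: {exc}") from exc
        model = from_cobra(cm, tool=tool)
    elif dialect == "tsv-triplet":
        model = _read_tsv_triplet(path, tool=tool)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    model.validate()
    return model


def write_model(model: Model, path, dialect: str = "sbml-fbc") -> None:
    path = Path(path)
    if dialect == "sbml-fbc":
        cobra.io.write_sbml_model(to_cobra(model), str(path))
    elif dialect == "tsv-triplet":
        _write_tsv_triplet(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# TSV triplet dialect
# ---------------------------------------------------------------------------

def _format_stoichiometry(stoich) -> str:
    return ";".join(f"{mid}:{coef:.10g}" for mid, coef in sorted(stoich.items()))


def _parse_stoichiometry(text: str, rxn_id: str):
    stoich = {}
    if not text:
        return stoich
    for item in text.split(";"):
        mid, sep, coef = item.rpartition(":")
        if not sep:
            raise ParseError(f"reaction {rxn_id}: bad stoichiometry term {item!r}")
        try:
            stoich[mid] = float(coef)
        except ValueError as exc:
            raise ParseError(
                f"reaction {rxn_id}: bad coefficient {coef!r} for {mid}"
            ) from exc
    return stoich


def _read_tsv_triplet(path: Path, tool: str) -> Model:
    for name in ("metabolites.tsv", "reactions.tsv", "gprs.tsv"):
        if not (path / name).exists():
            raise ParseError(f"tsv-triplet directory {path} is missing {name}")
    mets = pd.read_csv(path / "metabolites.tsv", sep="\t", dtype=str, comment="#").fillna("")
    rxns = pd.read_csv(path / "reactions.tsv", sep="\t", dtype=str, comment="#").fillna("")
    gprs = pd.read_csv(path / "gprs.tsv", sep="\t", dtype=str, comment="#").fillna("")
    gpr_map = dict(zip(gprs["reaction_id"], gprs["gpr"]))
    model = Model(id=path.name, tool=tool)
    for row in mets.itertuples(index=False):
        model.add_metabolite(
            Metabolite(
                id=row.id,
                name=row.name,
                formula=row.formula,
                charge=int(row.charge) if row.charge != "" else None,
                compartment=row.compartment,
            )
        )
    for row in rxns.itertuples(index=False):
        rxn = Reaction(
            id=row.id,
            stoichiometry=_parse_stoichiometry(row.stoichiometry, row.id),
            lower_bound=float(row.lower_bound) if row.lower_bound != "" else -DEFAULT_BOUND,
            upper_bound=float(row.upper_bound) if row.upper_bound != "" else DEFAULT_BOUND,
            gpr=gpr_map.get(row.id, ""),
            ec_numbers=tuple(e for e in row.ec_numbers.split(";") if e),
            kind=row.kind or "internal",
        )
        model.add_reaction(rxn)
    biomass = [r.id for r in model.reactions.values() if r.kind == "biomass"]
    model.objective = biomass[0] if biomass else None
    return model


def _write_tsv_triplet(model: Model, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    mets = pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "formula": m.formula,
                "charge": "" if m.charge is None else m.charge,
                "compartment": m.compartment,
            }
            for m in model.metabolites.values()
        ],
        columns=["id", "name", "formula", "charge", "compartment"],
    )
    rxns = pd.DataFrame(
        [
            {
                "id": r.id,
                "stoichiometry": _format_stoichiometry(r.stoichiometry),
                "lower_bound": f"{r.lower_bound:.10g}",
                "upper_bound": f"{r.upper_bound:.10g}",
                "kind": r.kind,
                "ec_numbers": ";".join(r.ec_numbers),
            }
            for r in model.reactions.values()
        ],
        columns=["id", "stoichiometry", "lower_bound", "upper_bound", "kind", "ec_numbers"],
    )
    gprs = pd.DataFrame(
        [{"reaction_id": r.id, "gpr": r.gpr} for r in model.reactions.values() if r.gpr],
        columns=["reaction_id", "gpr"],
    )
    mets.to_csv(path / "metabolites.tsv", sep="\t", index=False)
    rxns.to_csv(path / "reactions.tsv", sep="\t", index=False)
    gprs.to_csv(path / "gprs.tsv", sep="\t", index=False)
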