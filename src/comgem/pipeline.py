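"""End-to-end orchestration: translate -> merge -> gap-fill -> compare ->
enrich -> exchange, driven by one YAML config, with deterministic TSV/JSON
outputs and a machine-readable run manifest.

Input layout follows the fixture convention written by
:func:`comgem.synth.write_fixture`::

    fixture/
      models/<tool>/<MAG>.xml      draft models per reconstruction tool
      namespace/<tool>.tsv         id cross-reference tables
      media/lb.tsv, media/m9.tsv   initial (rich) and base (minimal) media
      universal_db.xml             gap-filling database
      abundance.tsv                MAG abundances
      biomass.json                 universal biomass composition

All stage outputs are sorted and written with fixed float formatting, so a
rerun on identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from pathlib import Path
from typing import Dict

import pandas as pd
import yaml

from . import __version__
from .compare import (
    FEATURES,
    enrich_ec_subclasses,
    enrichment_table,
    group_tests,
    pairwise_similarity,
)
from .consensus import merge_models, strip_boundary_and_biomass
from .core import Model, model_stats
from .errors import ComgemError, UndefinedStatisticError
from .exchange import cross_approach_jaccard, exchange_summary, membership_matrix
from .fluxes import Medium, blocked_reactions, export_flux_ranges
from .gapfill import (
    Community,
    add_universal_biomass,
    correlate_abundance_with_gapfill,
    iterative_community_gapfill,
)
from .io import read_model, write_model
from .namespace import coverage_table, load_reference_tables, translate_model

logger = logging.getLogger(__name__)

REQUIRED_KEYS = ("fixture", "order")
DEFAULTS = {
    "merge_order": ["carveme", "gapseq", "kbase"],
    "alpha": 0.05,
    "epsilon": 0.05,
    "relaxed": False,
    "seed": 1,
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULTS, **(config or {})}
    missing = [k for k in REQUIRED_KEYS if k not in cfg]
    if missing:
        raise ComgemError(f"config is missing required fields: {missing}")
    fixture = Path(cfg["fixture"])
    for rel in ("models", "namespace", "media/lb.tsv", "media/m9.tsv",
                "universal_db.xml", "abundance.tsv", "biomass.json"):
        if not (fixture / rel).exists():
            raise ComgemError(f"config pre-flight: missing input {fixture / rel}")
    if cfg["order"] not in ("descending", "ascending"):
        raise ComgemError(f"config: order must be descending or ascending, got {cfg['order']!r}")
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _load_inputs(cfg: dict):
    fixture = Path(cfg["fixture"])
    tools = sorted(p.name for p in (fixture / "models").iterdir() if p.is_dir())
    raw: Dict[str, Dict[str, Model]] = {}
    for tool in tools:
        raw[tool] = {}
        for path in sorted((fixture / "models" / tool).glob("*.xml")):
            raw[tool][path.stem] = read_model(path, tool=tool)
    maps = {
        tool: load_reference_tables([fixture / "namespace" / f"{tool}.tsv"])
        for tool in tools
    }
    abundance_df = pd.read_csv(fixture / "abundance.tsv", sep="\t")
    abundance = dict(zip(abundance_df["mag_id"], abundance_df["abundance"].astype(float)))
    init_medium = Medium.from_tsv(fixture / "media" / "lb.tsv")
    base_medium = Medium.from_tsv(fixture / "media" / "m9.tsv")
    universal_db = read_model(fixture / "universal_db.xml", tool="synthetic")
    biomass_spec = json.loads((fixture / "biomass.json").read_text())
    return raw, maps, abundance, init_medium, base_medium, universal_db, biomass_spec


def run_pipeline(config, out_dir) -> Path:
    """Execute every stage and write all outputs under ``out_dir``."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw, maps, abundance, init_medium, base_medium, universal_db, biomass_spec = _load_inputs(cfg)
    tools = sorted(raw)

    # stage 1: namespace harmonization
    translated: Dict[str, Dict[str, Model]] = {}
    reports = []
    for tool in tools:
        translated[tool] = {}
        for mag in sorted(raw[tool]):
            model, report = translate_model(raw[tool][mag], maps[tool])
            translated[tool][mag] = model
            reports.append(report)
    _write_tsv(coverage_table(reports), out / "translate" / "coverage.tsv")

    # stage 2: consensus merge
    mags = sorted(set(itertools.chain.from_iterable(translated[t] for t in tools)))
    consensus: Dict[str, Model] = {}
    merge_rows = []
    for mag in mags:
        views = [
            strip_boundary_and_biomass(translated[tool][mag])
            for tool in cfg["merge_order"]
            if mag in translated.get(tool, {})
        ]
        merged, report = merge_models(views, mag_id=mag)
        consensus[mag] = merged
        for view_label in sorted(report.per_view):
            counts = report.per_view[view_label]
            merge_rows.append({"mag_id": mag, "view": view_label, **counts})
        write_model(merged, _mkdir(out / "consensus") / f"{mag}.xml")
    _write_tsv(pd.DataFrame(merge_rows), out / "consensus" / "merge_report.tsv")

    approaches: Dict[str, Dict[str, Model]] = {**translated, "consensus": consensus}

    # stage 3: structural stats and similarity, on the boundary-free network
    # interiors so tool drafts and the (boundary-free) consensus are comparable
    comparable = {
        approach: {
            mag: strip_boundary_and_biomass(approaches[approach][mag])
            for mag in approaches[approach]
        }
        for approach in approaches
    }
    stats_rows = []
    for approach in sorted(comparable):
        for mag in sorted(comparable[approach]):
            s = model_stats(comparable[approach][mag])
            stats_rows.append(
                {
                    "approach": approach,
                    "mag_id": mag,
                    "n_reactions": s.n_reactions,
                    "n_metabolites": s.n_metabolites,
                    "n_genes": s.n_genes,
                    "n_dead_ends": s.n_dead_ends,
                    "frac_reactions_without_gpr": round(s.frac_reactions_without_gpr, 6),
                }
            )
    stats_df = pd.DataFrame(stats_rows)
    _write_tsv(stats_df, out / "compare" / "structural_stats.tsv")
    _write_tsv(_stat_group_tests(stats_df), out / "compare" / "structural_tests.tsv")

    sim_rows = []
    for mag in mags:
        models_by_tool = {a: comparable[a][mag] for a in sorted(comparable) if mag in comparable[a]}
        for feature in FEATURES:
            mat = pairwise_similarity(models_by_tool, feature)
            for a1 in mat.index:
                for a2 in mat.columns:
                    if a1 < a2:
                        sim_rows.append(
                            {
                                "mag_id": mag,
                                "feature": feature,
                                "approach_1": a1,
                                "approach_2": a2,
                                "jaccard": round(float(mat.loc[a1, a2]), 6),
                            }
                        )
    _write_tsv(pd.DataFrame(sim_rows), out / "compare" / "pairwise_similarity.tsv")

    # stage 4: community gap-filling per approach
    gapfilled, gapfill_df, corr_df, media_final = _gapfill_stage(
        approaches, abundance, init_medium, base_medium, universal_db, biomass_spec, cfg,
        cfg["order"],
    )
    _write_tsv(gapfill_df, out / "gapfill" / "gapfill_results.tsv")
    _write_tsv(corr_df, out / "gapfill" / "abundance_correlations.tsv")
    for approach, medium in sorted(media_final.items()):
        medium.to_tsv(_mkdir(out / "gapfill") / f"final_medium_{approach}.tsv")

    # stage 5: flux analysis — blocked reactions and export flux ranges
    blocked_rows, export_rows = [], []
    unblocked_by_approach: Dict[str, set] = {}
    for approach in sorted(gapfilled):
        unblocked: set = set()
        for mag in sorted(gapfilled[approach]):
            model, medium = gapfilled[approach][mag]
            if model.objective is None:
                continue
            blocked = blocked_reactions(model, medium)
            unblocked |= set(model.reactions) - blocked
            blocked_rows.append(
                {
                    "approach": approach,
                    "mag_id": mag,
                    "n_reactions": len(model.reactions),
                    "n_blocked": len(blocked),
                }
            )
            exported = sorted(
                mid for r in model.reactions_of_kind("sink") if r.upper_bound > 0
                for mid in r.stoichiometry
            )
            try:
                ranges = export_flux_ranges(model, medium, exported)
            except ComgemError as exc:
                logger.warning("export ranges failed for %s/%s: %s", approach, mag, exc)
                continue
            for met in sorted(ranges):
                entry = ranges[met]
                if "error" in entry:
                    continue
                export_rows.append(
                    {
                        "approach": approach,
                        "mag_id": mag,
                        "metabolite": met,
                        "min_flux": round(entry["min"], 6),
                        "max_flux": round(entry["max"], 6),
                    }
                )
        unblocked_by_approach[approach] = unblocked
    _write_tsv(pd.DataFrame(blocked_rows), out / "fva" / "blocked_reactions.tsv")
    _write_tsv(pd.DataFrame(export_rows), out / "fva" / "export_flux_ranges.tsv")

    # stage 6: EC-subclass enrichment on shared / unblocked-shared reactions
    enrich_df = _enrichment_stage(gapfilled, unblocked_by_approach, cfg["alpha"])
    _write_tsv(enrich_df, out / "enrich" / "ec_enrichment.tsv")

    # stage 7: exchanged metabolites (community level)
    communities = {
        approach: [gapfilled[approach][mag][0] for mag in sorted(gapfilled[approach])]
        for approach in sorted(gapfilled)
    }
    _write_tsv(exchange_summary(communities), out / "exchange" / "exchange_summary.tsv")
    _write_tsv(cross_approach_jaccard(communities), out / "exchange" / "exchanged_jaccard.tsv", index=True)
    _write_tsv(
        membership_matrix(communities).rename_axis("metabolite"),
        out / "exchange" / "exchanged_membership.tsv",
        index=True,
    )

    manifest = {
        "comgem_version": __version__,
        "config": {k: str(v) if isinstance(v, Path) else v for k, v in sorted(cfg.items())},
        "config_hash": hashlib.sha256(
            json.dumps({k: str(v) for k, v in sorted(cfg.items())}).encode()
        ).hexdigest(),
        "n_mags": len(mags),
        "approaches": sorted(approaches),
        "solver": "scipy-highs",
        "stages": [
            "translate", "consensus", "compare", "gapfill", "fva", "enrich", "exchange",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _mkdir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def _stat_group_tests(stats_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    metrics = ["n_reactions", "n_metabolites", "n_genes", "n_dead_ends"]
    for metric in metrics:
        values = {
            a: g[metric].tolist() for a, g in stats_df.groupby("approach")
        }
        values = {a: v for a, v in values.items() if len(v) >= 2}
        if len(values) < 2:
            rows.append({"metric": metric, "test": "NA", "statistic": "NA", "p_value": "NA"})
            continue
        try:
            res = group_tests(values)
            rows.append(
                {
                    "metric": metric,
                    "test": res.test,
                    "statistic": f"{res.statistic:.6g}",
                    "p_value": f"{res.p_value:.6g}",
                }
            )
        except (UndefinedStatisticError, ValueError) as exc:
            rows.append({"metric": metric, "test": "NA", "statistic": "NA", "p_value": str(exc)})
    return pd.DataFrame(rows, columns=["metric", "test", "statistic", "p_value"])


def _gapfill_stage(approaches, abundance, init_medium, base_medium, universal_db,
                   biomass_spec, cfg, order):
    gapfilled: Dict[str, Dict[str, tuple]] = {}
    rows = []
    corr_rows = []
    media_final: Dict[str, Medium] = {}
    for approach in sorted(approaches):
        members = []
        for mag in sorted(approaches[approach]):
            draft = strip_boundary_and_biomass(approaches[approach][mag])
            members.append((mag, add_universal_biomass(draft, biomass_spec)))
        community = Community(
            members=members,
            abundance={m: abundance[m] for m, _ in members},
            order=order,
        )
        results, final_medium, models = iterative_community_gapfill(
            community, init_medium, base_medium, universal_db,
            epsilon=cfg["epsilon"], relaxed=cfg["relaxed"],
        )
        media_final[approach] = final_medium
        per_mag = {}
        for res in results:
            medium = res.effective_medium if res.effective_medium is not None else base_medium
            per_mag[res.mag_id] = (models[res.mag_id], medium)
            rows.append(
                {
                    "approach": approach,
                    "mag_id": res.mag_id,
                    "abundance": f"{abundance[res.mag_id]:.6g}",
                    "n_added": len(res.added_reactions),
                    "n_imported": len(res.imported),
                    "n_exported": len(res.exported),
                    "growth": f"{res.growth:.6g}",
                    "status": "ok" if res.feasible else "infeasible",
                }
            )
        gapfilled[approach] = per_mag
        for metric in ("added", "imported", "exported"):
            try:
                r, p = correlate_abundance_with_gapfill(results, abundance, metric)
                corr_rows.append(
                    {"approach": approach, "order": order, "metric": metric,
                     "pearson_r": f"{r:.6g}", "p_value": f"{p:.6g}"}
                )
            except (UndefinedStatisticError, KeyError):
                corr_rows.append(
                    {"approach": approach, "order": order, "metric": metric,
                     "pearson_r": "NA", "p_value": "NA"}
                )
    columns = ["approach", "mag_id", "abundance", "n_added", "n_imported",
               "n_exported", "growth", "status"]
    corr_columns = ["approach", "order", "metric", "pearson_r", "p_value"]
    return (
        gapfilled,
        pd.DataFrame(rows, columns=columns),
        pd.DataFrame(corr_rows, columns=corr_columns),
        media_final,
    )


def _enrichment_stage(gapfilled, unblocked_by_approach, alpha) -> pd.DataFrame:
    frames = []
    approaches = sorted(gapfilled)
    for a1, a2 in itertools.combinations(approaches, 2):
        rxns1 = _approach_reactions(gapfilled[a1])
        rxns2 = _approach_reactions(gapfilled[a2])
        shared_ids = set(rxns1) & set(rxns2)
        background = [rxns1.get(rid) or rxns2.get(rid) for rid in sorted(set(rxns1) | set(rxns2))]
        for variant, target_ids in (
            ("shared", shared_ids),
            (
                "unblocked_shared",
                shared_ids & unblocked_by_approach[a1] & unblocked_by_approach[a2],
            ),
        ):
            target = [rxns1.get(rid) or rxns2.get(rid) for rid in sorted(target_ids)]
            results = enrich_ec_subclasses(target, background, alpha=alpha)
            table = enrichment_table(results)
            table.insert(0, "variant", variant)
            table.insert(0, "approach_pair", f"{a1}|{a2}")
            frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["approach_pair", "variant", "subclass", "k", "n", "K", "N",
                     "p_value", "adjusted_p", "enriched"]
        )
    return pd.concat(frames, ignore_index=True)


def _approach_reactions(per_mag) -> dict:
    out = {}
    for mag in sorted(per_mag):
        model, _ = per_mag[mag]
        for rid, rxn in model.reactions.items():
            out.setdefault(rid, rxn)
    return out


def compare_orders(config, out_dir) -> Path:
    """Run the gap-filling stage in both abundance orders and write paired
    per-order results plus abundance correlations."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw, maps, abundance, init_medium, base_medium, universal_db, biomass_spec = _load_inputs(cfg)
    translated = {
        tool: {mag: translate_model(raw[tool][mag], maps[tool])[0] for mag in sorted(raw[tool])}
        for tool in sorted(raw)
    }
    mags = sorted(set(itertools.chain.from_iterable(translated[t] for t in translated)))
    consensus = {}
    for mag in mags:
        views = [
            strip_boundary_and_biomass(translated[tool][mag])
            for tool in cfg["merge_order"]
            if mag in translated.get(tool, {})
        ]
        consensus[mag] = merge_models(views, mag_id=mag)[0]
    approaches = {**translated, "consensus": consensus}
    corr_frames = []
    for order in ("descending", "ascending"):
        _, gapfill_df, corr_df, _ = _gapfill_stage(
            approaches, abundance, init_medium, base_medium, universal_db,
            biomass_spec, cfg, order,
        )
        _write_tsv(gapfill_df, out / f"gapfill_results_{order}.tsv")
        corr_frames.append(corr_df)
    _write_tsv(pd.concat(corr_frames, ignore_index=True), out / "abundance_correlations.tsv")
    return out
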