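"""Imported, exported, and community-exchanged metabolite analysis.

Membership is bound-based (capability, not realised flux): a metabolite is
imported by a model if an exchange reaction permits its uptake
(lower bound < 0), and exported if a sink reaction permits its secretion
(upper bound > 0). A metabolite is *exchanged* in a community when it lies
in the intersection of the union of exported and the union of imported
metabolites across members. Realised flux ranges of exports live in
:mod:`comgem.fluxes` (:func:`export_flux_ranges`).
"""

from __future__ import annotations

from typing import Iterable, List, Mapping, Set

import numpy as np
import pandas as pd

from .compare import jaccard
from .core import Model
from .gapfill import exported_from_bounds, imported_from_bounds


def imported_metabolites(model: Model) -> Set[str]:
    """Metabolites whose exchange reactions permit uptake."""
    return imported_from_bounds(model)


def exported_metabolites(model: Model) -> Set[str]:
    """Metabolites whose sink reactions permit secretion."""
    return exported_from_bounds(model)


def community_exchanged(models: Iterable[Model]) -> Set[str]:
    """(union of exported) intersected with (union of imported)."""
    models = list(models)
    if not models:
        raise ValueError("community_exchanged needs at least one model")
    all_exported: Set[str] = set().union(*(exported_metabolites(m) for m in models))
    all_imported: Set[str] = set().union(*(imported_metabolites(m) for m in models))
    return all_exported & all_imported


def exchange_summary(communities: Mapping[str, List[Model]]) -> pd.DataFrame:
    """Per-approach summary: mean +/- sample sd of per-model import/export
    counts and the community exchanged-metabolite count."""
    rows = []
    for approach in sorted(communities):
        models = communities[approach]
        if not models:
            rows.append(
                {
                    "approach": approach,
                    "n_models": 0,
                    "mean_imported": "",
                    "sd_imported": "",
                    "mean_exported": "",
                    "sd_exported": "",
                    "n_exchanged": "",
                }
            )
            continue
        imp = np.array([len(imported_metabolites(m)) for m in models], dtype=float)
        exp = np.array([len(exported_metabolites(m)) for m in models], dtype=float)
        rows.append(
            {
                "approach": approach,
                "n_models": len(models),
                "mean_imported": f"{imp.mean():.6g}",
                "sd_imported": f"{imp.std(ddof=1):.6g}" if len(models) > 1 else "0",
                "mean_exported": f"{exp.mean():.6g}",
                "sd_exported": f"{exp.std(ddof=1):.6g}" if len(models) > 1 else "0",
                "n_exchanged": len(community_exchanged(models)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "approach",
            "n_models",
            "mean_imported",
            "sd_imported",
            "mean_exported",
            "sd_exported",
            "n_exchanged",
        ],
    )


def cross_approach_jaccard(communities: Mapping[str, List[Model]]) -> pd.DataFrame:
    """Approach x approach Jaccard similarity of exchanged-metabolite sets."""
    approaches = sorted(a for a, models in communities.items() if models)
    sets = {a: community_exchanged(communities[a]) for a in approaches}
    mat = pd.DataFrame(1.0, index=approaches, columns=approaches)
    for i, a1 in enumerate(approaches):
        for a2 in approaches[i + 1:]:
            sim = jaccard(sets[a1], sets[a2])
            mat.loc[a1, a2] = mat.loc[a2, a1] = sim
    return mat


def membership_matrix(communities: Mapping[str, List[Model]]) -> pd.DataFrame:
    """Metabolite x approach 0/1 matrix of exchanged-metabolite membership."""
    approaches = sorted(a for a, models in communities.items() if models)
    sets = {a: community_exchanged(communities[a]) for a in approaches}
    mets = sorted(set().union(*sets.values())) if sets else []
    return pd.DataFrame(
        [[int(m in sets[a]) for a in approaches] for m in mets],
        index=mets,
        columns=approaches,
    )
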