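"""Cross-tool comparison statistics.

Jaccard similarity of model feature sets (reactions, metabolites, dead
ends, genes), EC-subclass extraction, hypergeometric enrichment of enzyme
subclasses in shared (or shared-and-unblocked) reaction sets with
Benjamini-Hochberg correction, and the nonparametric group tests used to
contrast reconstruction approaches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Model, Reaction, find_dead_end_metabolites
from .errors import UndefinedStatisticError

FEATURES = ("reactions", "metabolites", "dead_ends", "genes")


def jaccard(a: Iterable, b: Iterable) -> float:
    """|a n b| / |a u b|; defined as 1.0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def feature_set(model: Model, feature: str) -> Set[str]:
    if feature == "reactions":
        return set(model.reactions)
    if feature == "metabolites":
        return set(model.metabolites)
    if feature == "dead_ends":
        return find_dead_end_metabolites(model)
    if feature == "genes":
        return set(model.genes)
    raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")


def pairwise_similarity(models_by_tool: Mapping[str, Model], feature: str) -> pd.DataFrame:
    """Symmetric tool x tool Jaccard matrix over one feature set."""
    tools = sorted(models_by_tool)
    sets = {t: feature_set(models_by_tool[t], feature) for t in tools}
    mat = pd.DataFrame(1.0, index=tools, columns=tools)
    for i, t1 in enumerate(tools):
        for t2 in tools[i + 1:]:
            sim = jaccard(sets[t1], sets[t2])
            mat.loc[t1, t2] = mat.loc[t2, t1] = sim
    return mat


_EC_FIELD = re.compile(r"^\d+$")


def ec_subclass(ec: str) -> Optional[str]:
    """First two fields of an EC number ('2.3.1.12' -> '2.3'); None when
    either of the two fields is non-numeric (e.g. '3.-.-.-')."""
    fields = ec.split(".")
    if len(fields) < 2:
        return None
    if _EC_FIELD.match(fields[0]) and _EC_FIELD.match(fields[1]):
        return f"{fields[0]}.{fields[1]}"
    return None


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentResult:
    """Hypergeometric test of one EC subclass in a target reaction set."""

    subclass: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    adjusted_p: float = float("nan")
    enriched: bool = False


def _subclasses_of(rxn: Reaction) -> Set[str]:
    return {s for s in (ec_subclass(ec) for ec in rxn.ec_numbers) if s is not None}


def enrich_ec_subclasses(
    target: Sequence[Reaction],
    background: Sequence[Reaction],
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Hypergeometric enrichment of EC subclasses in ``target`` vs ``background``.

    The population is the set of background reactions carrying at least one
    valid subclass annotation (N); the sample is the annotated target
    reactions (n). A reaction with EC numbers in several subclasses counts
    once per subclass. P-values are Benjamini-Hochberg adjusted; a subclass
    is enriched iff adjusted_p < alpha.
    """
    bg_ids = {r.id for r in background}
    stray = [r.id for r in target if r.id not in bg_ids]
    if stray:
        raise ValueError(f"target reactions not in background: {sorted(stray)}")
    bg_annotated = [r for r in background if _subclasses_of(r)]
    tg_annotated = [r for r in target if _subclasses_of(r)]
    N, n = len(bg_annotated), len(tg_annotated)
    counts_bg: Dict[str, int] = {}
    counts_tg: Dict[str, int] = {}
    for r in bg_annotated:
        for s in _subclasses_of(r):
            counts_bg[s] = counts_bg.get(s, 0) + 1
    for r in tg_annotated:
        for s in _subclasses_of(r):
            counts_tg[s] = counts_tg.get(s, 0) + 1
    results = [
        EnrichmentResult(
            subclass=s,
            k=counts_tg.get(s, 0),
            n=n,
            K=K,
            N=N,
            p_value=hypergeom_upper_tail(counts_tg.get(s, 0), n, K, N),
        )
        for s, K in sorted(counts_bg.items())
    ]
    if results:
        _, adjusted, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for res, adj in zip(results, adjusted):
            res.adjusted_p = float(adj)
            res.enriched = bool(adj < alpha)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subclass": r.subclass,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": f"{r.p_value:.6g}",
                "adjusted_p": f"{r.adjusted_p:.6g}",
                "enriched": int(r.enriched),
            }
            for r in results
        ],
        columns=["subclass", "k", "n", "K", "N", "p_value", "adjusted_p", "enriched"],
    )


@dataclass
class GroupTestResult:
    test: str
    statistic: float
    p_value: float


def group_tests(
    values_by_group: Mapping[str, Sequence[float]], paired: bool = False
) -> GroupTestResult:
    """Rank-based group comparison with tie correction.

    Kruskal-Wallis across >= 3 groups; Wilcoxon rank-sum (Mann-Whitney) for
    two groups; Pearson correlation for two paired numeric vectors.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise UndefinedStatisticError(f"group {g!r} has fewer than 2 observations")
    vals = list(groups.values())
    if paired:
        if len(vals) != 2 or len(vals[0]) != len(vals[1]):
            raise ValueError("paired comparison needs two equal-length groups")
        if np.ptp(vals[0]) == 0 or np.ptp(vals[1]) == 0:
            raise UndefinedStatisticError("zero variance in paired comparison")
        r, p = stats.pearsonr(vals[0], vals[1])
        return GroupTestResult("pearson", float(r), float(p))
    if len(vals) == 2:
        stat, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return GroupTestResult("wilcoxon_rank_sum", float(stat), float(p))
    if np.ptp(np.concatenate(vals)) == 0:
        # all observations identical: H is exactly 0, nothing to reject
        return GroupTestResult("kruskal_wallis", 0.0, 1.0)
    stat, p = stats.kruskal(*vals)
    return GroupTestResult("kruskal_wallis", float(stat), float(p))
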