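"""Parsimony pathway inference and pathway enrichment.

Naive one-hit mapping of observed functions (KOs or ECs) to every pathway
containing them inflates the inferred functional repertoire. Instead the
community's pathway content is taken to be a minimum-cardinality set of
pathways that jointly covers all observed functions — a minimum set
cover, solved exactly for small candidate sets and greedily above a size
limit. Enrichment between conditions follows the gene-set idea of testing
whether a pathway's members show coordinated fold changes: a two-sample
Welch t test of member log2 fold changes against non-member log2 fold
changes, BH-adjusted across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .compare_stats import bh_adjust

DEFAULT_EXACT_LIMIT = 20
DEFAULT_MIN_SET_SIZE = 3


@dataclass
class PathwayInference:
    pathways: list[str]  # sorted minimal cover
    mode: str  # "exact" | "greedy"
    covered: set[str]
    dropped_functions: set[str]  # observed functions in no definition
    optimality_gap_possible: bool  # True only in greedy mode


def _solution_key(
    solution: tuple[str, ...], defs: Mapping[str, set[str]], observed: set[str]
) -> tuple:
    """Ordering key among equal-size covers: prefer more observed functions
    covered per pathway (summed), then lexicographically smallest id tuple."""
    coverage = sum(len(defs[p] & observed) for p in solution)
    return (-coverage, tuple(sorted(solution)))


def infer_minimal_pathways(
    observed_functions: set[str],
    defs: Mapping[str, set[str]],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> PathwayInference:
    """Minimum-cardinality pathway set covering the observed functions.

    Functions belonging to no definition are dropped with a warning.
    Exact search (increasing subset size) when the number of candidate
    pathways (those intersecting the observed set) is at most
    ``exact_limit``; greedy set cover otherwise, flagged as potentially
    suboptimal. Ties among optimal covers prefer pathways covering more
    observed functions, then lexicographic ids.
    """
    observed = set(observed_functions)
    if not observed:
        raise ValueError("empty observed function set")
    coverable = observed & set().union(*defs.values()) if defs else set()
    dropped = observed - coverable
    if dropped:
        warnings.warn(
            f"{len(dropped)} observed functions belong to no pathway definition",
            stacklevel=2,
        )
    if not coverable:
        raise ValueError("no observed function belongs to any pathway definition")
    candidates = sorted(p for p in defs if defs[p] & coverable)
    if len(candidates) <= exact_limit:
        chosen = _exact_cover(coverable, defs, candidates)
        mode, gap = "exact", False
    else:
        chosen = _greedy_cover(coverable, defs, candidates)
        mode, gap = "greedy", True
    return PathwayInference(
        pathways=sorted(chosen),
        mode=mode,
        covered=coverable,
        dropped_functions=dropped,
        optimality_gap_possible=gap,
    )


def _exact_cover(
    observed: set[str], defs: Mapping[str, set[str]], candidates: list[str]
) -> tuple[str, ...]:
    for size in range(1, len(candidates) + 1):
        best: tuple[str, ...] | None = None
        best_key: tuple | None = None
        for combo in combinations(candidates, size):
            union: set[str] = set()
            for p in combo:
                union |= defs[p]
            if observed <= union:
                key = _solution_key(combo, defs, observed)
                if best_key is None or key < best_key:
                    best, best_key = combo, key
        if best is not None:
            return best
    raise AssertionError("unreachable: candidates jointly cover the observed set")


def _greedy_cover(
    observed: set[str], defs: Mapping[str, set[str]], candidates: list[str]
) -> tuple[str, ...]:
    uncovered = set(observed)
    chosen: list[str] = []
    remaining = list(candidates)
    while uncovered:
        # max new coverage; ties by total observed coverage, then id
        best = min(
            remaining,
            key=lambda p: (
                -len(defs[p] & uncovered),
                -len(defs[p] & observed),
                p,
            ),
        )
        gain = defs[best] & uncovered
        if not gain:
            break
        chosen.append(best)
        uncovered -= gain
        remaining.remove(best)
    return tuple(chosen)


def welch_t(member: np.ndarray, background: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t statistic, degrees of freedom and two-sided p.

    Degenerate cases are resolved deterministically: identical constant
    groups give (0, inf, 1); zero pooled standard error with unequal means
    gives (±inf, inf, 0).
    """
    m1, m2 = member.mean(), background.mean()
    n1, n2 = len(member), len(background)
    v1 = member.var(ddof=1) if n1 > 1 else 0.0
    v2 = background.var(ddof=1) if n2 > 1 else 0.0
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        if m1 == m2:
            return 0.0, float("inf"), 1.0
        return float(np.sign(m1 - m2)) * float("inf"), float("inf"), 0.0
    t = (m1 - m2) / np.sqrt(se2)
    num = se2**2
    den = 0.0
    if n1 > 1:
        den += (v1 / n1) ** 2 / (n1 - 1)
    if n2 > 1:
        den += (v2 / n2) ** 2 / (n2 - 1)
    df = num / den if den > 0 else float("inf")
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def pathway_enrichment(
    de: pd.DataFrame,
    defs: Mapping[str, set[str]],
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> pd.DataFrame:
    """Coordinated-fold-change enrichment per pathway.

    For each pathway with at least ``min_set_size`` members present in the
    differential-expression table, tests member log2 fold changes against
    all non-member log2 fold changes with a two-sided Welch t test; the
    sign of t gives the direction (enriched = members up relative to
    background). BH adjustment across the tested pathways.

    Returns a frame indexed by pathway: n_members, statistic, df, p_value,
    fdr, direction. Empty (with a warning) when no pathway is testable.
    """
    fc = de["log2_fc"]
    rows = []
    for pathway in sorted(defs):
        members = sorted(defs[pathway] & set(fc.index))
        if len(members) < min_set_size:
            continue
        member_fc = fc.loc[members].to_numpy(dtype=float)
        background = fc.drop(index=members).to_numpy(dtype=float)
        if len(background) < 2:
            continue
        t, df, p = welch_t(member_fc, background)
        rows.append((pathway, len(members), t, df, p))
    if not rows:
        warnings.warn("no pathway reaches the minimum testable size", stacklevel=2)
        return pd.DataFrame(
            columns=["n_members", "statistic", "df", "p_value", "fdr", "direction"]
        )
    out = pd.DataFrame(
        rows, columns=["pathway", "n_members", "statistic", "df", "p_value"]
    ).set_index("pathway")
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["direction"] = np.where(out["statistic"] >= 0, "enriched", "depleted")
    return out
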