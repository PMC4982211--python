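"""Depletion of non-coding-RNA-derived reads and reduced-database evaluation.

Metatranscriptome libraries are dominated by rRNA/tRNA; reads whose best
alignment to an ncRNA reference falls below an e-value threshold (default
1e-5, strict) are excluded before functional analysis. Because full ncRNA
databases are highly redundant, a random subset can stand in for the full
database; the subset's agreement with the full database is summarised by
relative accuracy (overlap / subset total) and relative sensitivity
(overlap / full-database total).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tab import AlignmentHit, best_hits, hits_frame

DEFAULT_EVALUE = 1e-5


@dataclass(frozen=True)
class FilterReport:
    n_input_reads: int
    n_flagged_ncrna: int
    n_retained: int
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_flagged_ncrna + self.n_retained != self.n_input_reads:
            raise ValueError("flagged + retained must equal input reads")


@dataclass(frozen=True)
class SubsetEvaluation:
    """Agreement between ncRNA flagging with a reduced vs the full database."""

    n_common: int
    n_subset_total: int
    n_full_total: int
    relative_accuracy: float
    relative_sensitivity: float


def flag_ncrna_reads(
    hits: Iterable[AlignmentHit] | pd.DataFrame,
    threshold: float = DEFAULT_EVALUE,
    all_read_ids: Iterable[str] | None = None,
) -> tuple[set[str], FilterReport]:
    """Flag reads whose best ncRNA hit has e-value strictly below ``threshold``.

    Best-hit semantics: minimum e-value, ties by maximum bit score then
    lexicographic subject id. Reads with no hit at all are retained. If
    ``all_read_ids`` is given, the report counts the whole read population;
    otherwise only reads appearing in ``hits`` are counted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    frame = hits_frame(hits)
    if frame.empty:
        flagged: set[str] = set()
    else:
        best = best_hits(frame)
        flagged = set(best.loc[best["e_value"] < threshold, "read_id"])
    if all_read_ids is not None:
        universe = set(all_read_ids)
        missing = flagged - universe
        if missing:
            raise ValueError(f"{len(missing)} flagged reads absent from all_read_ids")
    else:
        universe = set(frame["read_id"]) if len(frame) else set()
    n_input = len(universe)
    report = FilterReport(
        n_input_reads=n_input,
        n_flagged_ncrna=len(flagged),
        n_retained=n_input - len(flagged),
        threshold=threshold,
    )
    return flagged, report


def sample_reference_subset(records: Sequence, fraction: float, seed: int) -> list:
    """Sample floor(fraction * N) FASTA records uniformly without replacement.

    ``records`` is any sequence of Bio.SeqRecord (or anything else); the
    original record order is preserved in the output. Deterministic given
    ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(records)
    if n == 0:
        raise ValueError("no records to sample from")
    k = int(np.floor(fraction * n))
    if fraction == 1.0:
        return list(records)
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=k, replace=False))
    return [records[i] for i in chosen]


def evaluate_subset(flagged_subset: set[str], flagged_full: set[str]) -> SubsetEvaluation:
    """Relative accuracy and sensitivity of a reduced database's flagging.

    accuracy = |subset ∩ full| / |subset|; sensitivity = |subset ∩ full| /
    |full|. Either ratio is defined as 1.0 when its denominator is zero
    (an empty flag set trivially agrees with itself).
    """
    common = len(flagged_subset & flagged_full)
    n_sub = len(flagged_subset)
    n_full = len(flagged_full)
    return SubsetEvaluation(
        n_common=common,
        n_subset_total=n_sub,
        n_full_total=n_full,
        relative_accuracy=common / n_sub if n_sub else 1.0,
        relative_sensitivity=common / n_full if n_full else 1.0,
    )
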