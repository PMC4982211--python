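"""Functional profiling: best-hit gene assignment and relative abundances.

Each retained read is assigned to the gene of its best sub-threshold hit
(e-value < 1e-5 by default). Gene counts are then aggregated per
annotation system (KO, COG, EC): a gene annotated to k features
contributes its full count to each of the k features, and abundances are
normalised to the per-system annotated total of each sample, so every
non-degenerate profile column sums to 1. Higher hierarchy levels (COG
categories, KEGG pathways / modules / pathway classes, MetaCyc pathway
levels) are obtained by rolling feature abundances up a child->parent map
and re-normalising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_tab import AlignmentHit, AnnotationMap, HierarchyMap, best_hits, hits_frame

DEFAULT_EVALUE = 1e-5
UNCLASSIFIED = "Unclassified"


@dataclass
class AbundanceProfile:
    """feature x sample matrix of relative abundances for one system/level."""

    system: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        colsum = self.data.sum(axis=0)
        nonzero = colsum[colsum > 0]
        if len(nonzero) and not np.allclose(nonzero, 1.0, atol=1e-9):
            raise ValueError(f"profile columns for {self.system} do not sum to 1")
        if (self.data.values < 0).any():
            raise ValueError("negative abundance")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns


def assign_best_gene(
    hits: Iterable[AlignmentHit] | pd.DataFrame,
    threshold: float = DEFAULT_EVALUE,
) -> pd.Series:
    """Per-gene read counts for one sample from reads-vs-gene alignments.

    Each read goes to the gene of its best hit (min e-value, ties by max
    bit score then subject id) provided that hit's e-value is strictly
    below ``threshold``; otherwise the read is unassigned.
    """
    frame = hits_frame(hits)
    if frame.empty:
        return pd.Series(dtype="int64", name="count")
    best = best_hits(frame)
    kept = best[best["e_value"] < threshold]
    counts = kept.groupby("subject_id").size().sort_index()
    counts.name = "count"
    counts.index.name = "gene_id"
    return counts


def gene_count_matrix(per_sample: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample gene counts into a gene x sample integer matrix."""
    frame = pd.DataFrame(
        {sample: per_sample[sample] for sample in per_sample}
    ).fillna(0).astype("int64")
    return frame.sort_index()


def _membership(annot_system: Mapping[str, set[str]], genes: pd.Index) -> dict[str, list[str]]:
    """feature -> list of genes (restricted to ``genes``) annotated to it."""
    members: dict[str, list[str]] = {}
    gene_set = set(genes)
    for gene, features in annot_system.items():
        if gene not in gene_set:
            continue
        for feat in features:
            members.setdefault(feat, []).append(gene)
    return members


def profile_features(
    counts: pd.DataFrame,
    annot: AnnotationMap,
    system: str,
) -> AbundanceProfile:
    """Relative-abundance profile of one annotation system.

    ``counts`` is a gene x sample matrix of best-hit read counts. Feature
    count = sum of its genes' counts (a multi-annotated gene contributes
    fully to each feature); abundances are normalised per sample by that
    system's annotated total. A sample with zero annotated reads keeps an
    all-zero column and triggers a warning.
    """
    if system not in annot.systems:
        raise KeyError(f"annotation system {system!r} not in map")
    members = _membership(annot.systems[system], counts.index)
    if members:
        rows = {
            feat: counts.loc[genes].sum(axis=0) for feat, genes in members.items()
        }
        raw = pd.DataFrame(rows).T.sort_index()
    else:
        raw = pd.DataFrame(index=pd.Index([], name="feature"), columns=counts.columns, dtype=float)
    totals = raw.sum(axis=0)
    zero_samples = [s for s in counts.columns if totals.get(s, 0) == 0]
    if zero_samples:
        warnings.warn(
            f"samples with no {system}-annotated reads: {zero_samples}", stacklevel=2
        )
    data = raw.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    data = data.reindex(columns=counts.columns, fill_value=0.0)
    data.index.name = "feature"
    return AbundanceProfile(system=system, data=data)


def rollup(
    profile: AbundanceProfile,
    hier: HierarchyMap | Mapping[str, set[str]],
    level: str,
) -> AbundanceProfile:
    """Aggregate a profile one hierarchy level up and re-normalise.

    Parent abundance is the sum of its children's relative abundances; a
    child with several parents contributes fully to each, so columns are
    re-normalised to 1 afterwards. Children absent from the map fall under
    the "Unclassified" parent.
    """
    if isinstance(hier, HierarchyMap):
        if level not in hier.levels:
            raise KeyError(f"hierarchy level {level!r} not defined")
        child_parents = hier.levels[level]
    else:
        child_parents = hier
    rows: dict[str, np.ndarray] = {}
    for child in profile.data.index:
        parents = child_parents.get(child) or {UNCLASSIFIED}
        vec = profile.data.loc[child].to_numpy(dtype=float)
        for parent in parents:
            if parent in rows:
                rows[parent] = rows[parent] + vec
            else:
                rows[parent] = vec.copy()
    raw = pd.DataFrame(rows, index=profile.data.columns).T.sort_index()
    totals = raw.sum(axis=0)
    data = raw.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    data.index.name = "feature"
    return AbundanceProfile(system=f"{profile.system}:{level}", data=data)
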