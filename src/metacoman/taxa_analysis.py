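"""Taxonomy-resolved expression analyses at phylum level.

A functional group's per-sample relative abundance is an exact sum over
the contributing genes, hence over the phyla those genes come from. This
makes three analyses possible:

* contribution — decompose the between-condition change of each "most
  varied" functional group additively by phylum, and report each phylum's
  share of the total absolute change plus the top contributor;
* distribution — per condition, the fraction of a functional group's reads
  contributed by each phylum;
* transcription activation — divide expression by the phylum's metagenomic
  abundance in the same sample, separating genuine transcriptional
  regulation from mere shifts in community composition, and compare the
  normalised values between conditions (Wilcoxon + BH).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .compare_stats import bh_adjust, rank_sum_p
from .io_tab import AnnotationMap, SampleMetadata
from .profiling import UNCLASSIFIED


def feature_phylum_components(
    counts: pd.DataFrame,
    annot: AnnotationMap,
    system: str,
    features: Iterable[str] | None = None,
) -> pd.DataFrame:
    """(feature, phylum) x sample matrix of relative-abundance components.

    ``counts`` is the gene x sample best-hit count matrix. Components use
    the same per-system annotated-total denominator as profiling, so
    summing a feature's phylum components reproduces its profile entry.
    """
    if system not in annot.systems:
        raise KeyError(f"annotation system {system!r} not in map")
    gene_map = annot.systems[system]
    wanted = set(features) if features is not None else None
    # per-sample annotated totals (each gene counted once per feature annotation)
    rows: dict[tuple[str, str], np.ndarray] = {}
    total = np.zeros(counts.shape[1])
    for gene in counts.index:
        feats = gene_map.get(gene)
        if not feats:
            continue
        vec = counts.loc[gene].to_numpy(dtype=float)
        phylum = annot.phylum(gene)
        for feat in feats:
            total = total + vec
            if wanted is not None and feat not in wanted:
                continue
            key = (feat, phylum)
            rows[key] = rows[key] + vec if key in rows else vec.copy()
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["feature", "phylum"]),
            columns=counts.columns,
            dtype=float,
        )
    frame = pd.DataFrame(rows, index=counts.columns).T
    frame.index.names = ["feature", "phylum"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frame = frame.div(pd.Series(total, index=counts.columns).replace(0, np.nan), axis=1)
    return frame.fillna(0.0).sort_index()


def taxon_contribution(
    counts: pd.DataFrame,
    annot: AnnotationMap,
    meta: SampleMetadata,
    features: Iterable[str],
    system: str = "KO",
) -> pd.DataFrame:
    """Phylum-wise decomposition of each feature's between-condition change.

    For feature f and phylum p: delta = mean over condition-B samples minus
    mean over condition-A samples of the phylum-p abundance component;
    share = |delta| / sum_q |delta_q|; top_phylum = phylum with the largest
    share (ties to the lexicographically smaller name). Features with reads
    but zero total change are flagged ``no_variation``; features with no
    reads at all are dropped with a warning.

    Returns a frame indexed by (feature, phylum): delta, share, top_phylum
    flag.
    """
    features = list(features)
    comp = feature_phylum_components(counts, annot, system, features)
    cond_a, cond_b = meta.conditions
    sa = [s for s in meta.samples_of(cond_a) if s in comp.columns]
    sb = [s for s in meta.samples_of(cond_b) if s in comp.columns]
    records = []
    missing = []
    for feat in features:
        if feat not in comp.index.get_level_values("feature"):
            missing.append(feat)
            continue
        block = comp.loc[feat]
        delta = block[sb].mean(axis=1) - block[sa].mean(axis=1)
        total_abs = delta.abs().sum()
        if total_abs > 0:
            share = delta.abs() / total_abs
            top = share.sort_index().idxmax()  # ties -> lexicographic via sorted index
            flag = ""
        else:
            share = pd.Series(np.nan, index=delta.index)
            top = None
            flag = "no_variation"
        for phylum in sorted(delta.index):
            records.append(
                (
                    feat,
                    phylum,
                    float(delta[phylum]),
                    float(share[phylum]) if total_abs > 0 else np.nan,
                    phylum == top,
                    flag,
                )
            )
    if missing:
        warnings.warn(f"features with no reads dropped: {sorted(missing)}", stacklevel=2)
    out = pd.DataFrame(
        records, columns=["feature", "phylum", "delta", "share", "top_phylum", "flag"]
    )
    return out.set_index(["feature", "phylum"]).sort_index()


def taxon_distribution(
    counts: pd.DataFrame,
    annot: AnnotationMap,
    meta: SampleMetadata,
    features: Iterable[str],
    system: str = "KO",
) -> pd.DataFrame:
    """Per (feature, condition), each phylum's fraction of the feature's reads.

    Fractions are computed from summed read counts over the condition's
    samples; (feature, condition) pairs without reads yield no rows.
    """
    features = list(features)
    if system not in annot.systems:
        raise KeyError(f"annotation system {system!r} not in map")
    gene_map = annot.systems[system]
    wanted = set(features)
    rows: dict[tuple[str, str, str], float] = {}
    for gene in counts.index:
        feats = gene_map.get(gene)
        if not feats:
            continue
        phylum = annot.phylum(gene)
        gene_counts = counts.loc[gene]
        for feat in feats:
            if feat not in wanted:
                continue
            for cond in meta.conditions:
                c = float(gene_counts[[s for s in meta.samples_of(cond) if s in counts.columns]].sum())
                if c > 0:
                    key = (feat, cond, phylum)
                    rows[key] = rows.get(key, 0.0) + c
    if not rows:
        return pd.DataFrame(
            index=pd.MultiIndex.from_tuples([], names=["feature", "condition", "phylum"]),
            columns=["fraction"],
        )
    series = pd.Series(rows)
    series.index.names = ["feature", "condition", "phylum"]
    totals = series.groupby(level=["feature", "condition"]).transform("sum")
    out = (series / totals).to_frame("fraction").sort_index()
    return out


def transcription_activation(
    expression: pd.DataFrame,
    phylum_of: Mapping[str, str],
    taxa_profile: pd.DataFrame,
    meta: SampleMetadata,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise expression by phylum metagenomic abundance and compare conditions.

    ``expression`` is a feature/gene x sample matrix (relative abundances
    or counts); ``phylum_of`` assigns each row a phylum; ``taxa_profile``
    is a phylum x sample table of metagenomic abundances (fractions, or
    counts which are normalised per sample). The normalised value is
    expression / phylum fraction; where the phylum fraction is zero the
    value is missing (with a warning when the expression there is nonzero).
    Per feature, a two-sided Wilcoxon rank-sum test between conditions on
    the normalised values, BH-adjusted.

    Returns (normalised matrix, stats frame indexed by feature with
    mean_a, mean_b, p_value, fdr).
    """
    taxa = taxa_profile.copy().astype(float)
    colsum = taxa.sum(axis=0)
    if (colsum > 1 + 1e-6).any():
        taxa = taxa.div(colsum.replace(0, np.nan), axis=1)
    common = [s for s in expression.columns if s in taxa.columns]
    if not common:
        raise ValueError("expression and taxa profile share no samples")
    expr = expression[common].astype(float)
    normalised = pd.DataFrame(np.nan, index=expr.index, columns=common)
    warned = False
    for feat in expr.index:
        phylum = phylum_of.get(feat, UNCLASSIFIED)
        if phylum not in taxa.index:
            continue
        frac = taxa.loc[phylum, common].to_numpy(dtype=float)
        vals = expr.loc[feat].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(frac > 0, vals / frac, np.nan)
        if not warned and np.any((frac == 0) & (vals > 0)):
            warnings.warn(
                "zero phylum abundance with nonzero expression: values set missing",
                stacklevel=2,
            )
            warned = True
        normalised.loc[feat] = norm
    cond_a, cond_b = meta.conditions
    sa = [s for s in meta.samples_of(cond_a) if s in common]
    sb = [s for s in meta.samples_of(cond_b) if s in common]
    stats = []
    for feat in normalised.index:
        va = normalised.loc[feat, sa].dropna().to_numpy(dtype=float)
        vb = normalised.loc[feat, sb].dropna().to_numpy(dtype=float)
        if len(va) == 0 or len(vb) == 0:
            stats.append((feat, np.nan, np.nan, np.nan))
            continue
        stats.append((feat, va.mean(), vb.mean(), rank_sum_p(va, vb)))
    table = pd.DataFrame(stats, columns=["feature", "mean_a", "mean_b", "p_value"]).set_index(
        "feature"
    )
    tested = table["p_value"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if tested.any():
        fdr[tested] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
    table["fdr"] = fdr
    return normalised, table
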