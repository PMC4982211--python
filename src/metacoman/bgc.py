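"""Transcriptionally active biosynthetic gene clusters (BGCs).

A BGC is called detected in a sample when at least half of its
biosynthetic genes (non-biosynthetic members are excluded) carry at least
one assigned read. The detected cluster's abundance score is the mean
abundance of its biosynthetic genes, with uncovered genes contributing
zero (a covered-genes-only mean is available by flag). Per-sample BGC-type
abundances (sums of detected cluster scores by antiSMASH-style type) are
compared between conditions with Wilcoxon rank-sum tests, BH-adjusted,
alongside a per-sample type-proportion table.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compare_stats import bh_adjust, rank_sum_p
from .io_tab import SampleMetadata

DEFAULT_MIN_COV = 0.5


@dataclass(frozen=True)
class BgcRecord:
    cluster_id: str
    genes: tuple[str, ...]
    biosynthetic: tuple[bool, ...]
    bgc_type: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.biosynthetic):
            raise ValueError("genes and biosynthetic flags differ in length")
        if not self.bgc_type:
            raise ValueError("BGC type must be non-empty")

    @property
    def biosynthetic_genes(self) -> tuple[str, ...]:
        return tuple(g for g, b in zip(self.genes, self.biosynthetic) if b)


def read_bgc_definitions(path: str | os.PathLike) -> list[BgcRecord]:
    """Read a 4-column TSV: cluster_id, gene_id, biosynthetic (0/1), bgc_type."""
    frame = pd.read_csv(
        path,
        sep="\t",
        names=["cluster_id", "gene_id", "biosynthetic", "bgc_type"],
        dtype={"cluster_id": str, "gene_id": str, "bgc_type": str},
    )
    if frame["biosynthetic"].dtype == object and (frame["biosynthetic"] == "biosynthetic").any():
        # header row present
        frame = frame.iloc[1:].reset_index(drop=True)
    frame["biosynthetic"] = frame["biosynthetic"].astype(int).astype(bool)
    records = []
    for cluster_id, block in frame.groupby("cluster_id", sort=True):
        types = block["bgc_type"].unique()
        if len(types) != 1:
            raise ValueError(f"cluster {cluster_id!r} has inconsistent types {sorted(types)}")
        records.append(
            BgcRecord(
                cluster_id=str(cluster_id),
                genes=tuple(block["gene_id"]),
                biosynthetic=tuple(block["biosynthetic"]),
                bgc_type=str(types[0]),
            )
        )
    return records


def write_bgc_definitions(records: list[BgcRecord], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for rec in sorted(records, key=lambda r: r.cluster_id):
            for gene, bio in zip(rec.genes, rec.biosynthetic):
                fh.write(f"{rec.cluster_id}\t{gene}\t{int(bio)}\t{rec.bgc_type}\n")


def gene_abundances(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene fraction of a sample's total assigned reads."""
    totals = counts.sum(axis=0).astype(float)
    return counts.div(totals.replace(0, np.nan), axis=1).fillna(0.0)


def score_bgc(
    abundances: pd.Series,
    record: BgcRecord,
    min_cov: float = DEFAULT_MIN_COV,
    covered_only: bool = False,
) -> dict:
    """Coverage and abundance score of one cluster in one sample.

    ``abundances`` maps gene -> abundance for that sample. covered_fraction
    is the fraction of biosynthetic genes with nonzero abundance; the
    cluster is detected iff covered_fraction >= ``min_cov``, and then
    scored as the mean abundance over all biosynthetic genes (uncovered
    genes count as 0) — or over covered genes only with
    ``covered_only=True``. The score is None when not detected.
    """
    bio = record.biosynthetic_genes
    if not bio:
        raise ValueError(f"cluster {record.cluster_id!r} has no biosynthetic genes")
    values = np.array([float(abundances.get(g, 0.0)) for g in bio])
    covered = values > 0
    covered_fraction = covered.mean()
    detected = bool(covered_fraction >= min_cov)
    score = None
    if detected:
        score = float(values[covered].mean()) if covered_only else float(values.mean())
    return {
        "cluster_id": record.cluster_id,
        "bgc_type": record.bgc_type,
        "detected": detected,
        "covered_fraction": float(covered_fraction),
        "score": score,
    }


def score_all_bgcs(
    counts: pd.DataFrame,
    records: list[BgcRecord],
    min_cov: float = DEFAULT_MIN_COV,
    covered_only: bool = False,
) -> pd.DataFrame:
    """Score every cluster in every sample.

    ``counts`` is the gene x sample best-hit count matrix; abundances are
    fractions of each sample's total assigned reads. Clusters with no
    biosynthetic genes are skipped with a warning. Returns a long frame
    (cluster_id, sample_id, bgc_type, detected, covered_fraction, score).
    """
    abund = gene_abundances(counts)
    rows = []
    skipped = []
    for record in sorted(records, key=lambda r: r.cluster_id):
        if not record.biosynthetic_genes:
            skipped.append(record.cluster_id)
            continue
        for sample in abund.columns:
            res = score_bgc(abund[sample], record, min_cov=min_cov, covered_only=covered_only)
            rows.append(
                (
                    record.cluster_id,
                    sample,
                    record.bgc_type,
                    res["detected"],
                    res["covered_fraction"],
                    res["score"] if res["score"] is not None else np.nan,
                )
            )
    if skipped:
        warnings.warn(f"clusters without biosynthetic genes skipped: {skipped}", stacklevel=2)
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "sample_id", "bgc_type", "detected", "covered_fraction", "score"],
    )


def compare_bgc_types(
    scores: pd.DataFrame,
    meta: SampleMetadata,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-condition comparison of per-type BGC abundance.

    Per sample, a type's abundance is the sum of scores of its detected
    clusters (types detected in no sample are dropped). Returns
    (type DE frame indexed by bgc_type: mean_a, mean_b, p_value, fdr;
    proportion frame bgc_type x sample summing to 1 per sample with any
    detection).
    """
    if scores.empty or not scores["detected"].any():
        raise ValueError("no detected cluster in any sample")
    det = scores[scores["detected"]]
    samples = sorted(scores["sample_id"].unique())
    type_ab = (
        det.pivot_table(
            index="bgc_type", columns="sample_id", values="score", aggfunc="sum", fill_value=0.0
        )
        .reindex(columns=samples, fill_value=0.0)
        .sort_index()
    )
    type_ab = type_ab[(type_ab.sum(axis=1) > 0)]
    cond_a, cond_b = meta.conditions
    sa = [s for s in meta.samples_of(cond_a) if s in type_ab.columns]
    sb = [s for s in meta.samples_of(cond_b) if s in type_ab.columns]
    rows = []
    for bgc_type in type_ab.index:
        va = type_ab.loc[bgc_type, sa].to_numpy(dtype=float)
        vb = type_ab.loc[bgc_type, sb].to_numpy(dtype=float)
        rows.append((bgc_type, va.mean(), vb.mean(), rank_sum_p(va, vb)))
    de = pd.DataFrame(rows, columns=["bgc_type", "mean_a", "mean_b", "p_value"]).set_index(
        "bgc_type"
    )
    de["fdr"] = bh_adjust(de["p_value"].to_numpy())
    totals = type_ab.sum(axis=0)
    proportions = type_ab.div(totals.replace(0, np.nan), axis=1).fillna(0.0)
    return de, proportions
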