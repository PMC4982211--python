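"""Seeded synthetic datasets with planted signals.

Generates everything the pipeline consumes — per-sample alignment tables
in BLAST tabular form, gene annotation and phylum maps, a KO->pathway map
doubling as pathway definitions, BGC definitions, sample metadata and a
phylum-level metagenomic profile — all from one seed, with truth tables
recording every planted signal.

Generative model: baseline functional-group proportions come from a
symmetric Dirichlet; condition-B proportions multiply planted features
(and genes of the boosted BGC type) by their fold changes and
renormalise; per-sample read counts are multinomial over genes; each read
emits one sub-threshold alignment row. Reads flagged as non-coding RNA
and junk reads whose only hit is above the e-value cutoff are included so
the filtering rules are exercised end to end.

Two modelling choices matter. Planted differential features are assigned
a low baseline abundance (default 5e-4 each): regulated, inducible
functions are rarely part of the dominant housekeeping core, and the low
baseline keeps the planted mass from perceptibly shifting every other
feature's relative abundance through renormalisation. Inter-subject
biological variability is multiplicative lognormal per feature and sample
(default sigma of 0.6 on the log2 scale, about 45% CV regardless of
abundance), which dominates the multinomial sequencing noise at realistic
depth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tab import (
    AnnotationMap,
    HierarchyMap,
    M8_COLUMNS,
    SampleMetadata,
    write_metadata,
    write_pair_map,
)
from .bgc import BgcRecord, write_bgc_definitions
from .profiling import AbundanceProfile


@dataclass
class SimulationConfig:
    """Knobs of the synthetic community.

    Defaults are the study conditions used throughout the test-suite:
    9 samples per condition, 200 KO functional groups, 10 features planted
    at 4-fold up-regulation in the second condition.
    """

    n_samples_per_condition: int = 9
    n_features: int = 200
    genes_per_feature: int = 3
    reads_per_sample: int = 50_000
    n_planted: int = 10
    planted_fold: float = 4.0
    planted_phylum: str | None = "Firmicutes"
    phyla: tuple[str, ...] = (
        "Actinobacteria",
        "Bacteroidetes",
        "Firmicutes",
        "Proteobacteria",
    )
    n_pathways: int = 20
    n_bgc: int = 12
    bgc_types: tuple[str, ...] = ("NRPS", "PKS", "bacteriocin", "terpene")
    planted_bgc_type: str | None = "NRPS"
    planted_bgc_fold: float = 4.0
    dirichlet_concentration: float = 5.0
    planted_baseline: float = 5e-4
    sample_log2_sigma: float | None = 0.6
    junk_read_fraction: float = 0.05
    n_ncrna_reads: int = 500
    conditions: tuple[str, str] = ("control", "treatment")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("more planted features than features")
        for name in ("n_samples_per_condition", "n_features", "genes_per_feature", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.planted_fold <= 0 or self.planted_bgc_fold <= 0:
            raise ValueError("fold multipliers must be positive")


@dataclass
class SimulatedBundle:
    """In-memory synthetic dataset plus ground truth."""

    config: SimulationConfig
    meta: SampleMetadata
    annot: AnnotationMap
    hierarchy: HierarchyMap
    pathway_defs: dict[str, set[str]]
    bgc_records: list[BgcRecord]
    gene_m8: dict[str, pd.DataFrame]  # sample -> reads-vs-genes hits
    ncrna_m8: dict[str, pd.DataFrame]  # sample -> reads-vs-ncRNA hits
    taxa_profile: pd.DataFrame  # phylum x sample fractions
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)


def _feature_id(j: int) -> str:
    return f"K{j:05d}"


def _gene_id(i: int) -> str:
    return f"g{i:05d}"


def simulate_feature_profile(
    n_features: int,
    n_per_condition: int,
    reads_per_sample: int,
    planted: dict[int, float],
    concentration: float,
    seed: int,
    conditions: tuple[str, str] = ("control", "treatment"),
    sample_log2_sigma: float | None = 0.6,
    planted_baseline: float | None = 5e-4,
) -> tuple[AbundanceProfile, SampleMetadata, pd.DataFrame]:
    """Feature-level profile simulation (no gene/alignment layer).

    Baseline proportions ~ symmetric Dirichlet(concentration), with planted
    features re-assigned the low baseline ``planted_baseline`` (``None``
    keeps their Dirichlet draw); condition-B proportions multiply planted
    feature indices by their folds and renormalise. Each sample's own
    composition is the condition composition perturbed by per-feature
    lognormal noise of scale ``sample_log2_sigma`` on the log2 scale
    (inter-subject biological variability; ``None`` disables it), and read
    counts are multinomial on top. Returns (profile, metadata, truth).
    """
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_features, concentration))
    if planted_baseline is not None and planted:
        for idx in planted:
            base[idx] = planted_baseline
        base /= base.sum()
    boosted = base.copy()
    for idx, fold in planted.items():
        boosted[idx] *= fold
    boosted /= boosted.sum()
    features = [_feature_id(j) for j in range(n_features)]
    cond_a, cond_b = sorted(conditions)
    samples: dict[str, str] = {}
    columns = {}
    for label, props in ((cond_a, base), (cond_b, boosted)):
        for i in range(n_per_condition):
            sample = f"{label}_{i+1:02d}"
            samples[sample] = label
            sample_props = props
            if sample_log2_sigma is not None:
                noise = 2.0 ** rng.normal(0.0, sample_log2_sigma, size=n_features)
                sample_props = props * noise
                sample_props = sample_props / sample_props.sum()
            counts = rng.multinomial(reads_per_sample, sample_props)
            columns[sample] = counts / counts.sum()
    data = pd.DataFrame(columns, index=pd.Index(features, name="feature"))
    truth = pd.DataFrame(
        {
            "feature": [_feature_id(j) for j in sorted(planted)],
            "fold": [planted[j] for j in sorted(planted)],
        }
    )
    return AbundanceProfile(system="KO", data=data), SampleMetadata(samples), truth


def _random_m8_rows(
    rng: np.random.Generator,
    read_ids: np.ndarray,
    subject_ids: np.ndarray,
    log10_evalue_range: tuple[float, float],
) -> pd.DataFrame:
    n = len(read_ids)
    identity = np.round(rng.uniform(90.0, 100.0, n), 1)
    evalue = 10.0 ** rng.uniform(*log10_evalue_range, size=n)
    frame = pd.DataFrame(
        {
            "read_id": read_ids,
            "subject_id": subject_ids,
            "pct_identity": identity,
            "aln_length": np.full(n, 100, dtype=int),
            "mismatches": np.round((100 - identity)).astype(int),
            "gap_opens": np.zeros(n, dtype=int),
            "q_start": np.ones(n, dtype=int),
            "q_end": np.full(n, 100, dtype=int),
            "s_start": np.ones(n, dtype=int),
            "s_end": np.full(n, 100, dtype=int),
            "e_value": evalue,
            "bit_score": np.round(identity * 2 - 10, 1),
        }
    )
    return frame[M8_COLUMNS]


def simulate_dataset(cfg: SimulationConfig) -> SimulatedBundle:
    """Full synthetic input bundle with planted signals and truth tables."""
    rng = np.random.default_rng(cfg.seed)
    n_genes = cfg.n_features * cfg.genes_per_feature

    # --- annotation maps -------------------------------------------------
    genes = [_gene_id(i) for i in range(n_genes)]
    features = [_feature_id(j) for j in range(cfg.n_features)]
    gene_to_ko = {genes[i]: {features[i // cfg.genes_per_feature]} for i in range(n_genes)}
    n_cogs = max(cfg.n_features // 2, 1)
    gene_to_cog = {genes[i]: {f"COG{i % n_cogs:04d}"} for i in range(n_genes)}
    gene_to_ec = {
        genes[i]: {f"EC:1.1.1.{i}"} for i in range(0, n_genes, 2)
    }  # half the genes carry an enzyme annotation

    planted_idx = sorted(rng.choice(cfg.n_features, size=cfg.n_planted, replace=False).tolist())
    planted_features = [features[j] for j in planted_idx]

    phylum_of: dict[str, str] = {}
    for i, gene in enumerate(genes):
        feat_idx = i // cfg.genes_per_feature
        if cfg.planted_phylum is not None and feat_idx in planted_idx:
            phylum_of[gene] = cfg.planted_phylum
        else:
            phylum_of[gene] = cfg.phyla[int(rng.integers(len(cfg.phyla)))]
    annot = AnnotationMap(
        systems={"KO": gene_to_ko, "COG": gene_to_cog, "EC": gene_to_ec},
        phylum_of=phylum_of,
    )

    # --- hierarchy / pathway definitions --------------------------------
    ko_to_pathway: dict[str, set[str]] = {}
    for j, feat in enumerate(features):
        parents = {f"path{j % cfg.n_pathways:03d}"}
        if j % 7 == 0:  # some KOs sit in two pathways
            parents.add(f"path{(j + 1) % cfg.n_pathways:03d}")
        ko_to_pathway[feat] = parents
    hierarchy = HierarchyMap(levels={"pathway": ko_to_pathway})
    pathway_defs: dict[str, set[str]] = {}
    for feat, paths in ko_to_pathway.items():
        for p in paths:
            pathway_defs.setdefault(p, set()).add(feat)

    # --- BGC definitions -------------------------------------------------
    bgc_records: list[BgcRecord] = []
    bgc_gene_boost: set[str] = set()
    genes_per_bgc = 4
    for b in range(cfg.n_bgc):
        start = (b * (genes_per_bgc + 1)) % (n_genes - genes_per_bgc)
        members = genes[start : start + genes_per_bgc + 1]
        flags = tuple([True] * genes_per_bgc + [False])  # last member non-biosynthetic
        bgc_type = cfg.bgc_types[b % len(cfg.bgc_types)]
        bgc_records.append(
            BgcRecord(
                cluster_id=f"bgc{b:03d}",
                genes=tuple(members),
                biosynthetic=flags,
                bgc_type=bgc_type,
            )
        )
        if cfg.planted_bgc_type is not None and bgc_type == cfg.planted_bgc_type:
            bgc_gene_boost.update(m for m, f in zip(members, flags) if f)

    # --- gene-level proportions per condition ---------------------------
    feat_props = rng.dirichlet(np.full(cfg.n_features, cfg.dirichlet_concentration))
    if cfg.n_planted:
        feat_props[planted_idx] = cfg.planted_baseline  # low-baseline inducible functions
        feat_props /= feat_props.sum()
    gene_base = np.repeat(feat_props / cfg.genes_per_feature, cfg.genes_per_feature)
    gene_boost = gene_base.copy()
    for j in planted_idx:
        sl = slice(j * cfg.genes_per_feature, (j + 1) * cfg.genes_per_feature)
        gene_boost[sl] *= cfg.planted_fold
    for i, gene in enumerate(genes):
        if gene in bgc_gene_boost:
            gene_boost[i] *= cfg.planted_bgc_fold
    gene_boost /= gene_boost.sum()
    gene_base_n = gene_base / gene_base.sum()

    cond_a, cond_b = sorted(cfg.conditions)
    condition_of: dict[str, str] = {}
    gene_m8: dict[str, pd.DataFrame] = {}
    ncrna_m8: dict[str, pd.DataFrame] = {}
    truth_counts: dict[str, np.ndarray] = {}
    gene_arr = np.array(genes)

    for label, props in ((cond_a, gene_base_n), (cond_b, gene_boost)):
        for i in range(cfg.n_samples_per_condition):
            sample = f"{label}_{i+1:02d}"
            condition_of[sample] = label
            sample_props = props
            if cfg.sample_log2_sigma is not None:
                # inter-subject variability drawn at the feature level so a
                # feature's genes stay co-expressed within a subject
                noise = 2.0 ** rng.normal(0.0, cfg.sample_log2_sigma, size=cfg.n_features)
                sample_props = props * np.repeat(noise, cfg.genes_per_feature)
                sample_props = sample_props / sample_props.sum()
            counts = rng.multinomial(cfg.reads_per_sample, sample_props)
            truth_counts[sample] = counts
            subject = np.repeat(gene_arr, counts)
            read_ids = np.array([f"{sample}:r{k}" for k in range(len(subject))])
            rows = [_random_m8_rows(rng, read_ids, subject, (-40.0, -10.0))]

            # junk reads: only hit is above the cutoff -> must stay unassigned
            n_junk = int(cfg.junk_read_fraction * cfg.reads_per_sample)
            if n_junk:
                junk_ids = np.array([f"{sample}:junk{k}" for k in range(n_junk)])
                junk_subj = gene_arr[rng.integers(n_genes, size=n_junk)]
                rows.append(_random_m8_rows(rng, junk_ids, junk_subj, (-4.9, -1.0)))

            # ncRNA reads: flagged ones also carry a spurious gene hit that the
            # filter must remove before gene assignment
            n_nc = cfg.n_ncrna_reads
            nc_ids = np.array([f"{sample}:nc{k}" for k in range(n_nc)])
            nc_subj = np.array([f"rRNA_{k % 50}" for k in range(n_nc)])
            n_flag = int(0.9 * n_nc)
            nc_low = _random_m8_rows(rng, nc_ids[:n_flag], nc_subj[:n_flag], (-40.0, -10.0))
            nc_high = _random_m8_rows(rng, nc_ids[n_flag:], nc_subj[n_flag:], (-4.9, -1.0))
            ncrna_m8[sample] = pd.concat([nc_low, nc_high], ignore_index=True)
            spurious = _random_m8_rows(
                rng, nc_ids[:n_flag], gene_arr[rng.integers(n_genes, size=n_flag)], (-40.0, -10.0)
            )
            rows.append(spurious)
            gene_m8[sample] = pd.concat(rows, ignore_index=True)

    meta = SampleMetadata(condition_of)

    # --- metagenomic taxa profile (composition constant across conditions)
    phyla_sorted = sorted(set(phylum_of.values()))
    base_taxa = rng.dirichlet(np.full(len(phyla_sorted), 10.0))
    taxa_cols = {}
    for sample in condition_of:
        noise = rng.dirichlet(base_taxa * 500.0)
        taxa_cols[sample] = noise
    taxa_profile = pd.DataFrame(taxa_cols, index=pd.Index(phyla_sorted, name="phylum"))

    truth = {
        "planted_features": pd.DataFrame(
            {"feature": planted_features, "fold": cfg.planted_fold}
        ),
        "gene_counts": pd.DataFrame(truth_counts, index=pd.Index(genes, name="gene_id")),
        "feature_proportions": pd.DataFrame(
            {"baseline": feat_props}, index=pd.Index(features, name="feature")
        ),
        "planted_bgc": pd.DataFrame(
            {
                "bgc_type": [cfg.planted_bgc_type] if cfg.planted_bgc_type else [],
                "fold": [cfg.planted_bgc_fold] if cfg.planted_bgc_type else [],
            }
        ),
    }
    return SimulatedBundle(
        config=cfg,
        meta=meta,
        annot=annot,
        hierarchy=hierarchy,
        pathway_defs=pathway_defs,
        bgc_records=bgc_records,
        gene_m8=gene_m8,
        ncrna_m8=ncrna_m8,
        taxa_profile=taxa_profile,
        truth=truth,
    )


def write_bundle(bundle: SimulatedBundle, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a bundle to disk in the formats the pipeline reads.

    Deterministic given the bundle: identical config + seed produce
    byte-identical trees. Returns a name -> path manifest.
    """
    out = Path(outdir)
    (out / "reads_vs_genes").mkdir(parents=True, exist_ok=True)
    (out / "reads_vs_ncrna").mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    manifest: dict[str, str] = {}

    write_metadata(bundle.meta, out / "metadata.tsv")
    manifest["metadata"] = str(out / "metadata.tsv")
    for sample in sorted(bundle.gene_m8):
        p = out / "reads_vs_genes" / f"{sample}.m8"
        bundle.gene_m8[sample].to_csv(p, sep="\t", header=False, index=False)
        manifest[f"genes_m8:{sample}"] = str(p)
    for sample in sorted(bundle.ncrna_m8):
        p = out / "reads_vs_ncrna" / f"{sample}.m8"
        bundle.ncrna_m8[sample].to_csv(p, sep="\t", header=False, index=False)
        manifest[f"ncrna_m8:{sample}"] = str(p)
    for system, mapping in sorted(bundle.annot.systems.items()):
        p = out / "maps" / f"gene2{system.lower()}.tsv"
        write_pair_map(mapping, p)
        manifest[f"map:{system}"] = str(p)
    write_pair_map(bundle.annot.phylum_of, out / "maps" / "gene2phylum.tsv")
    manifest["map:phylum"] = str(out / "maps" / "gene2phylum.tsv")
    for level, mapping in sorted(bundle.hierarchy.levels.items()):
        p = out / "maps" / f"ko2{level}.tsv"
        write_pair_map(mapping, p)
        manifest[f"hierarchy:{level}"] = str(p)
    pathway_rows = {p: members for p, members in bundle.pathway_defs.items()}
    write_pair_map(pathway_rows, out / "maps" / "pathway_defs.tsv")
    manifest["pathway_defs"] = str(out / "maps" / "pathway_defs.tsv")
    write_bgc_definitions(bundle.bgc_records, out / "maps" / "bgc_defs.tsv")
    manifest["bgc_defs"] = str(out / "maps" / "bgc_defs.tsv")
    bundle.taxa_profile.to_csv(out / "taxa_profile.tsv", sep="\t")
    manifest["taxa_profile"] = str(out / "taxa_profile.tsv")
    for name, frame in sorted(bundle.truth.items()):
        p = out / "truth" / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=True)
        manifest[f"truth:{name}"] = str(p)
    return manifest
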