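"""End-to-end orchestration: filter -> assign -> profile -> compare -> interpret.

Stages run in fixed order (ncRNA filter, gene assignment, profiling,
differential expression + MDS, pathway inference/enrichment, taxonomic
analyses, BGC profiling, co-expression), each writing its TSV outputs plus
a README manifest. Stages whose optional inputs are missing (e.g. no
metagenomic taxa profile for transcription activation) are skipped with a
logged reason. A stage failure stops the pipeline, naming the stage;
outputs of completed stages are retained. Re-running with an identical
config and seed reproduces the output tree byte-identically.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import bgc as bgc_mod
from . import coexpr as coexpr_mod
from . import compare_stats, pathways, profiling, taxa_analysis
from .io_tab import (
    AnnotationMap,
    HierarchyMap,
    SampleMetadata,
    read_m8_frame,
    read_metadata,
    read_pair_map,
    write_tab_outputs,
)
from .ncrna_filter import flag_ncrna_reads

logger = logging.getLogger("metacoman")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one pipeline run."""

    metadata: str
    gene_m8_dir: str
    ncrna_m8_dir: str | None = None
    annotation_maps: dict[str, str] = field(default_factory=dict)  # system -> gene2feature TSV
    phylum_map: str | None = None
    hierarchy_maps: dict[str, str] = field(default_factory=dict)  # level -> child2parent TSV
    pathway_defs: str | None = None
    bgc_defs: str | None = None
    taxa_profile: str | None = None
    evalue: float = 1e-5
    fdr_cutoff: float = 0.10
    rho_threshold: float = 0.7
    bgc_min_cov: float = 0.5
    min_set_size: int = 3
    primary_system: str = "KO"
    reference_condition: str | None = None
    seed: int = 0
    stages: tuple[str, ...] = (
        "ncrna_filter",
        "profiling",
        "compare",
        "pathways",
        "taxa",
        "bgc",
        "coexpr",
    )

    def validate(self) -> None:
        if not 0 < self.fdr_cutoff < 1:
            raise ValueError("fdr_cutoff must be in (0,1)")
        if self.evalue <= 0:
            raise ValueError("evalue must be positive")
        if not 0 < self.rho_threshold <= 1:
            raise ValueError("rho_threshold must be in (0,1]")
        if not 0 < self.bgc_min_cov <= 1:
            raise ValueError("bgc_min_cov must be in (0,1]")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _m8_files(directory: str) -> dict[str, Path]:
    files = sorted(Path(directory).glob("*.m8"))
    return {p.stem: p for p in files}


def run_pipeline(cfg: PipelineConfig, outdir: str) -> dict[str, list[str]]:
    """Execute the enabled stages; returns stage -> written files manifest."""
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, list[str]] = {}
    try:
        _run_stages(cfg, out, manifest)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest: dict[str, list[str]]) -> None:
    meta = read_metadata(cfg.metadata, reference=cfg.reference_condition)
    gene_files = _m8_files(cfg.gene_m8_dir)
    missing = [s for s in meta.samples if s not in gene_files]
    if missing:
        raise StageError("input", ValueError(f"no alignment file for samples {missing}"))

    def timed(stage: str):
        t0 = time.time()
        logger.info("stage %s started", stage)
        return t0

    def done(stage: str, t0: float, files: list[str]):
        manifest[stage] = files
        logger.info("stage %s finished in %.1fs", stage, time.time() - t0)

    # ---- ncRNA filter ---------------------------------------------------
    flagged_by_sample: dict[str, set[str]] = {s: set() for s in meta.samples}
    if "ncrna_filter" in cfg.stages and cfg.ncrna_m8_dir:
        t0 = timed("ncrna_filter")
        try:
            nc_files = _m8_files(cfg.ncrna_m8_dir)
            rows = []
            for sample in meta.samples:
                if sample not in nc_files:
                    logger.info("sample %s has no ncRNA alignments; nothing flagged", sample)
                    continue
                hits = read_m8_frame(nc_files[sample])
                flagged, report = flag_ncrna_reads(hits, threshold=cfg.evalue)
                flagged_by_sample[sample] = flagged
                rows.append(
                    (sample, report.n_input_reads, report.n_flagged_ncrna, report.n_retained)
                )
            table = pd.DataFrame(
                rows, columns=["sample_id", "n_input_reads", "n_flagged_ncrna", "n_retained"]
            ).set_index("sample_id")
            files = write_tab_outputs(
                {"ncrna_filter_report": (table, "per-sample ncRNA read depletion counts")},
                out / "ncrna_filter",
            )
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("ncrna_filter", exc) from exc
        done("ncrna_filter", t0, files)
    elif "ncrna_filter" in cfg.stages:
        logger.info("stage ncrna_filter skipped: no ncRNA alignment directory given")

    # ---- gene assignment + profiling -----------------------------------
    t0 = timed("profiling")
    try:
        per_sample = {}
        for sample in meta.samples:
            hits = read_m8_frame(gene_files[sample])
            flagged = flagged_by_sample[sample]
            if flagged:
                hits = hits[~hits["read_id"].isin(flagged)]
            per_sample[sample] = profiling.assign_best_gene(hits, threshold=cfg.evalue)
        counts = profiling.gene_count_matrix(per_sample)
        annot = AnnotationMap.from_files(cfg.annotation_maps, cfg.phylum_map)
        profiles: dict[str, profiling.AbundanceProfile] = {}
        tables = {"gene_counts": (counts, "best-hit read counts per gene and sample")}
        for system in sorted(annot.systems):
            prof = profiling.profile_features(counts, annot, system)
            profiles[system] = prof
            tables[f"profile_{system}"] = (
                prof.data,
                f"relative abundance of {system} features per sample",
            )
        hierarchy = HierarchyMap.from_files(cfg.hierarchy_maps) if cfg.hierarchy_maps else None
        if hierarchy and cfg.primary_system in profiles:
            for level in sorted(hierarchy.levels):
                rolled = profiling.rollup(profiles[cfg.primary_system], hierarchy, level)
                profiles[rolled.system] = rolled
                tables[f"profile_{cfg.primary_system}_{level}"] = (
                    rolled.data,
                    f"relative abundance rolled up to {level}",
                )
        files = write_tab_outputs(tables, out / "profiling")
    except Exception as exc:
        raise StageError("profiling", exc) from exc
    done("profiling", t0, files)

    primary = profiles.get(cfg.primary_system)
    if primary is None:
        raise StageError(
            "profiling", ValueError(f"primary system {cfg.primary_system!r} not profiled")
        )

    # ---- DE + MDS + most varied ----------------------------------------
    de = None
    varied = None
    if "compare" in cfg.stages:
        t0 = timed("compare")
        try:
            de = compare_stats.wilcoxon_de(primary, meta, fdr_cutoff=cfg.fdr_cutoff)
            varied = compare_stats.select_most_varied(de, fdr_cutoff=cfg.fdr_cutoff)
            coords, eigvals = compare_stats.mds_ordination(primary)
            varied_table = pd.DataFrame(
                {"feature": varied.features, "selection_mode": varied.selection_mode}
            ).set_index("feature")
            files = write_tab_outputs(
                {
                    "differential_expression": (de, "per-feature Wilcoxon DE with BH FDR"),
                    "most_varied": (varied_table, "most varied functional groups"),
                    "mds_coordinates": (coords, "classical MDS sample coordinates (Bray-Curtis)"),
                },
                out / "compare",
            )
        except Exception as exc:
            raise StageError("compare", exc) from exc
        done("compare", t0, files)

    # ---- pathways -------------------------------------------------------
    if "pathways" in cfg.stages and cfg.pathway_defs and de is not None:
        t0 = timed("pathways")
        try:
            defs = read_pair_map(cfg.pathway_defs)
            observed = set(de.index[(de[["mean_a", "mean_b"]].sum(axis=1) > 0)])
            inference = pathways.infer_minimal_pathways(observed & _all_members(defs), defs)
            inferred = pd.DataFrame(
                {"pathway": inference.pathways, "mode": inference.mode}
            ).set_index("pathway")
            enrich = pathways.pathway_enrichment(de, defs, min_set_size=cfg.min_set_size)
            files = write_tab_outputs(
                {
                    "inferred_pathways": (inferred, "minimal pathway set covering observed functions"),
                    "pathway_enrichment": (enrich, "coordinated fold-change enrichment per pathway"),
                },
                out / "pathways",
            )
        except Exception as exc:
            raise StageError("pathways", exc) from exc
        done("pathways", t0, files)
    elif "pathways" in cfg.stages:
        logger.info("stage pathways skipped: no pathway definitions given")

    # ---- taxonomy-resolved analyses ------------------------------------
    if "taxa" in cfg.stages and cfg.phylum_map and varied is not None:
        t0 = timed("taxa")
        try:
            contribution = taxa_analysis.taxon_contribution(
                counts, annot, meta, varied.features, system=cfg.primary_system
            )
            distribution = taxa_analysis.taxon_distribution(
                counts, annot, meta, varied.features, system=cfg.primary_system
            )
            tables = {
                "taxon_contribution": (contribution, "phylum shares of between-condition change"),
                "taxon_distribution": (distribution, "per-condition phylum fractions per feature"),
            }
            if cfg.taxa_profile:
                taxa_prof = pd.read_csv(cfg.taxa_profile, sep="\t", index_col=0)
                feature_phylum = _dominant_phylum(
                    counts, annot, cfg.primary_system, varied.features
                )
                sub = primary.data.loc[[f for f in varied.features if f in primary.data.index]]
                sub_profile = primary.data.loc[sub.index]
                normalised, stats = taxa_analysis.transcription_activation(
                    sub_profile, feature_phylum, taxa_prof, meta
                )
                tables["activation_normalised"] = (
                    normalised,
                    "expression divided by phylum metagenomic abundance",
                )
                tables["activation_stats"] = (
                    stats,
                    "Wilcoxon comparison of normalised expression between conditions",
                )
            else:
                logger.info("transcription activation skipped: no metagenomic taxa profile")
            files = write_tab_outputs(tables, out / "taxa")
        except Exception as exc:
            raise StageError("taxa", exc) from exc
        done("taxa", t0, files)
    elif "taxa" in cfg.stages:
        logger.info("stage taxa skipped: no phylum map or no DE results")

    # ---- BGC ------------------------------------------------------------
    if "bgc" in cfg.stages and cfg.bgc_defs:
        t0 = timed("bgc")
        try:
            records = bgc_mod.read_bgc_definitions(cfg.bgc_defs)
            scores = bgc_mod.score_all_bgcs(counts, records, min_cov=cfg.bgc_min_cov)
            tables = {"bgc_scores": (scores.set_index("cluster_id"), "per-cluster detection and abundance score")}
            if scores["detected"].any():
                type_de, proportions = bgc_mod.compare_bgc_types(scores, meta)
                tables["bgc_type_de"] = (type_de, "Wilcoxon comparison of BGC-type abundance")
                tables["bgc_type_proportions"] = (proportions, "per-sample BGC type proportions")
            else:
                logger.info("no BGC detected in any sample; type comparison skipped")
            files = write_tab_outputs(tables, out / "bgc")
        except Exception as exc:
            raise StageError("bgc", exc) from exc
        done("bgc", t0, files)
    elif "bgc" in cfg.stages:
        logger.info("stage bgc skipped: no BGC definitions given")

    # ---- co-expression --------------------------------------------------
    if "coexpr" in cfg.stages and varied is not None:
        t0 = timed("coexpr")
        try:
            tables = {}
            for condition in meta.conditions:
                net = coexpr_mod.build_network(
                    primary, meta, condition,
                    features=varied.features, rho_threshold=cfg.rho_threshold,
                )
                net = coexpr_mod.detect_communities(net, seed=cfg.seed)
                net = coexpr_mod.find_hubs(net)
                nodes, edges = coexpr_mod.network_tables(net)
                tables[f"network_nodes_{condition}"] = (
                    nodes, f"co-expression nodes for condition {condition}"
                )
                tables[f"network_edges_{condition}"] = (
                    edges, f"co-expression edges for condition {condition}"
                )
            files = write_tab_outputs(tables, out / "coexpr")
        except Exception as exc:
            raise StageError("coexpr", exc) from exc
        done("coexpr", t0, files)

    # ---- top-level manifest --------------------------------------------
    with open(out / "README.txt", "wt") as fh:
        fh.write("# Pipeline output manifest\n")
        for stage in sorted(manifest):
            for fname in manifest[stage]:
                fh.write(f"{stage}/{fname}\n")


def _all_members(defs: dict[str, set[str]]) -> set[str]:
    out: set[str] = set()
    for members in defs.values():
        out |= members
    return out


def _dominant_phylum(
    counts: pd.DataFrame, annot: AnnotationMap, system: str, features: list[str]
) -> dict[str, str]:
    """Assign each feature the phylum contributing most of its reads overall."""
    comp = taxa_analysis.feature_phylum_components(counts, annot, system, features)
    result: dict[str, str] = {}
    if comp.empty:
        return result
    totals = comp.sum(axis=1)
    for feat in totals.index.get_level_values("feature").unique():
        block = totals.loc[feat].sort_index()
        result[feat] = block.idxmax()
    return result
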