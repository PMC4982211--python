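"""Tabular input/output for the pipeline.

Every external format here is plain TSV: BLAST tabular alignments
(12-column "m8" / outfmt 6), a two-column sample metadata table, and
two-column child/parent maps for annotations and hierarchies. Writers are
deterministic: rows are sorted by the first (index) column so re-runs on
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

M8_COLUMNS = [
    "read_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]

_M8_FLOAT = {"pct_identity", "e_value", "bit_score"}
_M8_INT = {
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
}


class M8FormatError(ValueError):
    """A malformed row in a BLAST tabular file."""


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column BLAST tabular alignment.

    Coordinates are 1-based inclusive, exactly as BLAST emits them.
    """

    read_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e-value {self.e_value} for read {self.read_id}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length {self.aln_length} < 1 for read {self.read_id}")
        for name in ("q_start", "q_end", "s_start", "s_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"coordinate {name}={getattr(self, name)} < 1 (1-based expected)")


def _parse_m8_fields(fields: list[str], lineno: int) -> tuple:
    try:
        return (
            fields[0],
            fields[1],
            float(fields[2]),
            int(fields[3]),
            int(fields[4]),
            int(fields[5]),
            int(fields[6]),
            int(fields[7]),
            int(fields[8]),
            int(fields[9]),
            float(fields[10]),
            float(fields[11]),
        )
    except ValueError as exc:
        raise M8FormatError(f"line {lineno}: cannot parse field ({exc})") from exc


def read_m8_frame(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BLAST tabular file into a DataFrame with columns M8_COLUMNS.

    Rows with more than 12 columns trigger one warning and the extras are
    ignored (several aligners append optional columns); rows with fewer
    than 12 raise :class:`M8FormatError` naming the line. An empty file
    yields an empty frame.
    """
    records: list[tuple] = []
    warned_extra = False
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise M8FormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                warnings.warn(
                    f"{path}: line {lineno}: {len(fields)} columns; extra columns ignored",
                    stacklevel=2,
                )
                warned_extra = True
            records.append(_parse_m8_fields(fields, lineno))
    frame = pd.DataFrame.from_records(records, columns=M8_COLUMNS)
    if len(frame):
        if (frame["e_value"] < 0).any():
            bad = int(frame.index[frame["e_value"] < 0][0]) + 1
            raise M8FormatError(f"{path}: row {bad}: negative e-value")
        if (frame["aln_length"] < 1).any():
            bad = int(frame.index[frame["aln_length"] < 1][0]) + 1
            raise M8FormatError(f"{path}: row {bad}: alignment length < 1")
    return frame


def read_m8(path: str | os.PathLike) -> list[AlignmentHit]:
    """Read a BLAST tabular file as a list of :class:`AlignmentHit`, in file order."""
    frame = read_m8_frame(path)
    return [AlignmentHit(*row) for row in frame.itertuples(index=False, name=None)]


def write_m8(hits: Iterable[AlignmentHit] | pd.DataFrame, path: str | os.PathLike) -> None:
    """Write hits back to 12-column tabular format (inverse of :func:`read_m8`)."""
    if not isinstance(hits, pd.DataFrame):
        hits = pd.DataFrame.from_records(
            [
                (
                    h.read_id, h.subject_id, h.pct_identity, h.aln_length, h.mismatches,
                    h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end, h.e_value, h.bit_score,
                )
                for h in hits
            ],
            columns=M8_COLUMNS,
        )
    hits.to_csv(path, sep="\t", header=False, index=False)


def hits_frame(hits: Iterable[AlignmentHit] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a hit sequence to the canonical DataFrame form."""
    if isinstance(hits, pd.DataFrame):
        return hits
    return pd.DataFrame.from_records(
        [
            (
                h.read_id, h.subject_id, h.pct_identity, h.aln_length, h.mismatches,
                h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end, h.e_value, h.bit_score,
            )
            for h in hits
        ],
        columns=M8_COLUMNS,
    )


def best_hits(hits: Iterable[AlignmentHit] | pd.DataFrame) -> pd.DataFrame:
    """One row per read: its best hit.

    Best is minimum e-value; ties broken by maximum bit score, then
    lexicographically smallest subject id. The rules are total, so the
    result is independent of input row order.
    """
    frame = hits_frame(hits)
    if frame.empty:
        return frame
    ordered = frame.sort_values(
        ["read_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("read_id", keep="first").reset_index(drop=True)


@dataclass(frozen=True)
class SampleMetadata:
    """Sample-to-condition assignment for a two-condition comparison.

    ``conditions`` is sorted lexicographically; the first label is the
    reference condition for fold-change direction unless overridden.
    """

    condition_of: Mapping[str, str]
    reference: str | None = None

    def __post_init__(self) -> None:
        labels = sorted(set(self.condition_of.values()))
        if len(labels) != 2:
            raise ValueError(
                f"exactly two conditions required, got {len(labels)}: {labels}"
            )
        if self.reference is not None and self.reference not in labels:
            raise ValueError(f"reference condition {self.reference!r} not among {labels}")

    @property
    def conditions(self) -> tuple[str, str]:
        """(reference, other) — reference is the lexicographically smaller label by default."""
        labels = sorted(set(self.condition_of.values()))
        if self.reference is not None and self.reference == labels[1]:
            return (labels[1], labels[0])
        return (labels[0], labels[1])

    @property
    def samples(self) -> list[str]:
        return list(self.condition_of)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.condition_of.items() if c == condition]


def read_metadata(path: str | os.PathLike, reference: str | None = None) -> SampleMetadata:
    """Read a two-column TSV (sample_id, condition).

    A header row whose first cell is ``sample_id`` is skipped. Exactly two
    distinct condition labels and unique sample ids are required.
    """
    condition_of: dict[str, str] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            sample, cond = fields
            if lineno == 1 and sample == "sample_id":
                continue
            if sample in condition_of:
                raise ValueError(f"{path}: line {lineno}: duplicate sample id {sample!r}")
            condition_of[sample] = cond
    return SampleMetadata(condition_of, reference=reference)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tcondition\n")
        for sample in sorted(meta.condition_of):
            fh.write(f"{sample}\t{meta.condition_of[sample]}\n")


def read_pair_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column TSV of (child, parent) pairs into child -> {parents}.

    Used for gene->feature annotation maps, feature->level hierarchy maps
    and pathway->member definitions alike (one row per pair).
    """
    mapping: dict[str, set[str]] = {}
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            child, parent = fields
            if not child or not parent:
                raise ValueError(f"{path}: line {lineno}: empty identifier")
            mapping.setdefault(child, set()).add(parent)
    return mapping


def write_pair_map(mapping: Mapping[str, set[str] | str], path: str | os.PathLike) -> None:
    with open(path, "wt") as fh:
        for child in sorted(mapping):
            parents = mapping[child]
            if isinstance(parents, str):
                parents = {parents}
            for parent in sorted(parents):
                fh.write(f"{child}\t{parent}\n")


@dataclass
class AnnotationMap:
    """Gene-level functional annotations and taxonomy.

    ``systems`` maps an annotation system name (e.g. ``"KO"``, ``"COG"``,
    ``"EC"``) to a gene -> {feature ids} mapping; a gene may carry several
    features in one system. ``phylum_of`` maps gene -> phylum of its source
    genome; genes absent from it are treated as "Unclassified".
    """

    systems: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    phylum_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_files(
        cls,
        system_paths: Mapping[str, str | os.PathLike],
        phylum_path: str | os.PathLike | None = None,
    ) -> "AnnotationMap":
        systems = {name: read_pair_map(p) for name, p in system_paths.items()}
        phylum_of: dict[str, str] = {}
        if phylum_path is not None:
            for gene, phyla in read_pair_map(phylum_path).items():
                if len(phyla) != 1:
                    raise ValueError(f"gene {gene!r} mapped to multiple phyla: {sorted(phyla)}")
                phylum_of[gene] = next(iter(phyla))
        return cls(systems=systems, phylum_of=phylum_of)

    def phylum(self, gene: str) -> str:
        return self.phylum_of.get(gene, "Unclassified")


@dataclass
class HierarchyMap:
    """Feature -> parent maps, one per hierarchy level name.

    Levels are e.g. COG category, KEGG pathway / module / pathway class,
    MetaCyc pathway levels. Each level maps feature -> {parent ids}.
    """

    levels: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @classmethod
    def from_files(cls, level_paths: Mapping[str, str | os.PathLike]) -> "HierarchyMap":
        return cls(levels={name: read_pair_map(p) for name, p in level_paths.items()})


def write_tab_outputs(
    tables: Mapping[str, tuple[pd.DataFrame, str]],
    outdir: str | os.PathLike,
    readme_name: str = "README.txt",
) -> list[str]:
    """Write named tables as TSV plus a README manifest.

    ``tables`` maps a file stem to (frame, one-line description). Each
    frame is written sorted by its index (ascending) with a header row, so
    output is byte-identical across runs on identical inputs. Returns the
    list of files written (manifest last).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    lines: list[str] = []
    for stem in sorted(tables):
        frame, description = tables[stem]
        fname = f"{stem}.tsv"
        frame.sort_index(kind="mergesort").to_csv(outdir / fname, sep="\t")
        written.append(fname)
        lines.append(f"{fname}\t{description}")
    with open(outdir / readme_name, "wt") as fh:
        fh.write("# Output files\n")
        for line in lines:
            fh.write(line + "\n")
    written.append(readme_name)
    return written
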