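"""Annotation transfer from a well-annotated reference genome.

Including a trusted, well-annotated genome in the dataset lets every
cluster that contains one of its genes inherit that gene's functional
annotation — a reference-based shortcut to annotating draft genomes by
orthology.  Transfer is lossless: when several annotated reference
paralogs sit in one cluster, all their annotations are kept, in member
order, with the contributing gene id as provenance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Union

from .orthomap import OrthologMap

__all__ = [
    "AnnotationTable",
    "ClusterAnnotation",
    "TransferResult",
    "read_annotation_table",
    "transfer_annotations",
    "write_annotations_tsv",
]


@dataclass(frozen=True)
class AnnotationTable:
    """gene_id -> annotation text for one reference genome."""

    genome_id: str
    annotations: dict[str, str]

    def __post_init__(self) -> None:
        for gene, text in self.annotations.items():
            if not text.strip():
                raise ValueError(f"empty annotation for gene {gene!r}")

    def get(self, gene_id: str) -> str | None:
        return self.annotations.get(gene_id)


@dataclass(frozen=True)
class ClusterAnnotation:
    """Annotations inherited by one cluster from the reference genome."""

    cluster_id: str
    annotations: tuple[tuple[str, str], ...]  # (reference gene_id, text), member order

    @property
    def status(self) -> str:
        return "annotated" if self.annotations else "unannotated"


@dataclass(frozen=True)
class TransferResult:
    """One ClusterAnnotation per cluster plus the reference-gene gap list."""

    reference: str
    clusters: tuple[ClusterAnnotation, ...]
    gaps: tuple[str, ...]  # reference genes present in clusters but absent from the table

    @property
    def n_annotated(self) -> int:
        return sum(1 for c in self.clusters if c.status == "annotated")

    @property
    def n_unannotated(self) -> int:
        return len(self.clusters) - self.n_annotated


def read_annotation_table(
    source: Union[str, Path, IO[str]], genome_id: str
) -> AnnotationTable:
    """Read a two-column TSV (gene_id, annotation) for the reference genome.

    A header row is optional and is detected by a literal ``gene_id`` first
    cell.  Annotation text is whitespace-trimmed and must be non-empty;
    duplicate gene ids are an error.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_annotation_table(fh, genome_id)
    annotations: dict[str, str] = {}
    reader = csv.reader(source, delimiter="\t")
    for row_no, row in enumerate(reader, start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row_no == 1 and row[0].strip() == "gene_id":
            continue
        if len(row) < 2:
            raise ValueError(f"annotation row {row_no}: expected 2 columns, got {len(row)}")
        gene, text = row[0].strip(), row[1].strip()
        if not gene or not text:
            raise ValueError(f"annotation row {row_no}: empty gene id or annotation")
        if gene in annotations:
            raise ValueError(f"annotation row {row_no}: duplicate gene id {gene!r}")
        annotations[gene] = text
    return AnnotationTable(genome_id=genome_id, annotations=annotations)


def transfer_annotations(
    omap: OrthologMap, reference: str, table: AnnotationTable
) -> TransferResult:
    """Transfer reference-genome annotations to every cluster containing one.

    For each cluster, all reference-genome members with a table entry are
    listed in member order; clusters without an annotated reference member
    are ``unannotated``.  Reference genes found in clusters but missing
    from the table are collected into the gap list (first-appearance
    order) so annotation coverage holes are visible.
    """
    if reference not in omap.genomes:
        raise ValueError(f"reference genome {reference!r} not in map (genomes: {omap.genomes})")
    results: list[ClusterAnnotation] = []
    gaps: list[str] = []
    gap_seen: set[str] = set()
    for c in omap.clusters:
        hits: list[tuple[str, str]] = []
        for m in c.members:
            if m.genome_id != reference:
                continue
            text = table.get(m.gene_id)
            if text is None:
                if m.gene_id not in gap_seen:
                    gap_seen.add(m.gene_id)
                    gaps.append(m.gene_id)
            else:
                hits.append((m.gene_id, text))
        results.append(ClusterAnnotation(cluster_id=c.cluster_id, annotations=tuple(hits)))
    return TransferResult(reference=reference, clusters=tuple(results), gaps=tuple(gaps))


def write_annotations_tsv(result: TransferResult, path: Union[str, Path]) -> None:
    """Write per-cluster annotations as TSV.

    Columns: cluster_id, status, reference_gene_ids (comma-joined),
    annotations (``;``-joined, tabs squashed to spaces).
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cluster_id\tstatus\treference_gene_ids\tannotations\n")
        for c in result.clusters:
            genes = ",".join(g for g, _ in c.annotations)
            texts = ";".join(t.replace("\t", " ") for _, t in c.annotations)
            fh.write(f"{c.cluster_id}\t{c.status}\t{genes}\t{texts}\n")
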