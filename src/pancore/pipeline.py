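"""End-to-end pipeline: parse, QC, rarefaction, classification, outputs.

Stage order follows the method's three steps — (1) reorganisation of the
map into the content matrix plus quality assessment, (2) random sampling of
genome subsets per event, (3) iterative computation of core/accessory size
and composition — and then writes every artefact: CG.txt and not_CG.txt
(core and accessory cluster membership in groups format), the curve table
and plot, the QC table and heatmap, optional transferred annotations, and a
machine-readable run summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from .annotation import read_annotation_table, transfer_annotations, write_annotations_tsv
from .matrix import (
    CorePartition,
    build_matrix,
    classify,
    qc_report,
)
from .orthomap import OrthologMap, genome_inventory, parse_orthomap
from .rarefaction import SamplingPlan, rarefaction_curve

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "write_core_files", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    input_path: Union[str, Path]
    outdir: Union[str, Path]
    expected_genomes: int | None = None
    iterations: int = 100
    seed: int = 0
    qc_threshold: float = 0.02
    a1: int = 1
    d: int = 1
    reference: str | None = None
    annotation_path: Union[str, Path, None] = None
    figure_format: str = "png"
    sep: str = "|"

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.figure_format not in ("png", "svg"):
            raise ValueError(f"figure format must be png or svg, got {self.figure_format!r}")
        if (self.reference is None) != (self.annotation_path is None):
            raise ValueError("reference genome and annotation path must be given together")


def write_core_files(
    partition: CorePartition, omap: OrthologMap, outdir: Union[str, Path]
) -> tuple[Path, Path]:
    """Write CG.txt (core clusters) and not_CG.txt (accessory clusters).

    Both files list full cluster lines in the input map's groups dialect
    and order, so they are themselves valid (possibly empty) groups files;
    their line counts sum to the cluster count.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cg = outdir / "CG.txt"
    not_cg = outdir / "not_CG.txt"
    with cg.open("w", encoding="utf-8", newline="\n") as fc, \
            not_cg.open("w", encoding="utf-8", newline="\n") as fa:
        for c in omap.clusters:
            sink = fc if c.cluster_id in partition.core else fa
            tokens = " ".join(f"{m.genome_id}|{m.gene_id}" for m in c.members)
            sink.write(f"{c.cluster_id}: {tokens}\n")
    return cg, not_cg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - annotate with stage name
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and return the machine-readable summary.

    Input validation (parse + genome-count check) happens before any output
    is written, so a mismatched genome count fails fast with no partial
    results.  Flagged genomes produce a warning only — exclusion is the
    user's call.  For a fixed config and seed, all text outputs are
    byte-identical across runs.
    """
    # --- validate input fully before touching the output directory
    try:
        omap = parse_orthomap(Path(config.input_path), sep=config.sep)
        genomes = genome_inventory(omap, config.expected_genomes)
    except Exception as e:
        raise PipelineError("parse", e) from e

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    fmt = config.figure_format

    matrix = _stage("matrix")(build_matrix)(omap)
    matrix.to_tsv(outdir / "matrix.tsv")
    outputs["matrix"] = "matrix.tsv"
    log.info("matrix: %d clusters x %d genomes", matrix.n_clusters, matrix.n_genomes)

    qc = None
    if matrix.n_genomes >= 2:
        qc = _stage("qc")(qc_report)(matrix, config.qc_threshold)
        qc.to_tsv(outdir / "qc_report.tsv")
        outputs["qc_report"] = "qc_report.tsv"
        from .plots import plot_heatmap  # deferred: matplotlib import is slow

        _stage("qc")(plot_heatmap)(matrix, outdir / f"heatmap.{fmt}")
        outputs["heatmap"] = f"heatmap.{fmt}"
        for g in sorted(qc.flagged):
            log.warning(
                "genome %s flagged: missing %d core genes (fraction %.3f > %.3f)",
                g, qc.missing_core_count(g), qc.missing_core_fraction(g),
                config.qc_threshold,
            )

    plan = SamplingPlan(
        n_genomes=matrix.n_genomes, a1=config.a1, d=config.d,
        iterations=config.iterations, seed=config.seed,
    )
    log.info("rarefaction: %d events per sweep, %d iterations", plan.n_events,
             plan.iterations)
    result = _stage("rarefaction")(rarefaction_curve)(matrix, plan)
    result.to_tsv(outdir / "curve.tsv")
    outputs["curve"] = "curve.tsv"
    from .plots import plot_curve

    _stage("rarefaction")(plot_curve)(result, outdir / f"curve.{fmt}")
    outputs["curve_plot"] = f"curve.{fmt}"

    partition = _stage("classify")(classify)(matrix)
    cg, not_cg = _stage("classify")(write_core_files)(partition, omap, outdir)
    outputs["core_clusters"] = cg.name
    outputs["accessory_clusters"] = not_cg.name

    annotation_summary = None
    if config.reference is not None:
        table = _stage("annotate")(read_annotation_table)(
            Path(config.annotation_path), config.reference
        )
        transfer = _stage("annotate")(transfer_annotations)(
            omap, config.reference, table
        )
        write_annotations_tsv(transfer, outdir / "annotations.tsv")
        outputs["annotations"] = "annotations.tsv"
        annotation_summary = {
            "reference": transfer.reference,
            "annotated_clusters": transfer.n_annotated,
            "unannotated_clusters": transfer.n_unannotated,
            "reference_gene_gaps": len(transfer.gaps),
        }

    summary = {
        "input": str(config.input_path),
        "genomes": len(genomes),
        "clusters": matrix.n_clusters,
        "genes": omap.n_genes,
        "core_size": partition.n_core,
        "accessory_size": partition.n_accessory,
        "flagged_genomes": sorted(qc.flagged) if qc is not None else [],
        "qc_threshold": config.qc_threshold,
        "event_count": plan.n_events,
        "iterations": config.iterations,
        "seed": config.seed,
        "annotation": annotation_summary,
        "outputs": outputs,
    }
    with (outdir / "summary.json").open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
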