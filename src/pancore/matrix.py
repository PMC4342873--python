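"""Genome-content matrix, core/accessory classification, and genome QC.

The content matrix is the central data structure: rows are ortholog
clusters, columns are genomes, entries are gene counts.  All core-genome
computations operate on *presence* (count >= 1), so paralogs — multiple
genes from one genome in one cluster — never inflate core sizes: each
cluster is counted once per genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Union

import numpy as np
import pandas as pd

from .orthomap import OrthologMap

__all__ = [
    "GenomeContentMatrix",
    "CorePartition",
    "QCReport",
    "build_matrix",
    "core_size",
    "classify",
    "qc_report",
    "heatmap_table",
]


@dataclass
class GenomeContentMatrix:
    """Cluster-by-genome table of gene counts.

    ``counts`` has cluster ids as the index (input file order) and genome
    ids as columns (first-appearance order).  ``presence`` thresholds the
    counts at one and is what every core computation uses.
    """

    counts: pd.DataFrame
    _presence: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.ndim != 2 or counts.size == 0:
            raise ValueError("counts must be a non-empty 2-D table")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (counts.to_numpy().sum(axis=1) == 0).any():
            raise ValueError("every cluster must have at least one member")
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise ValueError("cluster and genome ids must be unique")

    @property
    def cluster_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.index)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(self.counts.columns)

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    @property
    def presence(self) -> np.ndarray:
        """Boolean cluster-by-genome presence array (count >= 1), cached."""
        if self._presence is None:
            self._presence = self.counts.to_numpy() >= 1
        return self._presence

    @property
    def prevalence(self) -> np.ndarray:
        """Number of genomes each cluster is present in (paralog-excluded)."""
        return self.presence.sum(axis=1)

    def genome_indices(self, subset: Iterable[str]) -> np.ndarray:
        """Column indices of *subset*, validating genome ids."""
        lookup = {g: i for i, g in enumerate(self.counts.columns)}
        idx = []
        for g in subset:
            if g not in lookup:
                raise KeyError(f"unknown genome {g!r}")
            idx.append(lookup[g])
        if not idx:
            raise ValueError("subset must be non-empty")
        return np.asarray(idx, dtype=np.intp)

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Export the count matrix as TSV (first column ``cluster_id``)."""
        out = self.counts.copy()
        out.index.name = "cluster_id"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class CorePartition:
    """Disjoint split of cluster ids into core and accessory sets."""

    core: frozenset[str]
    accessory: frozenset[str]

    def __post_init__(self) -> None:
        if self.core & self.accessory:
            raise ValueError("core and accessory overlap")

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def n_accessory(self) -> int:
        return len(self.accessory)


@dataclass(frozen=True)
class QCReport:
    """Leave-one-out missing-core statistics per genome.

    ``missing_core_count(g)`` is the number of clusters present in every
    genome except *g* but absent from *g* — the genes *g* "should" have if
    it were complete.  The fraction normalises by *g*'s leave-one-out core
    size; genomes whose fraction exceeds the threshold are flagged as
    candidate poor-quality assemblies.
    """

    table: pd.DataFrame  # index genome_id; columns missing_core_count, missing_core_fraction
    flagged: frozenset[str]
    threshold: float

    def missing_core_count(self, genome_id: str) -> int:
        return int(self.table.loc[genome_id, "missing_core_count"])

    def missing_core_fraction(self, genome_id: str) -> float:
        return float(self.table.loc[genome_id, "missing_core_fraction"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.table.copy()
        out["flagged"] = [g in self.flagged for g in out.index]
        out.index.name = "genome_id"
        out.to_csv(path, sep="\t")


def build_matrix(omap: OrthologMap) -> GenomeContentMatrix:
    """Build the genome-content matrix from a parsed orthologous map.

    Rows follow cluster file order, columns genome first-appearance order;
    entry (c, g) is the number of genes genome *g* contributes to cluster
    *c*, so the matrix total equals the map's total gene count.
    """
    genomes = omap.genomes
    col = {g: j for j, g in enumerate(genomes)}
    counts = np.zeros((len(omap.clusters), len(genomes)), dtype=np.int64)
    for i, c in enumerate(omap.clusters):
        for m in c.members:
            counts[i, col[m.genome_id]] += 1
    frame = pd.DataFrame(counts, index=list(omap.cluster_ids), columns=list(genomes))
    return GenomeContentMatrix(frame)


def core_size(matrix: GenomeContentMatrix, subset: Iterable[str]) -> int:
    """Number of clusters present in every genome of *subset*.

    Each cluster counts at most once regardless of paralog multiplicity.
    """
    idx = matrix.genome_indices(subset)
    return int(matrix.presence[:, idx].all(axis=1).sum())


def classify(matrix: GenomeContentMatrix) -> CorePartition:
    """Split clusters into core (present in all genomes) and accessory."""
    is_core = matrix.presence.all(axis=1)
    ids = np.asarray(matrix.cluster_ids, dtype=object)
    return CorePartition(
        core=frozenset(ids[is_core]),
        accessory=frozenset(ids[~is_core]),
    )


def qc_report(matrix: GenomeContentMatrix, threshold: float = 0.02) -> QCReport:
    """Per-genome leave-one-out missing-core statistics.

    For each genome *g*, count clusters present in all other genomes but
    absent from *g*, and normalise by *g*'s leave-one-out core size (that
    count plus the full-dataset core size).  Genomes whose fraction
    strictly exceeds *threshold* are flagged.  Requires at least two
    genomes (leave-one-out is undefined otherwise).
    """
    if matrix.n_genomes < 2:
        raise ValueError("QC requires at least 2 genomes")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    P = matrix.presence
    n = matrix.n_genomes
    row_prev = P.sum(axis=1)
    full_core = int((row_prev == n).sum())
    rows = []
    flagged = []
    for j, g in enumerate(matrix.genome_ids):
        missing = int(((row_prev == n - 1) & ~P[:, j]).sum())
        loo_core = full_core + missing
        frac = missing / loo_core if loo_core else 0.0
        rows.append((missing, frac))
        if frac > threshold:
            flagged.append(g)
    table = pd.DataFrame(
        rows,
        index=list(matrix.genome_ids),
        columns=["missing_core_count", "missing_core_fraction"],
    )
    return QCReport(table=table, flagged=frozenset(flagged), threshold=threshold)


def heatmap_table(
    matrix: GenomeContentMatrix,
    order: Literal["input", "by_prevalence"] = "input",
) -> pd.DataFrame:
    """0/1 presence table ready for heatmap rendering.

    ``by_prevalence`` sorts rows by the number of genomes present
    (descending, ties broken by cluster id), which pulls the core block —
    rows present everywhere — to the top so it renders as a contiguous
    solid band.
    """
    pres = pd.DataFrame(
        matrix.presence.astype(np.int8),
        index=list(matrix.cluster_ids),
        columns=list(matrix.genome_ids),
    )
    if order == "input":
        return pres
    if order == "by_prevalence":
        key = pd.DataFrame(
            {"prev": pres.sum(axis=1), "cid": pres.index}, index=pres.index
        ).sort_values(["prev", "cid"], ascending=[False, True])
        return pres.loc[key.index]
    raise ValueError(f"unknown order {order!r}")
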