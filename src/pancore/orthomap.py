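"""Reading and writing orthologous gene maps in OrthoMCL ``groups`` format.

The format is line oriented: one ortholog cluster per line, a cluster
identifier terminated by a colon, then whitespace-separated members of the
form ``genome|gene`` (the separator character is configurable).  Blank lines
and ``#`` comment lines are ignored.  Example::

    CLUSTER1: strainA|geneX strainB|geneY
    CLUSTER2: strainA|geneZ

Parsing retains paralogs (multiple genes from one genome in one cluster);
collapsing multiplicities to presence/absence is the job of the content
matrix, not the parser.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

log = logging.getLogger(__name__)

__all__ = [
    "GeneRef",
    "OrthologCluster",
    "OrthologMap",
    "OrthoMapError",
    "ParseError",
    "GenomeCountMismatchError",
    "parse_orthomap",
    "write_orthomap",
    "genome_inventory",
]


class OrthoMapError(ValueError):
    """Base class for orthologous-map format and consistency errors."""


class ParseError(OrthoMapError):
    """Raised on a malformed or internally inconsistent groups file."""


class GenomeCountMismatchError(OrthoMapError):
    """Raised when the genome count found disagrees with the expected count."""

    def __init__(self, expected: int, found: int):
        self.expected = expected
        self.found = found
        super().__init__(
            f"genome count mismatch: expected {expected}, found {found}"
        )


@dataclass(frozen=True)
class GeneRef:
    """A single gene, identified by its genome and its within-genome gene id."""

    genome_id: str
    gene_id: str

    def __post_init__(self) -> None:
        for name, value in (("genome_id", self.genome_id), ("gene_id", self.gene_id)):
            if not value or any(ch.isspace() for ch in value):
                raise ValueError(f"{name} must be a non-empty whitespace-free token: {value!r}")


@dataclass(frozen=True)
class OrthologCluster:
    """One ortholog cluster: an id and its member genes, in file order."""

    cluster_id: str
    members: tuple[GeneRef, ...]

    def __post_init__(self) -> None:
        if not self.cluster_id or any(ch.isspace() for ch in self.cluster_id):
            raise ValueError(f"cluster_id must be a non-empty whitespace-free token: {self.cluster_id!r}")
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            key = (m.genome_id, m.gene_id)
            if key in seen:
                raise ValueError(
                    f"duplicate member {m.genome_id}|{m.gene_id} in cluster {self.cluster_id!r}"
                )
            seen.add(key)

    @property
    def genome_ids(self) -> tuple[str, ...]:
        """Genome ids of the members, in member order (with repeats)."""
        return tuple(m.genome_id for m in self.members)


@dataclass(frozen=True)
class OrthologMap:
    """An ordered collection of ortholog clusters plus the genome inventory.

    ``genomes`` is always the deduplicated union of member genomes in order
    of first appearance; it is derived, never supplied.
    """

    clusters: tuple[OrthologCluster, ...]
    genomes: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("no clusters found")
        cluster_ids: set[str] = set()
        gene_owner: dict[tuple[str, str], str] = {}
        genomes: list[str] = []
        seen_genomes: set[str] = set()
        for c in self.clusters:
            if c.cluster_id in cluster_ids:
                raise ValueError(f"duplicate cluster id {c.cluster_id!r}")
            cluster_ids.add(c.cluster_id)
            for m in c.members:
                key = (m.genome_id, m.gene_id)
                if key in gene_owner:
                    raise ValueError(
                        f"gene {m.genome_id}|{m.gene_id} appears in clusters "
                        f"{gene_owner[key]!r} and {c.cluster_id!r}"
                    )
                gene_owner[key] = c.cluster_id
                if m.genome_id not in seen_genomes:
                    seen_genomes.add(m.genome_id)
                    genomes.append(m.genome_id)
        object.__setattr__(self, "genomes", tuple(genomes))

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[OrthologCluster]:
        return iter(self.clusters)

    @property
    def cluster_ids(self) -> tuple[str, ...]:
        return tuple(c.cluster_id for c in self.clusters)

    @property
    def n_genes(self) -> int:
        """Total gene members over all clusters (paralogs counted)."""
        return sum(len(c.members) for c in self.clusters)


Source = Union[str, Path, IO[str], Iterable[str]]


def _iter_lines(source: Source):
    """Yield lines from a path, open text handle, string, or line iterable."""
    if isinstance(source, Path):
        with source.open("r", encoding="utf-8") as fh:
            yield from fh
    elif isinstance(source, str):
        if source and "\n" not in source and Path(source).exists():
            with open(source, "r", encoding="utf-8") as fh:
                yield from fh
        else:
            yield from io.StringIO(source)
    else:
        yield from source


def parse_orthomap(source: Source, sep: str = "|") -> OrthologMap:
    """Parse an OrthoMCL groups file into an :class:`OrthologMap`.

    Parameters
    ----------
    source:
        Path to a groups file, an open text stream, or the text itself.
    sep:
        Character separating genome id from gene id inside a member token.

    Raises
    ------
    ParseError
        On a malformed line (no colon, member token without the separator),
        a duplicate cluster id, a duplicate member within a cluster, the
        same gene in two clusters, or an empty input.
    """
    clusters: list[OrthologCluster] = []
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\r\n").strip()
        if not line or line.startswith("#"):
            continue
        head, colon, tail = line.partition(":")
        if not colon:
            raise ParseError(f"line {lineno}: missing ':' after cluster id")
        cluster_id = head.strip()
        if not cluster_id or any(ch.isspace() for ch in cluster_id):
            raise ParseError(f"line {lineno}: invalid cluster id {head.strip()!r}")
        tokens = tail.split()
        if not tokens:
            raise ParseError(f"line {lineno}: cluster {cluster_id!r} has no members")
        members: list[GeneRef] = []
        for tok in tokens:
            genome, s, gene = tok.partition(sep)
            if not s or not genome or not gene:
                raise ParseError(
                    f"line {lineno}: member token {tok!r} lacks the "
                    f"'genome{sep}gene' separator"
                )
            members.append(GeneRef(genome, gene))
        try:
            clusters.append(OrthologCluster(cluster_id, tuple(members)))
        except ValueError as e:
            raise ParseError(f"line {lineno}: {e}") from e
    if not clusters:
        raise ParseError("no clusters found")
    try:
        return OrthologMap(tuple(clusters))
    except ValueError as e:
        raise ParseError(str(e)) from e


def write_orthomap(omap: OrthologMap, sink: Union[str, Path, IO[str]], sep: str = "|") -> None:
    """Write *omap* in the same groups dialect :func:`parse_orthomap` reads.

    Output uses LF newlines and single spaces between tokens, so
    ``parse(write(m)) == m`` exactly (cluster order and member order).
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="\n") as fh:
            write_orthomap(omap, fh, sep=sep)
        return
    for c in omap.clusters:
        tokens = " ".join(f"{m.genome_id}{sep}{m.gene_id}" for m in c.members)
        sink.write(f"{c.cluster_id}: {tokens}\n")


def genome_inventory(omap: OrthologMap, expected_n: int | None = None) -> tuple[str, ...]:
    """Return the genome inventory, optionally checked against an expected count.

    The inventory is the deduplicated union of member genomes in order of
    first appearance.  When ``expected_n`` is given and disagrees with the
    count found, a :class:`GenomeCountMismatchError` is raised (fail fast
    rather than silently analysing a corrupt or truncated map).
    """
    found = len(omap.genomes)
    if expected_n is not None:
        if expected_n <= 0:
            raise ValueError(f"expected_n must be positive, got {expected_n}")
        if expected_n != found:
            raise GenomeCountMismatchError(expected_n, found)
    else:
        log.info("genome inventory: %d genomes found (no expected count supplied)", found)
    return omap.genomes
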