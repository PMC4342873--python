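"""Synthetic pan-genome maps with known ground truth.

Generates OrthoMCL-style groups data in which the true core/accessory split
is known by construction, so every pipeline stage can be tested end to end
without external data.  The model is deliberately simple:

* ``n_core`` clusters occupy every genome (minus optional per-genome
  dropout, which emulates incomplete or corrupt assemblies);
* ``n_accessory`` clusters occupy a random genome subset whose size is
  drawn from a prevalence law — uniform on 1..N-1 by default, or a fixed
  per-cluster prevalence list for exact oracle checks;
* paralogs: each (cluster, genome) occupancy independently gains extra
  gene copies with a geometric tail, P(extra = j) = p^j (1 - p).

Structure (subset choices, dropout) and paralog multiplicities are drawn
from separate RNG substreams, so changing the paralog rate never perturbs
the presence/absence pattern — the paralog-invariance property can be
tested seed-for-seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .matrix import CorePartition
from .orthomap import GeneRef, OrthologCluster, OrthologMap, parse_orthomap

__all__ = ["SyntheticSpec", "generate_map", "reference_fixture", "ReferenceFixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated pan-genome with known ground truth."""

    n_genomes: int
    n_core: int
    n_accessory: int = 0
    prevalence: Sequence[int] | None = None  # fixed per-accessory-cluster; None = uniform 1..N-1
    paralog_prob: float = 0.0
    dropout: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.n_core < 0 or self.n_accessory < 0:
            raise ValueError("cluster counts must be non-negative")
        if self.n_core + self.n_accessory < 1:
            raise ValueError("at least one cluster is required")
        if self.n_accessory > 0 and self.n_genomes < 2:
            raise ValueError("accessory clusters require at least 2 genomes")
        if self.prevalence is not None:
            if len(self.prevalence) != self.n_accessory:
                raise ValueError(
                    f"prevalence list length {len(self.prevalence)} != "
                    f"n_accessory {self.n_accessory}"
                )
            for p in self.prevalence:
                if not 1 <= p <= self.n_genomes - 1:
                    raise ValueError(
                        f"accessory prevalence {p} out of range 1..{self.n_genomes - 1}"
                    )
        if not 0.0 <= self.paralog_prob < 1.0:
            raise ValueError("paralog_prob must be in [0, 1)")
        for g, f in self.dropout.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"dropout fraction for {g!r} must be in [0, 1]")

    @property
    def genome_ids(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1}" for i in range(self.n_genomes))


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def generate_map(spec: SyntheticSpec) -> tuple[OrthologMap, CorePartition]:
    """Generate a groups map and its ground-truth core/accessory partition.

    Deterministic for a fixed spec (including seed).  With zero dropout the
    realised strict core equals the ground-truth core exactly; dropout can
    demote core clusters in the realised map while the returned partition
    still records the intended split.
    """
    genomes = spec.genome_ids
    n = spec.n_genomes
    structure = _substream(spec.seed, 0)
    paralog = _substream(spec.seed, 1)
    dropper = _substream(spec.seed, 2)

    # genome occupancy per cluster, as sorted genome indices
    occupancies: list[np.ndarray] = []
    cluster_ids: list[str] = []
    for i in range(spec.n_core):
        cluster_ids.append(f"CORE{i + 1:05d}")
        occupancies.append(np.arange(n))
    for i in range(spec.n_accessory):
        cluster_ids.append(f"ACC{i + 1:05d}")
        if spec.prevalence is not None:
            size = int(spec.prevalence[i])
        else:
            size = int(structure.integers(1, n))  # uniform on 1..N-1
        occupancies.append(np.sort(structure.choice(n, size=size, replace=False)))

    # per-genome core dropout: delete each core occupancy independently
    drop_frac = np.array([spec.dropout.get(g, 0.0) for g in genomes])
    if drop_frac.any():
        for ci in range(spec.n_core):
            occ = occupancies[ci]
            keep = dropper.random(occ.size) >= drop_frac[occ]
            if not keep.any():
                keep[0] = True  # clusters must stay non-empty
            occupancies[ci] = occ[keep]

    gene_counter = [0] * n
    clusters: list[OrthologCluster] = []
    core_ids: list[str] = []
    acc_ids: list[str] = []
    for cid, occ in zip(cluster_ids, occupancies):
        members: list[GeneRef] = []
        for j in occ:
            copies = 1
            if spec.paralog_prob > 0.0:
                # P(extra = e) = p^e (1 - p): geometric number of extra copies
                copies += int(paralog.geometric(1.0 - spec.paralog_prob)) - 1
            for _ in range(copies):
                gene_counter[j] += 1
                members.append(GeneRef(genomes[j], f"{genomes[j]}_{gene_counter[j]:05d}"))
        clusters.append(OrthologCluster(cid, tuple(members)))
        (core_ids if cid.startswith("CORE") else acc_ids).append(cid)
    truth = CorePartition(core=frozenset(core_ids), accessory=frozenset(acc_ids))
    return OrthologMap(tuple(clusters)), truth


@dataclass(frozen=True)
class ReferenceFixture:
    """The small worked example used throughout the documentation and tests."""

    text: str
    omap: OrthologMap
    counts: tuple[tuple[int, ...], ...]  # clusters x genomes gene counts
    partition: CorePartition
    expected_curve: tuple[Fraction, ...]  # exact E[core at k], k = 1..N


def reference_fixture() -> ReferenceFixture:
    """Three genomes, two clusters, one paralog pair — fully hand-checked.

    Cluster C1 holds two genes of genome A (paralogs) and one of B; C2
    holds one gene each of B and C.  Hence counts [[2, 1, 0], [0, 1, 1]],
    no cluster spans all three genomes (empty core), and the exact expected
    core sizes are E(1) = 4/3, E(2) = 2/3, E(3) = 0.
    """
    text = "C1: A|g1 A|g2 B|g5\nC2: B|g6 C|g7\n"
    omap = parse_orthomap(text)
    return ReferenceFixture(
        text=text,
        omap=omap,
        counts=((2, 1, 0), (0, 1, 1)),
        partition=CorePartition(core=frozenset(), accessory=frozenset({"C1", "C2"})),
        expected_curve=(Fraction(4, 3), Fraction(2, 3), Fraction(0)),
    )
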