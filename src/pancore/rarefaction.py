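"""Core-genome rarefaction by iterative random subsampling.

The central computation: for subset sizes running in arithmetic progression
(default 1, 2, ..., N), draw random genome subsets without replacement and
record the core size of each draw; averaging the draws per subset size gives
the mean core-genome curve.  The number of draws in one full sweep follows
the arithmetic-series formula

    S_N = N/2 * [2*a1 + (N - 1)*d]

with a1 the smallest subset size (default 1) and d the common difference
(default 1); under the defaults S_N = N(N+1)/2.

A closed-form oracle is also provided: because subsets are drawn uniformly
without replacement, a cluster present in n_c of N genomes survives a
k-subset with hypergeometric probability C(n_c, k) / C(N, k), so the exact
expected core size at k is the sum of those probabilities over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .matrix import GenomeContentMatrix

__all__ = [
    "SamplingPlan",
    "RarefactionResult",
    "event_count",
    "run_event",
    "rarefaction_curve",
    "expected_core_curve",
]


def event_count(n_genomes: int, a1: int = 1, d: int = 1) -> int:
    """Number of random sampling events in one sweep over subset sizes.

    Evaluates ``S_N = N/2 * [2*a1 + (N-1)*d]`` in exact integer arithmetic
    (the product is always even for integer arguments).  With the defaults
    a1 = d = 1 this is the triangular number N(N+1)/2.
    """
    if n_genomes < 1 or a1 < 1 or d < 1:
        raise ValueError(
            f"n_genomes, a1 and d must be positive (got {n_genomes}, {a1}, {d})"
        )
    total = n_genomes * (2 * a1 + (n_genomes - 1) * d)
    return total // 2


@dataclass(frozen=True)
class SamplingPlan:
    """Parameters of one rarefaction run.

    Subset sizes are the arithmetic progression a1, a1+d, ... truncated at
    the dataset size N; each size is sampled ``iterations`` times.
    """

    n_genomes: int
    a1: int = 1
    d: int = 1
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.a1 < 1 or self.d < 1:
            raise ValueError("a1 and d must be >= 1")
        if self.a1 > self.n_genomes:
            raise ValueError(f"a1={self.a1} exceeds n_genomes={self.n_genomes}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def subset_sizes(self) -> tuple[int, ...]:
        return tuple(range(self.a1, self.n_genomes + 1, self.d))

    @property
    def n_events(self) -> int:
        """Printed-formula event count for this plan's N, a1 and d."""
        return event_count(self.n_genomes, self.a1, self.d)


@dataclass(frozen=True)
class RarefactionResult:
    """Per-subset-size core sizes from every iteration, plus their means."""

    plan: SamplingPlan
    subset_sizes: tuple[int, ...]
    core_sizes: np.ndarray  # shape (len(subset_sizes), iterations)

    @property
    def means(self) -> np.ndarray:
        return self.core_sizes.mean(axis=1)

    @property
    def sds(self) -> np.ndarray:
        return self.core_sizes.std(axis=1, ddof=1) if self.plan.iterations > 1 \
            else np.zeros(len(self.subset_sizes))

    @property
    def ses(self) -> np.ndarray:
        return self.sds / np.sqrt(self.plan.iterations)

    def mean(self, k: int) -> float:
        return float(self.means[self.subset_sizes.index(k)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.subset_sizes),
                "mean_core": self.means,
                "sd": self.sds,
                "se": self.ses,
                "iterations": self.plan.iterations,
            }
        )

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_event(
    matrix: GenomeContentMatrix, k: int, rng: np.random.Generator
) -> int:
    """One sampling event: draw k distinct genomes uniformly, return core size.

    Genomes are drawn without replacement (each genome selected at most once
    per event); the draw consumes *rng* deterministically.
    """
    n = matrix.n_genomes
    if not 1 <= k <= n:
        raise ValueError(f"subset size k={k} out of range 1..{n}")
    idx = rng.choice(n, size=k, replace=False)
    return int(matrix.presence[:, idx].all(axis=1).sum())


def _event_rng(seed: int, k_index: int, iteration: int) -> np.random.Generator:
    # Independent substream per (subset size, iteration): results do not
    # depend on loop execution order.
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(k_index, iteration))
    return np.random.default_rng(ss)


def rarefaction_curve(
    matrix: GenomeContentMatrix, plan: SamplingPlan
) -> RarefactionResult:
    """Monte-Carlo mean core-size curve over the plan's subset sizes.

    Performs ``iterations`` independent events per subset size.  Fully
    reproducible: identical matrix, plan and seed give bit-identical
    results, independent of evaluation order, because each (size,
    iteration) pair uses its own deterministic RNG substream.
    """
    if plan.n_genomes != matrix.n_genomes:
        raise ValueError(
            f"plan expects {plan.n_genomes} genomes, matrix has {matrix.n_genomes}"
        )
    sizes = plan.subset_sizes
    out = np.empty((len(sizes), plan.iterations), dtype=np.int64)
    for ki, k in enumerate(sizes):
        for it in range(plan.iterations):
            out[ki, it] = run_event(matrix, k, _event_rng(plan.seed, ki, it))
    return RarefactionResult(plan=plan, subset_sizes=sizes, core_sizes=out)


def expected_core_curve(
    matrix: GenomeContentMatrix,
    subset_sizes: Sequence[int] | None = None,
    exact: bool = False,
):
    """Exact expected core size per subset size, in closed form.

    E[core at k] = sum over clusters c of C(n_c, k) / C(N, k), where n_c is
    the number of genomes cluster c is present in (C(n, k) = 0 for k > n).
    With ``exact=True`` returns a list of :class:`fractions.Fraction`,
    otherwise a float array.
    """
    n = matrix.n_genomes
    if subset_sizes is None:
        subset_sizes = range(1, n + 1)
    prev = matrix.prevalence
    # aggregate by prevalence value: few distinct n_c, many clusters
    values, counts = np.unique(prev, return_counts=True)
    out: list[Fraction] = []
    for k in subset_sizes:
        if not 1 <= k <= n:
            raise ValueError(f"subset size k={k} out of range 1..{n}")
        denom = comb(n, k)
        numer = sum(int(m) * comb(int(v), k) for v, m in zip(values, counts))
        out.append(Fraction(numer, denom))
    if exact:
        return out
    return np.array([float(x) for x in out])
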