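# Methods

## Data model

The input is an ortholog `groups` file: one cluster per line,
`clusterID: genome|gene genome|gene ...` (separator configurable). The
parser enforces the structural invariants a downstream analysis depends
on: cluster ids unique, members non-empty, no duplicate member within a
cluster, and no gene assigned to two clusters. Singleton genes that the
clustering tool never placed in a cluster cannot be represented in this
format and are therefore outside the data model — all statistics are over
clustered genes only. Comment (`#`) and blank lines are tolerated so
hand-edited fixtures parse cleanly.

The content matrix stores gene **counts** per (cluster, genome), not just
presence, so paralog statistics remain available; every core computation,
however, thresholds at count ≥ 1. This is the paralog-exclusion rule: a
genome contributes each cluster at most once, so within-genome
duplications can never inflate a core size. The property is tested
seed-for-seed (a paralog-free and a paralog-heavy map generated from the
same structural random stream must give identical presence matrices,
classifications, and curves).

## Rarefaction

Subset sizes run in arithmetic progression `a1, a1+d, ...` truncated at N
(defaults a1 = d = 1). For each size, `iterations` (default 100, the
value previously found to be sufficient for stable means; overridable)
independent subsets are drawn uniformly without replacement and their core
sizes recorded. The arithmetic-series formula
`S_N = N/2 [2 a1 + (N-1) d]` is evaluated in exact integer arithmetic and
reported in logs and the run summary as the events-per-sweep count; the
sampling loop itself is driven by the progression, never terminated by the
formula.

Randomness: one seed per run; each (subset size, iteration) pair gets its
own `SeedSequence` substream (`spawn_key=(k_index, iteration)`), so results
are bit-reproducible and independent of loop execution order. Whether the
100 input orders per event are realised as independent subsets per size or
as prefixes of permuted genome orders does not change the marginal
distribution at any size; independent subsets per size are drawn here.

Because subsets are uniform, a cluster present in `n_c` genomes survives a
k-subset with probability `C(n_c, k) / C(N, k)`. `expected_core_curve`
sums these hypergeometric terms with exact rational arithmetic and serves
as the closed-form oracle for the Monte-Carlo engine; a second, fully
independent oracle (averaging `core_size` over every k-subset by
enumeration) checks the closed form itself on small matrices. The exact
curve is non-increasing in k, and the k = N event is deterministic — both
are asserted as properties.

Mean, standard deviation and standard error per subset size are written to
`curve.tsv`; the method's original output is the mean only, the spread
columns are additive and labelled.

## Genome quality control

Quality is assessed by a leave-one-out missing-core statistic:
`missing_core_count(g)` counts clusters present in every genome except
`g`, and the fraction normalises by `g`'s leave-one-out core size
(`missing + full core`). The denominator choice makes the statistic the
share of the core `g` *should* have that it actually lacks. Flagging uses
a strict `fraction > threshold` rule with a 2% default; the threshold is
exposed as a CLI flag because the underlying judgement is inherently a
visual/contextual one and the numeric rule exists to make it scriptable
and testable.

Known sensitivity: accessory clusters at prevalence N−1 are
indistinguishable from dropped core genes in this statistic, so datasets
with many near-universal accessory clusters show nonzero missing-core
fractions for healthy genomes. At the default 2% threshold this matters
only for small cores; flagged genomes are warnings, never errors —
exclusion is the user's decision.

## Synthetic data generator

The generator emulates the structure of multi-strain bacterial datasets
(the kind of 16/70/140-genome pneumococcal collections this method targets)
with known ground truth: `n_core` clusters occupying every genome,
`n_accessory` clusters occupying a random subset whose size follows a
prevalence law, optional geometric paralog copies per occupancy, and
optional per-genome dropout of core occupancies (emulating incomplete
assemblies). Defaults used across tests: uniform prevalence on 1..N−1 —
real pan-genomes have U-shaped prevalence spectra, but the uniform law
covers intermediate prevalences that a U-shape would under-sample; a fixed
per-cluster prevalence mode exists for exact oracle checks. The QC
acceptance condition uses 5 genomes, a 50-cluster core, and 20% dropout on
one genome, matching a mid-sized strain panel with one poor assembly.

Structure, paralog multiplicities, and dropout use three separate RNG
substreams so any one can be varied without perturbing the others — this
is what makes paralog invariance testable with identical presence
patterns. If dropout would empty a cluster entirely, its first occupancy
is kept (clusters must be non-empty); at realistic dropout rates this path
is never taken.

What passing tests on synthetic data do **not** show: robustness to
clustering errors (mis-assigned orthologs), U-shaped prevalence spectra,
or correlated gene loss along a phylogeny — the generator draws occupancy
independently per cluster.

## Pipeline and outputs

Stages run in a fixed order: parse → genome-count check → content matrix →
QC (table + heatmap) → rarefaction (table + plot) → classification →
`CG.txt`/`not_CG.txt` → optional annotation transfer → `summary.json`.
Input validation completes before any file is written, so a genome-count
mismatch aborts with no partial outputs. `CG.txt` and `not_CG.txt` carry
full cluster lines in the input dialect (they are themselves valid groups
files), because "composition" means membership, not counts; the per-size
core numbers live in `curve.tsv`. All text outputs are byte-identical
across reruns with the same config and seed.

Annotation transfer is deliberately lossless: every annotated reference
paralog in a cluster is kept in member order with its gene id as
provenance (no merging or majority vote), reference genes missing from the
annotation table are surfaced as a gap list, and all clusters — core and
accessory — are annotated. The annotation input is a minimal two-column
TSV (gene id, text; optional `gene_id` header).

## Problem sizes and numerical choices

The end-to-end scale exercised by the test suite and acceptance script is
a 140-genome, 2000-cluster synthetic map at 100 iterations (9870 events
per sweep), which completes in seconds; oracle-agreement checks use 50
random matrices with N ≤ 12 and ≤ 200 clusters at 1000 iterations, small
enough for the closed form to be computed exactly. Monte-Carlo/oracle
agreement is asserted cell-wise at 3 standard errors with a 95% pass
floor; expectations are exact `Fraction`s, so the only stochastic element
is the sampling itself. Tie-breaks are deterministic everywhere (cluster
file order, genome first-appearance order, prevalence sort ties broken by
cluster id).

## Limitations

- No accessory/pan-genome size curve — only the core curve is estimated.
- No Heaps'-law or openness fitting on the curve.
- The QC statistic conflates near-universal accessory clusters with
  dropped core genes (see above).
- Singleton (unclustered) genes are invisible to the format and hence to
  all statistics.
- One reference genome per annotation run; no reconciliation across
  references and no sequence-based annotation.
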