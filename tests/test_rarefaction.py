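"""Event counting, random subsampling, and the closed-form expectation oracle."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from pancore import (
    GenomeContentMatrix,
    RarefactionResult,
    SamplingPlan,
    SyntheticSpec,
    build_matrix,
    classify,
    core_size,
    event_count,
    expected_core_curve,
    generate_map,
    rarefaction_curve,
    run_event,
)


class TestEventCount:
    def test_single_genome(self):
        assert event_count(1) == 1

    @pytest.mark.parametrize("n, expected", [(16, 136), (140, 9870)])
    def test_paper_dataset_sizes_match_brute_force(self, n, expected):
        assert sum(range(1, n + 1)) == expected  # independent summation
        assert event_count(n) == expected

    def test_general_progression(self):
        # a1=2, d=3, N=10: terms 2,5,8,... formula sum of 10 terms
        assert event_count(10, a1=2, d=3) == sum(2 + 3 * i for i in range(10))

    @pytest.mark.parametrize("n", [1, 2, 7, 50, 999])
    def test_triangular_identity(self, n):
        assert event_count(n) == n * (n + 1) // 2

    @pytest.mark.parametrize("bad", [(0, 1, 1), (5, 0, 1), (5, 1, 0), (-3, 1, 1)])
    def test_nonpositive_arguments_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            event_count(*bad)


class TestSamplingPlan:
    def test_subset_sizes_default(self):
        assert SamplingPlan(n_genomes=5).subset_sizes == (1, 2, 3, 4, 5)

    def test_subset_sizes_truncated_progression(self):
        assert SamplingPlan(n_genomes=10, a1=2, d=3).subset_sizes == (2, 5, 8)

    def test_n_events_matches_formula(self):
        plan = SamplingPlan(n_genomes=16)
        assert plan.n_events == event_count(16)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genomes": 0},
            {"n_genomes": 3, "a1": 4},
            {"n_genomes": 3, "iterations": 0},
            {"n_genomes": 3, "d": 0},
        ],
    )
    def test_invalid_plans_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SamplingPlan(**kwargs)


class TestRunEvent:
    def test_full_draw_is_exact_core(self, toy_matrix):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            assert run_event(toy_matrix, 3, rng) == 0

    def test_single_genome_draws_enumerate(self, toy_matrix):
        # presence [[1,1,0],[0,1,1]]: A -> 1, B -> 2, C -> 1
        seen = {run_event(toy_matrix, 1, np.random.default_rng(s)) for s in range(50)}
        assert seen == {1, 2}

    def test_same_seed_same_draws(self, toy_matrix):
        a = [run_event(toy_matrix, 2, np.random.default_rng(7)) for _ in range(3)]
        b = [run_event(toy_matrix, 2, np.random.default_rng(7)) for _ in range(3)]
        assert a[0] == b[0]

    @pytest.mark.parametrize("k", [0, 4, -1])
    def test_out_of_range_subset_size(self, toy_matrix, k):
        with pytest.raises(ValueError, match="out of range"):
            run_event(toy_matrix, k, np.random.default_rng(0))


class TestRarefactionCurve:
    def test_full_occupancy_flat_zero_variance(self):
        omap, _ = generate_map(SyntheticSpec(n_genomes=6, n_core=13, seed=0))
        m = build_matrix(omap)
        res = rarefaction_curve(m, SamplingPlan(n_genomes=6, iterations=50, seed=1))
        assert np.all(res.core_sizes == 13)
        assert np.all(res.sds == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_at_full_sample_equals_classify(self, seed):
        omap, _ = generate_map(
            SyntheticSpec(n_genomes=5, n_core=6, n_accessory=14, seed=seed)
        )
        m = build_matrix(omap)
        res = rarefaction_curve(m, SamplingPlan(n_genomes=5, iterations=20, seed=seed))
        assert res.mean(5) == classify(m).n_core

    def test_bit_identical_reproducibility(self, toy_matrix):
        plan = SamplingPlan(n_genomes=3, iterations=200, seed=42)
        a = rarefaction_curve(toy_matrix, plan)
        b = rarefaction_curve(toy_matrix, plan)
        assert np.array_equal(a.core_sizes, b.core_sizes)

    def test_different_seeds_differ(self, toy_matrix):
        a = rarefaction_curve(toy_matrix, SamplingPlan(n_genomes=3, iterations=200, seed=1))
        b = rarefaction_curve(toy_matrix, SamplingPlan(n_genomes=3, iterations=200, seed=2))
        assert not np.array_equal(a.core_sizes, b.core_sizes)

    def test_genome_count_mismatch_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="genomes"):
            rarefaction_curve(toy_matrix, SamplingPlan(n_genomes=4))

    def test_monte_carlo_matches_enumeration_at_k1(self, toy_matrix):
        """Mean at k=1 within 3 SE of the enumerated expectation 4/3."""
        res = rarefaction_curve(
            toy_matrix, SamplingPlan(n_genomes=3, iterations=10_000, seed=5)
        )
        se = res.ses[0]
        assert abs(res.mean(1) - 4 / 3) <= 3 * se

    def test_values_bounded_by_cluster_count(self, toy_matrix):
        res = rarefaction_curve(toy_matrix, SamplingPlan(n_genomes=3, iterations=100, seed=0))
        assert res.core_sizes.min() >= 0
        assert res.core_sizes.max() <= toy_matrix.n_clusters

    def test_frame_columns(self, toy_matrix):
        frame = rarefaction_curve(
            toy_matrix, SamplingPlan(n_genomes=3, iterations=10, seed=0)
        ).to_frame()
        assert list(frame.columns) == ["k", "mean_core", "sd", "se", "iterations"]
        assert list(frame["k"]) == [1, 2, 3]


def enumerated_expectation(matrix: GenomeContentMatrix, k: int) -> Fraction:
    """Independent oracle: average core size over every k-subset of genomes."""
    genomes = matrix.genome_ids
    subs = list(combinations(genomes, k))
    return Fraction(sum(core_size(matrix, s) for s in subs), len(subs))


class TestExpectedCoreCurve:
    def test_universal_cluster_contributes_one_everywhere(self):
        omap, _ = generate_map(SyntheticSpec(n_genomes=5, n_core=4, seed=0))
        curve = expected_core_curve(build_matrix(omap), exact=True)
        assert curve == [Fraction(4)] * 5

    def test_pair_cluster_among_three(self):
        # single cluster in 2 of 3 genomes: E at k=2 is C(2,2)/C(3,2) = 1/3
        counts = pd.DataFrame([[1, 1, 0]], index=["C1"], columns=["A", "B", "C"])
        curve = expected_core_curve(GenomeContentMatrix(counts), exact=True)
        assert curve[1] == Fraction(1, 3)

    def test_toy_fixture_exact_values(self, fixture, toy_matrix):
        assert tuple(expected_core_curve(toy_matrix, exact=True)) == fixture.expected_curve

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_subset_enumeration(self, seed):
        """Closed form equals brute-force enumeration over all subsets."""
        omap, _ = generate_map(
            SyntheticSpec(n_genomes=5, n_core=3, n_accessory=10, seed=seed)
        )
        m = build_matrix(omap)
        curve = expected_core_curve(m, exact=True)
        for k in range(1, 6):
            assert curve[k - 1] == enumerated_expectation(m, k)

    @pytest.mark.parametrize("seed", range(10))
    def test_non_increasing_in_k(self, seed):
        omap, _ = generate_map(
            SyntheticSpec(n_genomes=8, n_core=5, n_accessory=40,
                          paralog_prob=0.2, seed=seed)
        )
        curve = expected_core_curve(build_matrix(omap), exact=True)
        assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_out_of_range_subset_size(self, toy_matrix):
        with pytest.raises(ValueError, match="out of range"):
            expected_core_curve(toy_matrix, subset_sizes=[4])
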