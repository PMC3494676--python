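"""Selection, contribution allocation, distances and the annealer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixpurge.management import (
    ContributionPlan,
    DistanceObjective,
    InfeasibleCapError,
    SASchedule,
    allocate_contributions_random,
    count_native_alleles,
    distance,
    expected_frequencies,
    gamete_allele_probs,
    native_allele_counts,
    optimize_contributions_sa,
    select_max_native,
    truncation_plan,
)
from admixpurge.markers import make_panel
from admixpurge.population import Population


def make_pop(marker, is_male):
    """Population stub with prescribed marker genotypes (background unused)."""
    marker = np.asarray(marker, dtype=np.int8)
    n = marker.shape[0]
    return Population(
        generation=0,
        ids=np.arange(n),
        is_male=np.asarray(is_male, dtype=bool),
        nonmarker=np.zeros((n, 2, 1), dtype=np.int32),
        marker=marker,
        origin_native=np.ones(n, dtype=bool),
    )


class TestNativeAlleleCounts:
    @pytest.mark.parametrize(
        "hap_a,hap_b,expected",
        [
            (np.zeros(20), np.zeros(20), 40),  # pure native, diagnostic M=20
            (np.ones(20), np.ones(20), 0),  # pure exogenous
            (np.zeros(5), np.ones(5), 5),  # heterozygous at all 5 markers
        ],
    )
    def test_counts(self, hap_a, hap_b, expected):
        M = len(hap_a)
        panel = make_panel("diagnostic", M)
        pop = make_pop(np.stack([hap_a, hap_b], axis=0)[None], [True])
        assert native_allele_counts(pop, panel)[0] == expected
        assert count_native_alleles(pop.individual(0), panel) == expected


class TestSelectMaxNative:
    def test_sexwise_maxima(self):
        panel = make_panel("diagnostic", 20)
        # males carry 40 and 38 native copies, females 40 and 40
        marker = np.zeros((4, 2, 20), dtype=np.int8)
        marker[1, 0, :1] = 1  # male 1: 39? -> make it 38 by two foreign copies
        marker[1, :, 0] = 1
        pop = make_pop(marker, [True, True, False, False])
        sel_m, sel_f = select_max_native(pop, panel)
        assert sel_m.tolist() == [0]
        assert sorted(sel_f.tolist()) == [2, 3]

    def test_single_best_female_mothers_everyone(self, rng):
        panel = make_panel("diagnostic", 5)
        marker = np.ones((4, 2, 5), dtype=np.int8)
        marker[2] = 0  # one female is strictly purest
        pop = make_pop(marker, [True, True, False, False])
        _, sel_f = select_max_native(pop, panel)
        assert sel_f.tolist() == [2]
        plan = allocate_contributions_random(np.array([0, 1]), sel_f, 10, None, rng)
        assert plan.dam_counts.sum() == 10 and plan.dam_idx.tolist() == [2]

    def test_all_tied_selects_everyone(self):
        panel = make_panel("diagnostic", 5)
        marker = np.zeros((6, 2, 5), dtype=np.int8)
        pop = make_pop(marker, [True] * 3 + [False] * 3)
        sel_m, sel_f = select_max_native(pop, panel)
        assert sel_m.size == 3 and sel_f.size == 3


class TestAllocation:
    def test_cap_pigeonhole_saturates_everyone(self, rng):
        sel = np.arange(20)
        plan = allocate_contributions_random(sel, sel, 100, 5, rng)
        assert (plan.sire_counts == 5).all() and (plan.dam_counts == 5).all()

    def test_infeasible_cap_raises(self, rng):
        with pytest.raises(InfeasibleCapError):
            allocate_contributions_random(np.arange(3), np.arange(3), 100, 5, rng)

    def test_two_females_split_slots_evenly_in_expectation(self):
        totals = np.zeros(2)
        reps, N = 600, 20
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            plan = allocate_contributions_random(np.array([0]), np.array([1, 2]), N, None, rng)
            totals += plan.dam_counts
        mean = totals / reps
        se = np.sqrt(N * 0.25 / reps)
        assert abs(mean[0] - N / 2) < 3 * se

    def test_tier_relaxation_keeps_population_size(self, rng):
        """With a cap, too few top-tier parents admits the next count tier."""
        panel = make_panel("diagnostic", 5)
        marker = np.ones((20, 2, 5), dtype=np.int8)
        marker[0] = 0  # one pure male, one pure female; rest worse
        marker[10] = 0
        pop = make_pop(marker, [True] * 10 + [False] * 10)
        plan = truncation_plan(pop, panel, cap=5, rng=rng)
        assert plan.sire_counts.sum() == 20 and plan.dam_counts.sum() == 20
        assert (plan.sire_counts <= 5).all() and (plan.dam_counts <= 5).all()
        assert plan.sire_idx.size == 10  # whole next tier admitted


class TestExpectedFrequencies:
    def test_single_homozygous_pair(self):
        panel = make_panel("diagnostic", 2)
        marker = np.zeros((2, 2, 2), dtype=np.int8)
        pop = make_pop(marker, [True, False])
        plan = ContributionPlan(np.array([0]), np.array([4]), np.array([1]), np.array([4]), 4)
        p = expected_frequencies(plan, pop.marker, panel)
        assert np.allclose(p[:, 0], 1.0)

    def test_het_sire_homozygous_dam_gives_three_quarters(self):
        panel = make_panel("diagnostic", 1)
        marker = np.array([[[0], [1]], [[0], [0]]], dtype=np.int8)  # het male, aa female
        pop = make_pop(marker, [True, False])
        plan = ContributionPlan(np.array([0]), np.array([2]), np.array([1]), np.array([2]), 2)
        p = expected_frequencies(plan, pop.marker, panel)
        assert p[0, 0] == pytest.approx(0.75)

    def test_equal_contributions_recover_parental_frequency(self, rng):
        panel = make_panel("diagnostic_like", 3)
        marker = rng.integers(0, 2, size=(8, 2, 3)).astype(np.int8)
        pop = make_pop(marker, [True] * 4 + [False] * 4)
        plan = ContributionPlan(
            np.arange(4), np.full(4, 2), np.arange(4, 8), np.full(4, 2), 8
        )
        p = expected_frequencies(plan, pop.marker, panel)
        freq = (marker == 0).mean(axis=(0, 1))
        assert np.allclose(p[:, 0], freq)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_panel("non_diagnostic", 2)
        marker = rng.integers(0, 4, size=(6, 2, 2)).astype(np.int8)
        pop = make_pop(marker, [True] * 3 + [False] * 3)
        c_m = rng.multinomial(6, np.ones(3) / 3)
        c_f = rng.multinomial(6, np.ones(3) / 3)
        plan = ContributionPlan(np.arange(3), c_m, np.arange(3, 6), c_f, 6)
        p = expected_frequencies(plan, pop.marker, panel)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestDistances:
    @pytest.mark.parametrize("kind", ["chord", "nei_min", "kl"])
    def test_zero_at_reference(self, kind):
        p = np.array([[0.5, 0.3, 0.2]])
        obj = DistanceObjective(kind, p)
        assert distance(obj, p, p.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_kl_known_value(self):
        p = np.array([[1.0, 0.0]])
        obj = DistanceObjective("kl", p)
        assert distance(obj, p, np.array([[0.5, 0.5]])) == pytest.approx(np.log(2))

    def test_nei_min_known_value(self):
        p = np.array([[1.0, 0.0]])
        obj = DistanceObjective("nei_min", p)
        assert distance(obj, p, np.array([[0.0, 1.0]])) == pytest.approx(1.0)

    def test_chord_known_value(self):
        # disjoint supports: sqrt(2(1-0)) per marker, scaled by 2/(pi M)
        p = np.array([[1.0, 0.0]])
        obj = DistanceObjective("chord", p)
        assert distance(obj, p, np.array([[0.0, 1.0]])) == pytest.approx(
            2 * np.sqrt(2) / np.pi
        )

    def test_mismatched_shapes_rejected(self):
        obj = DistanceObjective("kl", np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            distance(obj, np.array([[0.5, 0.5]]), np.array([[0.3, 0.3, 0.4]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_nonnegative_on_random_frequencies(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(3), size=4)
        q = rng.dirichlet(np.ones(3), size=4)
        for kind in ("chord", "nei_min", "kl"):
            obj = DistanceObjective(kind, p)
            assert distance(obj, p, q) >= -1e-12


def brute_force_optimum(marker, is_male, panel, obj, N, cap):
    """Enumerate every feasible integer contribution plan; return min objective."""
    pop = make_pop(marker, is_male)
    males, females = pop.males(), pop.females()

    def compositions(k):
        idx = males if k == 0 else females
        eff = N if cap is None else cap
        for c in itertools.product(range(eff + 1), repeat=idx.size):
            if sum(c) == N:
                yield np.array(c)

    best = np.inf
    for cm in compositions(0):
        for cf in compositions(1):
            plan = ContributionPlan(males, cm, females, cf, N)
            p = expected_frequencies(plan, pop.marker, panel)
            best = min(best, distance(obj, obj.reference, p))
    return best


FAST_SA = SASchedule(moves_per_temp_factor=30, stall_limit=15, max_steps=120)


class TestSimulatedAnnealing:
    def test_disjoint_genotypes_reach_zero_distance(self, rng):
        # males {aa, bb}, females {aa, bb}; reference fixed on a
        panel = make_panel("diagnostic", 1)
        marker = np.array([[[0], [0]], [[1], [1]], [[0], [0]], [[1], [1]]], dtype=np.int8)
        pop = make_pop(marker, [True, True, False, False])
        obj = DistanceObjective("kl", panel.native_freqs)
        plan = optimize_contributions_sa(pop, obj, None, rng, schedule=FAST_SA)
        p = expected_frequencies(plan, pop.marker, panel)
        assert distance(obj, obj.reference, p) == pytest.approx(0.0, abs=1e-9)
        assert plan.sire_idx.tolist() == [0] and plan.dam_idx.tolist() == [2]

    @pytest.mark.parametrize("kind", ["chord", "nei_min", "kl"])
    def test_matches_exhaustive_optimum_small_instance(self, kind):
        rng = np.random.default_rng(7)
        panel = make_panel("non_diagnostic", 2)
        marker = rng.integers(0, 4, size=(6, 2, 2)).astype(np.int8)
        is_male = [True] * 3 + [False] * 3
        obj = DistanceObjective(kind, panel.native_freqs)
        best = brute_force_optimum(marker, is_male, panel, obj, N=6, cap=None)
        pop = make_pop(marker, is_male)
        plan = optimize_contributions_sa(pop, obj, None, rng, schedule=FAST_SA)
        p = expected_frequencies(plan, pop.marker, panel)
        assert distance(obj, obj.reference, p) == pytest.approx(best, abs=1e-9)

    def test_never_worse_than_equal_contributions(self, rng):
        panel = make_panel("non_diagnostic", 3)
        marker = rng.integers(0, 4, size=(10, 2, 3)).astype(np.int8)
        is_male = [True] * 5 + [False] * 5
        pop = make_pop(marker, is_male)
        obj = DistanceObjective("kl", panel.native_freqs)
        equal = ContributionPlan(
            pop.males(), np.full(5, 2), pop.females(), np.full(5, 2), 10
        )
        e_equal = distance(obj, obj.reference, expected_frequencies(equal, pop.marker, panel))
        plan = optimize_contributions_sa(pop, obj, None, rng, schedule=FAST_SA)
        e_sa = distance(obj, obj.reference, expected_frequencies(plan, pop.marker, panel))
        assert e_sa <= e_equal + 1e-12

    def test_respects_offspring_cap(self, rng):
        panel = make_panel("non_diagnostic", 2)
        marker = rng.integers(0, 4, size=(8, 2, 2)).astype(np.int8)
        pop = make_pop(marker, [True] * 4 + [False] * 4)
        obj = DistanceObjective("kl", panel.native_freqs)
        plan = optimize_contributions_sa(pop, obj, 3, rng, schedule=FAST_SA)
        assert (plan.sire_counts <= 3).all() and (plan.dam_counts <= 3).all()
        assert plan.sire_counts.sum() == 8
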