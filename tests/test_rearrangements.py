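import numpy as np
import pytest

from karyoshuffle.errors import KaryoshuffleError, ValidationError
from karyoshuffle.rearrangements import (
    SignedPermutation,
    all_signed_permutations,
    apply_scenario,
    bfs_oracle_distance,
    breakpoint_graph,
    count_breakpoints,
    exhaustive_median,
    inversion_distance,
    oracle_distance_map,
    read_permutation_file,
    reconstruct_ancestor,
    relabel,
    reverse_segment,
    sorting_scenario,
    write_permutation_file,
)


def random_perm(rng, n):
    xs = list(rng.permutation(np.arange(1, n + 1)))
    return tuple(int(x) * int(rng.choice((1, -1))) for x in xs)


def evolve(p, k, rng):
    n = len(p)
    for _ in range(k):
        i, j = sorted(int(x) for x in rng.integers(0, n, 2))
        p = reverse_segment(p, i, j)
    return p


class TestBreakpointGraph:
    def test_identity_has_no_breakpoints(self):
        g = breakpoint_graph((1, 2, 3))
        assert (g.cycles, g.hurdles, g.fortress) == (4, 0, 0)

    def test_transposed_pair_is_a_hurdle(self):
        g = breakpoint_graph((2, 1))
        assert (g.cycles, g.hurdles, g.fortress) == (1, 1, 0)

    def test_negated_transposed_pair(self):
        g = breakpoint_graph((-2, -1))
        assert (g.cycles, g.hurdles, g.fortress) == (2, 0, 0)

    def test_repeated_element_rejected(self):
        with pytest.raises(ValidationError):
            breakpoint_graph((1, 1))


class TestInversionDistance:
    @pytest.mark.parametrize(
        "perm,expected",
        [
            ((1, 2, 3, 4), 0),
            ((-4, -3, -2, -1), 1),  # one full reversal
            ((2, 1), 3),
            ((-1,), 1),
            ((3, 2, 1), 3),
            ((), 0),
        ],
    )
    def test_known_distances(self, perm, expected):
        assert inversion_distance(perm) == expected

    def test_exhaustive_agreement_small_n(self):
        for n in range(1, 6):
            table = oracle_distance_map(n)
            assert all(inversion_distance(p) == d for p, d in table.items())

    def test_distance_between_two_permutations(self):
        p = (1, -3, -2, 4)
        q = (1, 2, 3, 4)
        assert inversion_distance(p, q) == inversion_distance(p) == 1

    def test_symmetry_and_inverse_invariance(self, rng):
        ident = SignedPermutation.identity(7)
        for _ in range(30):
            p = SignedPermutation(random_perm(rng, 7))
            d = inversion_distance(p)
            assert 0 <= d <= len(p) + 1
            assert inversion_distance(p.inverse()) == d
            # reading BOTH genomes from the opposite telomere changes nothing
            assert inversion_distance(p.reflected(), ident.reflected()) == d

    def test_triangle_inequality(self, rng):
        for _ in range(20):
            p, q, r = (random_perm(rng, 6) for _ in range(3))
            assert inversion_distance(p, r) <= (
                inversion_distance(p, q) + inversion_distance(q, r)
            )


class TestOracle:
    def test_identity_and_single_flip(self):
        assert bfs_oracle_distance((1, 2, 3)) == 0
        assert bfs_oracle_distance((-1,)) == 1

    def test_refuses_large_n(self):
        with pytest.raises(KaryoshuffleError):
            bfs_oracle_distance(tuple(range(1, 10)))

    def test_group_size(self):
        # n! * 2^n signed permutations of n=4
        assert len(oracle_distance_map(4)) == 384
        assert len(list(all_signed_permutations(3))) == 48


class TestBreakpoints:
    def test_equal_permutations(self):
        assert count_breakpoints((1, -2, 3), (1, -2, 3)) == 0

    def test_fully_reversed(self):
        assert count_breakpoints((1, 2, 3), (-3, -2, -1)) == 2

    def test_signed_adjacency_equivalence(self):
        # the junction 1.2 survives in (... -2, -1 ...) read from the other
        # strand, so only the three frame-context junctions break
        assert count_breakpoints((1, 2, 3), (3, -2, -1)) == 3

    def test_bounded_by_twice_distance(self, rng):
        for _ in range(1000):
            p = random_perm(rng, 8)
            assert count_breakpoints(p, tuple(range(1, 9))) <= 2 * inversion_distance(p)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValidationError):
            count_breakpoints((1, 2), (1, 2, 3))


class TestSortingScenario:
    def test_already_sorted_is_empty(self):
        assert len(sorting_scenario((1, 2, 3))) == 0

    def test_single_planted_reversal_recovered(self):
        p = reverse_segment((1, 2, 3, 4, 5, 6), 1, 3)
        scen = sorting_scenario(p)
        assert scen.steps == ((1, 3),)

    def test_scenario_reaches_target_at_minimum_length(self, rng):
        for _ in range(15):
            p = random_perm(rng, 8)
            q = random_perm(rng, 8)
            scen = sorting_scenario(p, q)
            assert len(scen) == inversion_distance(p, q) == bfs_oracle_distance(p, q)
            assert apply_scenario(relabel(p, q), scen) == tuple(range(1, 9))

    def test_smallest_first_prefers_short_spans(self):
        # two independent single-block flips: smallest-first takes span-1 steps
        scen = sorting_scenario((-1, 2, -3))
        assert scen.steps == ((0, 0), (2, 2))

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            sorting_scenario((1,), policy="bogus")


class TestAncestorReconstruction:
    def test_identical_leaves_give_zero_counts(self, tree):
        p = (1, -3, -2, 4, 5)
        anc, counts = reconstruct_ancestor({sp: p for sp in tree.species}, tree)
        assert tuple(anc) == p
        assert all(v == 0 for v in counts.values())

    def test_one_leaf_event_per_species_recovers_root(self, tree, rng):
        n = 10
        root = tuple(range(1, n + 1))
        perms = {}
        for k, sp in enumerate(tree.species):
            i = 2 * k
            perms[sp] = reverse_segment(root, i, i + 2)
        anc, counts = reconstruct_ancestor(perms, tree)
        assert tuple(anc) == root
        assert [counts[sp] for sp in tree.species] == [1, 1, 1, 1]
        assert counts["cherry1"] == counts["cherry2"] == 0

    def test_shared_sister_event_assigned_to_internal_branch(self, tree):
        root = tuple(range(1, 11))
        shared = reverse_segment(root, 3, 6)
        perms = {
            tree.cherry1[0]: shared,
            tree.cherry1[1]: shared,
            tree.cherry2[0]: root,
            tree.cherry2[1]: root,
        }
        anc, counts = reconstruct_ancestor(perms, tree)
        assert tuple(anc) == root
        assert counts["cherry1"] == 1
        assert sum(counts.values()) == 1

    def test_matches_exhaustive_median_scale(self, tree, rng):
        # at n=5 the greedy root is as good as the exact median of the leaves
        n = 5
        for seed in range(5):
            r = np.random.default_rng(seed)
            root = random_perm(r, n)
            c1 = evolve(root, int(r.integers(0, 2)), r)
            c2 = evolve(root, int(r.integers(0, 2)), r)
            perms = {
                tree.cherry1[0]: evolve(c1, 1, r),
                tree.cherry1[1]: evolve(c1, 1, r),
                tree.cherry2[0]: evolve(c2, 1, r),
                tree.cherry2[1]: evolve(c2, 1, r),
            }
            anc, counts = reconstruct_ancestor(perms, tree)
            _, best_score = exhaustive_median(list(perms.values()))
            greedy_score = sum(
                inversion_distance(anc, p) for p in perms.values()
            )
            assert greedy_score <= best_score + 2

    def test_mismatched_block_sets_rejected(self, tree):
        perms = {sp: (1, 2, 3) for sp in tree.species}
        perms[tree.species[0]] = (1, 2)
        with pytest.raises(ValidationError):
            reconstruct_ancestor(perms, tree)

    def test_missing_species_rejected(self, tree):
        with pytest.raises(ValidationError):
            reconstruct_ancestor({tree.species[0]: (1, 2)}, tree)


class TestPermutationFiles:
    def test_round_trip(self, tmp_path):
        perms = {
            ("spA", "e1"): SignedPermutation((1, -3, -2)),
            ("spB", "e1"): SignedPermutation((2, 1, 3)),
        }
        p = tmp_path / "perms.txt"
        write_permutation_file(perms, p)
        assert read_permutation_file(p) == perms
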