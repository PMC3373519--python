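"""Fitch parsimony: scoring, fit indices, heuristic search."""

import numpy as np
import pytest

from morphoclade import trees as T
from morphoclade.parsimony import (
    char_max_steps,
    char_min_steps,
    ci_ri,
    exhaustive_search,
    fitch_length,
    heuristic_search,
)
from morphoclade.simulate import MatrixGenConfig, gen_matrix

import oracles
from conftest import make_matrix


class TestFitchLength:
    def test_single_informative_split(self, quartet_trees):
        M = make_matrix([[0, 0, 1, 1]])
        assert fitch_length(quartet_trees["AB|CD"], M) == 1
        assert fitch_length(quartet_trees["AC|BD"], M) == 2

    def test_constant_character_zero(self, quartet_trees):
        M = make_matrix([[1, 1, 1, 1]], n_states=2)
        for adj in quartet_trees.values():
            assert fitch_length(adj, M) == 0

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(4, 7))
            n_states = int(rng.integers(2, 5))
            adj = T.random_tree(n, rng)
            cols = [[int(rng.integers(n_states)) for _ in range(n)]
                    for _ in range(3)]
            M = make_matrix(cols, n_states=n_states)
            assert fitch_length(adj, M) == oracles.brute_force_tree_length(
                adj, M.masks)

    def test_invariant_to_taxon_relabelling(self):
        rng = np.random.default_rng(9)
        adj = T.random_tree(6, rng)
        cols = [[int(rng.integers(3)) for _ in range(6)] for _ in range(8)]
        M = make_matrix(cols, n_states=3)
        perm = list(rng.permutation(6))
        cols_p = [[col[perm[i]] for i in range(6)] for col in cols]
        M_p = make_matrix(cols_p, n_states=3)
        # relabel tree leaves consistently: leaf i becomes perm^-1(i)
        inv = {perm[i]: i for i in range(6)}
        mapping = {old: inv[old] if old < 6 else old for old in adj}
        adj_p = {mapping[k]: [mapping[w] for w in v] for k, v in adj.items()}
        assert fitch_length(adj_p, M_p) == fitch_length(adj, M)

    def test_polymorphic_and_missing_cells(self, quartet_trees):
        M = make_matrix([[{0, 1}, 0, 1, None], [0, 0, 0, 0]], n_states=2)
        assert fitch_length(quartet_trees["AB|CD"], M) == 1

    def test_leaf_mismatch_rejected(self, quartet_trees):
        M = make_matrix([[0, 0, 1, 1, 1]])
        with pytest.raises(ValueError):
            fitch_length(quartet_trees["AB|CD"], M)


class TestMinMaxSteps:
    def test_two_state_balanced(self):
        M = make_matrix([[0, 0, 1, 1]])
        assert char_min_steps(M, 0) == 1
        assert char_max_steps(M, 0) == 2

    def test_three_state(self):
        # 0,1,2,2,2 -> min 2; max 2 (5 scored - 3 copies of the mode)
        M = make_matrix([[0, 1, 2, 2, 2]], n_states=3)
        assert char_min_steps(M, 0) == 2
        assert char_max_steps(M, 0) == 2

    def test_max_matches_bush_tree(self):
        # g equals the Fitch length on the worst (fully unresolved star ->
        # here: caterpillar separating every minority taxon) arrangement
        M = make_matrix([[0, 1, 2, 2, 2]], n_states=3)
        worst = max(fitch_length(adj, M) for adj in T.all_topologies(5))
        assert char_max_steps(M, 0) == worst

    def test_effectively_constant(self):
        M = make_matrix([[0, None, 0, None], [1, 1, 1, 1]], n_states=2)
        assert char_min_steps(M, 0) == 0
        assert char_max_steps(M, 0) == 0


class TestCiRi:
    def test_hand_computed_example(self, quartet_trees):
        M = make_matrix([[0, 0, 1, 1], [0, 1, 0, 1]])
        ci, ri = ci_ri(quartet_trees["AB|CD"], M)
        assert ci == pytest.approx(2 / 3, abs=1e-12)
        assert ri == pytest.approx(0.5, abs=1e-12)

    def test_homoplasy_free_is_one(self):
        M, tree, _ = gen_matrix(MatrixGenConfig(n_taxa=8, n_characters=30,
                                                seed=1))
        ci, ri = ci_ri(tree, M)
        assert ci == 1.0 and ri == 1.0

    def test_uninformative_ri_undefined(self, quartet_trees):
        M = make_matrix([[0, 1, 1, 1]])  # autapomorphy: g == m
        _, ri = ci_ri(quartet_trees["AB|CD"], M)
        assert ri is None

    def test_constant_character_changes_nothing(self, quartet_trees):
        M1 = make_matrix([[0, 0, 1, 1]])
        M2 = make_matrix([[0, 0, 1, 1], [1, 1, 1, 1]])
        assert (fitch_length(quartet_trees["AB|CD"], M1)
                == fitch_length(quartet_trees["AB|CD"], M2))


class TestSearch:
    def test_quartet_single_informative_character(self):
        M = make_matrix([[0, 0, 1, 1]] * 3)
        res = heuristic_search(M, replicates=3, seed=0)
        assert res.length == 3
        assert res.splits_consensus == frozenset({frozenset({2, 3})})

    def test_homoplasy_free_recovery(self):
        cfg = MatrixGenConfig(n_taxa=8, n_characters=40, change_budget=1,
                              seed=5)
        M, tree, _ = gen_matrix(cfg)
        res = heuristic_search(M, replicates=5, swap="tbr", hold=10, seed=2)
        assert res.length == 40  # one step per character
        assert T.splits(tree, 8) in [T.splits(a, 8) for a in res.best_trees]

    def test_matches_exhaustive_on_noisy_matrix(self):
        cfg = MatrixGenConfig(n_taxa=7, n_characters=15, change_budget=2,
                              n_states=3, seed=6)
        M, _, _ = gen_matrix(cfg)
        res = heuristic_search(M, replicates=8, swap="tbr", hold=10, seed=3)
        L_star, best = exhaustive_search(M)
        assert res.length == L_star
        found = {T.splits(a, 7) for a in res.best_trees}
        expected = {T.splits(a, 7) for a in best}
        assert found == expected

    def test_seed_reproducibility(self):
        M, _, _ = gen_matrix(MatrixGenConfig(n_taxa=8, n_characters=20,
                                             change_budget=2, seed=7))
        r1 = heuristic_search(M, replicates=4, seed=9)
        r2 = heuristic_search(M, replicates=4, seed=9)
        assert r1.length == r2.length
        assert [T.splits(a, 8) for a in r1.best_trees] == \
            [T.splits(a, 8) for a in r2.best_trees]

    def test_too_few_taxa_rejected(self):
        M = make_matrix([[0, 1, 1]])
        with pytest.raises(ValueError):
            heuristic_search(M)
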