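"""Dispersal-vicariance reconstruction: costs, scenarios, exact DP."""

import dendropy
import numpy as np
import pytest

from morphoclade.biogeo import (
    AreaDistribution,
    diva_reconstruct,
    split_scenarios,
    transition_cost,
)
from morphoclade.simulate import RangeGenConfig, gen_ranges, random_rooted_tree

import oracles

AB = ("A", "B")
ABC = ("A", "B", "C")


class TestTransitionCost:
    def test_one_dispersal(self):
        assert transition_cost(0b01, 0b11) == 1

    def test_two_extinctions_one_dispersal(self):
        assert transition_cost(0b011, 0b100) == 3

    def test_identity_free(self):
        assert transition_cost(0b101, 0b101) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            transition_cost(0, 0b1)


class TestSplitScenarios:
    def test_single_area_duplicates(self):
        assert split_scenarios(0b1) == {(0b1, 0b1)}

    def test_two_areas_single_bipartition(self):
        assert split_scenarios(0b11) == {(0b01, 0b10)}

    def test_three_areas_three_bipartitions(self):
        assert len(split_scenarios(0b111)) == 3

    def test_counts_follow_formula(self):
        for k in range(1, 5):
            F = (1 << k) - 1
            expected = 1 if k == 1 else 2 ** (k - 1) - 1
            assert len(split_scenarios(F)) == expected


class TestReconstruct:
    def test_free_vicariance_of_sisters(self):
        rec = diva_reconstruct("(X,Y);", {"X": ["A"], "Y": ["B"]}, AB)
        assert rec.cost == 0
        assert rec.optima_names(["X", "Y"]) == (("A", "B"),)

    def test_uniform_ranges_cost_zero(self):
        rec = diva_reconstruct("((X,Y),Z);",
                               {"X": ["A"], "Y": ["A"], "Z": ["A"]}, AB)
        assert rec.cost == 0
        for optima in rec.node_optima.values():
            assert optima == (0b1,)

    def test_widespread_root_beats_single_area(self):
        rec = diva_reconstruct("((X,Y),Z);",
                               {"X": ["A"], "Y": ["A"], "Z": ["B"]}, AB)
        assert rec.cost == 0
        assert rec.optima_names(["X", "Y", "Z"]) == (("A", "B"),)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(12):
            n = int(rng.integers(3, 6))
            n_areas = int(rng.integers(2, 4))
            areas = ABC[:n_areas]
            tree = dendropy.Tree.get(data=random_rooted_tree(n, rng),
                                     schema="newick")
            ranges = {f"r{i}": oracles.random_range(rng, n_areas, areas)
                      for i in range(n)}
            rec = diva_reconstruct(tree, ranges, areas)
            cost, by_clade = oracles.brute_force_diva(tree, ranges, areas)
            assert rec.cost == cost
            for clade, opt in by_clade.items():
                assert frozenset(rec.node_optima[clade]) == opt

    def test_maxareas_monotonicity(self):
        rng = np.random.default_rng(23)
        tree_nw = random_rooted_tree(6, rng)
        ranges = {f"r{i}": AreaDistribution(1 << int(rng.integers(3)), ABC)
                  for i in range(6)}
        prev = None
        for maxa in (3, 2, 1):
            rec = diva_reconstruct(tree_nw, ranges, ABC, maxareas=maxa)
            if prev is not None:
                assert rec.cost >= prev
            prev = rec.cost

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            diva_reconstruct("(X,Y,Z);",
                             {"X": ["A"], "Y": ["A"], "Z": ["B"]}, AB)

    def test_unknown_area_rejected(self):
        with pytest.raises(ValueError):
            diva_reconstruct("(X,Y);", {"X": ["A"], "Y": ["Q"]}, AB)


class TestSimulatedHistories:
    def test_vicariance_only_costs_zero(self):
        for seed in range(5):
            nw, ranges, _ = gen_ranges(RangeGenConfig(
                n_taxa=6, n_areas=3, seed=seed))
            rec = diva_reconstruct(nw, ranges, ABC)
            assert rec.cost == 0

    def test_dispersal_bound(self):
        for k in (1, 2, 3):
            for seed in range(3):
                nw, ranges, trace = gen_ranges(RangeGenConfig(
                    n_taxa=6, n_areas=3, n_dispersals=k, seed=10 * k + seed))
                applied = ((trace.event == "dispersal")
                           & (trace.status == "ok")).sum()
                rec = diva_reconstruct(nw, ranges, ABC)
                assert rec.cost <= applied

    def test_seed_reproducibility(self):
        a = gen_ranges(RangeGenConfig(n_taxa=7, n_areas=3, n_dispersals=2,
                                      seed=5))
        b = gen_ranges(RangeGenConfig(n_taxa=7, n_areas=3, n_dispersals=2,
                                      seed=5))
        assert a[0] == b[0]
        assert {t: r.bits for t, r in a[1].items()} == \
            {t: r.bits for t, r in b[1].items()}
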