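"""Rank conversion, footrule distance, Borda and Kru-Bor merging.

The Kru-Bor oracle is an independent brute-force trace: at each step
enumerate all pair distances, merge the closest pair by averaging ranks.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_ranking, ranking_from_order
from dilipred.ranking import (
    GeneRanking,
    borda_merge,
    extreme_sets,
    footrule_distance,
    krubor_merge,
    zscores_to_ranking,
)


class TestZscoresToRanking:
    def test_descending_z_gives_ascending_ranks(self):
        z = pd.Series({"g1": 2.0, "g2": 0.0, "g3": -1.0})
        r = zscores_to_ranking(z, "d", "s")
        assert r.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}

    def test_ties_break_by_gene_identifier(self):
        z = pd.Series({"g2": 1.0, "g1": 1.0, "g3": 0.0})
        r = zscores_to_ranking(z, "d", "s")
        assert r.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}

    def test_all_equal_z_is_identifier_order(self):
        z = pd.Series(0.0, index=["g3", "g1", "g2"])
        r = zscores_to_ranking(z, "d", "s")
        assert list(r.ranks.sort_values().index) == ["g1", "g2", "g3"]

    def test_nan_rejected_with_diagnostic(self):
        z = pd.Series({"g1": 1.0, "g2": np.nan})
        with pytest.raises(ValueError, match="missing"):
            zscores_to_ranking(z, "d", "s")

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            GeneRanking("d", "s", pd.Series({"g1": 1, "g2": 1}))


class TestFootrule:
    def test_identical_rankings_distance_zero(self):
        r = ranking_from_order(["g1", "g2", "g3"])
        assert footrule_distance(r, r) == 0

    def test_reversal_of_three(self):
        r1 = ranking_from_order(["g1", "g2", "g3"])
        r2 = ranking_from_order(["g3", "g2", "g1"])
        assert footrule_distance(r1, r2) == 4  # |1-3| + |2-2| + |3-1|

    def test_universe_mismatch_rejected(self):
        r1 = ranking_from_order(["g1", "g2"])
        r2 = ranking_from_order(["g1", "g3"])
        with pytest.raises(ValueError):
            footrule_distance(r1, r2)

    def test_metric_axioms_on_random_triples(self, rng):
        genes = [f"g{i:02d}" for i in range(20)]
        for _ in range(300):
            a, b, c = (random_ranking(rng, genes) for _ in range(3))
            dab, dba = footrule_distance(a, b), footrule_distance(b, a)
            assert dab == dba  # symmetry
            assert dab >= 0
            assert (dab == 0) == a.ranks.equals(b.ranks)  # identity
            assert footrule_distance(a, c) <= dab + footrule_distance(b, c)


class TestBordaMerge:
    def test_idempotent_on_identical_ranking(self):
        r = ranking_from_order(["g1", "g2", "g3", "g4"])
        assert borda_merge(r, r).ranks.equals(r.ranks)

    def test_all_means_tie_resolves_to_identifier_order(self):
        r1 = ranking_from_order(["g1", "g2", "g3"])
        r2 = ranking_from_order(["g3", "g2", "g1"])
        merged = borda_merge(r1, r2)  # all means 2
        assert merged.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}

    def test_partial_tie_hand_computation(self):
        r1 = ranking_from_order(["g1", "g2", "g3"])
        r2 = ranking_from_order(["g2", "g1", "g3"])
        merged = borda_merge(r1, r2)  # means (1.5, 1.5, 3)
        assert merged.ranks.to_dict() == {"g1": 1, "g2": 2, "g3": 3}

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_commutative_exactly(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(12)]
        a, b = random_ranking(rng, genes), random_ranking(rng, genes)
        assert borda_merge(a, b).ranks.equals(borda_merge(b, a).ranks)


def krubor_oracle(rankings):
    """Brute-force Kru-Bor trace independent of the library implementation."""
    nodes = [(i, r.ranks.sort_index().to_numpy().astype(float)) for i, r in enumerate(rankings)]
    index = rankings[0].ranks.sort_index().index

    def rerank(values):
        order = np.argsort(values, kind="stable")
        out = np.empty(len(values))
        out[order] = np.arange(1, len(values) + 1)
        return out

    while len(nodes) > 1:
        options = []
        for (ia, a), (ib, b) in itertools.combinations(nodes, 2):
            d = np.abs(a - b).sum()
            options.append((d, min(ia, ib), max(ia, ib), ia, ib))
        d, _, _, ia, ib = min(options)
        a = next(v for i, v in nodes if i == ia)
        b = next(v for i, v in nodes if i == ib)
        merged = rerank((a + b) / 2.0)
        nodes = [(i, v) for i, v in nodes if i not in (ia, ib)] + [(min(ia, ib), merged)]
    return pd.Series(nodes[0][1].astype(int), index=index)


class TestKruborMerge:
    def test_identical_rankings_return_that_ranking(self):
        r = ranking_from_order(["g1", "g2", "g3", "g4"])
        merged = krubor_merge([r, r, r])
        assert merged.ranks.equals(r.ranks)
        assert merged.source == "merged"

    def test_singleton_returns_itself(self):
        r = ranking_from_order(["g1", "g2", "g3"])
        assert krubor_merge([r]) is r

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            krubor_merge([])

    def test_two_inputs_equal_borda_merge(self, rng):
        genes = [f"g{i:02d}" for i in range(15)]
        for _ in range(20):
            a, b = random_ranking(rng, genes), random_ranking(rng, genes)
            assert krubor_merge([a, b]).ranks.equals(borda_merge(a, b).ranks)

    def test_fixed_triple_matches_hand_traceable_oracle(self):
        r1 = ranking_from_order(["g1", "g2", "g3", "g4", "g5"])
        r2 = ranking_from_order(["g2", "g1", "g3", "g4", "g5"])
        r3 = ranking_from_order(["g5", "g4", "g3", "g2", "g1"])
        merged = krubor_merge([r1, r2, r3])
        assert merged.ranks.equals(krubor_oracle([r1, r2, r3]))

    def test_random_lists_match_oracle(self, rng):
        genes = [f"g{i:02d}" for i in range(10)]
        for _ in range(50):
            rs = [random_ranking(rng, genes, source=f"s{j}") for j in range(4)]
            assert krubor_merge(rs).ranks.equals(krubor_oracle(rs))

    def test_order_invariant_when_distances_distinct(self, rng):
        genes = [f"g{i:02d}" for i in range(12)]
        tries = 0
        while tries < 10:
            rs = [random_ranking(rng, genes, source=f"s{j}") for j in range(3)]
            d = [footrule_distance(a, b) for a, b in itertools.combinations(rs, 2)]
            if len(set(d)) < 3:
                continue
            tries += 1
            base = krubor_merge(rs).ranks
            for perm in itertools.permutations(rs):
                assert krubor_merge(list(perm)).ranks.equals(base)


class TestExtremeSets:
    def test_top_and_bottom_of_identity_ranking(self):
        r = ranking_from_order([f"g{i}" for i in range(1, 7)])
        es = extreme_sets(r, 2)
        assert es.top == {"g1", "g2"} and es.bottom == {"g5", "g6"}

    def test_half_universe_covers_everything(self):
        r = ranking_from_order(["g1", "g2", "g3", "g4"])
        es = extreme_sets(r, 2)
        assert es.members == {"g1", "g2", "g3", "g4"}

    def test_oversized_n_rejected(self):
        r = ranking_from_order(["g1", "g2", "g3"])
        with pytest.raises(ValueError):
            extreme_sets(r, 2)

    def test_reversal_swaps_top_and_bottom(self, rng):
        genes = [f"g{i:02d}" for i in range(10)]
        r = random_ranking(rng, genes)
        rev = GeneRanking(r.drug_id, r.source, 11 - r.ranks)
        es, es_rev = extreme_sets(r, 3), extreme_sets(rev, 3)
        assert es.top == es_rev.bottom and es.bottom == es_rev.top
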