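"""Enrichment: ranking stat, weighted KS enrichment score, permutation p,
hypergeometric over-representation and cross-layer term integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tepomics import (
    GeneSet,
    cross_layer_overlap,
    gsea_es,
    gsea_preranked,
    mirna_ora,
    ora_hypergeom,
    rank_stat,
)


def es_oracle(stats_sorted, member_mask, w=1.0):
    """Plain running-sum ES, one step per ranked feature."""
    stats_sorted = np.asarray(stats_sorted, float)
    member_mask = np.asarray(member_mask, bool)
    n, k = len(stats_sorted), member_mask.sum()
    wts = np.abs(stats_sorted[member_mask]) ** w
    wts = wts / wts.sum() if wts.sum() > 0 else np.full(k, 1 / k)
    dec = 1.0 / (n - k)
    running, best, j = 0.0, 0.0, 0
    for i in range(n):
        if member_mask[i]:
            running += wts[j]
            j += 1
        else:
            running -= dec
        if abs(running) > abs(best):
            best = running
    return best


def _ranked(rng, n=200):
    stats_ = np.sort(rng.normal(size=n))[::-1] * 3
    return pd.Series(stats_, index=[f"g{i:04d}" for i in range(n)])


class TestRankStat:
    @pytest.mark.parametrize(
        "p,lfc,expected",
        [(1.0, 1.0, 0.0), (0.01, -1.5, -2.0), (1e-5, 0.7, 5.0)],
    )
    def test_examples(self, p, lfc, expected):
        assert rank_stat(p, lfc) == pytest.approx(expected)

    def test_zero_p_is_floored(self):
        assert np.isfinite(rank_stat(0.0, 1.0))
        assert rank_stat(0.0, 1.0) == pytest.approx(300.0)


class TestGseaEs:
    def test_matches_running_sum_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ranked = _ranked(rng, n=int(rng.integers(50, 300)))
            k = int(rng.integers(3, 25))
            members = rng.choice(ranked.index, size=k, replace=False)
            gs = GeneSet("s", frozenset(members))
            mask = ranked.index.isin(gs.members)
            assert gsea_es(ranked, gs) == pytest.approx(
                es_oracle(ranked.to_numpy(), mask), abs=1e-12
            )

    def test_top_loaded_set_scores_near_one(self):
        rng = np.random.default_rng(1)
        ranked = _ranked(rng, 200)
        gs = GeneSet("top", frozenset(ranked.index[:10]))
        assert gsea_es(ranked, gs) > 0.9

    def test_single_member_ranked_first_scores_one(self):
        ranked = pd.Series([5.0, 1.0, 0.5, -2.0], index=list("abcd"))
        assert gsea_es(ranked, GeneSet("s", frozenset("a"))) == pytest.approx(1.0)

    def test_disjoint_or_universal_sets_rejected(self):
        ranked = pd.Series([2.0, 1.0, -1.0], index=list("abc"))
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("s", frozenset("xyz")))
        with pytest.raises(ValueError):
            gsea_es(ranked, GeneSet("s", frozenset("abc")))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        ranked = _ranked(rng, 80)
        members = rng.choice(ranked.index, size=8, replace=False)
        gs = GeneSet("s", frozenset(members))
        assert gsea_es(ranked * scale, gs) == pytest.approx(gsea_es(ranked, gs), abs=1e-12)


class TestGseaPreranked:
    def test_planted_top_set_detected(self):
        rng = np.random.default_rng(3)
        ranked = _ranked(rng, 500)
        gs = GeneSet("planted", frozenset(ranked.index[:20]))
        res = gsea_preranked(ranked, [gs], n_perm=500, seed=1)
        assert res.loc[0, "p_value"] < 0.05
        assert res.loc[0, "direction"] == 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        ranked = _ranked(rng, 100)
        sets = [GeneSet(f"s{i}", frozenset(
            np.random.default_rng(i).choice(ranked.index, size=10, replace=False)
        )) for i in range(3)]
        r1 = gsea_preranked(ranked, sets, n_perm=200, seed=7)
        r2 = gsea_preranked(ranked, sets, n_perm=200, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_p_values_bounded_below_by_permutation_resolution(self):
        rng = np.random.default_rng(5)
        ranked = _ranked(rng, 300)
        gs = GeneSet("top", frozenset(ranked.index[:15]))
        res = gsea_preranked(ranked, [gs], n_perm=200, seed=2)
        assert res.loc[0, "p_value"] >= 1 / 201

    def test_requires_enough_permutations(self):
        ranked = pd.Series([2.0, 1.0, -1.0, -2.0], index=list("abcd"))
        with pytest.raises(ValueError):
            gsea_preranked(ranked, [GeneSet("s", frozenset("a"))], n_perm=10)


class TestOra:
    def test_single_term_tail_example(self):
        # universe 10, set 5, hits 3, full overlap: p = (5*4*3)/(10*9*8)
        universe = set(f"m{i}" for i in range(10))
        gs = GeneSet("s", frozenset(list(universe)[:5]))
        hits = set(list(gs.members)[:3])
        assert ora_hypergeom(hits, universe, gs) == pytest.approx(
            (5 * 4 * 3) / (10 * 9 * 8), abs=1e-12
        )

    def test_zero_overlap_at_minimum_gives_one(self):
        universe = {"a", "b", "c", "d", "e"}
        gs = GeneSet("s", frozenset({"a"}))
        assert ora_hypergeom({"b"}, universe, gs) == pytest.approx(1.0)

    def test_matches_enumeration_for_small_universes(self):
        from itertools import combinations
        from math import comb
        rng = np.random.default_rng(6)
        for _ in range(25):
            n_u = int(rng.integers(4, 16))
            universe = [f"x{i}" for i in range(n_u)]
            set_size = int(rng.integers(1, n_u))
            n_hits = int(rng.integers(1, n_u))
            members = set(rng.choice(universe, size=set_size, replace=False))
            hits = set(rng.choice(universe, size=n_hits, replace=False))
            obs = len(hits & members)
            # exhaustive: over all hit draws of the same size, P(overlap >= obs)
            p_brute = sum(
                1 for c in combinations(universe, n_hits)
                if len(set(c) & members) >= obs
            ) / comb(n_u, n_hits)
            got = ora_hypergeom(hits, set(universe), GeneSet("s", frozenset(members)))
            assert got == pytest.approx(p_brute, abs=1e-12)

    def test_hits_must_be_in_universe(self):
        with pytest.raises(ValueError):
            ora_hypergeom({"q"}, {"a", "b"}, GeneSet("s", frozenset({"a"})))

    def test_mirna_ora_assigns_fixed_nes(self):
        universe = {f"m{i}" for i in range(30)}
        members = frozenset(list(universe)[:10])
        hits = set(list(members)[:8])
        res = mirna_ora(hits, universe, [GeneSet("s", members)], {"s": -1})
        row = res.iloc[0]
        assert row["significant"]
        assert row["nes"] == pytest.approx(-1.5)


class TestCrossLayerOverlap:
    def _frame(self, terms_p, layer):
        return pd.DataFrame(
            {
                "set_name": list(terms_p),
                "p_value": list(terms_p.values()),
                "nes": [1.6] * len(terms_p),
                "direction": [1] * len(terms_p),
            }
        )

    def test_disjoint_significant_sets_give_empty_overlap(self):
        res = {
            "mrna": self._frame({"t1": 0.01, "t2": 0.5}, "mrna"),
            "protein": self._frame({"t1": 0.5, "t2": 0.01}, "protein"),
        }
        assert len(cross_layer_overlap(res)) == 0

    def test_term_significant_everywhere_is_returned_per_layer(self):
        res = {
            "mrna": self._frame({"t1": 0.01, "t2": 0.001}, "mrna"),
            "intron": self._frame({"t1": 0.02, "t2": 0.2}, "intron"),
            "protein": self._frame({"t1": 0.03, "t2": 0.01}, "protein"),
        }
        out = cross_layer_overlap(res)
        assert set(out["term"]) == {"t1"}
        assert len(out) == 3  # one row per layer

    def test_requires_two_layers(self):
        with pytest.raises(ValueError):
            cross_layer_overlap({"mrna": self._frame({"t": 0.01}, "mrna")})
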