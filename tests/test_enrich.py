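"""Validation statistics against independent oracles and printed values."""

import math

import numpy as np
import pytest
from scipy import stats

from phewasrank.containers import ContingencyTable2x2, GeneSetCollection, RankedGeneList
from phewasrank.enrich import (
    bh_adjust,
    chi2_2x2,
    ks_top_enrichment,
    over_representation,
    overlap_stats,
)


def chi2_expected_counts_oracle(a, b, c, d):
    """Pearson statistic via the sum over cells of (O - E)^2 / E."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    return ((obs - exp) ** 2 / exp).sum()


def hypergeom_enumeration_oracle(overlap, universe, set_size, query):
    """P[X >= overlap] by summing the exact pmf over all possible overlaps."""
    total = 0.0
    for k in range(max(0, set_size + query - universe), min(set_size, query) + 1):
        if k >= overlap:
            total += (
                math.comb(set_size, k)
                * math.comb(universe - set_size, query - k)
                / math.comb(universe, query)
            )
    return total


def bh_stepup_oracle(p):
    """Brute-force BH: sort, scale, enforce monotone from the top, restore order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top, 1.0)
        adj[i] = val
        prev = val
    return adj


def ks_cutoff_scan_oracle(ranked, targets):
    """sup over every rank cutoff of F_targets - F_background."""
    n_t = sum(g in targets for g in ranked.gene_ids)
    n_b = len(ranked) - n_t
    best = 0.0
    ct = cb = 0
    for _, g, _ in ranked.entries:
        if g in targets:
            ct += 1
        else:
            cb += 1
        best = max(best, ct / n_t - cb / n_b)
    return best


class TestChi2:
    def test_equal_proportions_statistic_zero(self):
        res = chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0
        assert res.p_value == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_2x2(ContingencyTable2x2(0, 5, 0, 7))

    def test_matches_expected_counts_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 500, size=4)
            res = chi2_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert res.statistic == pytest.approx(
                chi2_expected_counts_oracle(a, b, c, d), abs=1e-10
            )

    def test_matches_scipy_uncorrected(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 300, size=4))
            res = chi2_2x2(ContingencyTable2x2(a, b, c, d))
            stat, p, dof, _ = stats.chi2_contingency(
                [[a, b], [c, d]], correction=False
            )
            assert res.statistic == pytest.approx(stat)
            assert res.p_value == pytest.approx(p)
            assert res.df == dof == 1


class TestOverlap:
    def test_disjoint(self):
        assert overlap_stats({"A", "B"}, {"C"}) == (0, 0.0)

    def test_subset_is_hundred_percent(self):
        assert overlap_stats({"A", "B"}, {"A", "B", "C"}) == (2, 100.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats(set(), {"A"})

    def test_rounding_two_decimals(self):
        genes = {f"g{k}" for k in range(3)}
        count, pct = overlap_stats(genes, {"g0"})
        assert (count, pct) == (1, 33.33)


class TestKS:
    def test_complete_separation_gives_d_one(self):
        entries = tuple((k + 1, f"g{k}", float(20 - k)) for k in range(20))
        ranked = RankedGeneList(entries)
        targets = {f"g{k}" for k in range(5)}
        res = ks_top_enrichment(ranked, targets)
        assert res.D == pytest.approx(1.0)
        assert res.n_targets == 5 and res.n_background == 15

    def test_matches_exhaustive_cutoff_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            entries = tuple((k + 1, f"g{k:02d}", float(n - k)) for k in range(n))
            ranked = RankedGeneList(entries)
            n_t = int(rng.integers(1, n))
            targets = {f"g{k:02d}" for k in rng.choice(n, size=n_t, replace=False)}
            res = ks_top_enrichment(ranked, targets)
            assert res.D == pytest.approx(ks_cutoff_scan_oracle(ranked, targets))

    def test_almost_all_targets_matches_scan(self):
        n = 12
        entries = tuple((k + 1, f"g{k:02d}", float(n - k)) for k in range(n))
        ranked = RankedGeneList(entries)
        targets = {f"g{k:02d}" for k in range(n - 1)}  # all but the last
        res = ks_top_enrichment(ranked, targets)
        assert res.D == pytest.approx(ks_cutoff_scan_oracle(ranked, targets))

    def test_depends_only_on_ranks_not_scores(self):
        # any strictly monotone transform of the scores leaves D unchanged
        n = 30
        rng = np.random.default_rng(9)
        targets = {f"g{k:02d}" for k in rng.choice(n, size=8, replace=False)}
        base = sorted(rng.uniform(1, 2, size=n))[::-1]
        r1 = RankedGeneList(tuple((k + 1, f"g{k:02d}", base[k]) for k in range(n)))
        r2 = RankedGeneList(
            tuple((k + 1, f"g{k:02d}", math.exp(3 * base[k])) for k in range(n))
        )
        assert ks_top_enrichment(r1, targets).D == ks_top_enrichment(r2, targets).D

    def test_one_sided_p_matches_scipy_on_rank_samples(self):
        # cross-check statistic against scipy's one-sided two-sample KS
        rng = np.random.default_rng(13)
        n = 80
        entries = tuple((k + 1, f"g{k:02d}", float(n - k)) for k in range(n))
        ranked = RankedGeneList(entries)
        targets = {f"g{k:02d}" for k in rng.choice(n, size=20, replace=False)}
        res = ks_top_enrichment(ranked, targets)
        t_ranks = [r for r, g, _ in entries if g in targets]
        b_ranks = [r for r, g, _ in entries if g not in targets]
        scipy_res = stats.ks_2samp(t_ranks, b_ranks, alternative="greater", method="asymp")
        assert res.D == pytest.approx(scipy_res.statistic)

    def test_no_targets_in_list_raises(self, ranked_ten):
        with pytest.raises(ValueError, match="target"):
            ks_top_enrichment(ranked_ten, {"absent"})

    def test_all_targets_raises(self, ranked_ten):
        with pytest.raises(ValueError, match="background"):
            ks_top_enrichment(ranked_ten, set(ranked_ten.gene_ids))


class TestBH:
    def test_singleton(self):
        assert bh_adjust([0.05]) == pytest.approx([0.05])

    def test_stepup_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40))).tolist()
            adj = bh_adjust(p)
            oracle = bh_stepup_oracle(p)
            assert adj == pytest.approx(oracle)
            assert all(lo <= hi <= 1 for lo, hi in zip(p, adj))


class TestORA:
    def test_full_overlap_exact_probability(self):
        universe = {f"g{k}" for k in range(20)}
        query = {f"g{k}" for k in range(5)}
        coll = GeneSetCollection({"S": frozenset(query)})
        row = over_representation(query, universe, coll)[0]
        assert row.overlap == 5
        assert row.p_raw == pytest.approx(1 / 15504)

    def test_disjoint_set_p_is_one(self):
        universe = {f"g{k}" for k in range(10)}
        coll = GeneSetCollection({"S": frozenset({"g8", "g9"})})
        row = over_representation({"g0", "g1"}, universe, coll)[0]
        assert row.overlap == 0
        assert row.p_raw == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            over_representation(
                {"x"}, {"a", "b"}, GeneSetCollection({"S": frozenset({"a"})})
            )

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n_u = int(rng.integers(5, 31))
            universe = {f"g{k:02d}" for k in range(n_u)}
            query = set(
                f"g{k:02d}" for k in rng.choice(n_u, size=int(rng.integers(1, n_u)), replace=False)
            )
            set_size = int(rng.integers(1, n_u + 1))
            members = frozenset(
                f"g{k:02d}" for k in rng.choice(n_u, size=set_size, replace=False)
            )
            coll = GeneSetCollection({"S": members})
            row = over_representation(query, universe, coll)[0]
            expect = hypergeom_enumeration_oracle(row.overlap, n_u, set_size, len(query))
            assert row.p_raw == pytest.approx(expect, abs=1e-12)

    def test_adjusted_at_least_raw_and_flags(self):
        universe = {f"g{k}" for k in range(25)}
        query = {f"g{k}" for k in range(6)}
        coll = GeneSetCollection(
            {
                "hit": frozenset({"g0", "g1", "g2", "g3"}),
                "miss": frozenset({"g20", "g21", "g22"}),
            }
        )
        rows = over_representation(query, universe, coll, cutoff=0.05)
        for row in rows:
            assert row.p_adjust >= row.p_raw
            assert row.significant == (row.p_adjust < 0.05)
        assert rows[0].set_name == "hit"
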