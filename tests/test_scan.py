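"""Pairwise AFD scans, category means, core-region chaining, F_ST."""

import itertools

import numpy as np
import pytest

from poolscan import (CategoryScan, ConfigError, GenomeLayout,
                      PopulationSpec, afd, detect_core_snps, hudson_fst,
                      integrate_category, marine_freshwater_scan,
                      pairwise_scan, standardize_pairs)
from conftest import make_matrix, random_matrix


class TestAFD:
    @pytest.mark.parametrize("p1,p2,expected", [
        (0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.85, 0.15, 0.70)])
    def test_values(self, p1, p2, expected):
        assert afd(p1, p2) == pytest.approx(expected)

    def test_allele_tracking_invariance(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(100), rng.random(100)
        assert np.allclose(afd(p1, p2), afd(1 - p1, 1 - p2))

    def test_missing_propagates(self):
        assert np.isnan(afd(np.nan, 0.5))


class TestPairwiseScan:
    def test_five_plus_five_yields_45_pairs(self, ten_pop_specs):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 20, populations=ten_pop_specs, max_count=80)
        table = pairwise_scan(m, min_depth_per_pop=50)
        assert len(table.pairs) == 45
        cats = {c: table.categories.count(c) for c in set(table.categories)}
        assert cats == {"BA": 25, "BB": 10, "AA": 10}

    def test_low_depth_pool_makes_snp_missing_for_its_pairs(self, layout2):
        pops = [PopulationSpec("B1", "basic", 30),
                PopulationSpec("B2", "basic", 30),
                PopulationSpec("A1", "acidic", 30)]
        m = make_matrix([("chrI", 1, "L1", "A", "G",
                          [(30, 19), (60, 0), (0, 60)])], pops, layout2)
        table = pairwise_scan(m, min_depth_per_pop=50)
        for j, pair in enumerate(table.pairs):
            if "B1" in pair:
                assert np.isnan(table.afd[0, j])
            else:
                assert not np.isnan(table.afd[0, j])

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            m = random_matrix(rng, 25, max_count=80)
            table = pairwise_scan(m, min_depth_per_pop=30)
            depth = m.depths()
            for i in range(m.n_snps):
                for j, (a, b) in enumerate(table.pairs):
                    ia, ib = m.pop_index(a), m.pop_index(b)
                    if depth[i, ia] < 30 or depth[i, ib] < 30:
                        assert np.isnan(table.afd[i, j])
                    else:
                        exp = abs(m.ref_counts[i, ia] / depth[i, ia]
                                  - m.ref_counts[i, ib] / depth[i, ib])
                        assert table.afd[i, j] == pytest.approx(exp)

    def test_marine_freshwater_pairs_lakes_against_marine(self, layout2):
        pops = [PopulationSpec("B1", "basic", 30),
                PopulationSpec("A1", "acidic", 30),
                PopulationSpec("MAR", "marine", 30)]
        m = make_matrix([("chrI", 1, "L1", "A", "G",
                          [(60, 0), (0, 60), (30, 30)])], pops, layout2)
        table = marine_freshwater_scan(m, "MAR")
        assert table.pairs == [("B1", "MAR"), ("A1", "MAR")]
        assert set(table.categories) == {"MF"}


class TestIntegrateCategory:
    def test_insufficient_pairs_gives_missing(self, ten_pop_specs):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 30, populations=ten_pop_specs, max_count=80)
        table = pairwise_scan(m, min_depth_per_pop=1)
        # knock one BA pair out at SNP 0: make B1 zero depth there
        ba_cols = table.pair_columns("BA")
        table.afd[0, ba_cols[:8]] = np.nan     # 17 of 25 remain
        scan = integrate_category(table, "BA", min_pairs=18)
        assert np.isnan(scan.mean_afd[0])
        assert scan.n_pairs[0] == 17

    def test_constant_pairs_average_to_constant(self, ten_pop_specs):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 10, populations=ten_pop_specs)
        table = pairwise_scan(m, min_depth_per_pop=1)
        table.afd[:, table.pair_columns("AA")] = 0.37
        scan = integrate_category(table, "AA", min_pairs=8)
        assert np.allclose(scan.mean_afd, 0.37)

    def test_matches_bruteforce_mean(self, ten_pop_specs):
        rng = np.random.default_rng(5)
        for _ in range(40):
            m = random_matrix(rng, 15, populations=ten_pop_specs, max_count=90)
            table = pairwise_scan(m, min_depth_per_pop=40)
            for cat, minp in (("BA", 18), ("BB", 8), ("AA", 8)):
                scan = integrate_category(table, cat, min_pairs=minp)
                cols = table.pair_columns(cat)
                for i in range(m.n_snps):
                    vals = [table.afd[i, j] for j in cols
                            if not np.isnan(table.afd[i, j])]
                    if len(vals) >= minp:
                        assert scan.mean_afd[i] == pytest.approx(np.mean(vals))
                    else:
                        assert np.isnan(scan.mean_afd[i])

    def test_mean_invariant_to_pair_order(self, ten_pop_specs):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 15, populations=ten_pop_specs, max_count=90)
        table = pairwise_scan(m, min_depth_per_pop=1)
        scan1 = integrate_category(table, "BA", min_pairs=1)
        perm = np.random.default_rng(0).permutation(len(table.pairs))
        table2 = type(table)(table.chrom, table.pos,
                             [table.pairs[i] for i in perm],
                             [table.categories[i] for i in perm],
                             table.afd[:, perm])
        scan2 = integrate_category(table2, "BA", min_pairs=1)
        assert np.allclose(scan1.mean_afd, scan2.mean_afd, equal_nan=True)


class TestStandardize:
    def test_constant_pair_becomes_unity(self, ten_pop_specs):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 10, populations=ten_pop_specs)
        table = pairwise_scan(m, min_depth_per_pop=1)
        table.afd[:, 0] = 0.42
        out = standardize_pairs(table)
        assert np.allclose(out.afd[:, 0], 1.0)

    def test_matches_bruteforce_division(self, ten_pop_specs):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 20, populations=ten_pop_specs, max_count=90)
        table = pairwise_scan(m, min_depth_per_pop=1)
        out = standardize_pairs(table)
        for j in range(len(table.pairs)):
            col = table.afd[:, j]
            mean = np.nanmean(col)
            assert np.allclose(out.afd[:, j], col / mean, equal_nan=True)

    def test_ranking_preserved_within_single_pair(self, ten_pop_specs):
        rng = np.random.default_rng(9)
        m = random_matrix(rng, 30, populations=ten_pop_specs, max_count=90)
        table = pairwise_scan(m, min_depth_per_pop=1)
        out = standardize_pairs(table)
        col, std_col = table.afd[:, 3], out.afd[:, 3]
        ok = ~np.isnan(col)
        assert np.array_equal(np.argsort(col[ok]), np.argsort(std_col[ok]))

    def test_zero_mean_pair_rejected(self, ten_pop_specs):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 10, populations=ten_pop_specs)
        table = pairwise_scan(m, min_depth_per_pop=1)
        table.afd[:, 2] = 0.0
        with pytest.raises(ConfigError):
            standardize_pairs(table)


def _scan(chrom, pos, vals):
    n = len(pos)
    return CategoryScan("BA", np.array(chrom, dtype=object),
                        np.array(pos, dtype=np.int64),
                        np.array(vals, dtype=float), np.full(n, 25))


class TestCoreRegions:
    def test_separation_boundary_at_50kb(self):
        one = detect_core_snps(_scan(["c", "c"], [100_000, 149_999],
                                     [0.8, 0.9]), threshold=0.7)
        assert len(one) == 1
        two = detect_core_snps(_scan(["c", "c"], [100_000, 150_001],
                                     [0.8, 0.9]), threshold=0.7)
        assert len(two) == 2

    def test_single_passing_snp_is_its_own_core(self):
        regions = detect_core_snps(_scan(["c"], [5], [0.9]), threshold=0.7)
        assert len(regions) == 1
        assert regions[0].core_pos == 5 and regions[0].core_afd == 0.9

    def test_no_passing_snps_is_empty_not_error(self):
        assert detect_core_snps(_scan(["c"], [5], [0.1]), threshold=0.7) == []

    def test_threshold_is_strict(self):
        assert detect_core_snps(_scan(["c"], [5], [0.7]), threshold=0.7) == []

    def test_tie_breaks_to_smallest_position(self):
        regions = detect_core_snps(_scan(["c", "c"], [10, 20], [0.9, 0.9]),
                                   threshold=0.7)
        assert regions[0].core_pos == 10

    def test_matches_union_find_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = 40
            chrom = sorted(rng.choice(["c1", "c2"], size=n))
            pos = np.sort(rng.choice(np.arange(1, 500_000), n, replace=False))
            vals = rng.uniform(0, 1, n)
            regions = detect_core_snps(_scan(chrom, pos, vals),
                                       threshold=0.6, max_gap=30_000)
            # brute force: union-find over passing SNPs
            passing = [i for i in range(n) if vals[i] > 0.6]
            parent = {i: i for i in passing}

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i, j in itertools.combinations(passing, 2):
                if (chrom[i] == chrom[j]
                        and abs(int(pos[i]) - int(pos[j])) < 30_000):
                    parent[find(j)] = find(i)
            groups = {}
            for i in passing:
                groups.setdefault(find(i), []).append(i)
            expected = sorted(
                (chrom[g[0]], tuple(int(pos[i]) for i in g))
                for g in groups.values())
            got = sorted((r.chrom, tuple(int(p) for p in r.positions))
                         for r in regions)
            assert got == expected

    def test_quantile_flags_expected_fraction(self):
        rng = np.random.default_rng(12)
        n = 20_000
        pos = np.sort(rng.choice(np.arange(1, 10 ** 8), n, replace=False))
        vals = rng.uniform(0, 1, n)
        regions = detect_core_snps(_scan(["c"] * n, pos, vals),
                                   quantile=0.9995, max_gap=1)
        n_flagged = sum(len(r.positions) for r in regions)
        assert n_flagged / n == pytest.approx(0.0005, abs=2e-4)


class TestHudsonFst:
    def test_equal_frequencies_give_zero(self):
        assert hudson_fst(0.3, 0.3, 100, 100) == 0.0

    def test_fixation_limit_approaches_one(self):
        assert hudson_fst(1.0, 0.0, 10_000, 10_000) > 0.99

    def test_monomorphic_pair_is_zero_by_convention(self):
        assert hudson_fst(0.0, 0.0, 50, 50) == 0.0

    def test_matches_independent_textbook_formula(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            p1, p2 = rng.random(2)
            n1, n2 = rng.integers(2, 500, size=2)
            got = hudson_fst(p1, p2, n1, n2)
            # independently coded estimator: numerator/denominator form
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) \
                - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            exp = 0.0 if den == 0 else min(max(num / den, 0.0), 1.0)
            assert got == pytest.approx(exp)
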