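"""Windowed high-MAF SNP density, sweep contrasts, diversity tests."""

import itertools

import numpy as np
import pytest

from poolscan import (ConfigError, GenomeLayout, PopulationSpec,
                      correlate_bootstrap, habitat_diversity_test,
                      high_maf_count, pooled_pi, relative_density,
                      sweep_contrasts)
from poolscan.sweep import (SweepStatistic, median_label_permutation,
                            window_count_matrix)
from conftest import make_matrix, random_matrix


def maf_matrix(mafs, pops=None, spacing=100, layout=None):
    """One population; SNPs at given per-pop MAFs, depth 100."""
    pops = pops or [PopulationSpec("P1", "basic", 30)]
    layout = layout or GenomeLayout((("chrI", 100_000),))
    records = []
    for i, maf in enumerate(mafs):
        counts = [(int(100 * maf), 100 - int(100 * maf))] * len(pops)
        records.append(("chrI", spacing * (i + 1), f"L{i}", "A", "G", counts))
    return make_matrix(records, pops, layout)


class TestHighMafCount:
    def test_strict_threshold(self):
        m = maf_matrix([0.1, 0.25, 0.31, 0.4, 0.5])
        count = high_maf_count(m, "P1", ("chrI", 300, 100_000), 0.3)
        assert count == 3

    def test_empty_window_is_zero(self):
        m = maf_matrix([0.4])
        assert high_maf_count(m, "P1", ("chrI", 50_000, 100), 0.3) == 0

    def test_zero_depth_snp_not_counted(self):
        pops = [PopulationSpec("P1", "basic", 30)]
        m = make_matrix([("chrI", 10, "L0", "A", "G", [(0, 0)])],
                        pops, GenomeLayout((("chrI", 100),)))
        assert high_maf_count(m, "P1", ("chrI", 10, 100), 0.3) == 0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            m = random_matrix(rng, 40, layout=GenomeLayout((("chrI", 5000),)))
            center = int(rng.integers(1, 5000))
            width = int(rng.integers(100, 4000))
            thr = float(rng.uniform(0.05, 0.45))
            pop = m.pop_names[int(rng.integers(0, m.n_pops))]
            got = high_maf_count(m, pop, ("chrI", center, width), thr)
            lo, hi = max(1, center - width // 2), min(5000, center + width // 2)
            j = m.pop_index(pop)
            exp = 0
            for i in range(m.n_snps):
                if not (lo <= m.pos[i] <= hi):
                    continue
                d = m.depths()[i, j]
                if d == 0:
                    continue
                f = m.ref_counts[i, j] / d
                exp += min(f, 1 - f) > thr
            assert got == exp


class TestRelativeDensity:
    def test_all_counts_in_small_window_gives_one(self):
        m = maf_matrix([0.4, 0.45, 0.5], spacing=10)
        r = relative_density(m, ("chrI", 20), ["P1"], w_small=100,
                             w_large=10_000)
        assert r == 1.0

    def test_empty_small_window_gives_zero(self):
        m = maf_matrix([0.4], spacing=10_000)
        r = relative_density(m, ("chrI", 50_000), ["P1"], w_small=100,
                             w_large=100_000)
        assert r == 0.0

    def test_undefined_when_large_window_empty(self):
        m = maf_matrix([0.05])
        r = relative_density(m, ("chrI", 100), ["P1"])
        assert np.isnan(r)

    def test_invariant_to_duplicating_populations(self):
        pops2 = [PopulationSpec("P1", "basic", 30),
                 PopulationSpec("P2", "basic", 30)]
        mafs = [0.4, 0.1, 0.35, 0.5, 0.2]
        m1 = maf_matrix(mafs)
        m2 = maf_matrix(mafs, pops=pops2)
        r1 = relative_density(m1, ("chrI", 300), ["P1"], 200, 10_000)
        r2 = relative_density(m2, ("chrI", 300), ["P1", "P2"], 200, 10_000)
        assert r1 == pytest.approx(r2)

    def test_matches_bruteforce_ratio(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            m = random_matrix(rng, 40, layout=GenomeLayout((("chrI", 5000),)))
            center = int(rng.integers(1, 5000))
            got = relative_density(m, ("chrI", center), m.pop_names[:2],
                                   w_small=500, w_large=3000,
                                   maf_threshold=0.3)
            small = sum(high_maf_count(m, p, ("chrI", center, 500), 0.3)
                        for p in m.pop_names[:2])
            large = sum(high_maf_count(m, p, ("chrI", center, 3000), 0.3)
                        for p in m.pop_names[:2])
            if large == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(small / large)


class TestSweepContrasts:
    def _matrix(self, rng, acidic_small_monomorphic=False):
        pops = ([PopulationSpec(f"B{i}", "basic", 30) for i in range(1, 3)]
                + [PopulationSpec(f"A{i}", "acidic", 30) for i in range(1, 3)])
        layout = GenomeLayout((("chrI", 2_000_000),))
        records = []
        for i in range(200):
            pos = 10_000 * (i + 1)
            counts = []
            for p in pops:
                maf = rng.uniform(0.31, 0.5)
                near_focal = abs(pos - 1_000_000) <= 20_000
                if (acidic_small_monomorphic and p.habitat == "acidic"
                        and near_focal):
                    maf = 0.0
                counts.append((int(100 * maf), 100 - int(100 * maf)))
            records.append(("chrI", pos, f"L{i}", "A", "G", counts))
        return make_matrix(records, pops, layout)

    def test_identical_habitats_give_zero_delta(self):
        rng = np.random.default_rng(2)
        pops = ([PopulationSpec("B1", "basic", 30),
                 PopulationSpec("A1", "acidic", 30)])
        layout = GenomeLayout((("chrI", 2_000_000),))
        records = []
        for i in range(100):
            maf = rng.uniform(0.31, 0.5)
            c = (int(100 * maf), 100 - int(100 * maf))
            records.append(("chrI", 10_000 * (i + 1), f"L{i}", "A", "G",
                            [c, c]))
        m = make_matrix(records, pops, layout)
        stats = sweep_contrasts(m, [("chrI", 1_000_000)], ["B1"], ["A1"],
                                [0.3])
        assert stats[0].delta == pytest.approx(0.0)

    def test_reduced_acidic_small_window_diversity_gives_positive_delta(self):
        rng = np.random.default_rng(3)
        m = self._matrix(rng, acidic_small_monomorphic=True)
        stats = sweep_contrasts(m, [("chrI", 1_000_000)],
                                ["B1", "B2"], ["A1", "A2"], [0.2])
        assert stats[0].delta > 0


class TestCorrelateBootstrap:
    def _stats(self, deltas, freqs):
        return [SweepStatistic("c", i, 0, 0, d, f)
                for i, (d, f) in enumerate(zip(deltas, freqs))]

    def test_perfect_negative_relation(self):
        freqs = np.linspace(0.1, 0.9, 20)
        res = correlate_bootstrap(self._stats(-freqs, freqs), n_boot=200,
                                  seed=0)
        assert res.r == pytest.approx(-1.0)
        assert res.ci_low <= res.r <= res.ci_high

    def test_null_pairs_centre_on_zero(self):
        rng = np.random.default_rng(4)
        rs = []
        for _ in range(50):
            d, f = rng.normal(size=42), rng.uniform(0, 1, 42)
            rs.append(correlate_bootstrap(self._stats(d, f), n_boot=10,
                                          seed=0).r)
        assert abs(np.mean(rs)) < 2 / np.sqrt(42)

    def test_zero_variance_rejected(self):
        with pytest.raises(ConfigError):
            correlate_bootstrap(self._stats([1, 1, 1], [0.1, 0.5, 0.9]),
                                n_boot=10)


class TestPooledPi:
    def test_empty_window_is_zero(self):
        m = maf_matrix([0.4])
        assert pooled_pi(m, "P1", ("chrI", 50_000, 1000)) == 0.0

    def test_single_balanced_snp_large_depth_limit(self):
        pops = [PopulationSpec("P1", "basic", 30)]
        m = make_matrix([("chrI", 500, "L0", "A", "G", [(50_000, 50_000)])],
                        pops, GenomeLayout((("chrI", 100_000),)))
        pi = pooled_pi(m, "P1", ("chrI", 500, 998))
        assert pi == pytest.approx(0.5 / 999, rel=1e-3)

    def test_matches_bruteforce_recomputation(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            m = random_matrix(rng, 30, layout=GenomeLayout((("chrI", 5000),)))
            center = int(rng.integers(1, 5000))
            width = int(rng.integers(200, 4000))
            pop = m.pop_names[0]
            got = pooled_pi(m, pop, ("chrI", center, width))
            lo, hi = max(1, center - width // 2), min(5000, center + width // 2)
            j = m.pop_index(pop)
            acc = 0.0
            for i in range(m.n_snps):
                d = int(m.depths()[i, j])
                if lo <= m.pos[i] <= hi and d > 1:
                    p = m.ref_counts[i, j] / d
                    acc += d / (d - 1) * 2 * p * (1 - p)
            assert got == pytest.approx(acc / (hi - lo + 1))


class TestFootprintMonotonicity:
    def test_rarer_planted_allele_increases_mean_sweep_contrast(self):
        # three cohorts identical except for the ancestral frequency of the
        # acidic-favoured allele: rarer start -> wider footprint -> larger
        # basic-minus-acidic density contrast at planted loci
        from poolscan import CohortConfig, simulate_cohort
        deltas = []
        for lo, hi in ((0.06, 0.10), (0.22, 0.28), (0.38, 0.44)):
            cfg = CohortConfig(
                seed=99, n_neutral_snps=15_000, n_selected_loci=6,
                ancestral_acidic_freq_range=(lo, hi),
                layout=GenomeLayout((("chrI", 15_000_000),
                                     ("chrII", 15_000_000))))
            m, truth = simulate_cohort(cfg)
            sel = truth[truth["class"] == "selected_core"]
            focal = list(zip(sel["chrom"], sel["pos"]))
            stats = sweep_contrasts(
                m, focal, [f"B{i}" for i in range(1, 6)],
                [f"A{i}" for i in range(1, 6)],
                sel["p0"].tolist())
            deltas.append(np.mean([s.delta for s in stats]))
        assert deltas[0] > deltas[1] > deltas[2]


class TestHabitatDiversityTest:
    def test_identical_populations_give_p_one(self):
        pops = ([PopulationSpec(f"B{i}", "basic", 30) for i in range(1, 3)]
                + [PopulationSpec(f"A{i}", "acidic", 30) for i in range(1, 3)])
        m = maf_matrix([0.4] * 20, pops=pops)
        windows = [("chrI", 500, 400), ("chrI", 1500, 400)]
        res = habitat_diversity_test(m, windows, ["B1", "B2"], ["A1", "A2"],
                                     n_iter=99, seed=0)
        assert res.p_value == 1.0

    def test_exhaustive_five_plus_five_matches_enumeration(self):
        rng = np.random.default_rng(6)
        medians = rng.poisson(200, size=10).astype(float)
        res = median_label_permutation(medians, 5, exhaustive=True)
        obs = abs(np.median(medians[:5]) - np.median(medians[5:]))
        count = total = 0
        for combo in itertools.combinations(range(10), 5):
            rest = [i for i in range(10) if i not in combo]
            stat = abs(np.median(medians[list(combo)])
                       - np.median(medians[rest]))
            count += stat >= obs - 1e-12
            total += 1
        assert total == 252
        assert res.p_value == pytest.approx(count / total)
        assert res.n_iterations == 252

    def test_window_count_matrix_equals_per_window_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = random_matrix(rng, 40, layout=GenomeLayout((("chrI", 5000),)))
            windows = [("chrI", int(rng.integers(1, 5000)),
                        int(rng.integers(100, 3000))) for _ in range(5)]
            got = window_count_matrix(m, m.pop_names, windows, 0.3)
            exp = [[high_maf_count(m, p, w, 0.3) for p in m.pop_names]
                   for w in windows]
            assert np.array_equal(got, np.array(exp, dtype=float))

    def test_needs_two_populations_per_habitat(self):
        m = maf_matrix([0.4])
        with pytest.raises(ConfigError):
            habitat_diversity_test(m, [("chrI", 100, 50)], ["P1"], ["P1"])
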