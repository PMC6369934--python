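"""Windowed diversity statistics around focal SNPs: sweep detection.

Selective sweeps shift the site-frequency spectrum toward rare alleles, so
the density of *high-MAF* SNPs (per-population MAF > 0.3) is a sensitive,
depth-robust diversity measure.  Around each focal (core) SNP the count of
high-MAF SNPs in a small (40 kb) window, summed over the populations of a
habitat and divided by the analogous sum in a large (1 Mb) window, gives a
relative SNP density per habitat; the basic-minus-acidic contrast of these
densities measures which habitat swept harder at that locus, and its
correlation with the ancestral (marine) frequency of the acidic allele
tests whether rarer standing variants produced stronger sweeps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ConfigError, SNPMatrix
from .polarity import TestResult

logger = logging.getLogger("poolscan")


@dataclass
class SweepStatistic:
    chrom: str
    pos: int
    density_basic: float        # small-window / large-window high-MAF ratio
    density_acidic: float
    delta: float                # density_basic - density_acidic
    marine_acidic_freq: float


@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None = None


def _window_bounds(matrix: SNPMatrix, chrom: str, center: int,
                   width: int) -> tuple[int, int]:
    length = matrix.layout.length(chrom)
    lo = max(1, center - width // 2)
    hi = min(length, center + width // 2)
    return lo, hi


def high_maf_count(matrix: SNPMatrix, population: str,
                   window: tuple[str, int, int],
                   maf_threshold: float = 0.3) -> int:
    """Count SNPs with per-population MAF strictly above the threshold
    within the window (inclusive, clipped to chromosome bounds).

    SNPs with zero depth in the population are missing and not counted.
    """
    chrom, center, width = window
    lo, hi = _window_bounds(matrix, chrom, center, width)
    j = matrix.pop_index(population)
    mask = (matrix.chrom == chrom) & (matrix.pos >= lo) & (matrix.pos <= hi)
    f = matrix.freqs()[mask, j]
    maf = np.minimum(f, 1.0 - f)
    with np.errstate(invalid="ignore"):
        return int(np.sum(maf > maf_threshold))


def _counts_for_pops(matrix: SNPMatrix, pops: Sequence[str],
                     window: tuple[str, int, int],
                     maf_threshold: float) -> int:
    return sum(high_maf_count(matrix, p, window, maf_threshold) for p in pops)


def relative_density(matrix: SNPMatrix, focal: tuple[str, int],
                     habitat_pops: Sequence[str], w_small: int = 40_000,
                     w_large: int = 1_000_000,
                     maf_threshold: float = 0.3) -> float:
    """Relative high-MAF SNP density: small-window sum / large-window sum.

    Counts are summed over the habitat's populations; NaN when the
    large-window sum is zero.
    """
    if w_small > w_large:
        raise ConfigError("w_small must not exceed w_large")
    chrom, pos = focal
    small = _counts_for_pops(matrix, habitat_pops, (chrom, pos, w_small),
                             maf_threshold)
    large = _counts_for_pops(matrix, habitat_pops, (chrom, pos, w_large),
                             maf_threshold)
    return small / large if large > 0 else float("nan")


def sweep_contrasts(matrix: SNPMatrix, focal_snps: Sequence[tuple[str, int]],
                    basic_pops: Sequence[str], acidic_pops: Sequence[str],
                    marine_freqs: Sequence[float], w_small: int = 40_000,
                    w_large: int = 1_000_000,
                    maf_threshold: float = 0.3) -> list[SweepStatistic]:
    """One basic-minus-acidic relative-density contrast per focal SNP.

    Focal SNPs with an undefined density in either habitat are excluded
    and logged.
    """
    out: list[SweepStatistic] = []
    for (chrom, pos), mf in zip(focal_snps, marine_freqs):
        db = relative_density(matrix, (chrom, pos), basic_pops, w_small,
                              w_large, maf_threshold)
        da = relative_density(matrix, (chrom, pos), acidic_pops, w_small,
                              w_large, maf_threshold)
        if np.isnan(db) or np.isnan(da):
            logger.warning("sweep contrast undefined at %s:%d; excluded",
                           chrom, pos)
            continue
        out.append(SweepStatistic(chrom, int(pos), db, da, db - da,
                                  float(mf)))
    return out


def correlate_bootstrap(stats: Sequence[SweepStatistic], n_boot: int = 10_000,
                        seed: int | None = None) -> CorrelationResult:
    """Pearson correlation of delta vs marine acidic-allele frequency with
    a percentile 95% bootstrap CI over resampled SNPs."""
    x = np.array([s.delta for s in stats], dtype=float)
    y = np.array([s.marine_acidic_freq for s in stats], dtype=float)
    if x.size < 3:
        raise ConfigError("need >= 3 sweep statistics")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ConfigError("zero variance in delta or marine frequency")
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (xc * yc).sum(axis=1) / denom
    rs = rs[np.isfinite(rs)]
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return CorrelationResult(r, float(lo), float(hi), n_boot, seed)


def pooled_pi(matrix: SNPMatrix, population: str,
              window: tuple[str, int, int]) -> float:
    """Pooled nucleotide diversity per bp within a window.

    Sums ``depth/(depth-1) * 2*p*(1-p)`` over SNPs (the binomial
    sample-size correction for read-sampled frequencies) and divides by
    the clipped window length; SNPs at depth <= 1 are skipped, monomorphic
    positions contribute 0.  A comparison utility, sensitive to MAF
    pre-filtering in a way the high-MAF SNP density is not.
    """
    chrom, center, width = window
    lo, hi = _window_bounds(matrix, chrom, center, width)
    j = matrix.pop_index(population)
    mask = (matrix.chrom == chrom) & (matrix.pos >= lo) & (matrix.pos <= hi)
    depth = matrix.depths()[mask, j].astype(float)
    f = matrix.freqs()[mask, j]
    ok = depth > 1
    contrib = depth[ok] / (depth[ok] - 1.0) * 2.0 * f[ok] * (1.0 - f[ok])
    return float(contrib.sum() / (hi - lo + 1))


def window_count_matrix(matrix: SNPMatrix, pops: Sequence[str],
                        windows: Sequence[tuple[str, int, int]],
                        maf_threshold: float = 0.3) -> np.ndarray:
    """(n_windows, n_pops) high-MAF SNP counts; equals per-window
    :func:`high_maf_count` but shares one frequency pass over the matrix."""
    idx = [matrix.pop_index(p) for p in pops]
    f = matrix.freqs()[:, idx]
    with np.errstate(invalid="ignore"):
        ok = np.minimum(f, 1.0 - f) > maf_threshold
    counts = np.zeros((len(windows), len(pops)), dtype=float)
    for w, (chrom, center, width) in enumerate(windows):
        lo, hi = _window_bounds(matrix, chrom, center, width)
        mask = (matrix.chrom == chrom) & (matrix.pos >= lo) & (matrix.pos <= hi)
        counts[w] = ok[mask].sum(axis=0)
    return counts


def habitat_diversity_test(matrix: SNPMatrix,
                           windows: Sequence[tuple[str, int, int]],
                           basic_pops: Sequence[str],
                           acidic_pops: Sequence[str],
                           maf_threshold: float = 0.3, n_iter: int = 9999,
                           seed: int | None = None,
                           exhaustive: bool = False) -> TestResult:
    """Genome-wide habitat diversity contrast at control windows.

    Per population, the median high-MAF SNP count across the windows is
    taken as one data point; the statistic is the absolute difference of
    the basic and acidic medians of those population medians, and the null
    permutes habitat labels over populations.
    """
    if len(basic_pops) < 2 or len(acidic_pops) < 2:
        raise ConfigError("need >= 2 populations per habitat")
    pops = list(basic_pops) + list(acidic_pops)
    counts = window_count_matrix(matrix, pops, windows, maf_threshold)
    medians = np.median(counts, axis=0)          # one value per population
    return median_label_permutation(medians, len(basic_pops), n_iter=n_iter,
                                    seed=seed, exhaustive=exhaustive)


def median_label_permutation(values: Sequence[float], n_group_a: int,
                             n_iter: int = 9999, seed: int | None = None,
                             exhaustive: bool = False) -> TestResult:
    """|median(group A) - median(group B)| label-permutation test on
    per-population data points."""
    v = np.asarray(values, dtype=float)
    na, ntot = n_group_a, v.size
    obs = abs(float(np.median(v[:na])) - float(np.median(v[na:])))
    if exhaustive:
        count = total = 0
        for combo in itertools.combinations(range(ntot), na):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(combo)] = True
            stat = abs(float(np.median(v[mask])) - float(np.median(v[~mask])))
            count += stat >= obs - 1e-12
            total += 1
        return TestResult(obs, count / total, "permutation",
                          n_iterations=total, seed=seed)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_iter, ntot)), axis=1)
    perm = v[order]
    stat = np.abs(np.median(perm[:, :na], axis=1)
                  - np.median(perm[:, na:], axis=1))
    exceed = int(np.sum(stat >= obs - 1e-12))
    return TestResult(obs, (exceed + 1) / (n_iter + 1), "permutation",
                      n_iterations=n_iter, seed=seed)
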