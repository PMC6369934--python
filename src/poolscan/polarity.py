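"""Allele polarity at core SNPs and ancestral-asymmetry tests.

At each core SNP the two alleles are classified as "basic" or "acidic" by
their unweighted mean frequency across the populations of each habitat
(the allele averaging > 0.5 across basic pools is the basic allele, and
vice versa).  The frequency of the acidic allele in the combined marine
pool — the present-day proxy of the shared ancestor — then tests whether
adaptation to the ecologically more extreme acidic habitat recruited
alleles rare in the ancestor: an exact two-tailed binomial sign test on
the count of core SNPs whose acidic allele is the marine minor allele,
plus a two-tailed median-difference permutation test against matched
random control SNPs of median-level differentiation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import ConfigError, SNPMatrix
from .scan import CategoryScan

logger = logging.getLogger("poolscan")


@dataclass
class PolarizedCoreSNP:
    chrom: str
    pos: int
    basic_allele: str
    acidic_allele: str
    mean_basic_freq: float      # basic allele across basic pools
    mean_acidic_freq: float     # acidic allele across acidic pools
    marine_acidic_freq: float   # acidic allele in the combined marine pool
    marine_subsample_freqs: dict[str, float] | None = None


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str                 # "exact_binomial" or "permutation"
    n_iterations: int | None = None
    seed: int | None = None


def polarize(matrix: SNPMatrix, snps: Sequence[tuple[str, int]]
             ) -> list[PolarizedCoreSNP]:
    """Assign basic/acidic allele labels at the given sites.

    The basic allele is defined by the basic-habitat mean alone; the acidic
    label goes to the complementary allele (a warning is raised if that
    allele's acidic-habitat mean is <= 0.5).  Sites whose means are exactly
    0.5 in both habitats are unpolarizable and excluded with a warning.
    Labels are invariant to which allele is stored as ref.
    """
    basic = matrix.pops_by_habitat("basic")
    acidic = matrix.pops_by_habitat("acidic")
    marine = matrix.pops_by_habitat("marine")
    if not basic or not acidic:
        raise ConfigError("polarization needs >= 1 population per habitat")
    lut = matrix.site_lookup()
    freqs = matrix.freqs()
    b_idx = [matrix.pop_index(n) for n in basic]
    a_idx = [matrix.pop_index(n) for n in acidic]
    out: list[PolarizedCoreSNP] = []
    for chrom, pos in snps:
        try:
            i = lut[(chrom, int(pos))]
        except KeyError:
            raise ConfigError(f"SNP {chrom}:{pos} not in matrix") from None
        b_mean = float(np.nanmean(freqs[i, b_idx]))  # ref-allele mean
        a_mean = float(np.nanmean(freqs[i, a_idx]))
        if b_mean > 0.5:
            basic_allele, acidic_allele = matrix.ref[i], matrix.alt[i]
        elif b_mean < 0.5:
            basic_allele, acidic_allele = matrix.alt[i], matrix.ref[i]
        elif a_mean > 0.5:       # basic means tied; acidic habitat decides
            basic_allele, acidic_allele = matrix.alt[i], matrix.ref[i]
        elif a_mean < 0.5:
            basic_allele, acidic_allele = matrix.ref[i], matrix.alt[i]
        else:
            logger.warning("SNP %s:%d unpolarizable (both habitat means 0.5); "
                           "excluded", chrom, pos)
            continue
        acid_is_ref = acidic_allele == matrix.ref[i]
        mean_basic = b_mean if basic_allele == matrix.ref[i] else 1.0 - b_mean
        mean_acidic = a_mean if acid_is_ref else 1.0 - a_mean
        if mean_acidic <= 0.5:
            logger.warning("SNP %s:%d: acidic allele not predominant in "
                           "acidic pools (mean %.3f)", chrom, pos, mean_acidic)
        if marine:
            mi = [matrix.pop_index(n) for n in marine]
            r = matrix.ref_counts[i, mi].sum()
            d = r + matrix.alt_counts[i, mi].sum()
            marine_ref = r / d if d > 0 else math.nan
            marine_acidic = marine_ref if acid_is_ref else 1.0 - marine_ref
            subs = {}
            for n in marine:
                j = matrix.pop_index(n)
                dj = matrix.ref_counts[i, j] + matrix.alt_counts[i, j]
                fj = matrix.ref_counts[i, j] / dj if dj > 0 else math.nan
                subs[n] = fj if acid_is_ref else 1.0 - fj
        else:
            marine_acidic, subs = math.nan, None
        out.append(PolarizedCoreSNP(chrom, int(pos), str(basic_allele),
                                    str(acidic_allele), mean_basic,
                                    mean_acidic, marine_acidic, subs))
    return out


def marine_minor_count(polarized: Sequence[PolarizedCoreSNP]) -> tuple[int, int]:
    """(k, n): k = SNPs whose acidic allele is the marine minor allele.

    A frequency of exactly 0.5 counts as not-minor; n is the list length.
    """
    if not polarized:
        raise ConfigError("no polarized SNPs")
    k = sum(1 for p in polarized if p.marine_acidic_freq < 0.5)
    return k, len(polarized)


def sign_binomial_test(k: int, n: int) -> TestResult:
    """Exact two-tailed binomial sign test of k successes in n at P = 1/2.

    p = min(1, 2 * P(X >= max(k, n-k))) — the probability of an asymmetry
    of this magnitude or greater in either direction.
    """
    if n <= 0:
        raise ConfigError("sign test needs n > 0")
    if not 0 <= k <= n:
        raise ConfigError("k must lie in [0, n]")
    m = max(k, n - k)
    p = min(1.0, 2.0 * float(stats.binom.sf(m - 1, n, 0.5)))
    return TestResult(statistic=float(k), p_value=p, method="exact_binomial")


def select_random_controls(scan: CategoryScan, n: int,
                           tolerance: float = 0.005, seed: int | None = None,
                           absolute: bool = False) -> list[tuple[str, int]]:
    """Sample n SNPs with near-median integrated AFD (matched controls).

    Eligible SNPs have mean AFD within `tolerance` of the genome-wide
    median — relative (median * (1 +/- tol)) by default, or an absolute
    +/- tol window with ``absolute=True``.  Sampling is without replacement
    and deterministic under `seed`.
    """
    vals = scan.mean_afd
    valid = ~np.isnan(vals)
    med = float(np.median(vals[valid]))
    if absolute:
        lo, hi = med - tolerance, med + tolerance
    else:
        lo, hi = med * (1.0 - tolerance), med * (1.0 + tolerance)
    eligible = np.flatnonzero(valid & (vals >= lo) & (vals <= hi))
    if eligible.size < n:
        raise ConfigError(
            f"only {eligible.size} SNPs within the AFD window "
            f"[{lo:.4g}, {hi:.4g}]; {n} requested")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n, replace=False))
    return [(str(scan.chrom[i]), int(scan.pos[i])) for i in chosen]


def median_permutation_test(freqs_a: Sequence[float], freqs_b: Sequence[float],
                            n_iter: int = 9999, seed: int | None = None,
                            exhaustive: bool = False) -> TestResult:
    """Two-tailed permutation test on |median(a) - median(b)|.

    The null is built by relabelling the pooled values at the original
    group sizes; p = (b + 1) / (m + 1) with the +1 correction, or the exact
    enumeration fraction when ``exhaustive=True``.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    na, ntot = a.size, a.size + b.size
    obs = abs(float(np.median(a)) - float(np.median(b)))
    if exhaustive:
        count = 0
        total = 0
        for combo in itertools.combinations(range(ntot), na):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(combo)] = True
            stat = abs(float(np.median(pooled[mask]))
                       - float(np.median(pooled[~mask])))
            count += stat >= obs - 1e-12
            total += 1
        return TestResult(obs, count / total, "permutation",
                          n_iterations=total, seed=seed)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_iter, ntot)), axis=1)
    perm = pooled[order]
    stat = np.abs(np.median(perm[:, :na], axis=1)
                  - np.median(perm[:, na:], axis=1))
    exceed = int(np.sum(stat >= obs - 1e-12))
    return TestResult(obs, (exceed + 1) / (n_iter + 1), "permutation",
                      n_iterations=n_iter, seed=seed)
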