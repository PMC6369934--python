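"""Pairwise AFD genome scans, category integration and core-SNP detection.

Population differentiation at a biallelic SNP is quantified by the absolute
allele frequency difference AFD = |p_i - p_j|, computed for every
population pair whose pools both meet a per-population depth threshold.
Pair-level AFD values are then integrated (unweighted mean) within
comparison categories — basic-acidic (BA), basic-basic (BB), acidic-acidic
(AA) and marine-freshwater (MF) — provided enough pairs contribute.
Regions of exceptional, *parallel* BA differentiation are found by chaining
SNPs above an AFD threshold (or empirical quantile) into regions separated
by at least ``max_gap`` bp; the strongest SNP of each region is its "core
SNP".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfigError, SNPMatrix

logger = logging.getLogger("poolscan")

#: minimum number of contributing pairs per category (25 BA / 10 BB / 10 AA
#: pairs exist for a 5+5 design; MF pairs one marine pool against each lake)
CATEGORY_MIN_PAIRS = {"BA": 18, "BB": 8, "AA": 8, "MF": 8}


def afd(p1: float | np.ndarray, p2: float | np.ndarray) -> float | np.ndarray:
    """Absolute allele frequency difference; NaN propagates as missing.

    Invariant to which of the two alleles (ref or alt) is tracked:
    |p1 - p2| = |(1-p1) - (1-p2)|.
    """
    return np.abs(np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float))


def _pair_category(h1: str, h2: str) -> str:
    if "marine" in (h1, h2):
        return "MF"
    if h1 == h2:
        return "BB" if h1 == "basic" else "AA"
    return "BA"


@dataclass
class PairwiseAFDTable:
    """Per-SNP AFD (and optionally Hudson F_ST) for population pairs."""

    chrom: np.ndarray
    pos: np.ndarray
    pairs: list[tuple[str, str]]
    categories: list[str]              # per pair: BA / BB / AA / MF
    afd: np.ndarray                    # (n_snps, n_pairs), NaN = missing
    fst: np.ndarray | None = None

    def pair_columns(self, category: str) -> np.ndarray:
        cols = [j for j, c in enumerate(self.categories) if c == category]
        if not cols:
            raise ConfigError(f"no pairs in category {category!r}")
        return np.array(cols)


@dataclass
class CategoryScan:
    """Integrated (mean) AFD per SNP for one comparison category."""

    category: str
    chrom: np.ndarray
    pos: np.ndarray
    mean_afd: np.ndarray               # NaN where < min_pairs contributed
    n_pairs: np.ndarray

    def valid(self) -> np.ndarray:
        return ~np.isnan(self.mean_afd)


@dataclass
class CoreRegion:
    """A chained run of high-differentiation SNPs on one chromosome."""

    chrom: str
    positions: np.ndarray              # member SNPs, ascending
    afds: np.ndarray
    core_pos: int = field(init=False)
    core_afd: float = field(init=False)

    def __post_init__(self) -> None:
        i = int(np.argmax(self.afds))   # first max -> smallest position on ties
        self.core_pos = int(self.positions[i])
        self.core_afd = float(self.afds[i])

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])


def hudson_fst(p1, p2, depth1, depth2):
    """Hudson-style F_ST from pooled frequencies with sample-size correction.

    Reported alongside AFD for parity with standard summaries; clipped to
    [0, 1], with monomorphic pairs returning 0 by convention.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(depth1, dtype=float)
    n2 = np.asarray(depth2, dtype=float)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ConfigError("hudson_fst requires depths > 1")
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(out, 0.0, 1.0)


def pairwise_scan(matrix: SNPMatrix, min_depth_per_pop: int = 50,
                  populations: Sequence[str] | None = None,
                  pairs: Sequence[tuple[str, str]] | None = None,
                  compute_fst: bool = False) -> PairwiseAFDTable:
    """AFD for every unordered population pair at every adequately covered SNP.

    By default enumerates all pairs among the freshwater (basic + acidic)
    populations: a 5+5 design yields 25 BA, 10 BB and 10 AA pairs.  A SNP
    is missing for a pair when either pool is below `min_depth_per_pop`.
    """
    if populations is None:
        populations = (matrix.pops_by_habitat("basic")
                       + matrix.pops_by_habitat("acidic"))
    if pairs is None:
        pairs = list(itertools.combinations(populations, 2))
    if not pairs:
        raise ConfigError("pairwise scan needs at least two populations")
    habitat = {p.name: p.habitat for p in matrix.populations}
    categories = [_pair_category(habitat[a], habitat[b]) for a, b in pairs]
    freq = matrix.freqs()
    depth = matrix.depths()
    ok = depth >= min_depth_per_pop
    f = np.where(ok, freq, np.nan)
    cols = np.empty((matrix.n_snps, len(pairs)))
    fst_cols = np.empty_like(cols) if compute_fst else None
    for j, (a, b) in enumerate(pairs):
        ia, ib = matrix.pop_index(a), matrix.pop_index(b)
        cols[:, j] = afd(f[:, ia], f[:, ib])
        if compute_fst:
            with np.errstate(invalid="ignore", divide="ignore"):
                d1 = np.where(ok[:, ia], depth[:, ia], np.nan)
                d2 = np.where(ok[:, ib], depth[:, ib], np.nan)
                num = ((f[:, ia] - f[:, ib]) ** 2
                       - f[:, ia] * (1 - f[:, ia]) / (d1 - 1)
                       - f[:, ib] * (1 - f[:, ib]) / (d2 - 1))
                den = f[:, ia] * (1 - f[:, ib]) + f[:, ib] * (1 - f[:, ia])
                fst_cols[:, j] = np.where(den > 0, np.clip(num / den, 0, 1),
                                          np.where(np.isnan(den), np.nan, 0.0))
    return PairwiseAFDTable(matrix.chrom.copy(), matrix.pos.copy(),
                            list(pairs), categories, cols, fst_cols)


def marine_freshwater_scan(matrix: SNPMatrix, marine_name: str,
                           min_depth_per_pop: int = 50) -> PairwiseAFDTable:
    """All lake populations each paired against the (combined) marine pool."""
    lakes = matrix.pops_by_habitat("basic") + matrix.pops_by_habitat("acidic")
    pairs = [(lake, marine_name) for lake in lakes]
    return pairwise_scan(matrix, min_depth_per_pop,
                         populations=lakes + [marine_name], pairs=pairs)


def integrate_category(table: PairwiseAFDTable, category: str,
                       min_pairs: int | None = None) -> CategoryScan:
    """Unweighted mean of available pair AFDs per SNP within one category.

    The mean is missing (NaN) wherever fewer than `min_pairs` pairs
    contribute (defaults: 18 for BA, 8 for BB/AA/MF).
    """
    if min_pairs is None:
        min_pairs = CATEGORY_MIN_PAIRS[category]
    cols = table.pair_columns(category)
    sub = table.afd[:, cols]
    n = np.sum(~np.isnan(sub), axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.where(n >= max(min_pairs, 1),
                        np.nansum(sub, axis=1) / np.maximum(n, 1),
                        np.nan)
    return CategoryScan(category, table.chrom, table.pos, mean, n)


def standardize_pairs(table: PairwiseAFDTable) -> PairwiseAFDTable:
    """Divide each pair's AFD values by that pair's genome-wide mean AFD.

    A robustness variant: adjusts each comparison by its overall level of
    differentiation so that no single strongly diverged pair dominates the
    category mean.
    """
    means = np.nanmean(table.afd, axis=0)
    if np.any(np.isnan(means)) or np.any(means == 0):
        raise ConfigError("standardization requires a non-zero mean AFD "
                          "for every pair")
    return PairwiseAFDTable(table.chrom, table.pos, list(table.pairs),
                            list(table.categories), table.afd / means,
                            table.fst)


def detect_core_snps(scan: CategoryScan, threshold: float | None = None,
                     quantile: float | None = None,
                     max_gap: int = 50_000) -> list[CoreRegion]:
    """Chain SNPs above an AFD threshold into independent genome regions.

    SNPs with mean AFD strictly above `threshold` (or above the empirical
    `quantile`, linear interpolation) are single-linkage chained per
    chromosome; two high-AFD SNPs separated by at least `max_gap` bp belong
    to independent regions.  Each region's core SNP is its maximal-AFD
    member (ties broken toward the smallest position).
    """
    if (threshold is None) == (quantile is None):
        raise ConfigError("give exactly one of threshold / quantile")
    vals = scan.mean_afd
    if quantile is not None:
        valid = vals[~np.isnan(vals)]
        if valid.size == 0:
            return []
        threshold = float(np.quantile(valid, quantile))
    with np.errstate(invalid="ignore"):
        passing = vals > threshold
    regions: list[CoreRegion] = []
    for c in dict.fromkeys(scan.chrom.tolist()):
        mask = passing & (scan.chrom == c)
        pos = scan.pos[mask]
        av = vals[mask]
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= max_gap) + 1
        for seg_pos, seg_afd in zip(np.split(pos, breaks), np.split(av, breaks)):
            regions.append(CoreRegion(c, seg_pos, seg_afd))
    logger.info("core-SNP detection (> %.3g, gap %d bp): %d regions",
                threshold, max_gap, len(regions))
    return regions


def core_positions(regions: Sequence[CoreRegion]) -> list[tuple[str, int]]:
    return [(r.chrom, r.core_pos) for r in regions]


def regions_to_bed(regions: Sequence[CoreRegion]) -> str:
    """BED (0-based half-open) text for detected regions."""
    lines = [f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.core_pos}\t{r.core_afd:.4f}"
             for r in regions]
    return "\n".join(lines) + ("\n" if lines else "")
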