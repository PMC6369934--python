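"""SNP ascertainment filters.

All filters take and return an :class:`~poolscan.core.SNPMatrix`, are
idempotent, keep the output sorted, and never increase the SNP count.
Default thresholds mirror the marker-generation protocol: total coverage
150-2800 over the global freshwater pool, pooled MAF strictly above 0.05,
and at least 12 bp to the nearest polymorphism.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import numpy as np

from .core import ConfigError, SNPMatrix

logger = logging.getLogger("poolscan")


def filter_coverage(matrix: SNPMatrix, scope: Sequence[str],
                    min_total: int, max_total: float) -> SNPMatrix:
    """Keep SNPs whose summed read depth over `scope` lies in [min, max]."""
    if not scope:
        raise ConfigError("coverage filter needs a non-empty population scope")
    if min_total > max_total:
        raise ConfigError("min_total must not exceed max_total")
    idx = [matrix.pop_index(n) for n in scope]
    total = matrix.depths()[:, idx].sum(axis=1)
    keep = (total >= min_total) & (total <= max_total)
    logger.info("coverage filter [%s, %s]: %d -> %d SNPs",
                min_total, max_total, matrix.n_snps, int(keep.sum()))
    return matrix.subset(keep)


def filter_maf(matrix: SNPMatrix, scope: Sequence[str],
               min_maf: float) -> SNPMatrix:
    """Keep SNPs with pooled minor-allele frequency strictly above `min_maf`."""
    if not scope:
        raise ConfigError("MAF filter needs a non-empty population scope")
    if not 0.0 <= min_maf < 0.5:
        raise ConfigError("min_maf must lie in [0, 0.5)")
    maf = matrix.maf(scope)
    keep = maf > min_maf  # strict: "superior to" the threshold
    keep &= ~np.isnan(maf)
    logger.info("MAF filter > %.3g: %d -> %d SNPs",
                min_maf, matrix.n_snps, int(keep.sum()))
    return matrix.subset(keep)


def filter_spacing(matrix: SNPMatrix, min_gap: int) -> SNPMatrix:
    """Remove every SNP closer than `min_gap` bp to its nearest neighbour.

    Both members of a too-close pair are removed — the only reading of a
    per-SNP eligibility rule that is independent of scan order.  A distance
    of exactly `min_gap` satisfies the rule.
    """
    keep = np.ones(matrix.n_snps, dtype=bool)
    for c in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.flatnonzero(matrix.chrom == c)
        if len(idx) < 2:
            continue
        pos = matrix.pos[idx]
        gaps = np.diff(pos)
        close = gaps < min_gap
        keep[idx[:-1][close]] = False
        keep[idx[1:][close]] = False
    logger.info("spacing filter >= %d bp: %d -> %d SNPs",
                min_gap, matrix.n_snps, int(keep.sum()))
    return matrix.subset(keep)


def select_loner_snps(matrix: SNPMatrix) -> SNPMatrix:
    """Keep SNPs that are the only polymorphism on their RAD locus."""
    if any(l is None or l == "" for l in matrix.locus_id):
        raise ConfigError("loner selection requires populated locus_ids")
    counts = Counter(matrix.locus_id.tolist())
    keep = np.array([counts[l] == 1 for l in matrix.locus_id])
    logger.info("loner filter: %d -> %d SNPs", matrix.n_snps, int(keep.sum()))
    return matrix.subset(keep)


def select_phylogeny_snps(matrix: SNPMatrix, scan_ba, scan_mf,
                          min_pool_cov: int = 40, max_afd: float = 0.5,
                          tip_window: int = 5_000_000) -> SNPMatrix:
    """Select loner SNPs suitable for phylogeny / ordination input.

    Keeps loner SNPs with depth >= `min_pool_cov` in *every* pool, not
    showing AFD above `max_afd` in both the basic-acidic and the
    marine-freshwater scans (high differentiation in both marks likely
    selection targets), and lying within `tip_window` bp of a chromosome
    tip (the high-recombination chromosome peripheries).
    """
    if matrix.layout is None:
        raise ConfigError("phylogeny SNP selection requires a genome layout")
    m = select_loner_snps(matrix)
    depth_ok = (m.depths() >= min_pool_cov).all(axis=1)

    def _afd_for(scan) -> np.ndarray:
        lut = {(c, int(p)): v for c, p, v in
               zip(scan.chrom, scan.pos, scan.mean_afd)}
        return np.array([lut.get((c, int(p)), np.nan)
                         for c, p in zip(m.chrom, m.pos)])

    afd_ba = _afd_for(scan_ba)
    afd_mf = _afd_for(scan_mf)
    with np.errstate(invalid="ignore"):
        selected_like = (afd_ba > max_afd) & (afd_mf > max_afd)
    lengths = np.array([m.layout.length(c) for c in m.chrom])
    tip_dist = np.minimum(m.pos - 1, lengths - m.pos)
    near_tip = tip_dist <= tip_window
    keep = depth_ok & ~selected_like & near_tip
    logger.info("phylogeny SNP filter: %d -> %d SNPs",
                matrix.n_snps, int(keep.sum()))
    return m.subset(keep)


def thin_by_distance(matrix: SNPMatrix, min_gap: int) -> SNPMatrix:
    """Greedy left-to-right thinning: keep a SNP iff >= `min_gap` bp from
    the last kept SNP on the same chromosome."""
    keep = np.zeros(matrix.n_snps, dtype=bool)
    last: dict[str, int] = {}
    for i, (c, p) in enumerate(zip(matrix.chrom, matrix.pos)):
        if c not in last or p - last[c] >= min_gap:
            keep[i] = True
            last[c] = p
    logger.info("distance thinning >= %d bp: %d -> %d SNPs",
                min_gap, matrix.n_snps, int(keep.sum()))
    return matrix.subset(keep)
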