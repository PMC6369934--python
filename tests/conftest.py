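"""Shared fixtures: hand-built and random SNP matrices."""

from __future__ import annotations

import numpy as np
import pytest

from poolscan import GenomeLayout, PopulationSpec, SNPMatrix


def make_matrix(records, populations, layout):
    """Build an SNPMatrix from (chrom, pos, locus, ref, alt, [(r, a), ...])."""
    chrom = [r[0] for r in records]
    pos = [r[1] for r in records]
    locus = [r[2] for r in records]
    ref = [r[3] for r in records]
    alt = [r[4] for r in records]
    rc = [[pair[0] for pair in r[5]] for r in records]
    ac = [[pair[1] for pair in r[5]] for r in records]
    return SNPMatrix(list(populations), layout,
                     np.array(chrom, dtype=object), np.array(pos),
                     np.array(locus, dtype=object),
                     np.array(ref, dtype=object), np.array(alt, dtype=object),
                     np.array(rc), np.array(ac))


def random_matrix(rng, n_snps=50, populations=None, layout=None,
                  max_count=60, chroms=("chrI", "chrII")):
    """A random biallelic matrix with distinct positions, for oracle tests."""
    if layout is None:
        layout = GenomeLayout(tuple((c, 1_000_000) for c in chroms))
    if populations is None:
        populations = [PopulationSpec("B1", "basic", 30),
                       PopulationSpec("B2", "basic", 30),
                       PopulationSpec("A1", "acidic", 30),
                       PopulationSpec("A2", "acidic", 30)]
    k = len(populations)
    names = [c for c, _ in layout.chromosomes]
    chrom = rng.choice(names, size=n_snps)
    pos = np.zeros(n_snps, dtype=np.int64)
    for c in names:
        m = chrom == c
        pos[m] = rng.choice(np.arange(1, layout.length(c) + 1),
                            size=int(m.sum()), replace=False)
    nts = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    locus = np.array([f"L{rng.integers(0, max(2, n_snps))}"
                      for _ in range(n_snps)], dtype=object)
    return SNPMatrix(list(populations), layout,
                     chrom.astype(object), pos, locus,
                     nts[ref_i], nts[alt_i],
                     rng.integers(0, max_count, size=(n_snps, k)),
                     rng.integers(0, max_count, size=(n_snps, k)))


@pytest.fixture
def layout2():
    return GenomeLayout((("chrI", 1_000_000), ("chrII", 1_000_000)))


@pytest.fixture
def two_pops():
    return [PopulationSpec("P1", "basic", 30), PopulationSpec("P2", "acidic", 30)]


@pytest.fixture
def small_matrix(layout2, two_pops):
    """Three SNPs, two populations."""
    return make_matrix(
        [("chrI", 100, "L1", "A", "G", [(10, 0), (0, 12)]),
         ("chrI", 500, "L2", "C", "T", [(5, 5), (10, 0)]),
         ("chrII", 42, "L3", "G", "A", [(30, 30), (15, 45)])],
        two_pops, layout2)


@pytest.fixture
def ten_pop_specs():
    pops = [PopulationSpec(f"B{i}", "basic", 30) for i in range(1, 6)]
    pops += [PopulationSpec(f"A{i}", "acidic", 30) for i in range(1, 6)]
    return pops
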