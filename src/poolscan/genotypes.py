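"""Individual-like inputs from pooled frequencies.

Pool-seq yields allele frequencies but no genotypes, so population-level
phylogeny and ordination inputs are synthesised: (i) diploid multilocus
genotypes drawn without replacement from a reconstructed finite allele
pool, concatenated as IUPAC characters and exportable as FASTA; (ii) a
binary population dissimilarity matrix from one randomly sampled allele
per population per SNP (1 = global major allele), feeding (iii) a
neighbour-joining tree and (iv) non-metric multidimensional scaling
(Kruskal stress-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj
from sklearn.manifold import smacof

from .core import ConfigError, SNPMatrix

logger = logging.getLogger("poolscan")

#: canonical two-base ambiguity codes for heterozygous sites
IUPAC_HET = {frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
             frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M"}


@dataclass
class SyntheticIndividual:
    population: str
    name: str
    sequence: str                # one IUPAC character per SNP, fixed order


@dataclass
class PopulationDistanceMatrix:
    names: list[str]
    matrix: np.ndarray           # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names), len(self.names)):
            raise ConfigError("distance matrix shape mismatch")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ConfigError("distance matrix must be symmetric with "
                              "zero diagonal")
        self.matrix = m


def _iupac(b1: str, b2: str) -> str:
    if b1 == b2:
        return b1
    return IUPAC_HET[frozenset((b1, b2))]


def synthesize_genotypes(matrix: SNPMatrix, snps: Sequence[tuple[str, int]],
                         n_individuals: int, seed: int | None = None
                         ) -> list[SyntheticIndividual]:
    """Draw synthetic diploid genotypes from each population pool.

    Per population and SNP the discrete allele pool of size 2*pool_size is
    reconstructed by rounding ref_freq * 2 * pool_size to the nearest
    integer (ties up); two alleles per individual are then drawn without
    replacement, with all individuals of a population drawing from the
    same pool at a SNP (no replenishment between individuals).
    """
    lut = matrix.site_lookup()
    try:
        idx = [lut[(c, int(p))] for c, p in snps]
    except KeyError as exc:
        raise ConfigError(f"SNP {exc.args[0]} not in matrix") from None
    depths = matrix.depths()
    freqs = matrix.freqs()
    if np.any(depths[idx] == 0):
        raise ConfigError("every SNP must have depth > 0 in each population")
    rng = np.random.default_rng(seed)
    out: list[SyntheticIndividual] = []
    for j, spec in enumerate(matrix.populations):
        two_n = 2 * spec.pool_size
        if 2 * n_individuals > two_n:
            raise ConfigError(
                f"pool exhausted: {n_individuals} diploids need "
                f"{2 * n_individuals} alleles but {spec.name} holds {two_n}")
        chars = np.empty((n_individuals, len(idx)), dtype=object)
        for s, i in enumerate(idx):
            n_ref = int(np.floor(freqs[i, j] * two_n + 0.5))  # ties round up
            pool = np.array([matrix.ref[i]] * n_ref
                            + [matrix.alt[i]] * (two_n - n_ref), dtype=object)
            draw = rng.permutation(pool)[:2 * n_individuals]
            for ind in range(n_individuals):
                chars[ind, s] = _iupac(draw[2 * ind], draw[2 * ind + 1])
        for ind in range(n_individuals):
            out.append(SyntheticIndividual(
                spec.name, f"{spec.name}_{ind + 1}",
                "".join(chars[ind])))
    return out


def write_fasta(individuals: Sequence[SyntheticIndividual],
                path: str | Path) -> None:
    records = [SeqRecord(Seq(ind.sequence), id=ind.name, description="")
               for ind in individuals]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[SyntheticIndividual]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        pop = rec.id.rsplit("_", 1)[0]
        out.append(SyntheticIndividual(pop, rec.id, str(rec.seq)))
    return out


def binary_similarity(matrix: SNPMatrix, snps: Sequence[tuple[str, int]],
                      scope_for_major: Sequence[str],
                      seed: int | None = None) -> PopulationDistanceMatrix:
    """Binary population dissimilarity from single sampled alleles.

    Per SNP the major allele is identified over `scope_for_major` (the
    global freshwater pool); one allele is then sampled per population
    (probability = its pool frequency) and coded 1 (major) / 0 (minor).
    The distance between two populations is the Euclidean distance between
    their 0/1 vectors (the square root of the mismatch count), which is
    invariant to relabelling ref/alt.
    """
    lut = matrix.site_lookup()
    idx = []
    for c, p in snps:
        if (c, int(p)) not in lut:
            raise ConfigError(f"SNP {c}:{p} not in matrix")
        idx.append(lut[(c, int(p))])
    idx = np.array(idx, dtype=int)
    pooled = matrix.pooled_freq(scope_for_major)[idx]      # ref freq in scope
    freqs = matrix.freqs()[idx]                            # ref freq per pop
    defined = ~np.isnan(freqs).any(axis=1) & ~np.isnan(pooled)
    if not defined.all():
        logger.warning("binary_similarity: skipping %d SNPs with undefined "
                       "frequencies", int((~defined).sum()))
    major_is_ref = pooled[defined] >= 0.5
    p_major = np.where(major_is_ref[:, None], freqs[defined],
                       1.0 - freqs[defined])
    rng = np.random.default_rng(seed)
    codes = (rng.random(p_major.shape) < p_major).astype(int)
    diff = codes[:, :, None] != codes[:, None, :]
    dist = np.sqrt(diff.sum(axis=0).astype(float))
    return PopulationDistanceMatrix(matrix.pop_names, dist)


def nj_tree(dist: PopulationDistanceMatrix) -> str:
    """Neighbour-joining tree (Newick, with branch lengths).

    Standard NJ agglomeration, deterministic given the matrix; requires at
    least three populations.
    """
    if len(dist.names) < 3:
        raise ConfigError("NJ needs at least 3 populations")
    dm = DistanceMatrix(dist.matrix, ids=dist.names)
    tree = nj(dm)
    return str(tree).strip()


def classical_mds(dist: np.ndarray, n_dims: int) -> np.ndarray:
    """Torgerson/Gower principal-coordinates embedding (used as NMDS init)."""
    d2 = np.asarray(dist, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:n_dims]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)


def ordinate(dist: PopulationDistanceMatrix, n_dims: int = 2,
             seed: int | None = None, max_iter: int = 1000,
             eps: float = 1e-9) -> tuple[np.ndarray, float]:
    """Non-metric MDS (Kruskal stress-1 minimisation).

    Initialised from the classical-MDS embedding and refined with the
    SMACOF algorithm; returns (coordinates, final stress-1), deterministic
    under `seed`.
    """
    d = dist.matrix
    if np.allclose(d, 0):
        raise ConfigError("degenerate all-zero distance matrix")
    if len(dist.names) < n_dims + 1:
        raise ConfigError("need more populations than ordination dimensions")
    init = classical_mds(d, n_dims)
    coords, stress = smacof(
        d, metric=False, n_components=n_dims, init=init, n_init=1,
        max_iter=max_iter, eps=eps, random_state=seed,
        normalized_stress=True)
    return coords, float(stress)
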