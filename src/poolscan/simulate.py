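"""Synthetic cohort simulator: parallel adaptation from standing variation.

Emulates the study system: one large marine ancestor population and ten
independently founded freshwater lake populations (five basic, five acidic)
that diverged from it by drift and by divergent selection on standing
variation.  The marine pool keeps the ancestral allele frequencies (the
ancestor-proxy assumption made explicit); each lake experiences a founder
bottleneck, Wright-Fisher drift, deterministic selection endpoints at
planted loci, and hitchhiking ("sweep footprint") at physically linked
SNPs.  Pooled sequencing is then emulated by sampling read depths and
allele counts per SNP and pool.

The sweep footprint model
-------------------------
At a selected locus the habitat-favoured allele rises from its ancestral
frequency ``p0`` toward ``selected_target_freq``.  A linked SNP at distance
``d`` has a fraction

    h(d, p0) = exp(-d / lambda(p0)),   lambda(p0) = lambda0 * ln(1/p0) / ln 4

of the population's lineages descending from the founding swept haplotype,
so its post-sweep frequency is ``(1-h) * p_drift + h * x`` where ``x`` is
the allele carried on that haplotype background.  ``lambda`` equals
``lambda0`` at p0 = 0.25 and grows as the selected allele starts rarer:
rarer standing variants produce wider, stronger footprints.  The background
alleles (one on the acidic-allele haplotype, one on the basic one) are
drawn once in the *ancestor* and therefore shared by all populations of a
habitat — parallel adaptation reuses the same ancestral haplotype, which is
what makes linked SNPs near selected loci differentiate in parallel between
the habitats.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (ConfigError, GenomeLayout, PopulationSpec, SNPMatrix)

logger = logging.getLogger("poolscan")

SNP_CLASSES = ("neutral", "selected_core", "linked")


def default_layout() -> GenomeLayout:
    """Four 25-Mb chromosomes: 100 Mb total, ~1 RAD locus per 2 kb."""
    return GenomeLayout(tuple((f"chr{r}", 25_000_000) for r in "I II III IV".split()))


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults follow the study design: 5 basic + 5 acidic lake pools of 30
    diploids sequenced to a mean 63x, one marine ancestor pool of 30
    diploids at 133x (two sub-samples, OBSM N=20 / ARDH N=10), neutral SNPs
    at long-segregating (uniform) ancestral frequencies and selected loci
    whose acidic-favoured allele is rare in the ancestor.
    """

    seed: int
    layout: GenomeLayout = field(default_factory=default_layout)
    n_basic: int = 5
    n_acidic: int = 5
    pool_size: int = 30
    marine_subpools: tuple[tuple[str, int], ...] = (("OBSM", 20), ("ARDH", 10))
    ne: int = 500
    founder_size: int = 50
    generations: int = 100
    n_neutral_snps: int = 50_000
    n_selected_loci: int = 20
    selected_target_freq: float = 0.95
    ancestral_acidic_freq_range: tuple[float, float] = (0.05, 0.45)
    neutral_freq_range: tuple[float, float] = (0.05, 0.95)
    depth_mean_lake: float = 63.0
    depth_mean_marine: float = 133.0
    depth_dispersion: float = 2000.0
    rad_locus_spacing: int = 2_000
    second_snp_prob: float = 0.10
    lambda0: float = 10_000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory for reproducibility")
        for name in ("n_basic", "n_acidic", "pool_size", "ne", "founder_size",
                     "generations", "n_neutral_snps", "n_selected_loci",
                     "rad_locus_spacing"):
            if getattr(self, name) < 0 or (name not in
                    ("n_selected_loci",) and getattr(self, name) < 1):
                raise ConfigError(f"{name} must be positive")
        for lo, hi in (self.ancestral_acidic_freq_range, self.neutral_freq_range):
            if not (0.0 < lo < hi < 1.0):
                raise ConfigError("frequency ranges must satisfy 0 < lo < hi < 1")
        if not 0.0 < self.selected_target_freq < 1.0:
            raise ConfigError("selected_target_freq must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "layout" in raw:
            raw["layout"] = GenomeLayout(
                tuple((c, int(l)) for c, l in raw["layout"]))
        for key in ("marine_subpools",):
            if key in raw:
                raw[key] = tuple((n, int(s)) for n, s in raw[key])
        for key in ("ancestral_acidic_freq_range", "neutral_freq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def population_specs(self) -> list[PopulationSpec]:
        pops = [PopulationSpec(f"B{i + 1}", "basic", self.pool_size)
                for i in range(self.n_basic)]
        pops += [PopulationSpec(f"A{i + 1}", "acidic", self.pool_size)
                 for i in range(self.n_acidic)]
        pops += [PopulationSpec(name, "marine", size, group_tag=name)
                 for name, size in self.marine_subpools]
        return pops


@dataclass
class AncestralCohort:
    """Ancestral SNP state: positions, alleles, frequencies and truth table."""

    config: CohortConfig
    chrom: np.ndarray
    pos: np.ndarray
    locus_id: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    p_ref: np.ndarray          # ancestral ref-allele frequency
    truth: pd.DataFrame        # per-SNP class, p0, owner, distance, backgrounds

    @property
    def n_snps(self) -> int:
        return len(self.pos)


def sweep_coupling(d: np.ndarray | float, p0: np.ndarray | float,
                   lambda0: float) -> np.ndarray | float:
    """Fraction of lineages descending from the swept founding haplotype.

    Monotone decreasing in distance ``d`` and, at fixed ``d``, decreasing in
    the starting frequency ``p0`` of the selected allele (a rarer start
    means a wider footprint).
    """
    lam = lambda0 * np.log(1.0 / np.asarray(p0, dtype=float)) / math.log(4.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(lam > 0, np.exp(-np.asarray(d, dtype=float)
                                     / np.where(lam > 0, lam, 1.0)), 0.0)
    return h


# ---------------------------------------------------------------------------
# stage 1: ancestral frequencies
# ---------------------------------------------------------------------------

def simulate_ancestral_frequencies(config: CohortConfig,
                                   rng: np.random.Generator | None = None
                                   ) -> AncestralCohort:
    """Lay out RAD loci, draw ancestral frequencies and build the truth table.

    Neutral SNPs get ref-allele frequencies uniform on
    ``neutral_freq_range`` (the long-segregating neutral expectation);
    each selected locus gets an acidic-favoured allele whose ancestral
    frequency is drawn from ``ancestral_acidic_freq_range``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    spacing = config.rad_locus_spacing
    loci: list[tuple[str, int]] = []          # (chrom, locus start)
    for name, length in config.layout.chromosomes:
        loci.extend((name, p) for p in range(spacing, length - spacing, spacing))
    # each RAD locus hosts at most two SNPs
    if config.n_selected_loci > len(loci) or (
            config.n_neutral_snps > 2 * (len(loci) - config.n_selected_loci)):
        raise ConfigError(
            f"cannot place {config.n_neutral_snps + config.n_selected_loci} "
            f"SNPs on {len(loci)} RAD loci; enlarge the layout or spacing")

    # selected loci: one per equal genome segment, placed in the central half
    # of the segment, which guarantees wide separation between them
    sel_loci_idx: list[int] = []
    if config.n_selected_loci:
        seg = len(loci) / config.n_selected_loci
        for s in range(config.n_selected_loci):
            lo = int(seg * (s + 0.25))
            hi = max(lo + 1, int(seg * (s + 0.75)))
            sel_loci_idx.append(int(rng.integers(lo, hi)))
    sel_set = set(sel_loci_idx)

    # host loci for neutral SNPs are drawn uniformly over the genome, so
    # coverage has no systematic holes; a fraction of loci host two SNPs
    non_sel = np.array([i for i in range(len(loci)) if i not in sel_set])
    p2 = config.second_snp_prob
    n_double = max(config.n_neutral_snps - len(non_sel),
                   int(round(config.n_neutral_snps * p2 / (1.0 + p2))))
    n_single_hosts = config.n_neutral_snps - n_double
    hosts = np.sort(rng.choice(non_sel, size=n_single_hosts, replace=False))
    doubles = set(rng.choice(hosts, size=n_double, replace=False).tolist())
    entries: list[tuple[int, str, int, str]] = [
        (li, loci[li][0], loci[li][1], "selected_core") for li in sel_loci_idx]
    for li in hosts:
        c, start = loci[li]
        offset = int(rng.integers(0, 150))
        entries.append((li, c, start + offset, "neutral"))
        if li in doubles:
            entries.append((li, c, start + offset + int(rng.integers(20, 200)),
                            "neutral"))
    layout_order = {name: i for i, (name, _) in enumerate(config.layout.chromosomes)}
    entries.sort(key=lambda e: (layout_order[e[1]], e[2]))
    chrom = [e[1] for e in entries]
    pos = [e[2] for e in entries]
    locus_id = [f"L{e[0]}" for e in entries]
    cls = [e[3] for e in entries]
    chrom = np.array(chrom, dtype=object)
    pos = np.array(pos, dtype=np.int64)
    locus_id = np.array(locus_id, dtype=object)
    cls = np.array(cls, dtype=object)
    n = len(pos)

    # alleles: two distinct nucleotides per SNP
    nts = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref, alt = nts[ref_i], nts[alt_i]

    lo, hi = config.neutral_freq_range
    p_ref = rng.uniform(lo, hi, size=n)
    p0 = np.full(n, np.nan)
    acidic_is_ref = np.zeros(n, dtype=bool)
    sel_mask = cls == "selected_core"
    a_lo, a_hi = config.ancestral_acidic_freq_range
    p0_sel = rng.uniform(a_lo, a_hi, size=int(sel_mask.sum()))
    acid_ref_sel = rng.random(int(sel_mask.sum())) < 0.5
    p0[sel_mask] = p0_sel
    acidic_is_ref[sel_mask] = acid_ref_sel
    p_ref[sel_mask] = np.where(acid_ref_sel, p0_sel, 1.0 - p0_sel)

    # linked SNPs: within 5*lambda0 of a selected locus on the same chromosome
    owner_pos = np.full(n, -1, dtype=np.int64)
    distance = np.full(n, np.nan)
    radius = 5.0 * config.lambda0
    sel_idx = np.flatnonzero(sel_mask)
    for si in sel_idx:
        same = (chrom == chrom[si]) & ~sel_mask
        d = np.abs(pos - pos[si])
        near = same & (d <= radius)
        closer = np.isnan(distance[near]) | (d[near] < distance[near])
        tgt = np.flatnonzero(near)[closer]
        cls[tgt] = "linked"
        owner_pos[tgt] = pos[si]
        distance[tgt] = d[tgt]
        p0[tgt] = p0[si]

    # haplotype backgrounds drawn in the ancestor: the allele at each linked
    # SNP carried on the acidic-allele haplotype and on the basic one
    linked_mask = cls == "linked"
    bg_acidic = np.full(n, -1, dtype=np.int8)
    bg_basic = np.full(n, -1, dtype=np.int8)
    nl = int(linked_mask.sum())
    bg_acidic[linked_mask] = (rng.random(nl) < p_ref[linked_mask]).astype(np.int8)
    bg_basic[linked_mask] = (rng.random(nl) < p_ref[linked_mask]).astype(np.int8)

    acidic_allele = np.where(cls == "neutral", "",
                             np.where(acidic_is_ref, ref, alt))
    # for linked SNPs the acidic allele is the owner's; record blank
    acidic_allele[linked_mask] = ""

    truth = pd.DataFrame({
        "chrom": chrom, "pos": pos, "locus_id": locus_id,
        "class": cls, "ref": ref, "alt": alt, "p_ref_anc": p_ref,
        "acidic_allele": acidic_allele, "p0": p0,
        "owner_pos": owner_pos, "distance": distance,
        "bg_acidic_is_ref": bg_acidic, "bg_basic_is_ref": bg_basic,
    })
    return AncestralCohort(config, chrom, pos, locus_id, ref, alt, p_ref, truth)


# ---------------------------------------------------------------------------
# stage 2: derived population frequencies
# ---------------------------------------------------------------------------

def simulate_derived_populations(ancestral: AncestralCohort,
                                 config: CohortConfig | None = None,
                                 rng: np.random.Generator | None = None
                                 ) -> dict[str, np.ndarray]:
    """True ref-allele frequencies per population after drift and selection.

    Each lake evolves independently given the ancestor: founder bottleneck,
    ``generations`` rounds of binomial Wright-Fisher resampling, then the
    selection endpoint at planted loci and the hitchhiking blend at linked
    SNPs.  Marine sub-pools keep the ancestral frequencies unchanged.
    """
    config = config or ancestral.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    t = ancestral.truth
    cls = t["class"].to_numpy()
    sel = cls == "selected_core"
    linked = cls == "linked"
    acid_is_ref = np.zeros(len(t), dtype=bool)
    acid_is_ref[sel] = (t.loc[sel, "acidic_allele"]
                        == t.loc[sel, "ref"]).to_numpy()
    p0 = t["p0"].to_numpy()
    d = t["distance"].to_numpy()
    bg_a = t["bg_acidic_is_ref"].to_numpy().astype(float)
    bg_b = t["bg_basic_is_ref"].to_numpy().astype(float)
    # the acidic allele of the *owner* maps to this SNP's ref axis through the
    # habitat backgrounds; only p0 of the owner matters for lambda
    target = config.selected_target_freq

    out: dict[str, np.ndarray] = {}
    lakes = ([(f"B{i + 1}", "basic") for i in range(config.n_basic)]
             + [(f"A{i + 1}", "acidic") for i in range(config.n_acidic)])
    # independent RNG substream per lake, derived from the master seed
    for lake_no, (name, habitat) in enumerate(lakes):
        sub = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2, lake_no]))
        p = ancestral.p_ref.copy()
        n2 = 2 * config.founder_size
        p = sub.binomial(n2, p) / n2
        n2 = 2 * config.ne
        for _ in range(config.generations):
            p = sub.binomial(n2, p) / n2
        # selection endpoint: the habitat-favoured allele reaches the target
        if habitat == "acidic":
            p[sel] = np.where(acid_is_ref[sel], target, 1.0 - target)
            p0_local = p0
            bg = bg_a
        else:
            p[sel] = np.where(acid_is_ref[sel], 1.0 - target, target)
            p0_local = 1.0 - p0
            bg = bg_b
        h = np.zeros(len(p))
        h[linked] = sweep_coupling(d[linked], p0_local[linked], config.lambda0)
        p[linked] = (1.0 - h[linked]) * p[linked] + h[linked] * bg[linked]
        out[name] = p
    for name, _size in config.marine_subpools:
        out[name] = ancestral.p_ref.copy()
    return out


# ---------------------------------------------------------------------------
# stage 3: pooled read sampling
# ---------------------------------------------------------------------------

def simulate_pooled_reads(true_freqs: dict[str, np.ndarray],
                          ancestral: AncestralCohort,
                          config: CohortConfig | None = None,
                          rng: np.random.Generator | None = None) -> SNPMatrix:
    """Sample per-pool read depths and reference-allele counts.

    Depth per SNP and pool is negative binomial with the configured mean and
    dispersion (variance = m + m^2/k, clipped to a minimum depth of 1);
    reference read counts are binomial(depth, true frequency).
    """
    config = config or ancestral.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    pops = config.population_specs()
    n = ancestral.n_snps
    total_marine_n = sum(s for _, s in config.marine_subpools)
    ref_counts = np.zeros((n, len(pops)), dtype=np.int64)
    alt_counts = np.zeros_like(ref_counts)
    for j, spec in enumerate(pops):
        if spec.habitat == "marine":
            mean = config.depth_mean_marine * spec.pool_size / total_marine_n
        else:
            mean = config.depth_mean_lake
        k = config.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + mean), size=n)
        depth = np.maximum(depth, 1)
        p = np.clip(true_freqs[spec.name], 0.0, 1.0)
        r = rng.binomial(depth, p)
        ref_counts[:, j] = r
        alt_counts[:, j] = depth - r
    return SNPMatrix(pops, config.layout, ancestral.chrom, ancestral.pos,
                     ancestral.locus_id, ancestral.ref, ancestral.alt,
                     ref_counts, alt_counts)


def simulate_cohort(config: CohortConfig) -> tuple[SNPMatrix, pd.DataFrame]:
    """Run all three stages and return (SNP matrix, truth table)."""
    anc = simulate_ancestral_frequencies(config)
    freqs = simulate_derived_populations(anc, config)
    matrix = simulate_pooled_reads(freqs, anc, config)
    logger.info("simulated cohort: %d SNPs, %d populations (%d selected loci)",
                matrix.n_snps, matrix.n_pops, config.n_selected_loci)
    return matrix, anc.truth


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t")
    truth["acidic_allele"] = truth["acidic_allele"].fillna("")
    return truth
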