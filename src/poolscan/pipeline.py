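"""End-to-end orchestration: simulate -> filter -> scan -> polarize ->
genotypes/ordinate -> sweep -> concord.

Every stage draws its randomness from a substream derived from the master
seed by stable hashing of the stage name, so a pipeline run is fully
reproducible and stages stay reproducible individually.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ascertain, concord, genotypes, polarity, scan, sweep
from .core import (ConfigError, SNPMatrix, combine_populations,
                   write_snp_matrix)
from .simulate import CohortConfig, simulate_cohort, write_truth_table

logger = logging.getLogger("poolscan")


def _dumps(obj: dict) -> str:
    """JSON text with numpy scalars converted to native Python numbers."""
    return json.dumps(obj, indent=2,
                      default=lambda o: o.item() if hasattr(o, "item") else str(o))


def stage_seed(master: int, stage: str) -> int:
    """Derive a per-stage 31-bit seed from the master seed by stable hashing."""
    h = int.from_bytes(hashlib.blake2s(stage.encode(), digest_size=4).digest(),
                       "big")
    return (master * 1_000_003 + h) % (2 ** 31 - 1)


@dataclass
class AnalysisParams:
    """Thresholds of the analysis stages (defaults follow the protocol)."""

    asc_min_total: int = 150
    asc_max_total: int = 2800
    asc_min_maf: float = 0.05
    asc_min_gap: int = 12
    scan_min_depth: int = 50
    scan_min_maf: float = 0.2
    core_threshold: float = 0.70
    core_max_gap: int = 50_000
    control_tolerance: float = 0.005
    n_controls: int | None = None      # default: number of core regions
    w_small: int = 40_000
    w_large: int = 1_000_000
    sweep_maf: float = 0.3
    n_perm: int = 9999
    n_boot: int = 10_000
    nmds_dims: int = 2
    phylo_min_cov: int = 40
    phylo_max_afd: float = 0.5
    tip_window: int = 5_000_000
    thin_gap: int = 1_000_000
    n_synthetic: int = 10
    max_phylo_snps: int = 2_000


@dataclass
class PipelineResult:
    summary: dict
    matrix: SNPMatrix
    regions: list
    polarized_cores: list
    out_dir: Path


def planted_recovery(regions, truth: pd.DataFrame, margin: int) -> dict:
    """Compare detected regions against planted selected loci.

    A planted locus is recovered when it lies within `margin` bp of a
    member SNP of some detected region (the region's chaining equivalence
    class); a region is spurious when no planted locus does.
    """
    sel = truth[truth["class"] == "selected_core"]
    planted = list(zip(sel["chrom"], sel["pos"]))
    hit = 0
    region_has_locus = [False] * len(regions)
    for chrom, pos in planted:
        found = False
        for ri, r in enumerate(regions):
            if r.chrom == chrom and np.min(np.abs(r.positions - pos)) <= margin:
                found = True
                region_has_locus[ri] = True
        hit += found
    n_planted = len(planted)
    n_regions = len(regions)
    n_false = sum(1 for f in region_has_locus if not f)
    return {
        "n_planted": n_planted,
        "n_recovered": hit,
        "recovery_rate": hit / n_planted if n_planted else float("nan"),
        "n_regions": n_regions,
        "n_false_regions": n_false,
        "false_region_rate": n_false / n_regions if n_regions else 0.0,
    }


def _habitat_split_statistic(dist: genotypes.PopulationDistanceMatrix,
                             habitats: dict[str, str],
                             n_iter: int, seed: int) -> polarity.TestResult:
    """Permutation test for habitat clustering among lake populations:
    statistic = mean between-habitat minus mean within-habitat distance."""
    lakes = [n for n in dist.names if habitats[n] in ("basic", "acidic")]
    idx = [dist.names.index(n) for n in lakes]
    sub = dist.matrix[np.ix_(idx, idx)]
    labels = np.array([habitats[n] == "basic" for n in lakes])

    def stat(lab: np.ndarray) -> float:
        same = lab[:, None] == lab[None, :]
        iu = np.triu_indices(len(lab), 1)
        within = sub[iu][same[iu]]
        between = sub[iu][~same[iu]]
        return float(between.mean() - within.mean())

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    null = np.array([stat(rng.permutation(labels)) for _ in range(n_iter)])
    p = (int(np.sum(null >= obs - 1e-12)) + 1) / (n_iter + 1)
    return polarity.TestResult(obs, p, "permutation", n_iter, seed)


def run_pipeline(config: CohortConfig | str | Path, out_dir: str | Path,
                 seed: int | None = None,
                 params: AnalysisParams | None = None,
                 matrix: SNPMatrix | None = None,
                 truth: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full analysis; writes artifacts and a JSON summary to out_dir.

    `config` may be a CohortConfig or a path to its YAML form; pass a
    pre-built `matrix` (and optionally `truth`) to skip simulation.
    """
    params = params or AnalysisParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(config, (str, Path)):
        config = CohortConfig.from_yaml(config)
    if seed is not None and matrix is None:
        config = dataclasses.replace(config, seed=seed)
    master = config.seed if matrix is None else (seed or 0)
    summary: dict = {"seed": master}

    # -- simulate ----------------------------------------------------------
    if matrix is None:
        matrix, truth = simulate_cohort(config)
        write_snp_matrix(matrix, out / "matrix.tsv")
        write_truth_table(truth, out / "truth.tsv")
    summary["n_snps_simulated"] = matrix.n_snps

    freshwater = (matrix.pops_by_habitat("basic")
                  + matrix.pops_by_habitat("acidic"))
    basic = matrix.pops_by_habitat("basic")
    acidic = matrix.pops_by_habitat("acidic")
    marine_subs = matrix.pops_by_habitat("marine")

    # -- ascertainment -----------------------------------------------------
    m = ascertain.filter_coverage(matrix, freshwater, params.asc_min_total,
                                  params.asc_max_total)
    m = ascertain.filter_maf(m, freshwater, params.asc_min_maf)
    m = ascertain.filter_spacing(m, params.asc_min_gap)
    summary["n_snps_ascertained"] = m.n_snps

    # combined marine ancestor-proxy pool
    if len(marine_subs) >= 2:
        m_comb = combine_populations(m, marine_subs, "MAR")
        marine_name = "MAR"
    else:
        m_comb = m
        marine_name = marine_subs[0] if marine_subs else None

    # -- divergence scan ---------------------------------------------------
    m_scan = ascertain.filter_maf(m_comb, freshwater, params.scan_min_maf)
    summary["n_snps_scanned"] = m_scan.n_snps
    table = scan.pairwise_scan(m_scan, params.scan_min_depth,
                               populations=freshwater)
    ba = scan.integrate_category(table, "BA")
    scan_df = pd.DataFrame({"chrom": ba.chrom, "pos": ba.pos,
                            "mean_afd_BA": ba.mean_afd, "n_pairs_BA": ba.n_pairs})
    for cat in ("BB", "AA"):
        cs = scan.integrate_category(table, cat)
        scan_df[f"mean_afd_{cat}"] = cs.mean_afd
        scan_df[f"n_pairs_{cat}"] = cs.n_pairs
    scan_df.to_csv(out / "scan.tsv", sep="\t", index=False)
    regions = scan.detect_core_snps(ba, threshold=params.core_threshold,
                                    max_gap=params.core_max_gap)
    (out / "core_regions.bed").write_text(scan.regions_to_bed(regions))
    summary["n_core_regions"] = len(regions)
    cores = scan.core_positions(regions)
    if truth is not None:
        summary["recovery"] = planted_recovery(regions, truth,
                                               params.core_max_gap)

    if not regions:
        (out / "summary.json").write_text(_dumps(summary))
        return PipelineResult(summary, matrix, regions, [], out)

    # -- polarity and asymmetry tests --------------------------------------
    pol = polarity.polarize(m_comb, cores)
    pd.DataFrame([dataclasses.asdict(p) for p in pol]).to_csv(
        out / "polarized_cores.tsv", sep="\t", index=False)
    k, n = polarity.marine_minor_count(pol)
    sign = polarity.sign_binomial_test(k, n)
    summary["marine_minor_k"] = k
    summary["marine_minor_n"] = n
    summary["sign_binomial_p"] = sign.p_value

    n_controls = params.n_controls or len(pol)
    controls = polarity.select_random_controls(
        ba, n_controls, params.control_tolerance,
        seed=stage_seed(master, "controls"))
    pol_ctl = polarity.polarize(m_comb, controls)
    perm = polarity.median_permutation_test(
        [p.marine_acidic_freq for p in pol],
        [p.marine_acidic_freq for p in pol_ctl],
        n_iter=params.n_perm, seed=stage_seed(master, "median_perm"))
    summary["median_perm_p"] = perm.p_value
    summary["median_perm_stat"] = perm.statistic

    # -- genotype-level structure: NJ tree and NMDS ------------------------
    habitats = {p.name: p.habitat for p in m_comb.populations}
    structure: dict = {}
    for label, snp_set in (("core", cores), ("control", controls)):
        dist = genotypes.binary_similarity(
            m_comb, snp_set, scope_for_major=freshwater,
            seed=stage_seed(master, f"similarity_{label}"))
        newick = genotypes.nj_tree(dist)
        (out / f"nj_{label}.nwk").write_text(newick + "\n")
        coords, stress = genotypes.ordinate(
            dist, n_dims=params.nmds_dims,
            seed=stage_seed(master, f"nmds_{label}"))
        pd.DataFrame(coords, index=dist.names).to_csv(
            out / f"nmds_{label}.tsv", sep="\t", header=False)
        clust = _habitat_split_statistic(
            dist, habitats, params.n_perm,
            stage_seed(master, f"cluster_{label}"))
        structure[label] = {"nmds_stress": stress,
                            "habitat_clustering_p": clust.p_value,
                            "habitat_clustering_stat": clust.statistic}
    summary["structure"] = structure

    # synthetic diploid genotypes at core SNPs (one individual per pool)
    inds = genotypes.synthesize_genotypes(
        m_comb, cores, n_individuals=1,
        seed=stage_seed(master, "genotypes"))
    genotypes.write_fasta(inds, out / "core_genotypes.fasta")

    # genome-wide neutral structure: phylogeny-suitable loner SNPs in the
    # high-recombination chromosome peripheries, away from selection
    if marine_name is not None:
        mf_table = scan.marine_freshwater_scan(m_comb, marine_name,
                                               params.scan_min_depth)
        mf = scan.integrate_category(mf_table, "MF")
        phylo = ascertain.select_phylogeny_snps(
            m_comb, ba, mf, min_pool_cov=params.phylo_min_cov,
            max_afd=params.phylo_max_afd, tip_window=params.tip_window)
        phylo_thin = ascertain.thin_by_distance(phylo, params.thin_gap)
        summary["n_phylogeny_snps"] = phylo.n_snps
        summary["n_phylogeny_snps_thinned"] = phylo_thin.n_snps
        phylo_sites = list(zip(phylo.chrom.tolist(),
                               phylo.pos.tolist()))[:params.max_phylo_snps]
        if len(phylo_sites) >= 3:
            inds = genotypes.synthesize_genotypes(
                m_comb, phylo_sites, n_individuals=params.n_synthetic,
                seed=stage_seed(master, "phylo_genotypes"))
            genotypes.write_fasta(inds, out / "phylogeny_genotypes.fasta")
            dist = genotypes.binary_similarity(
                m_comb, phylo_sites, scope_for_major=freshwater,
                seed=stage_seed(master, "similarity_neutral"))
            (out / "nj_neutral.nwk").write_text(
                genotypes.nj_tree(dist) + "\n")

    # -- sweep scan --------------------------------------------------------
    sweep_report: dict = {}
    for label, snp_set, pol_set in (("core", cores, pol),
                                    ("control", controls, pol_ctl)):
        stats = sweep.sweep_contrasts(
            m_comb, snp_set, basic, acidic,
            [p.marine_acidic_freq for p in pol_set],
            params.w_small, params.w_large, params.sweep_maf)
        pd.DataFrame([dataclasses.asdict(s) for s in stats]).to_csv(
            out / f"sweep_{label}.tsv", sep="\t", index=False)
        if len(stats) >= 3:
            corr = sweep.correlate_bootstrap(
                stats, params.n_boot, seed=stage_seed(master, f"boot_{label}"))
            sweep_report[label] = {"r": corr.r, "ci_low": corr.ci_low,
                                   "ci_high": corr.ci_high, "n": len(stats)}
        else:
            sweep_report[label] = {"r": None, "ci_low": None,
                                   "ci_high": None, "n": len(stats)}
    summary["sweep"] = sweep_report

    windows = [(c, p, params.w_large) for c, p in controls]
    hab = sweep.habitat_diversity_test(
        m_comb, windows, basic, acidic, params.sweep_maf,
        n_iter=params.n_perm, seed=stage_seed(master, "habitat_div"))
    summary["habitat_diversity_p"] = hab.p_value
    summary["habitat_diversity_stat"] = hab.statistic

    # -- marine sub-sample concordance -------------------------------------
    pol_subs = polarity.polarize(m, cores) if len(marine_subs) >= 2 else []
    if len(pol_subs) >= 3:
        s1, s2 = marine_subs[0], marine_subs[1]
        xs = [p.marine_subsample_freqs[s1] for p in pol_subs]
        ys = [p.marine_subsample_freqs[s2] for p in pol_subs]
        fit = concord.major_axis_fit(xs, ys, params.n_boot,
                                     seed=stage_seed(master, "concord"))
        summary["major_axis"] = {"slope": fit.slope,
                                 "intercept": fit.intercept,
                                 "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                                 "n_points": fit.n_points}

    (out / "summary.json").write_text(_dumps(summary))
    logger.info("pipeline complete: %d regions, summary at %s",
                len(regions), out / "summary.json")
    return PipelineResult(summary, matrix, regions, pol, out)
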