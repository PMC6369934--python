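# poolscan

Genome scans for **parallel adaptation from pooled sequencing**, with the
ancestral population in the picture.

When multiple populations adapt independently to the same two habitat types
(here: *basic* vs *acidic* freshwater lakes colonised from a shared *marine*
ancestor), loci repeatedly involved in adaptation show strong, consistent
between-habitat allele-frequency differentiation. `poolscan` implements the
full analysis chain for pooled-sequencing (Pool-seq) SNP count data:

- **Divergence scan.** Differentiation at a biallelic SNP between pools *i*
  and *j* is the absolute allele frequency difference, AFD = |p_i − p_j|.
  AFD is computed for all population pairs, averaged within comparison
  categories (basic–acidic BA, basic–basic BB, acidic–acidic AA), and SNPs
  with mean BA AFD above a threshold (default 0.70, or an empirical
  quantile) are chained into independent genome regions separated by ≥50 kb.
  The strongest SNP of each region is its **core SNP**.
- **Ancestral polarity.** At each core SNP the alleles are classified as
  "basic" or "acidic" by their mean frequency within each habitat; the
  frequency of the acidic allele in the marine ancestor-proxy pool tests
  whether adaptation to the more extreme habitat recruited ancestrally rare
  alleles (exact two-tailed binomial sign test, plus a median-difference
  permutation test against matched random control SNPs).
- **Selective sweeps.** Diversity around each core SNP is measured as the
  number of SNPs with per-pool MAF > 0.3 in a 40-kb window, summed per
  habitat and divided by the same count in a 1-Mb window. The
  basic-minus-acidic contrast of this relative SNP density, correlated with
  the marine frequency of the acidic allele (Pearson r with bootstrap CI),
  tests whether rarer standing variants swept harder.
- **Population structure inputs.** Synthetic diploid IUPAC genotypes drawn
  without replacement from each pool (FASTA export), binary similarity
  matrices, neighbour-joining trees and non-metric MDS ordination.
- **Concordance.** Major-axis regression between the acidic-allele
  frequencies of two marine sub-samples, with bootstrap CI.
- **Synthetic cohort simulator.** A Wright–Fisher generator of the whole
  study design — an ancestral marine pool, 5 basic + 5 acidic lakes founded
  independently from it, selection on standing variation, sweep footprints
  on linked sites, and pooled read sampling — with a per-SNP truth table,
  so every stage is exercised without external data.

## Worked example

Simulate a scaled cohort, run the scan and the ancestry tests:

```python
import poolscan as ps

cfg = ps.CohortConfig(seed=42, n_neutral_snps=20_000, n_selected_loci=8,
                      layout=ps.GenomeLayout((("chrI", 20_000_000),
                                              ("chrII", 20_000_000))))
matrix, truth = ps.simulate_cohort(cfg)

fresh = matrix.pops_by_habitat("basic") + matrix.pops_by_habitat("acidic")
m = ps.filter_coverage(matrix, fresh, 150, 2800)   # total-depth window
m = ps.filter_maf(m, fresh, 0.05)                  # pooled MAF > 0.05
m = ps.filter_spacing(m, 12)                       # >= 12 bp apart
m = ps.combine_populations(m, ["OBSM", "ARDH"], "MAR")
m = ps.filter_maf(m, fresh, 0.2)                   # scan MAF > 0.2

table = ps.pairwise_scan(m, min_depth_per_pop=50)  # 45 pairs for 5+5 pools
ba = ps.integrate_category(table, "BA")            # >= 18 of 25 BA pairs
regions = ps.detect_core_snps(ba, threshold=0.70, max_gap=50_000)
print(f"{len(regions)} core regions from {m.n_snps} scanned SNPs")

cores = [(r.chrom, r.core_pos) for r in regions]
pol = ps.polarize(m, cores)
k, n = ps.marine_minor_count(pol)
test = ps.sign_binomial_test(k, n)
print(f"acidic allele is the marine minor allele at {k} of {n} core SNPs "
      f"(two-tailed binomial P = {test.p_value:.2e})")

stats = ps.sweep_contrasts(m, cores, m.pops_by_habitat("basic"),
                           m.pops_by_habitat("acidic"),
                           [p.marine_acidic_freq for p in pol])
corr = ps.correlate_bootstrap(stats, n_boot=10_000, seed=1)
print(f"sweep contrast vs marine frequency: r = {corr.r:.2f} "
      f"(95% bootstrap CI {corr.ci_low:.2f} to {corr.ci_high:.2f})")
```

Output:

```
8 core regions from 13234 scanned SNPs
acidic allele is the marine minor allele at 8 of 8 core SNPs (two-tailed binomial P = 7.81e-03)
sweep contrast vs marine frequency: r = -0.83 (95% bootstrap CI -0.98 to -0.62)
```

All 8 planted selected loci are recovered as core regions; at every one of
them the acidic-favoured allele is rare in the ancestor (it was planted
that way), and the sweep contrast is more positive — diversity more
strongly reduced in the acidic pools — the rarer the acidic allele was,
giving the negative correlation.

The same chain is available from the shell
(`poolscan simulate | filter | scan | polarize | genotypes | ordinate |
sweep | concord | run`); `poolscan run --config cohort.yaml --out-dir out/`
executes everything and writes per-stage TSV/BED/FASTA/Newick artifacts
plus a JSON summary.

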