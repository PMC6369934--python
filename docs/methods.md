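# Methods

This note documents the models and procedures implemented in `poolscan`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open.

## Data model

The substrate is a per-SNP, per-population matrix of biallelic read counts
(`SNPMatrix`). Populations are pools of diploid individuals labelled
`basic`, `acidic` or `marine`. The allele frequency of a pool at a SNP is
the reference-read fraction; a pool with zero depth has an *undefined*
frequency that propagates as missing (NaN), never as zero. Coordinates are
1-based inclusive; BED output is 0-based half-open. Two on-disk formats are
supported: a TSV dialect (`chrom pos locus_id ref alt <pop>:ref <pop>:alt
...`) and the popoolation2 sync format. Sync sites are reduced to the two
most frequent nucleotides (the declared reference base keeps the `ref` role
when it is one of them); a site whose third allele exceeds 10% of total
depth is skipped with a warning, since the analysis is strictly biallelic.
Marine sub-samples are merged by read-count summation, which weights
sub-samples by depth; this is the only merging rule that commutes with
frequency estimation.

## Divergence scan

Pairwise differentiation is AFD = |p_i − p_j|, computed at every SNP where
both pools have depth ≥ 50×. For a 5+5 design this yields 45 pairs (25 BA,
10 BB, 10 AA). Category integration is the *unweighted* mean of available
pair AFDs, reported only where at least 18 (BA) or 8 (BB/AA) pairs
contribute; an optional standardisation divides each pair's values by its
genome-wide mean AFD before averaging, as a robustness variant. SNPs with
mean BA AFD strictly above 0.70 (or above an empirical quantile, type-7
interpolation) are chained per chromosome: two passing SNPs separated by at
least `max_gap` (50 kb) belong to independent regions, so the link
condition is strictly-less-than. The core SNP of a region is its
maximal-AFD member, ties broken toward the smaller position for
determinism. A Hudson-type F_ST with read-depth sample-size correction is
available for parity with conventional summaries; it is a companion
statistic, not part of the detection path.

## Ancestral polarity and asymmetry tests

At a core SNP, the allele averaging > 0.5 across basic pools (unweighted
across populations) is the basic allele; the complementary allele is
labelled acidic, with a warning when its acidic-habitat mean is ≤ 0.5.
Sites with both habitat means exactly 0.5 are unpolarizable and excluded.
Equal weighting of populations (rather than depth weighting) keeps the
classification insensitive to coverage differences between lakes.

Asymmetry of the acidic alleles in the marine ancestor-proxy is tested two
ways:

- an exact two-tailed binomial sign test on the count k of core SNPs whose
  acidic allele is the marine *minor* allele (frequency < 0.5; exactly 0.5
  counts as not-minor): p = min(1, 2·P(X ≥ max(k, n−k))) under X ~
  Binomial(n, 1/2);
- a two-tailed permutation test on the absolute difference in median
  marine acidic-allele frequency between the core SNPs and matched random
  controls, with p = (b+1)/(m+1) over m relabelings (default 9999), or the
  exact enumeration fraction when the null is exhausted.

Control SNPs are sampled without replacement among SNPs whose mean BA AFD
lies within 0.5% of the genome-wide median — relative by default, with an
absolute ±tolerance window available, since either reading of "within
0.5% of the median" is defensible.

Note an ascertainment subtlety the simulator makes visible: at *neutral*
SNPs the allele labelled acidic is the complement of the basic-pool
majority allele, which tends to be the ancestrally minor allele as well,
so control acidic alleles are themselves biased below 0.5 in the marine
pool. The core-vs-control median contrast is therefore conservative in
the simulated cohort.

## Synthetic genotypes, trees, ordination

Pool-seq provides no individual genotypes, so population-level inputs are
synthesised. For diploid genotypes, the discrete allele pool of size
2·pool_size is reconstructed per SNP by rounding ref_freq·2N to the
nearest integer (ties up); two alleles per individual are drawn without
replacement, with all individuals of a population drawing from the same
pool at a SNP (no replenishment between individuals — the most
conservative reading, flagged as a modelling choice). Heterozygotes are
encoded with the two-base IUPAC codes; FASTA export is provided so
external maximum-likelihood tools can be used. In-repo tree inference is
neighbour joining (scikit-bio), which is deterministic given the distance
matrix; ML tree estimation is deliberately out of scope.

The binary similarity matrix samples one allele per population per SNP
(probability = its pool frequency), codes it 1/0 against the global
freshwater major allele, and takes Euclidean distances (√mismatch count).
The coding is invariant to ref/alt relabelling. Ordination is non-metric
MDS minimising Kruskal stress-1, run with scikit-learn's SMACOF from a
classical-MDS (principal coordinates) initialisation; the deterministic
initialisation makes perfect embeddings reach stress ~0 and fixed seeds
reproduce coordinates exactly.

## Sweep statistics

Diversity around a focal SNP is the count of SNPs with per-pool MAF
strictly > 0.3 inside a window (inclusive, clipped at chromosome ends;
zero-depth SNPs are not counted). The relative SNP density is the 40-kb
count summed over a habitat's pools divided by the analogous 1-Mb sum; the
small window is *not* subtracted from the large one. The basic-minus-acidic
contrast of these densities is correlated (Pearson) with the marine
frequency of the acidic allele; the 95% CI is a percentile bootstrap over
SNPs (default 10,000 resamples). A pooled nucleotide diversity π per bp is
provided for comparison, using the depth/(depth−1) binomial correction; it
is a comparison utility, since the high-MAF density is the statistic the
detection path uses. The genome-wide habitat diversity test takes each
population's median 1-Mb high-MAF count across the control windows as one
data point and permutes habitat labels over populations, using
|median(basic) − median(acidic)| as statistic; for a 5+5 design the
exhaustive null has C(10,5) = 252 splits.

### Calibration caveat

The habitat label-permutation test is *valid but conservative* at
α = 0.05: the median-of-five statistic attains its maximum on 12 of the
252 splits, so the smallest attainable p is 12/252 ≈ 0.0476, and integer
window counts make population medians tie on a half-integer grid, pushing
additional mass above 0.05. Measured type-I error under null simulations
is ≈ 0.02–0.03; with effectively continuous data the exhaustive test
calibrates (≈ 0.0476), confirming the permutation machinery itself is
exact. The median permutation test on 42+42 continuous frequencies does
calibrate (rejection rate inside the 95% binomial interval around 0.05
over 500 null replicates). Mid-p corrections would remove the
conservatism but were not adopted, to keep the stated exceedance/(b+1)
conventions.

## Major-axis concordance

The slope between two marine sub-samples' acidic-allele frequencies is the
direction of the first principal axis of the 2×2 covariance matrix
(major-axis regression, appropriate when both variables carry error of
similar magnitude), intercept through the centroid, percentile bootstrap
CI over points. A vertical principal axis is flagged rather than reported
as a finite slope. Because the two sub-samples are sequenced to different
depths (≈ 89× vs 44×), their error variances differ and the major-axis
slope is mildly biased away from 1 even for identical underlying
frequencies; a Deming-type unequal-variance generalisation is deliberately
out of scope.

## The synthetic cohort

The generator emulates the study design, not any particular dataset:

- **Layout:** four 25-Mb chromosomes, RAD loci every 2 kb (~1 SNP per
  2 kb, the study's marker resolution); ~50,000 neutral SNPs, 10% of host
  loci carrying a second SNP ≥ 20 bp away; 20 selected loci placed one per
  equal genome segment (guaranteeing multi-Mb separation).
- **Ancestor:** neutral ref-allele frequencies uniform on [0.05, 0.95]
  (the long-segregating neutral expectation); at each selected locus the
  acidic-favoured allele's ancestral frequency p0 is uniform on
  [0.05, 0.45] — rare-to-uncommon in the ancestor by design. The marine
  pool keeps ancestral frequencies exactly (the ancestor-proxy assumption
  made explicit), split into two sub-samples (OBSM N=20, ARDH N=10) that
  share frequencies and differ only in read sampling.
- **Lakes:** each of the 10 lakes evolves independently given the
  ancestor: a founder bottleneck of 50 diploids, then 100 generations of
  binomial Wright–Fisher drift at Ne = 500 (≈10% of heterozygosity lost —
  young postglacial populations), using per-lake RNG substreams derived
  from the master seed.
- **Selection:** imposed as a deterministic endpoint — the locally
  favoured allele (acidic allele in acidic lakes, its alternative in basic
  lakes) is set to frequency 0.95. Endpoint control rather than a
  per-generation selection coefficient keeps recovery tests stable and
  makes no claim about trajectories.
- **Sweep footprints:** a linked SNP at distance d from a selected locus
  has fraction h(d, p0) = exp(−d/λ), λ = λ0·ln(1/p0)/ln 4, of its lineages
  descending from the founding swept haplotype; its frequency becomes
  (1−h)·p_drift + h·x. λ0 = 10 kb, so λ = λ0 at p0 = 0.25 and grows as
  the selected allele starts rarer — rarer standing variants erase more
  linked diversity, the relationship the sweep scan is designed to
  detect. The background alleles x (one for the acidic-allele haplotype,
  one for the basic) are drawn once *in the ancestor* and shared by all
  populations of a habitat: parallel adaptation reuses the same ancestral
  haplotype, which is what produces parallel high differentiation at SNPs
  flanking selected loci and low within-habitat differentiation there.
  Each habitat's footprint uses the starting frequency of *its* favoured
  allele (p0 in acidic lakes, 1−p0 in basic lakes), so the habitat
  selecting the rare allele sweeps wider.
- **Reads:** depth per SNP and pool is negative binomial with mean 63×
  (lakes) or 133× split across the marine sub-samples, dispersion 2000
  (near-Poisson), minimum 1; reference counts are binomial(depth, freq).
  Near-Poisson depth is used because with strong over-dispersion the
  ≥ 50×-per-pool scan filter would discard most SNPs, which is
  inconsistent with a design where the large majority of ascertained SNPs
  are analysable; the dispersion is exposed for users who want noisier
  coverage.

What the generator deliberately does **not** model: recombination maps and
coalescent linkage (footprints are imposed, not emergent), gene flow,
inversions, reference bias, sequencing error, or locus-correlated coverage.
Passing recovery tests therefore demonstrates that the statistics detect
the patterns they target under the stated model, not that they are robust
to every artefact of real Pool-seq data.

## Problem sizes and determinism

The recovery suite runs the full pipeline on the default cohort
(~50k SNPs, 20 planted loci, 9999 permutations, 10,000 bootstrap
resamples), which completes in well under a minute on one CPU; unit and
oracle suites use matrices of tens of SNPs with ≥ 1000 random instances
per operation. Every stochastic stage draws from a substream derived from
the master seed by stable hashing of the stage name, so summaries are
byte-identical across runs at a fixed seed and individual stages remain
reproducible in isolation.

## Known limitations

- Depth censoring is real: with mean 63× and the ≥ 50× pair filter,
  roughly one pool in twenty falls below threshold per SNP, so a planted
  locus occasionally fails the 18-of-25-pairs rule and is invisible to
  the scan (the recovery criterion's margin absorbs this).
- The control-SNP polarity bias described above makes the core-vs-control
  median permutation test conservative on simulated cohorts.
- The habitat diversity permutation test is conservative at α = 0.05 for
  structural reasons (see the calibration caveat).
- NJ and NMDS are delegated to scikit-bio/scikit-learn; no bootstrap
  support values or ML trees are produced in-repo.
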