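# Methods

This note documents the models, estimators, numerical choices and known
limitations of the toolkit, and what the built-in simulator does and does
not emulate.

## Data model and site filtering

Genotypes are held as a sites × samples dosage matrix (0/1/2, −1 for
missing) with a site table (chrom, pos, ref, alt, missingness, pooled
MAF); fully phased data additionally yields a sites × haplotypes binary
matrix with two haplotypes per sample in fixed order.  Internally all
coordinates are 0-based half-open; VCF and GFF3 keep their native 1-based
conventions at the boundary, and BED output is 0-based half-open.

The default site filter keeps sites with **no missing calls and pooled
MAF ≥ 0.05**; a site at exactly the MAF threshold survives (the removal
rule is "< threshold").  Multiallelic and non-SNP records are skipped on
read, never split.  One deliberate asymmetry: the EHH-family scans run on
the *unfiltered* phased site set, with the MAF threshold applied to core
SNPs only.  Rare variants are what makes haplotype homozygosity decay;
filtering them out of the matrix would leave EHH flat to the chromosome
end on desk-scale chromosomes and invalidate every core.  This mirrors
selscan's behaviour (its `--maf` option filters cores, not the matrix).
π, F_ST and XP-CLR use the filtered set.

## Windowed diversity and ROD

Per window, π = Σ_j [n_j/(n_j−1)] · 2p̂_j(1−p̂_j) / L over variant sites j,
with n_j called haplotypes and L the window length in bp.  This is
algebraically identical to the mean pairwise Hamming distance per bp
(the test suite asserts exact agreement with that oracle).  Sites with
fewer than two called haplotypes are skipped and counted.  ROD is
1 − π_test/π_ref per window; windows with π_ref = 0 or fewer than
`min_snps` SNPs (default 10) in either track are flagged invalid and
excluded from outlier ranking but kept in the output.  Orientation:
the *test* (weedy-like) population in the numerator, ranked on the upper
tail, so large ROD means diversity loss in the test population.

## Weir–Cockerham F_ST

Per site, the r = 2 variance components a (between populations),
b (between individuals within populations) and c (within individuals) are
computed from diploid sample sizes, alt frequencies and observed
heterozygote proportions; θ = a/(a+b+c).  Negative per-site θ values are
retained (standard behaviour of the estimator).  Window values are the
**ratio of averages** Σa/Σ(a+b+c), not the mean of per-site ratios; sites
where a+b+c = 0 (e.g. both populations monomorphic for the same allele)
or where a population has no calls (or n̄ ≤ 1) are undefined and excluded.
The unit tests pin every component against an exact rational-arithmetic
transcription of the formulas.

## EHH, iHS and XP-EHH

EHH at extension x is Σ_g C(n_g,2)/C(n,2) over groups of carrier
haplotypes identical at every site from the core through x, computed by
partition refinement one site at a time.  The core site's alleles seed
the partition (identity is over the closed interval [core..x]); EHH at
the core itself is defined as 1.  This distinction is invisible for iHS
(whose carrier sets share the core allele by construction) but matters
for XP-EHH, where EHH is computed over *all* haplotypes of a population.

iHH integrates EHH over genetic distance (cM) by trapezoids between
consecutive sites, in both directions from the core, truncated at the
first site where EHH < 0.05 (that final trapezoid included).  A core is
invalid when EHH fails to fall below the cutoff before the chromosome end
or the maximum extension (default 1 Mb).  Note that under trapezoidal
integration, inserting a site at which no carrier differs can increase
the integral slightly (the new point pins EHH at its previous value
partway across the gap); only insertion at an identical genetic position
is exactly neutral.  We accept this, as selscan does, because the
trapezoid is the standard convention.

iHS is ln(iHH_ancestral) − ln(iHH_derived) per core SNP with derived
frequency ≥ 0.05 in the scanned population, standardized to zero mean and
unit variance (sample SD) within 50 equal-width derived-frequency bins;
bins with fewer than 20 scores are merged with their right neighbour
(the last merges leftwards).  The ancestral allele defaults to the
reference allele; an annotation table (site → ancestral base) can
override, as one would with an outgroup.  Outliers use |iHS| (two-sided).

XP-EHH is ln(iHH_pop1) − ln(iHH_pop2) per core (computed as a difference
of logs so that swapping the populations negates every score
bit-exactly), standardized genome-wide over valid cores.  Each
population's iHH is truncated at its own EHH cutoff.  With the test
population first, selection in it pushes scores positive, so the upper
tail is ranked.  No gap-scaling penalty is applied (selscan's max-gap
heuristic is omitted); the maximum-extension cap plays that role.

A numba-compiled kernel performs the per-core partition refinement and
integration; a pure-numpy implementation with identical semantics is the
fallback and the reference for the oracle tests.

## Simplified XP-CLR

The drift null models the test population's frequency p_t at a SNP with
reference frequency p_r as Normal(p_r, ω·p_r(1−p_r)) truncated to (0,1),
with the truncated tail masses placed as point masses at 0 and 1
(fixation/loss).  ω is estimated genome-wide as the mean of
(p_t − p_r)²/(p_r(1−p_r)) over sites with 0 < p_r < 1 (floored at 1e-6).
The sweep model at genetic distance d (Morgans) from a proposed selected
site uses escape probability c = 1 − e^{−d/s}: with probability p_r a
lineage hitchhikes toward fixation (mean 1 − c + c·p_r), otherwise toward
loss (mean c·p_r); at c = 1 the mixture reduces exactly to the neutral
density.  Per grid point, the composite log-likelihood sums log densities
over the nearest ≤ 200 SNPs within the likelihood window, is maximized
over a 12-point logarithmic s-grid (1e-5 … 1e-1 Morgans), and
CLR = 2(ℓ̂ − ℓ_neutral), clamped at 0.  Grid points with fewer than 5
usable SNPs are invalid.  For the outlier pipeline the per-window summary
is the maximum CLR among grid points in the window.

This is a deliberate simplification of the published XP-CLR: Gaussian
drift instead of the full diffusion transition, and a SNP cap instead of
LD-based down-weighting.  Consequences: ω estimated from sweep-containing
data is somewhat inflated (the estimator is a mean of ratios and absorbs
both populations' drift), which makes the scan conservative, and CLR
values are comparable within a dataset but not across datasets.

## Outlier calling and candidate genes

Per metric, exactly ⌈q·M⌉ of the M valid records are flagged (q = 0.025),
ranked by the tail-appropriate score with ties broken deterministically
by genomic order, so repeated runs flag identical sets.  Thresholds are
applied genome-wide, not per chromosome.  Window-metric outliers map to
genes by ≥ 1 bp interval overlap; site-metric outliers by containment in
the gene extended by a configurable flank (default 0).  Genes hit by ≥ 2
metrics are candidates; a Venn-style combination table is emitted, and a
flank query (default ± 600 kb) supports checking the neighbourhood of a
known locus.  Tail conventions: ROD, F_ST, XP-EHH, XP-CLR upper; iHS
two-sided.

## LD and PCA

Phased r² is D²/(p_A q_A p_B q_B); unphased input falls back to the
squared Pearson correlation of dosages (composite LD) with per-site mean
imputation of missing calls.  The decay curve is the mean r² per physical
distance bin; the half-decay distance is the midpoint of the first bin
whose mean has fallen to half the curve's maximum.  PCA centres each site
at 2p̂ and scales by √(2p̂(1−p̂)) after mean imputation; coordinates are
left singular vectors scaled by singular values (monomorphic sites are
dropped as they carry no variance).

## Co-expression clustering

Expression values are log2(x+1)-transformed and z-scored per gene
(constant genes become zero vectors, not dropped), then clustered with
k-means (k = 10 by default, best of 10 restarts, seeded).  A cluster is
tissue-specific for tissue t when |centroid_t − mean(centroid)| >
2 × SD(centroid across tissues), using the sample SD (ddof = 1) and a
strict inequality so flat centroids are never flagged; the deviation's
sign separates high-in-t from low-in-t patterns.  The rule is applied at
the centroid level and propagated to member genes (applying it per gene
is noisier; the centroid form is the stable reading of the twofold-SD
rule).  Clusters whose mean member expression falls below the bottom
decile of gene-level means are flagged low-expression and excluded from
tissue-specific gene lists while remaining in the report.

## The simulator

A discrete-generation, diploid Wright–Fisher forward simulator: parents
are sampled proportional to fitness, gametes recombine with per-adjacent-
bp probability r (crossover positions uniform), and each gamete receives
Poisson(μL) new biallelic mutations at uniform positions (repeat hits
re-drawn).  An ancestral population of N diploids runs a burn-in of
T_burn generations — optionally seeded with `n_standing` standing-
variation sites whose frequencies are drawn from a 1/x neutral SFS and
assigned to haplotypes at linkage equilibrium (burn-in generations then
build LD) — and splits into two populations of size N evolving
independently for T_split generations.  A sweep is seeded as a single
copy in the test population with additive fitness (1, 1+s/2, 1+s);
conditioning on fixation re-runs the test population's trajectory (never
the reference, never the seed placement) until the allele is fixed at
sampling time.  n diploids per population are sampled and written as a
phased VCF over the union of segregating sites, together with the uniform
genetic map implied by r, a GFF of genes tiled every 20 kb (5 kb long,
for reproducible gene-mapping tests) and a truth JSON (sweep position, s,
fixation, final frequency, split time, realized mean windowed F_ST).
Forward simulation keeps sweeps, conditioning and LD exact by
construction; a desk-scale guard (N ≤ 1000, L ≤ 1 Mb) keeps runs to
seconds.  A fast frequency-only companion, `drift_only`, draws ancestral
frequencies from the 1/x SFS and evolves the test frequency by T
binomial(2N) resampling steps while the reference column keeps the
ancestral frequency — the baseline the XP-CLR drift model conditions on —
so the ω estimator provably targets 1 − (1 − 1/2N)^T ≈ T/2N.
`expression_sim` builds cluster centroids in log2 space (base level +
per-tissue variation, single-tissue spikes for some clusters, one
low-expression cluster) and adds Gaussian noise in log space.

### Study conditions used by the tests and acceptance script

* **Drift calibrations** (windowed F_ST and ω): N = 200, T = 40, 50
  replicates, against 1 − (1 − 1/2N)^T ≈ 0.095.  The F_ST runs use μ = 0
  with 800 standing sites on 200 kb, because the closed form describes
  drift of variation present at the split; post-split mutations are
  private, weakly differentiated sites that dilute windowed F_ST (we
  measured ≈ 0.079 with μ = 2e-6 versus ≈ 0.090 drift-only).
* **Standardization null**: three neutral 1-Mb replicates (μ = 4e-6,
  2000 standing sites, T_split = 40) merged as three chromosomes, giving
  > 10 000 valid cores for iHS and XP-EHH in one standardization.
* **Sweep scenario**: N = 200, L = 500 kb, μ = 2e-6, r = 1e-6/bp,
  T_burn = 100 with 800 standing sites, T_split = 50, sweep s = 0.7 at
  225 kb conditioned on fixation.  The recombination rate is deliberately
  scaled up (100 cM/Mb, with the matching map written out): at a
  realistic plant-genome rate the hitchhiking footprint
  (~ s·ln2/ln(2Ns) Morgans) would span the whole desk-scale chromosome
  and no scan could localize anything.  T_split = 50 keeps the background
  drift-fixation probability near 12% so random fixations rarely outrank
  the sweep.  XP-CLR uses a 50-kb grid and a 20-cM window under this map;
  the sweep sits on a grid point so "nearest grid point attains the
  maximum" is unambiguous.

What the simulator does *not* emulate: migration or admixture after the
split (the weedy-rice system shows gene flow), population growth or
bottlenecks, soft sweeps or selection on standing variation, mutation-
rate or recombination-rate heterogeneity, genotyping error and missing
data (the simulator's output is complete and phased), and multi-
chromosome genomes within a single run (tests merge independent runs as
separate chromosomes).  Passing tests therefore demonstrate correctness
of the estimators and calibration under idealized two-population
divergence, not robustness to demographic misspecification on real data.

## Numerical conventions

Window tiling starts at 0 with step = size by default (non-overlapping);
the final partial window is kept if non-empty.  Outlier tie-breaks are by
(score, chrom, start).  Log densities are floored at 1e-300 before
summation.  Standardizations use the sample SD (ddof = 1); bins with one
score or zero SD yield invalid scores rather than infinities.  Genetic
maps interpolate linearly between anchors and extrapolate with the
boundary segment's rate; the default uniform rate is 4 cM/Mb (a
plant-genome-scale average) unless a map file or rate is given.  All
randomness flows from explicit integer seeds through numpy Generators;
identical configuration and seed reproduce every output byte for byte.

## Known limitations

* XP-EHH truncates each population's iHH at its own EHH cutoff rather
  than at a shared boundary; scores remain exactly antisymmetric, but
  the statistic is not numerically identical to selscan's.
* The XP-CLR ω estimator mixes both populations' drift when applied to
  real two-population data (conservative; see above).
* ⌈q·M⌉ outlier counting makes the flagged fraction slightly exceed q
  for small M.
* The co-expression module clusters patterns, not levels; genuinely
  low-expressed but pattern-coherent clusters are handled by the
  low-expression flag, not removed from clustering itself.
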