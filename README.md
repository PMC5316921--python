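# sweepscan

Selection scans between two closely related plant populations — a
cultivated reference (landrace-like) and a feral test population
(weedy-like) — packaged as a tested, reusable toolkit.  It was built for
the weedy-rice setting, where a weed population derived from cultivated
*Oryza sativa* is screened for recent positive and divergent selection,
but nothing in the code is rice-specific: any pair of diverged populations
with diploid genotypes in VCF works.

Five complementary statistics are computed from one genotype panel, the
empirical top 2.5% of each is flagged, and genes hit by the outliers of at
least two statistics become *candidate selection genes*:

| statistic | unit | signal |
|---|---|---|
| ROD = 1 − π_test/π_ref | 100-kb window | diversity loss in the test population |
| F_ST (Weir–Cockerham 1984) | 100-kb window | allele-frequency differentiation |
| iHS | SNP | long haplotypes around an unusually frequent derived allele |
| XP-EHH | SNP | haplotype homozygosity excess in one population over the other |
| XP-CLR (simplified) | grid/window | multilocus frequency distortion under a hitchhiking model |

Windowed nucleotide diversity uses the unbiased per-site estimator
π = Σ_j [n_j/(n_j−1)] · 2p̂_j(1−p̂_j) / L, which equals the mean pairwise
Hamming distance between sampled haplotypes per bp.  Window F_ST is the
ratio of averages Σa / Σ(a+b+c) over the per-site variance components.
iHS is ln(iHH_A/iHH_D) standardized within derived-allele-frequency bins;
XP-EHH is ln(iHH_pop1/iHH_pop2) standardized genome-wide, with EHH
integrated over genetic distance by trapezoids and truncated at
EHH < 0.05.  The XP-CLR model scores the test population's frequency at
each SNP under a two-component mixture (hitchhiked vs escaped, escape
probability c = 1 − e^{−d/s}) against a Gaussian drift null with
genome-wide variance inflation ω, and reports the composite likelihood
ratio 2(ℓ̂_sweep − ℓ_neutral) on a grid of proposed sweep positions.

The package also provides LD-decay curves with half-decay distance,
allele-frequency-standardized genotype PCA, k-means co-expression
clustering across tissues (with twofold-SD tissue-specificity calls and a
low-expression-cluster filter), and — so that everything is testable
without any external data — a two-population Wright–Fisher forward
simulator with recombination, mutation, standing variation and an optional
hard sweep conditioned on fixation, which emits VCF + genetic map + GFF +
ground truth.

## Worked example

Simulate two populations that split 50 generations ago, with a hard sweep
(s = 0.7, conditioned on fixation) planted at 225 kb in the weedy
population, then scan:

```sh
sweepscan simulate --n 200 --length 500000 --mu 2e-6 --rec 1e-6 \
    --t-burn 100 --t-split 50 --n-standing 800 \
    --sweep-pos 225000 --sweep-s 0.7 --seed 7 -o demo

sweepscan run --vcf demo/sim.vcf --pops demo/pops.tsv --gff demo/genes.gff3 \
    --map demo/map.tsv --ref-pop landrace --test-pop weedy \
    --xpclr-grid 50000 --xpclr-window 20 --seed 7 -o demo_out
```

The simulator prints its ground truth (`"fixed": true`, realized mean
F_ST 0.147) and the scan prints a summary:

```json
{
  "candidate_count": 5,
  "n_sites_input": 3218,
  "n_sites_filtered": 1125,
  "n_windows": 5,
  "per_metric": {
    "FST":   {"n_genes": 5, "n_outliers": 1,  "n_valid": 5},
    "IHS":   {"n_genes": 4, "n_outliers": 21, "n_valid": 839},
    "ROD":   {"n_genes": 5, "n_outliers": 1,  "n_valid": 5},
    "XPCLR": {"n_genes": 5, "n_outliers": 1,  "n_valid": 5},
    "XPEHH": {"n_genes": 1, "n_outliers": 28, "n_valid": 1082}
  }
}
```

3218 segregating sites were read; 1125 survive the site filter (no
missing calls, MAF ≥ 0.05).  Each metric flags its empirical top 2.5%
(⌈0.025·5⌉ = 1 window for the window metrics, ⌈0.025·839⌉ = 21 cores for
iHS).  `demo_out/candidate_genes.tsv` lists the genes supported by ≥ 2
metrics:

```
gene_id   support  metrics
gene0011  4        FST,ROD,XPCLR,XPEHH
gene0012  3        FST,ROD,XPCLR
gene0013  3        FST,ROD,XPCLR
gene0014  3        FST,ROD,XPCLR
gene0015  4        FST,IHS,ROD,XPCLR
```

All five candidates sit in the 100-kb window containing the planted sweep
(gene0012 spans position 225 000 itself): ROD, F_ST and XP-CLR all rank
that window first, and XP-EHH/iHS add site-level support.  Other outputs:
per-metric tracks (`track_*.tsv`), outlier regions in BED
(0-based half-open), the metric-combination overlap table and
`summary.json`.

The same analyses are available as library functions
(`sweepscan.window_pi`, `wc_fst_site`, `ihs_scan`, `xpehh_scan`,
`xpclr_scan`, `call_outliers`, `candidate_genes`, `ld_curve`, `pca`,
`cluster_expression`, `simulate`, …); see the docstrings and
`docs/methods.md`.

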