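# invscan

Detection, genotyping and population-genetic characterisation of
megabase-scale chromosomal inversion polymorphisms from population
genotype data.

Large inversions suppress recombination in heterozygotes across their whole
length. A segregating inversion therefore behaves like a single Mendelian
"supergene": the windows it spans show a three-cluster sample structure
along PC1 (two arrangement homozygotes plus high-heterozygosity
heterozygotes in the middle), a block of elevated linkage disequilibrium
that disappears within arrangement homozygotes, elevated F_ST between the
arrangement classes, and near-zero crossover recovery in F2 offspring of
heterozygous parents. `invscan` implements the full workflow that exploits
these signatures, for population geneticists working with multi-sample VCFs
(the motivating system is forest/prairie ecotypes of deer mice, but nothing
is species-specific):

* **scan** — local PCA per 100 kb window; window dissimilarity
  d² = Σλ_a² + Σλ_b² − 2Σλ_aλ_b(u_a·u_b)² between rank-2 covariance maps;
  classical MDS; k-means (k = 2..10, silhouette-selected); candidate
  regions = runs of ≥ 10 consecutive same-cluster windows with MDS1
  z-score > 1.5.
* **genotyping** — region PCA with Patterson scaling (centre 2p̂, scale
  √(p̂(1−p̂))), 1-D k-means on PC1 started at min/mid/max, heterozygosity
  validation of the middle cluster, projection genotyping of new samples,
  diagnostic-SNP ML calls for low-coverage panels, HWE chi-square.
* **popgen** — vcftools-style geno-r² (MAF > 5%, 1 kb thinning, mean r²
  between 500 kb windows) and windowed Hudson F_ST (ratio of sums).
* **cross_recomb** — crossover counting in F2 intercross ancestry panels
  with error-run cleaning; cM/Mb = 100·crossovers/(2·n_F2) per Mb.
* **annotation_stats** — pN/pS and π_N/π_S in 500 kb windows with Welch
  t-tests; TSS distances; binomial gene-disruption test; KS test of
  segmental-duplication density at breakpoints.
* **adaptation** — two-deme Wright–Fisher simulation with divergent
  selection, migration and λ-rescaling (Nm, Ns invariant); ten-family
  hybrid-zone cline fitting ranked by AICc; additive genotype–trait
  association with PVE and Bonferroni correction.
* **synthetic_data** — seeded generators for every input the pipeline
  takes, with truth tables for scoring.

## Worked example

Simulate 30 diploids on a 50 Mb chromosome carrying a 5 Mb inversion at
frequency 0.3, scan it, genotype it, and measure arrangement F_ST:

```python
import numpy as np
from invscan import (PopulationSpec, InversionSpec, simulate_population_vcf,
                     scan_genome, call_inversion_genotypes, hudson_fst_windowed)

pop = PopulationSpec()            # 30 diploids, 50 Mb chromosome, 2 SNPs/kb
inv = InversionSpec()             # 5 Mb inversion at 20-25 Mb, freq 0.3
gm, truth = simulate_population_vcf(pop, inv, seed=1)

regions, mds, labels = scan_genome(gm, chrom_lengths={"chr1": 50_000_000}, seed=1)
r = regions[0].region
print(f"detected {len(regions)} region: {r.chrom}:{r.start:,}-{r.end:,} "
      f"({regions[0].max_run_length} windows)")

call, pca = call_inversion_genotypes(gm, r)
counts = np.bincount(call.genotype, minlength=3)
print(f"genotype counts 0/1/2: {counts[0]}/{counts[1]}/{counts[2]} "
      f"(truth {np.bincount(truth.inv_genotype, minlength=3)})")
print("het % by cluster:", np.round(call.het_by_cluster, 1),
      " HWE p =", round(call.hwe['p'], 3))

g0 = [gm.sample_ids[i] for i in np.nonzero(call.genotype == 0)[0]]
g2 = [gm.sample_ids[i] for i in np.nonzero(call.genotype == 2)[0]]
fst = hudson_fst_windowed(gm, g0, g2, window_size=1_000_000,
                          chrom_lengths={"chr1": 50_000_000})
inside = [w.fst for w in fst if w.window.start >= r.start and w.window.end <= r.end]
outside = [w.fst for w in fst if w.window.end <= r.start or w.window.start >= r.end]
print(f"mean homozygote-class F_ST inside inversion: {np.nanmean(inside):.3f}; "
      f"outside: {np.nanmean(outside):.3f}")
```

Output:

```
detected 1 region: chr1:20,000,000-25,000,000 (50 windows)
genotype counts 0/1/2: 16/12/2 (truth [16 12  2])
het % by cluster: [28.5 52.5 28.3]  HWE p = 0.901
mean homozygote-class F_ST inside inversion: 0.461; outside: -0.000
```

The scan recovers the planted region to the window; all 30 genotype calls
match the simulator's truth; the middle (heterozygote) cluster shows
roughly double the homozygote heterozygosity; and arrangement F_ST forms a
block inside the inversion while staying at zero outside — the full
signature set the method is built on.

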