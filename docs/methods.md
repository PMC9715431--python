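# Methods

`invscan` implements a population-genomic workflow for finding and
characterising large (megabase-scale) chromosomal inversion polymorphisms
from genotype matrices, together with synthetic-data generators that
reproduce the statistical structure each stage relies on. This note
describes the models, the parameters that matter, the numerical choices,
and what the synthetic data do and do not emulate.

## Detection: local PCA / MDS scan

Sample structure is summarised per 100 kb window (`scan.window_pca`) by the
top two eigenpairs of the sample–sample covariance of mean-centred dosages
(missing dosages mean-imputed per SNP, monomorphic sites dropped, windows
with fewer than 10 polymorphic SNPs excluded). Eigenvalues are divided by
the window's covariance trace so windows with different SNP counts are
comparable; this normalisation is configurable but is the default for all
results here.

Dissimilarity between two windows' "PCA maps" is the Frobenius distance
between their rank-2 covariance reconstructions,

    d² = Σ λ_a² + Σ λ_b² − 2 Σ_{a,b} λ_a λ_b (u_a · u_b)²,

which is cheap to evaluate from the eigenpairs and is verified in the test
suite against dense reconstructions. Windows are embedded by classical
(Torgerson) scaling — eigendecomposition of −½ J D² J with negative
eigenvalues truncated — and clustered by k-means over (MDS1, MDS2) for
k = 2..10 with 10 seeded restarts, choosing k by maximal mean silhouette
(ties toward smaller k). A candidate region is a maximal run of at least 10
consecutive same-chromosome, same-cluster windows whose genome-wide MDS1
z-score exceeds 1.5 (one-sided by default; an absolute-value mode exists).
Excluded windows break runs; runs never span chromosomes. MDS axis signs
are fixed by making the largest-magnitude coordinate positive, which makes
the one-sided test orient the minority (outlier) windows positive.

Two ambiguities had to be resolved: the z-score is computed genome-wide
(not per chromosome), and runs are not allowed to jump excluded windows.
Both choices are the stricter reading and are exercised by tests.

## Genotyping

Within a candidate region, PCA over all region SNPs (no MAF filter or
thinning) with Patterson scaling — centre by 2p̂, divide by √(p̂(1−p̂)),
missing dosages imputed to the SNP mean — yields PC1 scores along which
samples form three clusters: the two arrangement homozygotes at the
extremes and heterozygotes in the middle. 1-D k-means with starting centres
at the minimum, middle and maximum PC1 score (plain Lloyd iterations,
deterministic) assigns genotypes; if a cluster empties, k = 2 is retried.
The middle cluster must show the maximal mean heterozygosity (% of
non-missing sites heterozygous); if it does not, the call set is flagged
`ambiguous` rather than reassigned. Hardy–Weinberg deviation is tested with
the asymptotic Pearson chi-square (df = 1, no continuity correction).

New samples are genotyped by projection: their dosages are scaled with the
*training* allele frequencies, projected on the stored loadings, and
assigned the nearest cluster mean on PC1 — unless the distance exceeds
half the adjacent inter-centre gap, in which case the call is missing
(the ambiguity margin is configurable). For low-coverage panels a
diagnostic-SNP caller assigns the maximum-likelihood genotype from allele
counts at arrangement-diagnostic SNPs under per-read error ε (default
0.01); it replaces a full ancestry HMM and achieves ≥95% accuracy at 2
reads × 50 SNPs in simulation.

## LD and differentiation

LD follows the `geno-r2` convention: squared Pearson correlation of
dosages over pairwise-complete samples (pairs with fewer than 4 complete
samples skipped), after a strict MAF > 5% filter and thinning to one SNP
per kb, summarised as the mean r² over all cross-window SNP pairs for
500 kb window pairs. Background SNPs in the simulator are independent, so
the inversion's block of elevated inter-window r² — present with all
genotypes, absent within a homozygote class — is unambiguous.

Differentiation uses the Hudson F_ST estimator with windowed
ratio-of-sums: per SNP, num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)
and den = p₁(1−p₂) + p₂(1−p₁) with n counted in alleles; a window's F_ST is
Σnum/Σden. Negative values are reported as computed. Note that comparing a
group of samples against itself gives ≈ −1/(n_alleles−1), not exactly zero
— a property of the sample-size correction, asserted in tests. Defaults:
10 kb windows for inversion-vs-standard haplotype F_ST, 100 kb for
ecotype-vs-ecotype scans. Loess smoothing of F_ST tracks is presentation
only (statsmodels lowess, default span 5% of the chromosome).

## Recombination from F2 intercrosses

Crossovers are counted as ancestry state changes (AA/AB/BB) along ordered
markers; an AA↔BB transition counts two. Map length is
cM = 100 × crossovers / (2 n_F2) — two meioses per F2 — and the rate is
cM per Mb of interval, attributing each crossover to the interval
containing its flanking-marker midpoint (half-open). Within an inversion,
only F2s from inversion-heterozygous F1 parents are informative.

Genotyping error is handled by parsimony cleaning instead of an HMM:
interior single-marker switches are always removed; interior runs up to
`max_error_run_len` markers are removed only when both flanks share a
state (a short heterozygous run *between* the two homozygous states is the
genuine crossover path and is kept); terminal runs are never removed,
because a terminal switch is indistinguishable from a real crossover near
the chromosome end and removal cascades. `max_error_run()` derives the
cleaning length from the error model: the longest run L for which
errorᴸ ≥ (rate × spacing / 100)², i.e. where L consistent miscalls are
more likely than two flanking crossovers — the same decision an ancestry
HMM makes at these rates. At 0.5% error, 0.8 cM/Mb and 100 kb markers this
gives L = 2. Two known biases are accepted and documented: double
crossovers between adjacent markers are invisible (downward bias at sparse
markers), and cleaning removes genuine double crossovers spanning ≤ L
markers (negligible at ≤2 markers and ≲1 cM/Mb).

## Mutational load

Coding SNPs are classified by swapping the alternate allele into the
reference codon (strand-aware, standard genetic code); codons carrying more
than one variant are excluded — conservative, since the reference behaviour
of the package this mirrors is undocumented. Per 500 kb window and within a
set of samples homozygous for one arrangement, pN and pS count segregating
nonsynonymous/synonymous sites and π_N, π_S average the unbiased per-site
diversity 2p̂(1−p̂)·n/(n−1) over those sites; ratios with zero denominators
are flagged and excluded. Welch (unequal-variance) t-tests compare
inversion vs standard windows (two-sided) and each against genome-wide
windows (one-sided for enrichment); Welch matches the R default this
pipeline mirrors, with a pooled-variance flag available.

## Breakpoint annotation

Distance to the nearest transcription start site and an in-gene flag are
computed per breakpoint. Gene disruption is tested with the two-sided
binomial test under the minimum-likelihood rule (the `binom.test`
convention), with gene density always recomputed from the supplied
annotation as union(gene spans)/genome length — the published 39% only
reproduces with the original annotation. Segmental-duplication enrichment
compares SD density in ±500 kb breakpoint flanks (truncated at chromosome
edges, realized length as denominator; chromosome-end breakpoints excluded)
against random genomic sites with a two-sample Kolmogorov–Smirnov test. SD
interval filters (≥1 kb, ≥70% identity, <70% common-repeat masking) are a
declarative function over externally provided interval tables; SD discovery
itself is out of scope.

## Divergent selection

A two-deme Wright–Fisher model (forest/prairie) iterates
selection → migration → binomial drift each generation; fitnesses are
1+s, 1+hs, 1 with h = 0.5 by default (the simulator convention for
unspecified dominance), deme-specific s, symmetric migration m, and the
variant introduced in one deme t_intro generations before present
(t_split = 2.2 × 10⁶ generations is the only anchored time; other
demographic values are config-driven placeholders). Rescaling by λ divides
N and times and multiplies m and s by λ, keeping Nm and Ns invariant; the
default λ = 100 keeps runtimes low, and scaled |s| is bounded at 1. The
event order matters at large scaled s, which is why it is fixed and stated.
The summary statistic is the fraction of replicates whose final
|p_forest − p_prairie| exceeds 0.5.

Two subtleties of single-copy introduction: (1) the initial frequency
1/(2N) is *not* scale-invariant, so the λ-equivalence validation fixes a
common `init_freq` across scalings; (2) establishment from one copy is a
branching process with survival ≈ 0.58 at scaled s = 1, h = 0.5, so even
arbitrarily strong divergent selection cannot push P(|Δp|>0.5) to 1 from a
single copy — the near-1 regime applies to established variants, and the
tests start there when probing it.

## Clines

Allele frequency along a transect follows
p(x) = pMin + (pMax−pMin)·g(x) with centre sigmoid
g(x) = (1 + tanh(2(x−c)/w))/2. Beyond distance δ from the centre an
exponential tail replaces the sigmoid, continuous in value at the junction
with initial slope τ × the sigmoid slope there (τ ∈ (0,1]; `mirror` shares
one δ, τ on both sides, `both` fits them separately). This is the standard
hybrid-zone tail parameterisation expressed in a form that guarantees
junction continuity; the internal form of the MCMC package it replaces is
not published. Ten families (fixed/free scaling × none/left/right/mirror/
both) are fitted by bounded L-BFGS-B maximum likelihood on the binomial
log-likelihood, 20 restarts (one informed by the empirical frequency
profile, the rest random within bounds), and ranked by
AICc = −2lnL̂ + 2κ + 2κ(κ+1)/(n_sites−κ−1); families with n_sites ≤ κ+1 are
skipped, and ties resolve toward fewer parameters. With nine sites the
8-parameter free/both family is undefined and silently absent.

## Associations

Trait ~ genotype (+ body length) by least squares, genotype coded 0/1/2.
The genotype p-value is the sequential-ANOVA F test (genotype entered
first, F against the full-model residual), PVE is the genotype sum of
squares over the total, and Bonferroni multiplies by the number of
inversions tested (default 13, capped at 1).

## Synthetic data: what it does and does not emulate

The population generator embeds two haplotype classes in a recombining
background: outside the inversion every haplotype draws alleles
independently per SNP from a Uniform(0.05, 0.5) frequency law (random
allele orientation); inside, haplotypes join the inverted class with
probability `inv_freq` (HWE pairing unless an inbreeding-style deviation is
set) and a fraction `divergence` of region SNPs carry class frequencies
differing by exactly `delta_af`. Defaults are the detection study
conditions: a 50 Mb chromosome at 2 SNPs/kb (typical hard-filtered
mammalian WGS density; 200 SNPs per 100 kb window keeps per-window
eigenstructure stable, and a 5 Mb inversion is 10% of windows, preserving
the genome-wide z contrast), n = 30 diploids, inversion frequency 0.3,
divergence 0.3 with |Δp| = 0.9 at divergent sites.

Deliberate simplifications: no background LD (so the inversion's block
signal is unambiguous — real genomes have decaying LD that adds noise, not
structure, at these scales), allele-frequency contrasts instead of a
coalescent history (sufficient for PCA/LD/F_ST/heterozygosity signatures;
no site-frequency-spectrum realism), no crossover interference (pure
Poisson), and one chromosome per run by default. Passing tests therefore
demonstrate that the estimators recover the structure they target under
the model's assumptions, not that real data meet those assumptions.

The cross generator places Poisson crossovers (rate × L/100 per gamete)
with uniform positions, zeroes them inside inversions heterozygous in the
F1 parents, and reports marker states with independent miscall
probability. The transect generator draws Binomial(2n, p(x)) allele counts
under a true cline. The coding-region generator writes random sense-codon
genes (alternating strands) and plants at most one variant per codon —
synonymous variants segregating in all samples, nonsynonymous ones only
within their sample class — so truth tables score the classifier exactly.
Phenotypes are additive (a·g + b·body length + Gaussian noise; body length
~ Normal(92 mm, 4 mm), the deer-mouse scale).

All generators are deterministic given their seed.

## Problem sizes

The shipped validation uses desk-scale problem sizes chosen to keep the
whole suite in minutes while leaving Monte-Carlo margins comfortable:
detection and null specificity over 20 seeds each at the defaults above;
recombination targets at 300–500 F2 × 100 Mb; scaling equivalence at 1,000
replicates; cline recovery at 15 sites × 50 diploids × 20 seeds;
association calibration at 500 null replicates and effect recovery at
n = 547 (the published F2 panel size) with a 2.7 mm planted effect.
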