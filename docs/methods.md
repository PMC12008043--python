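# Methods

`urbanpopgen` analyzes reduced-representation (GBS) SNP data sampled along
an urbanization gradient: genetic diversity, differentiation, spatial
structure, and the demographic history of effective population size (Ne),
ending in a breakpoint regression that delimits periods of constant
exponential growth or decline. This note records the models, the default
parameters and why they hold their values, what the synthetic data do and
do not emulate, and the numerical choices that a maintainer would
otherwise have to reverse-engineer.

## Data model

Genotypes are biallelic SNP calls coded as alternate-allele counts
{0, 1, 2} with a missing code, organized as individuals x SNPs. Each SNP
belongs to a short locus (default 74 nt, the scale of a PstI GBS fragment
after trimming); the per-locus count of genotyped nucleotide sites
(variant plus invariant) is carried alongside so that per-site diversity
is scaled by all sequence actually genotyped, not only the variant
positions. Sampling metadata attach each individual to a sampling site
with WGS84 coordinates and an optional externally measured urbanization
score.

## Filtering and relatedness

Two filtered datasets mirror the two-criteria design common in GBS
studies: a permissive dataset that keeps rare variants (MAF floor of two
copies per sampled individual count, call rate >= 0.5) for diversity and
demographic analyses, and a strict dataset (MAF >= 0.05, call rate
>= 0.75) for structure analyses and F_IS. Both keep a single SNP per
locus, chosen as the smallest position (ties broken by allele strings),
to avoid intra-locus linkage. MAF is always a fraction of non-missing
allele copies.

Relatedness uses the method-of-moments IBS/IBD decomposition (the PLINK
`--genome` PI_HAT convention) with factorial-moment corrections for
sample-estimated allele frequencies; a plain IBS fraction is available.
One member of each pair inside the configured identity band
(0.25–0.75, i.e. half-sib or closer but not clonal) is removed — the
member with more missing data, ties to the lexicographically larger id.
The estimator's sampling noise with a few hundred markers is of order
0.1, large enough to flag unrelated pairs, so pairs sharing fewer than
1,000 informative markers are reported but never pruned.

## Urbanization classification

Distance to the city center uses the haversine formula on a sphere of
radius 6,371.0088 km; at metropolitan scale the difference from an
ellipsoidal geodesic (< 0.5%) is immaterial against a 30 km threshold.
A site is urban by distance iff its centroid lies within 30 km
(inclusive), and urban by score iff its urbanization score is positive
(score 0 is rural). Both labelings are carried side by side.

## Diversity statistics

Per SNP, nucleotide diversity is the unbiased pairwise estimator
pi_s = 2 a (n - a) / (n (n - 1)) on non-missing allele copies; unit-level
pi divides the summed pi_s by the total genotyped sites (a variant-sites-
only denominator is available). Watterson's theta is S / (a1 L) with the
harmonic number a1 evaluated at the unit's median allele-copy count — a
deterministic compromise for uneven missingness that avoids projecting
the data at this stage. Observed/expected heterozygosity use the
small-sample correction n/(n-1); per-site F_IS = 1 - Ho/He is averaged
over sites polymorphic within the unit (monomorphic sites are excluded,
not zero-filled). Tajima's D uses the canonical constants at the median
copy count of each 100 kb window; windows tile each chromosome from
position 1, the last partial window is kept, and windows with S < 2 are
flagged undefined and excluded from the t-tests. Group means of windowed
D are compared to zero by one-sample t-tests and to each other by
Welch's t.

The site-level urbanization model is a fixed-effects linear regression of
a site statistic (pi or F_IS) on one urbanization metric plus the number
of genotyped individuals, fitted by least squares (equivalently ML for
the Gaussian model); each term's type-II Wald chi-square is reported.
Sites with a single genotyped individual are excluded.

## Differentiation

Hudson's F_ST between two sampling sites is the ratio-of-averages
estimator: per SNP, numerator (p1-p2)^2 - p1(1-p1)/(n1-1) -
p2(1-p2)/(n2-1) and denominator p1(1-p2) + p2(1-p1), summed across SNPs
before dividing. The sampling-correction denominator defaults to allele
copies, with an individuals-count option; sites with one genotyped
individual are excluded either way because the correction is undefined.

AMOVA partitions squared Euclidean distances between individual
allele-count vectors (missing entries mean-imputed per SNP) over
habitat / site / individual, with the standard unbalanced-design
coefficients. Significance per component permutes the exchangeable units:
whole sites among groups, individuals among sites within their group, and
individuals across all sites (tested one-sided toward smaller within-site
variance). PERMANOVA and PERMDISP are implemented directly — pseudo-F
from the within/among partition of the distance matrix, and an ANOVA F on
distances to own-group centers (spatial median by default, centroid
optional) after a principal-coordinate embedding restricted to
positive-eigenvalue axes (a warning fires if > 10% of the eigenvalue mass
is negative). All permutation tests report the add-one p-value
(1 + #{stat_perm >= stat_obs}) / (1 + n_perm) and take a seed. Default
permutation counts are 999 and configurable. Note one design caveat
established during calibration: with very few sites per group the
site-to-group permutation space is coarse (for 4 + 4 sites, only 35
distinct partitions), which makes the among-group p-value visibly
conservative; null-uniformity checks use at least 6 sites per group.

## Spatial structure

PCA runs on the mean-imputed centered genotype matrix (full SVD, so
results are deterministic). Mantel correlograms use equal-width
geographic distance classes with the class count from Sturges' rule on
the number of pairs; the per-class statistic is the correlation between
genetic distances and class membership, sign-flipped so positive means
within-class genetic similarity; p-values come from joint row/column
permutations and receive a progressive Holm correction, and classes
beyond the median distance are flagged low-power. Moran eigenvector maps
are built from the pairwise great-circle distances truncated at the
largest minimum-spanning-tree edge (beyond-threshold entries set to four
times the threshold), double-centered, and eigendecomposed; positive-
eigenvalue eigenvectors form the orthonormal spatial basis. Forward
selection against genotype PC scores adds the MEM with the largest
incremental R^2, tests it with a max-statistic permutation of response
rows, and stops at the first non-significant candidate or when the
selected model's Ezekiel-adjusted R^2 would exceed the full-basis
model's (the standard double stopping rule). When nothing is selected the
report states that the data are consistent with a single panmictic
population. The exact truncation and selection defaults of existing MEM
software are not published in detail; this construction is the package's
documented stand-in.

## Demographic reconstruction

The folded SFS is built per analysis group by hypergeometric projection
of each SNP's minor-allele count to a fixed even number of copies
(default 0.8x the maximum observed, rounded down to even); SNPs with too
few called copies, or monomorphic after projection, are dropped and
counted. Projection draws one hypergeometric sample per SNP (seeded); an
exact-expectation mode exists for validation.

Ne histories are estimated stairway-style: one Ne parameter per
coalescent lineage-count interval, grouped into contiguous blocks. Under
this parameterization the expected unfolded spectrum

    E[xi_i] = mu L sum_k k E[T_k] p(i|k),   E[T_k] = 2 N_k / C(k,2),
    p(i|k) = C(n-i-1, k-2) / C(n-1, k-1)

is linear in the block Ne values, so the Poisson composite likelihood of
the folded bins is convex in Ne and the box-constrained quasi-Newton fit
reaches the global optimum. Block boundaries are found by exhaustive
search at two and three blocks and greedy augmentation beyond; the number
of blocks is chosen on a 67%/33% train/test thinning of the spectrum with
a parsimony penalty of one held-out log-likelihood unit per free block,
and the boundaries are then re-placed on the full spectrum.
Two degeneracies are handled explicitly: (i) the likelihood is flat in
the duration of a vanishing epoch, so fits with any block pinned at the
Ne floor (1.0) are time-collapse artifacts and are excluded from model
selection and from the bootstrap; (ii) the recent end of the history is
informed only by the excess of rare variants, a signal of a few dozen
counts per 10^4 SNPs, so recovering a severe recent decline needs a few
tens of thousands of loci (the decline-recovery experiments use 24,000).
Uncertainty comes from multinomial bootstrap over SFS bins (default 200
replicates; bootstrap refits that fail or collapse are excluded with a
count), summarized as the 2.5/50/97.5 percentile trajectory on a common
year grid. Defaults: mutation rate 1.8e-8 per site per generation,
generation time 2 years; a sensitivity sweep re-runs the fit over grids
of both (the defaults match published herbaceous-plant rates and the
study system's life history). Exact expectations for arbitrary
piecewise-constant time histories use the lineage-count death chain
integrated per epoch via the matrix exponential of its bidiagonal
generator, with a Monte Carlo genealogy mode as cross-check.

The composite likelihood treats folded bins as independent Poisson
counts; this matches the multinomial up to the total-S term and ignores
linkage between SNPs of the same locus, which the one-SNP-per-locus
filter keeps small.

## Breakpoint regression

ln(Ne) at systematically subsampled years (every year 1–100, every 19th
year 100–2,000, every 130th year 2,000–15,000; 300 points after
deduplication) is modeled as piecewise linear in time. Under exponential
change Ne_t = Ne_0 (1+r)^t the slope within a period is b = ln(1+r);
because the axis runs backwards in time the forward-time rate is
r = -(e^b - 1) and its CI is the slope CI transformed with endpoints
swapped. Trajectory values are read with step-function semantics (most
recent step at or before t), matching the stepwise estimator output.

Breakpoints are estimated by Muggeo's iterative linearization (regress on
{1, t, (t-psi)+, -1[t>psi]}, update psi by gamma/beta, iterate to 1e-6).
Models grow one breakpoint at a time: candidates come from an exhaustive
single-breakpoint augmentation scan of the previous solution plus staged
initializations fitted within each of the three subsampling ranges; the
fixed-design scan guarantees the RSS never increases with k. Breakpoints
are re-sorted each iteration and merged when fewer than two grid points
separate them. Segment-slope CIs use the OLS covariance with a numerical
floor on the residual variance (1e-8 of the response scale) so that an
exact interpolation cannot turn round-off-level slopes into significant
effects; breakpoint standard errors use the delta method on gamma/beta.

## Synthetic data

The generator draws one genealogy per locus (msprime, no intra-locus
recombination, loci independent) under single-population piecewise-
constant Ne or a symmetric two-deme model, and places Poisson
infinite-sites mutations branch-proportionally in an in-package pass
(statistically equivalent to a binary infinite-sites mutation model;
asserted against msprime's own mutation engine in the test suite). Each
mutation gets a distinct integer position in its 74 nt locus; in the rare
overflow case surplus mutations are dropped and counted. Loci are laid
1 kb apart on one chromosome so windowed statistics see a realistic
position axis. Presets: `null_panmixia` (constant Ne 65,000, chosen so
2,000 loci at 40 sampled copies carry roughly 3,000 segregating sites at
mu = 1.8e-8 — the data scale of a large outcrossing plant),
`fragmentation` and `facilitation` (two demes, scaled migration M = 4 and
24), and `decline` (100-fold collapse from Ne 100,000 to 1,000 at
generation 500). The migration knob is calibrated so that the two-deme
Hudson F_ST expectation is 1/(1+M): for symmetric demes of size N the
coalescent gives F_ST = 1/(1+8Nm), so the per-lineage migration rate is
m = M/(8N).

The landscape generator scatters urban sites one per 2.5 km grid cell
within 30 km of the city center and rural sites one per 10 km cell
beyond, with 1–5 individuals per site separated by more than 3 m
(distinct ramets), an optional transect, and a synthetic urbanization
score (a noisy decreasing function of distance — labelled synthetic
because the real score is an external image-analysis measurement).
Missingness masks genotypes uniformly; full-sib pairs are planted by
Mendelian sampling from a parent pair whose rows the children replace.

What the synthetic data deliberately do not emulate: clonal ramet
structure beyond the sib utility, selection, recombination and linked
sites, sequencing-depth-dependent genotyping error, overlapping
generations, and allele dropout — so passing tests demonstrate the
statistical machinery under the stated coalescent assumptions, not
robustness to those real-data complications.

## Problem sizes in the checks

The bundled end-to-end checks use desk-scale sizes chosen for stable
statistics: 200 neutral replicates of 2,000 loci for estimator
calibration; 50 seeds x 1,000 loci per migration setting for F_ST;
500 structureless datasets with 99 permutations each for null
uniformity; three replicate simulations of 24,000 loci, summarized by
their median, for the decline recovery (the recent end of the SFS
likelihood is information-limited, so a single replicate's ratio is
noisy) and 6,000-locus constant controls; smoke-scale runs (hundreds of
loci) for pipeline determinism. The reproduction script uses the same designs at reduced
replicate counts.

## Known limitations

- The Ne estimator's recent end is resolution-limited (see above);
  absolute recent Ne below the identifiable scale is reported at the
  resolution floor rather than extrapolated.
- Hudson F_ST between tiny sites (2–5 individuals) is noisy and often
  negative; group means are the meaningful summary.
- The urbanization regression is a fixed-effects approximation; with a
  single statistic per site there is no within-site replication to
  support a random-effects structure.
- Mantel correlograms and MEM selection have limited power at a few
  dozen sites; a null verdict is "no detectable structure", not
  demonstrated panmixia.
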