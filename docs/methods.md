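# Methods

`admixcape` characterizes admixture in diploid biallelic SNP panels: where
an admixed population's ancestry comes from (f3/f4 tests, supervised
ancestry fractions, shared private alleles), when it happened (weighted-LD
decay dating), and what it did to the genome (locus-specific branch
lengths, haplotype-homozygosity selection scans, runs of homozygosity).
Because the motivating use case — a recently founded, predominantly
European colonial population with ~5% combined African and Asian ancestry
— relies on access-restricted genotype data, the package ships a synthetic
cohort generator whose statistical structure stands in for that data, and
every method is validated by parameter recovery against the generator's
known truth.

## The synthetic world

**Source panels.** K source populations diverge from a common ancestral
allele-frequency spectrum under the Balding–Nichols model: for ancestral
frequency p and divergence F, the source frequency is drawn from
Beta(p(1−F)/F, (1−p)(1−F)/F), so E[p_k] = p and Var[p_k] = F·p(1−p).
The ancestral spectrum defaults to Uniform(0.05, 0.95), which avoids
monomorphic SNPs that several statistics must otherwise skip; all emitted
frequencies are clamped to [1e−6, 1−1e−6].

**Admixture.** The admixed population forms in a single pulse g
generations before sampling. Each haplotype is a Markov mosaic along the
genetic map: ancestry switch points are a Poisson process of rate g per
Morgan, and each tract's ancestry is drawn independently from the
proportion vector α. This is the simplest process whose ancestry
autocorrelation at genetic distance d is exactly exp(−g·d) — which makes
the weighted-LD decay curve a single exponential with rate g, the same
model the dating module fits. Truth emitted per run: phased haplotypes,
tracts tiling each chromosome, and realized per-individual ancestry
fractions.

**Default sizes** (chosen once for adequate statistical power, not tuned
to any test outcome): one 2-Morgan chromosome at 1 cM/Mb, 20,000 evenly
spaced SNPs, five source panels of 80 diploids each (the motivating study
downsampled its comparative panels to 80), 200 admixed diploids,
α = (95.3, 1.7, 1.3, 0.9, 0.8)% across sources labelled EUR/SAS/KHS/EAS/WAF
with divergences F = 0.10/0.10/0.20/0.12/0.15, pulse at g = 9.3
generations. Haplotypes pair at random (no inbreeding): runs of
homozygosity therefore essentially never arise in simulated cohorts, and
the RoH caller is validated on planted autozygous segments instead.

**What the generator does not emulate:** background LD within sources
(SNPs are independent given ancestry), recombination-map heterogeneity,
genotyping error and missingness patterns, array ascertainment of SNPs,
selection, multiple admixture pulses, and pedigree structure. A green
recovery test therefore establishes correctness of the estimator under
the stated model, not robustness to real-data artifacts.

## Statistics

**QC** (order: structural removals → individual missingness 15% → SNP
missingness 10% → exact HWE p < 0.001 → A/T, C/G removal) mirrors
standard array practice; SNP statistics are recomputed after sample
removal. The HWE test is the plain exact test (no mid-p). On
multi-population cohorts the pooled test is confounded by the Wahlund
effect and preferentially removes the most differentiated SNPs (~22% of
SNPs in the default cohort), so the pipeline tests HWE within each
population and removes a SNP that fails in any. Merging keeps overlapping
(chrom, pos), complements the second dataset's alleles at most once
(strand flip), recodes swapped ref/alt, and drops irreconcilable sites.
Relatedness is a PI-HAT-style method-of-moments IBD decomposition of
genome-wide IBS given sample allele frequencies, thresholded at 0.25
(conventional second-degree cutoff); raw mean IBS is reported alongside.

**FST** is the Weir–Cockerham (1984) variance-components estimator;
per-SNP values may be negative and are used as-is, the genome-wide value
is the ratio of summed components. **LSBL** for target T against
references R1, R2 is (FST(T,R1) + FST(T,R2) − FST(R1,R2))/2 per SNP; no
clamping, which preserves exact additivity of the three branch lengths.
Peaks are called greedily: the highest remaining SNP seeds a peak and
absorbs unassigned SNPs within 500 kb on its chromosome.

**f3/f4** use population allele frequencies from non-missing calls
(minimum two diploids per population per SNP; SNPs with any undefined
frequency are dropped per statistic). f3(T; A, B) averages (t−a)(t−b); by
default the target sampling-noise term h_t/n_t (h_t the unbiased
heterozygosity, n_t the sampled allele count) is subtracted, and the
uncorrected value is reported alongside. Standard errors come from a
weighted delete-one-block jackknife (Busing form) over 5-cM map blocks
(5 Mb physical fallback). Z is defined as 0 in the degenerate case of
value and SE both exactly 0.

**EHH/iHS/XP-EHH.** EHH uses the unbiased pair-counting estimator
Σ C(n_h,2)/C(n_core,2); note this is O(1/n) sensitive to duplicating all
haplotypes (the frequency-squared estimator would be exactly invariant).
Computation truncates below EHH = 0.05 and at inter-SNP gaps > 200 kb
(truncation, not penalization); integration is trapezoidal over cM up to
the last point at or above the floor. iHS = ln(iHH_ancestral /
iHH_derived), standardized within derived-allele-frequency bins of width
0.05 (bins under 20 SNPs merged left-to-right); ancestral states come
from unanimous non-missing outgroup alleles. XP-EHH determines each focal
SNP's truncation extent on the pooled haplotypes of both populations and
integrates each population over that shared extent — this makes
self-comparison identically zero and population swap an exact sign flip —
then standardizes genome-wide.

**RoH** follows the scanning-window heuristic with the conventional
parameters (5 Mb windows anchored at every SNP, ≤ 1 heterozygote and ≤ 5
missing calls per homozygous window, hit-rate ≥ 0.05, segments ≥ 500 kb,
≥ 25 SNPs, ≤ 50 kb/SNP density, split at > 100 kb gaps). Windows shrink
at chromosome edges; a SNP's denominator counts the windows that contain
it. The missing-call cap matters: without it a fully masked ancestry
tract (no evidence at all) reads as a long homozygous run.

**Shared private alleles** are rarefied exactly: with k of n sampled
copies, P_present at subsample size g is 1 − C(n−k, g)/C(n, g); a
shared-private contribution multiplies presence in both focal populations
by absence in every other population's subsample. Loci with fewer than g
copies in any population are excluded and counted. The curve is provably
non-decreasing in g only without third populations; with them, larger
subsamples also detect the allele elsewhere, and the expectation can
decrease (counterexample: counts A 2/2, B 2/2, C 1/2 gives 0.5 at g=1,
0 at g=2).

**Weighted-LD dating** averages, per genetic-distance bin (0.1 cM bins
over 0.5–30 cM), the admixed-sample genotype covariance of SNP pairs
weighted by δ(l1)δ(l2), δ = reference frequency difference. The curve is
fit by weighted least squares to A·exp(−n·d) + c, with A and c profiled
out analytically and n found by bounded multi-start 1-D minimization
(starts 1, 5, 10, 50, 200; noise-free recovery to 1e−6). A fit is failed,
with no rate reported, when A ≤ 0 or n pins at the search bounds. A
delete-one-chromosome jackknife SD of n is available for multi-chromosome
panels. Conversions: years ago = generations × generation time (default
30 y); calendar year subtracts from the mean participant birth year.
Ancestor equivalents express fraction f as f·2^g of the 2^g ancestor
slots g generations ago, truncated (not rounded) to one decimal —
truncation is pinned by the 0.008 × 2048 = 16.384 → 16.3 case.

**Supervised ancestry fractions** maximize, per admixed individual, the
binomial likelihood of genotypes given π_l = Σ_k q_k·p_kl with q on the
K-simplex, by EM. Source frequencies are re-estimated within the EM from
the panel genotype counts under a Beta(1.5, 1.5) prior: treating
panel-estimated frequencies as known puts the panel sampling noise on
both sides of the likelihood and inflates small components (≈ +3%
absolute on a 4.7% non-European total with 80-diploid panels; ≈ +0.2%
with the joint update). Passing explicit frequencies disables the update.
The EM map is accelerated by SQUAREM extrapolation with a monotonicity
fallback, so the recorded objective never decreases. Replicate Q matrices
are grouped into modes by G′ = 1 − ‖Q − Q′P‖_F/√(2C) maximized over
column permutations (exhaustive for K ≤ 8, Hungarian assignment behind an
explicit flag above), linking replicates at G′ ≥ 0.9 and averaging the
largest connected component after alignment.

## Pipeline

`run_pipeline` materializes every default into the written config, fans
one global seed out to per-stage seeds by SHA-256 of the stage name, and
writes per-stage TSV artifacts plus `stage_<name>.json` files from which
the final `report.json` is assembled; re-running with an identical config
hash reuses completed stage files (the cheap deterministic simulation is
regenerated). Interfaces are TSV/JSON throughout; no plots are produced.

## Numerical choices and degenerate inputs

Missing genotypes use a single sentinel (−1), never zero-filled; weighted
LD mean-imputes them for covariance only. Monomorphic SNPs are skipped by
FST and flagged by the scans. All-identical bins fail standardization and
are dropped with a warning. Exact tests (HWE, Fisher) run in log-gamma
space. The G′ normalization √(2C) bounds similarity in [0,1] for
simplex-row matrices; residual normalization differences against other
mode-matching conventions are absorbed by the 0.9 threshold.

## Known limitations

Single-pulse dating only (no multi-wave decomposition or LD-ascertainment
affine correction); no unsupervised clustering or cross-validation over
K; no phasing (the simulator emits phase; real unphased data must be
phased upstream); binary PLINK formats are not parsed; the EHH floor and
gap defaults follow common tooling and are not re-derived.
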