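# Methods

This note documents the models, estimators, numerical choices and known
limitations of `cacao-popgen`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Genotype representation and coordinates

Genotypes are diploid biallelic dosages in {0, 1, 2, missing}. Physical
positions are 1-based everywhere inside the package; all window output
(BED-like tracks) is 0-based half-open, and windows tile each chromosome from
coordinate 0 in fixed physical steps (they are position-anchored, not
SNP-anchored). Multiallelic and indel VCF records are skipped with a logged
count. Sites with more than 50% missing calls can be dropped up front
(`GenotypeMatrix.drop_high_missing`, configurable); the estimators themselves
handle residual missingness per site.

## Diversity estimators

Per-site pairwise diversity uses the unbiased estimator
π_site = n/(n−1) · 2p̂(1−p̂) with n the non-missing haploid count at the site;
window π sums sites and divides by window length. Watterson's θ_W divides the
window's segregating-site count by a_{n−1} = Σ 1/i computed at the window's
median non-missing haploid n — a pragmatic choice under missingness (the exact
likelihood would require per-site sample-size bookkeeping that changes results
only in the third digit at the missingness levels simulated here).

The inbreeding coefficient is the moment estimator F = 1 − Het_obs/Het_exp per
individual, with expected heterozygosity summed over the individual's
non-missing sites at cohort allele frequencies. In a structured cohort the
Wahlund effect inflates F; the estimator is interpreted relative to the cohort,
matching its use in comparing groups.

LD pruning computes r² as the squared Pearson correlation of dosages on
jointly non-missing samples, in 2000-SNP windows advancing with 500-SNP
overlap after a MAF ≥ 0.05 filter. Pruning is greedy left-to-right and removes
the later (higher-index) member of any pair with r² strictly greater than the
threshold (a pair at exactly the threshold is kept), which makes the result
deterministic.

MDS standardizes each site by centering at 2p̂ and scaling by sqrt(2p̂(1−p̂)),
mean-imputes missing dosages (zero contribution after centering), and takes
the top-k left singular vectors scaled by their singular values; eigenvalues
are squared singular values over the site count.

Kruskal–Wallis uses the tie-corrected H with a chi-square reference on k−1
degrees of freedom. The Nemenyi post-hoc p-values use the studentized-range
distribution on mean ranks with infinite degrees of freedom (the large-sample
approximation); no variant is canonical, and this choice matches common
implementations.

The harmonic-mean N_e of an externally supplied trajectory is
t_max / Σ(duration/N_e), the generation-weighted harmonic mean — chosen
because the smallest sizes dominate drift.

## Differentiation

Weir–Cockerham (1984) two-population variance components a (among
populations), b (between individuals within populations) and c (within
individuals) are computed per site from sample sizes, allele frequencies and
observed heterozygosity. Windows report ratio of sums Σa/Σ(a+b+c) — not the
mean of per-site ratios — the standard windowed form; negative per-site
components are retained in the sums, and only final reporting may floor at
zero via a flag. "Low-frequency alleles filtered" is implemented as combined
MAF ≥ 0.05, configurable. Genome-wide summaries are exposed both as ratio of
sums and as the mean of per-site ratios, since published pairwise ranges may
use either. Top-fraction outlier selection flags all windows at or above the
(1−f) empirical quantile, ties included, with ceil(f·n) defining the
threshold rank.

Island-model bookkeeping: with time scaled in 2N_ref generations and scaled
pairwise backward migration m̃ per lineage, the equilibrium two-deme
expectation is F_ST = 1/(1+4m̃) (from between/within coalescence times). The
textbook island-model form 1/(1+4Nm(d/(d−1))²) at d = 2 equals 1/(1+16Nm);
the two agree when m̃ = 4Nm, i.e. the finite-island correction (d/(d−1))² = 4
folds into the pairwise rate. The calibration tests set m12 = m21 = 1.0 to
realize 4Nm = 1 (expected F_ST 0.2).

## Demographic inference

The observable is the folded joint site-frequency spectrum at haploid sizes
(n1, n2): each biallelic site adds one count at its minor-allele coordinate;
with missing data, sites are hypergeometrically projected down to the target
sizes and contribute fractional mass. Cells are folded when
2(i+j) > n1+n2, the fold line is kept at the lexicographically smaller member,
and the monomorphic corner plus the redundant half are masked out of every
likelihood sum. Ancestral states are never required.

Three nested histories are fit: `SI` (an ancestral population of size N_ref
splits T×2N_ref generations ago into populations of relative sizes nu1, nu2;
no migration), `IM` (split with asymmetric scaled migration m12, m21,
receiving-population convention, population 1 held at the ancestral size) and
`IM_B` (IM with a founder bottleneck: population 1 is founded at relative size
nu_B and stays there). The domesticate is population 1.

Expected spectra are estimated by Monte-Carlo branch tallying: simulate
genealogies of the n1+n2 sample under the structured coalescent and accumulate
the branch length subtending exactly (i, j) sampled lineages; the folded,
halved tally times θ = 4N_ref·μ·L gives expected site counts, so the Poisson
composite likelihood profiles θ in closed form (θ̂ = Σobs/Σmodel over unmasked
cells). Model cells that are empty at the Monte-Carlo resolution are floored
at 0.05/reps so rare cells penalize the likelihood smoothly. Anscombe
residuals r = (3/2)(obs^{2/3} − μ^{2/3})/μ^{1/6} diagnose fit quality; AIC
(with the profiled θ counted as a parameter) ranks models.

Two engines implement the same process: a readable Python event-driven
simulator that returns explicit branches for infinite-sites genotype output,
and a numba-compiled tallier for the optimizer's inner loop. They are
cross-validated against each other and against an independent coalescent
simulator (msprime) in the test suite.

### Optimization

The likelihood surface is deterministic given the Monte-Carlo seed (common
random numbers) but locally rugged, and the folded spectrum carries a strong
ridge along which split time trades off against migration. The default search
therefore runs: (1) a warm-started profile over T on a descending log grid
(continuation: each conditional 4-parameter Nelder–Mead starts from the
previous grid point's solution) at 2000 genealogies per evaluation; (2) a
coarse wide-simplex Nelder–Mead from a neutral default start plus optional
log-uniform random restarts; (3) a mid-resolution tournament among the top
candidates; (4) a refinement ladder that quadruples the Monte-Carlo
resolution per rung up to 32,000 genealogies with a tight simplex, so the
simplex stops chasing tally noise and follows the model signal. Optimization
is in log-parameter space with bounds ν ∈ [1e-4, 100], T ∈ [1e-4, 10],
m ∈ [1e-6, 20]. Warm-started fits (bootstrap refits) skip the profile.

Single-replicate maximum-likelihood estimates of T scatter along the ridge —
direct likelihood comparisons at high Monte-Carlo resolution show parameter
sets differing by ~2× in T within a few log-likelihood units of each other at
5×10⁴ folded SNPs and 16+16 haploids — so validation asserts recovery on
medians over independent data replicates, and uncertainty is reported by the
block bootstrap.

### Bootstrap and scaling

Confidence intervals resample contiguous physical blocks (default 1 Mb) of
sites with replacement, rebuild the folded spectrum from precomputed per-block
tallies, and refit from warm starts: the point estimate plus ridge-aware
variants with T nudged down/up (×0.6, ×1.67), letting each refit slide along
the ridge when its resample supports it. Intervals are 2.5/97.5 percentiles
of the B refits; B = 1000 mirrors a full analysis and is reduced for
desk-scale runs. Physical units: N_ref = θ̂/(4μL), per-population sizes
ν·N_ref, T_years = 2·N_ref·T·g, per-generation migration m/(2N_ref); defaults
μ = 7.1×10⁻⁹ (alternate 3.1×10⁻⁹) per bp per generation and g = 5 years.

## Sweep scan

At each grid point (every 2 kb), SNPs within ±0.025 cM (map positions from a
genetic-map TSV by linear interpolation, or a flat 1 cM/Mb default) are used,
deterministically thinned to 200 by index if more. Conditional on the
reference frequency p, the neutral model for the test population's frequency
is Normal(p, ω·p(1−p)) on (0,1) with tail mass below 0/above 1 reassigned to
loss/fixation, compounded with binomial sampling; ω is a genome-wide
method-of-moments estimate with the binomial sampling variance removed,
floored at 0. Near a sweep a site escapes with probability
c = 1 − exp(−d/s̃) (d in Morgans, s̃ a composite selection scale on a 12-point
log grid over [1e-5, 1]); non-escaping sites are dragged to fixation (count
n_B with probability p) or loss. The window statistic is
CLR = 2(max_s̃ loglik − neutral loglik) ≥ 0, with the neutral model as the
boundary case. The neutral integral uses 1000-point midpoint quadrature.

The CLR is a boundary statistic with a point mass at exactly 0 on neutral
data, so the scan ranks only strictly positive scores, capped at the top
fraction (default 1%) of all evaluated windows; a literal "top 1% with ties"
rule would flag every window of a null scan. The generic
`top_fraction_outliers` keeps the tie-inclusive rule for continuous statistics
such as F_ST.

## Burden tests

Annotated sites are classified deleterious iff their SIFT-style conservation
score is ≤ 0.05, and binned by within-population minor allele frequency into
rare (0, 0.25], intermediate (0.25, 0.375], frequent (0.375, 0.5] — bins are
right-closed and sites monomorphic within a population are excluded for it.
MAF is within-population because compared groups have unequal sample sizes.
The log-linear test fits Poisson models with all two-way interactions (null)
versus adding population×effect×bin (full); the LRT has 2 degrees of freedom.
Zero cells are lifted by 0.5 with a warning. The Cochran–Mantel–Haenszel test
stratifies 2×2 (population × effect) tables by MAF bin, without continuity
correction, and reports the Mantel–Haenszel common odds ratio; strata with an
empty margin are dropped.

## Supervised ancestry and the yield model

Ancestry proportions maximize the binomial likelihood
Σ_j [g_j log(Σ_k q_k f_kj) + (2−g_j) log(Σ_k q_k(1−f_kj))] by the standard
admixture EM update with panel frequencies fixed (clamped to [1e-6, 1−1e-6]);
missing sites are dropped, the log-likelihood is non-decreasing by
construction, and convergence is a gain below 1e-6 (cap 2000 iterations).

Yield is fit as a Gaussian GLM y = β₀ + β₁·q_focal + β₂·F + ε on complete
cases. Ancestry enters as a proportion in [0, 1]: β₁ is the yield change over
the full ancestry range, and a per-percent slope (β₁/100) is reported
alongside because both conventions appear in practice. A companion fit
swapping in an alternative population's ancestry separates the domesticate
effect from inbreeding. An ill-conditioned design (ancestry nearly collinear
with inbreeding) attaches a warning rather than failing.

## Synthetic-data generators

* **Coalescent IM genotypes.** Loci are independent and non-recombining;
  infinite-sites mutations are Poisson on branches at θ_locus/2 per unit
  branch length (2N_ref generations); haplotypes pair at random into diploids
  (Hardy–Weinberg within deme). Migration is implemented backwards in time as
  lineage relabeling at the scaled rate of the lineage's current deme
  (receiving-population convention). Seeds split per locus via
  `SeedSequence.spawn`, so output is bit-identical given a seed. Validation
  sizes use many short loci (e.g. 4000 loci for ~5×10⁴ SNPs) so that
  within-locus linkage does not dominate the composite-likelihood noise
  budget. Because consumers analyze frequency summaries, intra-locus
  recombination and sequence-level output are deliberately absent.
* **Forward Wright–Fisher per-site engine.** Reproduction mixes selfing (rate
  σ) with random mating at the genotype-frequency level starting from
  Hardy–Weinberg, so heterozygosity halves per generation at σ = 1 and the
  equilibrium F = σ/(2−σ) emerges dynamically; viability selection uses
  fitnesses (1, 1−hs, 1−s) against the alt allele; drift is multinomial over
  the N diploid genotypes (allele-count binomial sampling would destroy the
  selfing-generated genotype structure). N is diploid individuals throughout.
* **Balding–Nichols panels.** Ancestral frequencies are Uniform(0.05, 0.95);
  population frequencies are Beta with mean p and variance F_ST·p(1−p).
  Cohort individuals carry true inbreeding F_i ~ Uniform(0, 0.3) — cacao
  germplasm mixes outbred hybrids with partially selfed accessions — realized
  as identity-by-descent allele copying, and yields are linear in focal
  ancestry and F_i with Gaussian noise (defaults β₀ = 2000, β₁ = −319.9,
  β₂ = −500 kg·ha⁻¹·yr⁻¹, σ_e = 100).
* **Sweep sampler.** Matches the scan's mixture density exactly: escaped sites
  draw a clipped-normal drifted frequency then a binomial count; swept sites
  emit fixation or loss. Post-sweep drift on the dragged class is ignored,
  keeping generator and scan density self-consistent.

What passing tests show — and what they do not: the generators realize the
modeled processes exactly (no sequencing error, no genotyping bias, no
reference bias, free recombination between loci, equilibrium demography within
epochs), so green validation demonstrates correctness of the estimators and
inference machinery under the stated models, not robustness to the artifacts
of real resequencing data.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` size their simulations for a
single CPU: 600 neutral loci for estimator calibration; 400 windows for the
island model; three independent ~5×10⁴-SNP replicates (16+16 haploids) for
demographic recovery with B = 20 bootstrap refits each; 100 sweep windows of
200 SNPs against a 150–200-window self-generated null plus a 3000-SNP null
scan; 800–2000 null tables for burden-test calibration and 200–300 for power;
three 700-replicate forward batches per arm for the selfing purge; a
40-individual, 5000-SNP cohort for ancestry and 500 regression replicates for
the yield slope. These are the package's chosen study conditions; thresholds
(5% calibration error, 25/30% recovery error, 80% power/coverage, 0.05±0.02
type-I error) are fixed independently of the realized draws.

## Known limitations

* The expected-SFS engine is Monte-Carlo: likelihood values carry tally noise
  (mitigated by common random numbers, the epsilon floor tied to resolution,
  and the refinement ladder), and fits near likelihood ridges inherit the
  scatter described above. A diffusion/ODE expectation would be deterministic
  but is out of scope.
* Folded spectra discard ancestral-state information; split-time/migration
  identifiability is correspondingly weaker than with polarized data.
* The sweep scan omits the LD-based SNP weighting of the original
  cross-population CLR method and ranks rather than calibrates significance.
* `ld_prune` is quadratic per window in the worst case; at the default
  2000-SNP windows it is intended for pre-clustering reductions, not
  genome-scale dense scans.
* The supervised-ancestry panel is treated as fixed and error-free; panel
  sampling noise propagates into q̂ without being modeled.
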