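# Methods

`ficipop` reimplements, as a tested library, the population-genomic
analyses used to characterize the history of the figleaf gourd
(*Cucurbita ficifolia*) and its gene flow with the wild xerophytic
*Cucurbita* of the Mexican highlands: SNP filtering, diversity and
F-statistics, SFS-based coalescent model selection, mismatch-distribution
expansion dating, and ABBA-BABA introgression tests.  The original
genotype data are not redistributable, so a coalescent data generator
with the statistical structure of the fitted models stands in for them;
this note records the models, conventions, defaults, and the limits of
what synthetic-data tests can show.

## Filtering cascade

Nuclear SNPs pass four pure subset filters, in order: missingness
(sites with a missing-genotype fraction above 0.30 are dropped; the
bound is inclusive), distance thinning (greedy left-to-right scan per
chromosome, keeping a site only if it lies ≥ 250 bp from the last kept
site — a deterministic stand-in for "one SNP per locus"), a
Hardy–Weinberg exact conditional test (drop when p < 1e-4, computed on
all samples pooled since the source analysis describes a single
dataset-level filter), and LD pruning (any pair of surviving sites
within 100 kbp with squared dosage correlation above 0.25 loses one
member).  The LD removal policy — drop the member with more missing
data, ties broken against the downstream site — is our deterministic
choice where the original tool's internal rule is unspecified; the scan
order makes the operation idempotent, and r² uses pairwise-complete
observations with a minimum of 4 complete pairs.  Plastome (haploid)
sites instead pass missingness ≤ 0.20, mean depth ≤ 800× (strict), and
exclusion of inverted-repeat intervals supplied as BED (half-open,
0-based, converted to the internal 1-based convention on read).

## Diversity statistics

Per variant site, with p the alternate-allele frequency over the 2n
non-missing copies: π = (2n/(2n−1))·2p(1−p) (unbiased probability that
two sampled copies differ), H_E = 2p(1−p), H_O = the heterozygous
fraction, and F_IS = 1 − H_O/π where π > 0.  Summaries are unweighted
means and sample variances (n−1) over variant sites, so magnitudes are
per-SNP, not per-bp.  F_ST is Hudson-style 1 − ΣH_w/ΣH_t with the
within-group term averaged over groups per site and both terms summed
across sites before the ratio (ratio-of-sums), which avoids per-site
ratio bias and makes the estimator invariant to duplicating sites.

## Coalescent engine

The simulator is a backward-in-time structured coalescent with named
demes, piecewise-constant sizes, split events, hybrid-origin
(admixture) events, and migration, in the continuous-time
approximation, with time in generations.  Conventions that differ
between tools and are therefore fixed explicitly here:

* **Size convention.** `N` is the diploid effective size: pairs
  coalesce at rate 1/(2N) per generation (`ploidy=2`).  Haploid,
  maternally inherited plastome loci use `ploidy=1` (rate 1/N).
* **Migration direction.** Rates are forward-time fractions m[donor →
  recipient]; backward in time each lineage in the recipient jumps to
  the donor at rate m.  Worked example: m[ficifolia → radicans] =
  1.1e-4 means a radicans lineage traces its ancestry into the crop at
  rate 1.1e-4 per generation.  Migration involving a deme that has
  already merged into its ancestor is switched off automatically.
* **One genealogy per SNP** for nuclear matrices (free recombination
  between loci, matching LD-pruned data) and a single genealogy for the
  non-recombining plastome.

The expected SFS uses the branch-statistic estimator: entry j is the
mean total branch length subtending exactly j sampled lineages, with no
mutation dropping, normalized over polymorphic classes.  For a single
unstructured deme this is computed by a vectorized time-rescaled path
(epoch-wise inversion of exponential waiting times plus random pair
merging across replicates); the structured engine is event-driven.  The
two paths are statistically identical and their agreement is tested, as
is agreement with an independent simulator (msprime) on a bottleneck
model.  Genotype-level inbreeding is modelled by a coefficient f — the
probability that an individual's two allele copies at a site are copies
of one of them — rather than by selfing genealogies; this is sufficient
to reproduce and recover the crop's heterozygote deficit (F_IS ≈ f) and
keeps the genealogy process neutral.

## Composite-likelihood model selection

The composite log-likelihood of an observed spectrum is Σ m_j ln p_j
over unmasked entries, with monomorphic classes always masked
(conditioning on polymorphism) and expected probabilities floored at
1e-10 before renormalization so finitely many simulation replicates
cannot produce −∞.  Published model-selection arithmetic behaves as
natural-log likelihoods (AIC = 2k − 2 lnL reproduces both printed
tables exactly), and both ΔAIC sign conventions that appear in print
(best − AIC ≤ 0, and AIC − best ≥ 0) are emitted, labelled.  Ranking
ties break toward the smaller parameter count.

Fitting maximizes the composite likelihood over log-scaled parameters
with multi-start Nelder–Mead (default 20 starts, log-uniform in the
search bounds, optional warm starts e.g. from a nested model's
solution), 5,000 expected-SFS replicates per evaluation, and common
random numbers across evaluations so the optimizer sees a smooth
deterministic surface.  Ordered times are parameterized as a first time
plus positive gaps, so t2 > t1 holds by construction.

**Identifiability.** Because the likelihood is conditioned on
polymorphism, the normalized SFS is invariant to multiplying all sizes
and times by a common constant: absolute N is not identifiable — only
size ratios and times measured in units of N are.  Tests therefore
check shape recovery and directional quantities (e.g. N_curr < N_anc1,
the bottleneck direction), not absolute sizes.  Parametric bootstrap
CIs are percentile intervals over refits of datasets simulated under
the fitted model with the observed SNP total; failed refits are dropped
and counted.

The shipped catalogs are: single population (constant, k=1; one change,
k=3; two changes, k=5); the wild-group stage (simultaneous divergence,
the putative hybrid sister to either parent, or a true hybrid origin
via an admixture event with equal parental proportions, each with and
without parental gene flow into the hybrid); and the five-taxon
crop-wild stage on the fixed topology (((foetidissima, scabridifolia,
pedatifolia), radicans), ficifolia) with no migration (k=13: 9 sizes +
4 times, outgroup size fixed) or bidirectional crop–relative migration
(k=15), active while both demes exist.

## Mismatch distribution and expansion dating

The mismatch distribution counts pairwise differences among haplotypes
(missing symbols excluded pairwise).  The sudden-expansion expectation
is the classic closed form

F_j(τ) = G_j(θ1) + e^{−τ(θ1+1)/θ1} Σ_{i≤j} [τ^{j−i}/(j−i)!]·(G_i(θ0) − G_i(θ1)),
G_j(θ) = θ^j/(1+θ)^{j+1},

which reduces to the equilibrium geometric G(θ0) at τ = 0 and to G(θ1)
as τ → ∞; it is computed via a Poisson-kernel convolution in a
numerically safe log form and verified against coalescent simulation.
Fitting minimizes the sum of squared differences between observed and
expected *frequencies* (SSD magnitudes then match printed values like
0.00048) with a coarse grid over log τ ∈ [−3, 2] and log θ followed by
Nelder–Mead refinement in (log τ, log θ0, log(θ1−θ0)), so θ0 ≤ θ1 by
construction.  This is direct minimization of the statistic being
tested; the original tool's generalized-least-squares estimator is not
reproduced.  Significance is a parametric bootstrap: single-locus
datasets are re-simulated under the fitted expansion (haploid coalescent
with per-locus rate u = 1/2 so mutational units equal generations),
refitted, and p is the fraction with SSD at least the observed value;
the same refits give the percentile τ CI, floored at 0.  Calendar time
is t = τ/(2·m_T·μ) with m_T the concatenated locus length (44,143 bp
for the plastome dataset) and μ per site per year; rates quoted per Myr
are divided by 1e6 at the interface.  Only non-coding sites (BED
classification, supplied not inferred) should enter the observed
distribution.

## ABBA-BABA

For a trio (P1, P2, P3) and outgroup with per-site derived-allele
frequencies p1..p4 (derived = the outgroup minor allele; the outgroup
frequency is retained in the formulas rather than forced to 0, the
frequency-based dialect), pattern mass is

ABBA = (1−p1)p2p3(1−p4) + p1(1−p2)(1−p3)p4, and BABA, BBAA by symmetry;
D = (ABBA − BABA)/(ABBA + BABA).

When the outgroup is fixed (p4 = 0) this reduces to the classic
three-population form.  Significance uses a delete-one block jackknife
over contiguous, near-equal SNP blocks (default 20, configurable — the
original tool's default is not published): SE =
sqrt(((B−1)/B)·Σ(D_(−j) − mean)²), z = D/SE, with a one-tailed normal
p (directional introgression hypothesis, matching printed p ≈ 0.21 at
z ≈ 0.80).  The trio table pools *C. foetidissima* and *C.* x
*scabridifolia* into a joint "foetscabri" group and reports the
Bonferroni threshold α/m.

## Synthetic data generator

Three named fixtures mirror the study's data shapes:

* **ficifolia-2524** — 28 diploids × 2,524 SNPs under the fitted
  two-change history (N_anc2 = 215,232 → N_anc1 = 359,555 at 123,660
  generations → N_curr = 43,229 at 2,409 generations) with f = 0.23.
* **five-taxa-6292** — 142 + 11 diploids × 6,292 SNPs on the five-taxon
  topology with split times at 1/100 of the published divergence dates
  (which leaves the SFS shape invariant when sizes scale too, and keeps
  desk-scale runtimes), N = 20,000 per deme, and crop–wild migration
  (1.1e-4 with radicans, 6.1e-6 with pedatifolia) restricted to the
  most recent 2,409 generations — the era of crop cultivation — so that
  gene flow is detectable without homogenizing the taxa.
* **plastome-440** — 36 haploids × 440 SNP columns positioned over a
  44,143 bp coordinate space, one genealogy under a sudden maternal
  expansion (haploid 200 → 5,000,000 at 45,000 generations), conditioned
  on the observed number of segregating sites, with a BED marking ~240
  coding sites.  The expansion age is chosen so the fixture is
  internally consistent: 440 polymorphic columns among 36 haplotypes
  force a mean pairwise difference of at least ~2S/n ≈ 24, so the
  fixture's own clock (u = m_T·μ) must sit near τ ≈ 24 — a shallow
  τ ≈ 1 expansion cannot produce 440 segregating sites in a 36-sequence
  crop alignment (in real data most plastome variation separates taxa).

What the generator does **not** emulate: sequencing error and allele
dropout, linked selection, within-locus recombination, missing-data
patterns of real GBS libraries (fixtures are complete-case), spatial
structure within taxa, and selfing genealogies (inbreeding is
genotype-level).  Passing tests therefore demonstrate correctness of
the estimators and pipelines under the stated models, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's
own defaults for verification: 10,000 genealogy replicates for
closed-form engine checks; 2,524 SNPs × 18 haploid genomes × 20 seeded
runs for bottleneck-direction recovery (multi-start fits, 10 starts,
5,000 SFS replicates per likelihood evaluation); 20 trials × 1,000 SNPs
for D-statistic null calibration; 20 trials × 40 bootstrap replicates
for mismatch-dating calibration.  Zero-probability floor 1e-10;
Nelder–Mead tolerances xatol = fatol = 0.01 in log-parameter space;
optimizer warm starts available for nested-model comparisons.  The
five-taxon joint SFS is held sparsely (dict of count tuples), since the
dense array over five axes would be astronomically larger than the
number of observed configurations.

## Known limitations

Absolute effective sizes and times in generations are reported as
fitted numbers but are only identified up to the common scale (see
Identifiability above); converting generations to years assumes one
generation per year, a caveat for a crop that is not strictly annual.
The composite likelihood treats SNPs as independent, which LD pruning
only approximates.  The block jackknife assumes blocks are exchangeable
and contiguous blocks capture linkage.  The hybrid-origin model fixes
parental proportions at 1/2.  Very strong migration combined with deep
splits makes the event-driven engine slow (event counts grow with the
expected number of migrations per lineage).
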