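# Methods

This note documents the models and procedures implemented in
`wildhyb`, the defaults and why they were chosen, the numerical
choices that affect results, and what the synthetic-data generator
does and does not emulate.

## Data model

A genotype is an unordered pair of integer allele codes at one
microsatellite locus; codes are treated as opaque labels (no mutation
model, no fragment-size semantics). Missing data is a whole-genotype
property: a half-called genotype is rejected on input. The `Dataset`
container pairs the individuals × loci genotype grid with
per-individual metadata (population, morphology-based subspecies, sex,
coordinates, sample material). GenePop (2- or 3-digit, auto-detected)
and two-row STRUCTURE files are supported for interchange; the
package's canonical CSV dialect is the only format that carries the
full metadata, so round-trips through the grid formats preserve
genotypes, IDs and the population partition but not the free-text
labels. Multiple sampling locations per individual live in a separate
long-format CSV because grid formats cannot hold them.

## Consensus genotyping and the quality index

Per locus, across a sample's 2–4 PCR repeats: a heterozygote wins over
homozygotes for either of its alleles (allelic dropout produces false
homozygotes, so a contained homozygote is evidence *for* the
heterozygote, not against it); unanimous homozygotes stand; three or
more distinct alleles, or two disagreeing homozygotes, are
irreconcilable and yield a missing consensus with a conflict flag.
A heterozygote must be seen in ≥ 2 repeats where three or more repeats
amplified, and in ≥ 1 where only one or two did — the usual multi-tube
safeguard. Failed amplifications carry no information, so they do not
raise that bar; this is the one place where the rule needed
interpretation, and it is a configuration knob (`min_het_repeats`).

The quality index scores each repeat against the consensus (1 match,
0.5 false homozygote at a heterozygous consensus, 0 missing or
otherwise unexplained), averaged over repeats per locus and over loci
per sample. Filters: ≥ 5 loci amplified at the first genotyping and
QI strictly greater than 0.6. Samples genotyped once (blood) pass
through with QI 1.0 by convention, flagged as single-repeat.

Two samples are the same individual when their consensus vectors are
(a) identical, (b) differ only by missing data spanning at most ten
loci (counted over the union of the two missing sets — the tighter of
the defensible readings), or (c) differ at exactly one called locus by
a dropout-compatible heterozygote/contained-homozygote pair. Grouping
is single-linkage; groups containing a non-matching pair are kept but
flagged. The collapse recovery experiment in the test suite feeds one
noisy replicate set per true individual through consensus + collapse
and requires the recovered count to equal the truth; with the default
error rates two *independently* resampled consensuses of the same
individual routinely differ at more than one dropout locus, so
re-identification of repeat captures needs either lower error rates or
more repeats — a real limitation of single-difference matching, not of
the implementation.

## Diversity and differentiation

Expected heterozygosity uses Nei's small-sample unbiased estimator
(2n/(2n−1))(1 − Σp²) because that is what the standard
microsatellite toolchain reports; plain gene diversity is a flag.
Summary (Mean/SD) rows over loci use the sample SD (ddof = 1).
Rarefaction draws n individuals (default 18, the smallest population)
without replacement, 100 times, and averages per-locus summaries.

F-statistics follow Weir & Cockerham (1984): per allele and locus the
variance components a (among populations), b (among individuals
within) and c (within individuals) are accumulated and
θ = Σa / Σ(a+b+c), f = 1 − Σc / Σ(b+c); per-locus sample sizes count
called genotypes only. A pair of populations with no polymorphic locus
has undefined θ and raises. The Hardy–Weinberg test uses f as the
statistic and a null built by re-pairing the 2n allele copies; the
linkage test uses the log-likelihood G of the two-locus genotype table
with one locus permuted across individuals. All permutation p-values
use the plus-one estimator (b+1)/(m+1), so the attainable floor is
1/(m+1) and p is never zero. Hardy–Weinberg rejection does *not*
automatically discard a locus: discarding is a config option, default
off, because retaining a complete panel keeps analyses comparable
across populations; the null-allele diagnosis (Brookfield estimator 1
plus a binomial test of the expected r² blank rate) is reported
alongside so the user can decide.

PCA operates on the individuals × allele-indicator matrix
(within-individual allele frequency 0/0.5/1), mean-imputes missing
cells, centres columns, and fixes axis signs by making the
largest-magnitude loading positive — a deterministic convention so
repeated runs are comparable.

## Admixture model

`fit_admixture` is a Gibbs sampler over the standard admixture model:
each allele copy carries a latent cluster of origin z; ancestry
vectors q have a symmetric Dirichlet(α) prior with α sampled by a
Metropolis random walk (step 0.05, uniform prior on (0, 10]); cluster
allele frequencies have a flat Dirichlet(1) prior in the default
independent-frequencies model. The correlated F-model (per-cluster
drift parameter with a Metropolis update, Dirichlet prior centred on
ancestral frequencies fixed at the smoothed empirical pooled
frequencies) is available behind a flag; it is not the default because
the threshold-calibrated detection pipeline is self-correcting against
the modest q-shrinkage the simpler model costs, and the independent
model mixes faster. Missing genotypes are skipped in the likelihood,
not imputed.

Defaults are 10,000 burn-in and 30,000 sweeps with every 10th draw
retained (≥ 3,000 draws, which makes the 5th/95th percentile error of
the credibility intervals negligible); the test suite and the bundled
examples use shorter chains (hundreds of burn-in sweeps, 800–2,000
kept sweeps) because the two-cluster posterior at F_ST ≈ 0.15 mixes
within tens of sweeps — chain-length knobs are exposed everywhere.
Credibility intervals are equal-tailed (5th–95th percentiles of
retained draws). A crude non-mixing diagnostic (first-third versus
last-third trace means) attaches a warning, never an error.

Evanno's ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) is computed from
the mean retained-draw data log-likelihood of repeated runs; zero SD
yields an infinite ΔK rather than a crash. Label switching across runs
is resolved by exhaustive permutation (K ≤ 5, so K! is trivial)
against reference individual subsets, with ties broken toward the
lexicographically first permutation and flagged.

## Hybrid classes by EM

The six early-generation classes fix, per locus independently, a
distribution over the unordered pair of parental gene pools the two
allele copies come from: pure A (A,A); pure B (B,B); F1 (A,B);
F2 ¼(A,A) + ½(A,B) + ¼(B,B); backcrosses ½(own,own) + ½(A,B). Given
pool frequencies, an origin pair (X,Y) gives genotype (i,j)
probability pXᵢpYⱼ + pXⱼpYᵢ (i ≠ j) or pXᵢpYᵢ (i = j). EM alternates
class responsibilities (with estimated mixing proportions) and, in
joint mode, pool-frequency updates from expected allele origins; fixed
mode freezes the frequencies at the reference individuals' estimates.
A 1e-6 pseudocount keeps frequencies interior, so the log-likelihood
trace is monotone up to that regularisation (the tests allow 1e-6
slack). Convergence is declared when the largest responsibility change
drops below `tol` (default 1e-8); non-convergence returns a flagged
result. This deterministic classifier plays the role that MCMC-based
genotype-class programs play in the field's standard workflow, over
exactly the same class kernels.

With 22 microsatellites at F_ST ≈ 0.15, backcrosses overlap the
parental q distribution; the classifier recovers ≈ 78% of simulated
first-generation backcrosses (test suite), and an F1-only class set is
provided for analyses where backcross calls would add noise.

## Detection rules and the resampling procedure

Conservative rule: own-cluster posterior mean q < t. Relaxed rule:
own-cluster 90% CrI lower bound < t. Because lo ≤ q, every
conservative hybrid is a relaxed hybrid; the two bracket the true
rate from below and above. The general analysis uses the fixed
literature threshold t = 0.8 for both rules.

The resampling procedure addresses the ~9:1 domestic:wildcat sampling
imbalance: per dataset, 70 of the domestic cats are drawn without
replacement (all wildcats and all other-region individuals always
included), admixture is fitted, individuals with q > 0.9 (strict)
become reference parentals, 200 parentals per subspecies and 30
hybrids per class (F1 and both backcrosses) are simulated from the
reference allele frequencies by frequency-based gamete draws, the
simulants are analysed *separately* with the same settings (cluster
identity re-anchored on the simulated parentals), and t is the lowest
own-cluster q of any simulated parental. Analysing simulants
separately rather than jointly with the real data is the closer
literal reading of the workflow this mirrors; a joint run would make
the threshold depend on the real individuals being classified.
With 30 datasets of 70 from 371, each domestic cat is drawn
30·70/371 = 5.66 times on average (the total is fixed at 2,100, so
the mean is deterministic; only the spread is stochastic). Rates per
population and rule are summarised by the mean and the empirical
2.5/97.5 percentiles over datasets; a normal-approximation CI is a
flag. An individual's final call requires detection in ≥ 15 datasets —
an absolute count, as the rule is stated, not a fraction of times
sampled (fraction columns are reported too). A dataset whose reference
set comes up empty is skipped, logged, and removed from the
denominator.

## Relatedness and spatial analysis

The pair likelihood mixes the standard genotype-pair probabilities
conditional on sharing 0/1/2 IBD alleles; maximization over the
(k0, k2) simplex is a deterministic two-stage grid (step 0.02
globally, then 0.001 within ±0.025 of the coarse optimum), so results
are exactly reproducible. Allele frequencies default to leave-pair-out
estimates to reduce the small-sample bias of including the focal pair;
at loci where excluding the pair would empty an allele class the
full-sample frequencies are used for that locus. Genotyping error is
not modelled in the likelihood — consensus genotypes are taken as
true, a documented limitation. The genetic-feasibility constraint
k1² ≥ 4·k0·k2 is available but off by default.

Geographic distance between two individuals is the Euclidean distance,
averaged over all cross-pairs of sampling locations for individuals
sampled several times. The distance ~ relatedness model is OLS within
a sex stratum (FF or MM) or pooled with the sex-pair class as a
covariate; the relatedness coefficient is tested by its df = 1 F
statistic. Because pairs sharing an individual are not independent, an
optional permutation test shuffles individual identities over the
distance side (999 permutations by default) and recomputes F.

## Synthetic-data generator

Parental gene pools follow the F-model: population frequencies are
Dirichlet-drawn around the ancestral frequencies with concentration
(1−F)/F, so F is the expected fixation of each pool relative to the
ancestor and, empirically, the realized pairwise Weir–Cockerham F_ST
between two pools drawn at the same F is close to F (a calibration
helper measures the mapping). Defaults mirror the study design the
package targets: 22 loci, 8 alleles per locus, uniform ancestral
frequencies, F = 0.15 between subspecies (0.17 reproduces the more
diverged regional pair), regional drift 0.02 (domestic) and 0.04
(wild) on top of the subspecies pools, and sample sizes
371/42/21/18 for NE-domestic/NE-wild/PO-domestic/PO-wild. Genotypes
are HWE draws; hybrids are gamete-level crosses (F2 uses two freshly
simulated F1 parents). The error model applies, per locus and repeat,
amplification failure (default 0.15) and then allelic dropout of one
uniformly chosen allele of a heterozygote (default 0.2, applied per
genotype-repeat because that is how dropout is diagnosed — as a false
homozygote); these rates are loosely motivated by typical noninvasive
amplification success in the 74–82% range and are knobs, not claims.
Full-sib families (sizes 2–4, the smallest structure that makes the
kin-spatial regression testable) can share a spatial centre with
isotropic Gaussian scatter, or be placed uniformly to produce a null.

What the generator does **not** emulate: mutation (no stepwise model),
linkage, null alleles as a locus property (dropout is genotype-wise
and unbiased across alleles), multi-generation pedigrees beyond the
four hybrid classes, age/sex-biased dispersal, and spatially explicit
gene flow. Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical assumptions, not robustness to
every failure mode of real noninvasive data.

## Problem sizes in the test suite

The suite exercises the full pipeline at reduced scale chosen to keep
Monte-Carlo error well inside the asserted bands: admixture chains of
200–1,500 kept sweeps (the two-cluster posterior mixes in tens of
sweeps at these divergences), 60–230 individuals per fit, 6–8
resampled datasets, 6–20 seeds per recovery experiment, and 199
permutations per permutation test. Each assertion band matches the
statistical expectation at that scale (e.g. binomial error of a
90%-coverage check over 200 simulants), not a tuned margin.
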