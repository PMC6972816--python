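# wildhyb

Tools for studying hybridization between the European wildcat
(*Felis silvestris silvestris*) and the domestic cat (*F. s. catus*)
from replicated microsatellite genotypes: consensus genotyping with
quality control for noninvasive samples, population-genetic summary
statistics, Bayesian admixture inference, simulation-calibrated hybrid
detection with resampling confidence intervals, and maximum-likelihood
pairwise relatedness with spatial kin-structure analysis.

The package is aimed at conservation geneticists working with
codominant marker panels (here 22 autosomal microsatellites) in a
two-subspecies setting with heavily unbalanced sampling — typically a
few dozen wildcats against several hundred free-ranging domestic cats
across two regions. Every stage can be exercised end-to-end on the
built-in synthetic-data generator, which emulates two parental gene
pools with tunable differentiation, the early-generation hybrid
classes, and a noninvasive genotyping error model.

## What it computes

* **Genotyping QC** (`genotyping_qc`). Noninvasive samples (feces,
  hair) are genotyped 2–4 times; repeats are reconciled into a
  consensus genotype per sample. Each repeat scores a quality index at
  each locus: 1 if it reproduces the consensus, 0.5 if it is a
  homozygote while the consensus is heterozygous (the allelic-dropout
  signature), 0 if missing; scores are averaged over repeats, then over
  loci. Samples with QI ≤ 0.6 or fewer than five loci amplified on the
  first pass are discarded, and matching samples are collapsed into
  unique individuals.
* **Diversity and differentiation** (`popgen_stats`). Per-locus allele
  counts Na, observed heterozygosity Ho, Nei's unbiased expected
  heterozygosity He = (2n/(2n−1))(1 − Σpᵢ²); rarefied diversity at
  equalized sample size (default 18 individuals × 100 draws);
  permutation tests of Hardy–Weinberg and linkage equilibrium;
  Brookfield null-allele frequencies r = (He − Ho)/(1 + He) with a
  binomial blank-count check; Weir & Cockerham (1984) F_IS and pairwise
  F_ST from the a/b/c variance components with permutation
  significance; and a model-free PCA of allele indicators.
* **Admixture** (`admixture`). A Gibbs sampler over the standard
  admixture model yields each individual's posterior mean ancestry
  q and an equal-tailed 90% credibility interval; Evanno's ΔK selects
  the number of clusters; a deterministic EM classifier assigns
  individuals to the genotype-frequency classes pure A/B, F1, F2 and
  first-generation backcrosses.
* **Hybrid detection** (`hybrid_detection`). Hybrids are called
  *conservatively* (own-cluster q below a threshold) or *relaxedly*
  (CrI lower bound below it); the two rules bracket the hybridization
  rate. Thresholds are either the literature value 0.8 or calibrated
  per dataset as the lowest q reached by parentals simulated from
  high-confidence (q > 0.9) reference individuals. A resampling loop
  (30 datasets of 70 subsampled domestic cats by default) yields
  per-individual detection counts, a ≥ 15-of-30 individual call rule,
  and population rates with empirical 95% CIs.
* **Relatedness and space** (`relatedness_spatial`). Maximum-likelihood
  IBD coefficients (k0, k1, k2) per pair, r = k2 + k1/2, and an OLS of
  pairwise geographic distance on relatedness per sex stratum, with an
  optional identity-permutation test.

## Worked example

```python
from wildhyb.synthetic_data import PopModel, simulate_study_design
from wildhyb.popgen_stats import wc_fstats
from wildhyb.hybrid_detection import DetectionConfig, run_general_analysis

model = PopModel(n_loci=22, alleles_per_locus=8, divergence=0.15)
ds, freqs = simulate_study_design(
    seed=1, model=model,
    n_ne_domestic=120, n_ne_wild=30, n_po_domestic=12, n_po_wild=12,
    n_hybrids={"F1": 4},
)
print(wc_fstats(ds).fst.round(3))
ga = run_general_analysis(ds, cfg=DetectionConfig(burnin=500, iters=2000, thin=5), seed=2)
print(int(ga.conservative.sum()), int(ga.relaxed.sum()))
```

prints

```
             NE_domestic  NE_wild  PO_domestic  PO_wild
NE_domestic          NaN    0.185        0.013    0.198
NE_wild            0.185      NaN        0.168    0.050
PO_domestic        0.013    0.168          NaN    0.192
PO_wild            0.198    0.050        0.192      NaN
4 5
```

The F_ST matrix shows the generated structure: strong wild–domestic
differentiation (≈ 0.17–0.20), mild regional structure within each
subspecies. The general analysis at the fixed 0.8 threshold flags 4
individuals under the conservative rule — exactly the 4 simulated F1s —
and one additional borderline individual under the relaxed rule, which
by construction flags a superset.

The same operations are available from the shell via the `wildhyb`
command (`convert`, `simulate`, `qc`, `stats`, `admix`, `detect`,
`kin`); run `wildhyb --help` for the options.

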