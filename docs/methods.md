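# Methods

This note documents the models, estimators and design choices behind
`hybridorigin`, in the order the pipeline runs them, together with the
numerical conventions and the limits of what the synthetic-data checks can
show about real data.

## Data model

Genotypes are unordered diploid pairs of positive integer allele codes per
individual and locus; `(0, 0)` is missing, and half-missing genotypes
(exactly one zero code) are rejected at construction because no downstream
statistic has a defensible treatment for a single observed gene copy.
Allele codes are opaque labels: none of the implemented statistics uses
allele size or repeat number. I/O is the GENEPOP text dialect (2- and
3-digit encodings read; 3-digit written; missing = `000000`). GENEPOP has
no field for population names, so labels round-trip through the common
`<label>_<id>` individual-naming convention; files without it get
positional `pop1, pop2, ...` labels.

Behavioral trials are rows (female, population, male combination, m, n)
with m and n the times spent in the two males' interaction zones. Units
are the caller's (seconds by convention); the preference estimate is
unit-invariant but G statistics are not (below).

## Synthetic data generator

The generator emulates the three-population hybrid-diagnosis design: two
parental gene pools and one admixed group, typed at a few highly
multiallelic loci.

* **Parental divergence** follows the Balding–Nichols construction: per
  locus an ancestral frequency vector is drawn from a symmetric
  Dirichlet(1, …, 1) over the allele registry, and each population's
  vector from Dirichlet(ancestral × (1−F)/F). The single parameter F sits
  directly on the FST scale: Weir–Cockerham θ estimated from large
  simulated samples (500 per population, 20 replicates) is centered on F
  (0.107 observed at F = 0.11, 0.24 at F = 0.25 — computed by the test
  suite's calibration check). F = 0 returns identical populations.
* **Genealogical classes** are encoded by their expected diploid
  ancestry-pair proportions (AA, AB, BB): pure A = (1,0,0), pure B =
  (0,0,1), F1 = (0,1,0), F2 = (¼,½,¼), backcrosses = (½,½,0)/(0,½,½).
  Each individual × locus draws an ancestry pair independently across loci
  (no linkage — consistent with analysing unlinked markers), then each
  gene copy from the corresponding population's frequencies. Missingness
  is i.i.d. per genotype.
* **Study preset**: 7 loci, 10–23 alleles per locus, F = 0.11,
  populations of 40 (parental A), 24 (parental B) and 40 (admixed, F2
  ancestry), 2% missing genotypes. These are the sample sizes and marker
  properties of the field design the package emulates.
* **Trials**: each female's time share with the focal male is
  Beta(mean = P, concentration = 8); the concentration is a calibration
  choice reproducing a realistic between-female spread of roughly 0.12–0.13
  SD in time share, not a measured value. 7 females per group and
  3000-second (50-minute) totals mirror the experimental design.
* **Null alleles** can be injected (heterozygote miscalled as homozygote,
  null homozygote dropped to missing) but are off by default, and no
  correction for the induced heterozygote deficit is implemented anywhere.

What the generator does **not** emulate: mutation processes (stepwise or
otherwise), linkage, genotyping error beyond the optional null allele,
population-specific missingness, and — importantly — the private-allele
structure of real microsatellites. Under Balding–Nichols at a given FST,
divergence is spread smoothly across the shared registry; real
microsatellite pairs at the same FST typically carry more
individually-diagnostic alleles. Passing the synthetic checks therefore
demonstrates correctness of the estimators under the model, not that any
particular real marker panel has equivalent resolving power (see
"Known limits" below).

## Estimators and tests

**Weir–Cockerham θ.** Per locus and allele the two-level diploid ANOVA
components: a (among populations), b (among individuals within
populations), c (within individuals), from the standard formulas with
unequal sample sizes (n̄, n_c). Per-locus θ = Σa/Σ(a+b+c) over alleles;
multilocus θ pools components over loci (ratio of sums, not mean of
ratios). Negative components are retained, so θ can be slightly negative
for undifferentiated samples — truncating would bias the estimator.
Monomorphic loci carry no information and are skipped. Significance:
whole individuals are permuted between the two populations;
p = (x+1)/(n_perm+1) where x counts permuted θ ≥ observed. All permutation
p-values in the package use this add-one smoothing, so p ∈ (0, 1].

**HWE.** The test statistic is the conditional probability of the observed
genotype array given the allele counts (the probability-test analogue of
the exact test); the null distribution is simulated by randomly re-pairing
the observed allele pool, and p is the smoothed fraction of replicates
with probability ≤ observed (ties counted as ≤). The direction (deficit /
excess) compares observed heterozygosity with the small-sample-corrected
gene diversity. Monomorphic loci are flagged untestable rather than
raising; fewer than 5 genotypes is an error. Which exact-test variant the
classic GUI programs run by default is configuration-dependent; the
statistic used here is documented, not claimed to match any of them.

**LD.** Two-locus genotypic likelihood ratio
G = 2[lnL(joint genotype table) − lnL(independent margins)] with the null
distribution from permuting one locus's genotypes among individuals
(margins fixed). Both tests are calibrated: under their simulated nulls
(random union of gametes; unlinked loci) the p-value distributions pass a
Kolmogorov–Smirnov uniformity check at α = 0.01 with 200 replicates (run
by the acceptance suite).

**Admixture EM.** The likelihood treats every gene copy as independently
drawing a cluster from the individual's ancestry vector q_i and an allele
from that cluster's locus frequencies. EM alternates copy-level
responsibilities with closed-form updates of Q and the cluster
frequencies; the log-likelihood is non-decreasing every iteration
(asserted to 1e-9 in tests), convergence is a per-iteration gain below
`tol` (default 1e-6, `max_iter` 1000). K = 1 reduces exactly to the pooled-
frequency closed form. Missing genotypes are marginalized by omission.
This is a deliberate deterministic surrogate for Bayesian MCMC admixture
samplers with correlated frequencies: ΔK consumes only log-likelihoods,
and at the divergence regimes targeted here (θ ≈ 0.1–0.25) the correlated
prior is not load-bearing. It is a surrogate, not a replica.

**Evanno ΔK.** For each K in the range, `n_replicates` (default 10) seeded
random starts; L(K) = mean replicate log-likelihood, SD(K) = replicate
standard deviation; ΔK = |L(K+1) − 2L(K) + L(K−1)|/SD(K) for interior K;
chosen K = argmax with ties toward smaller K. Zero replicate SD yields
ΔK = +∞ with a warning (still comparable). Because ΔK cannot evaluate
K = 1, a dominance heuristic flags "no strong structure" when the ΔK peak
fails to double the median of the remaining ΔK values; with the default
K = 1–4 range that is a single comparison, so treat the flag as a caution,
not a test. Replicate seeds derive from the master seed via numpy
`SeedSequence.spawn`, recorded in pipeline provenance.

**Genealogical-class posteriors.** P(genotype | class) mixes the three
ancestry configurations with the class weights; for configuration (X, Y)
with frequency vectors f, h the unordered pair (x, y) has probability
f(x)h(y) + f(y)h(x) (x ≠ y) or f(x)h(x). Per-individual log-likelihoods
sum over non-missing loci (unlinked assumption); the posterior combines a
uniform prior over the six classes. Parental frequencies are plugged in
from the labeled parental samples — a deterministic surrogate for joint
MCMC over frequencies and classes, defensible because the design provides
labeled parental references. Alleles unseen in a reference sample receive
a floor of 1/(2n+1) (n = genotyped reference individuals at the locus),
with observed frequencies rescaled; the floor prevents a single sampling
gap from annihilating a class likelihood. An individual missing at every
locus gets the prior back, with a warning. Later-generation classes (F3+,
double backcrosses) are out of scope.

**Correspondence analysis.** Individuals × alleles counts (0/1/2, grouped
by locus; missing genotype = zero block — chosen over row-mean imputation
to keep row masses interpretable). Standard CA: divide by the grand total,
standardized residuals (P − rcᵀ)/√(rcᵀ), SVD, row principal coordinates
U·Σ/√r. Per-axis inertia = squared singular value over total inertia, and
total inertia equals the matrix chi-square statistic divided by the grand
total (asserted to 1e-10). Axis signs are arbitrary; tests compare up to
sign. Centering is global, not per population.

**Preference likelihood.** ln L(P) = Σ[mᵢ ln P + nᵢ ln(1−P)] per group;
the numeric maximizer (bounded scalar minimization, xatol 1e-12) coincides
with P̂ = Σm/Σ(m+n) (asserted to 1e-8 over random trial sets). P is
clamped to [1e-9, 1−1e-9] for log evaluation only — reported boundary
estimates are exactly 0 or 1 with one-sided intervals. Support limits are
the profile interval at a 2-unit ln L drop (asymptotically ≈ 95%
confidence), found by bisection to 1e-9 and verified against a 1e-5-step
grid scan. LRTs: indifference (null P = 0.5, df 1) and
combination-dependence (null shared P, df = #combinations − 1), with
chi-square upper-tail p-values and G clamped at 0.

A unit caveat that shapes interpretation: P̂ is invariant to rescaling all
times, but ln L — and therefore G and the width of a fixed-drop support
interval — scales linearly with the time unit. Seconds-weighted G treats
every second as an independent Bernoulli trial and thus ignores
between-female overdispersion; under the Beta-overdispersed generator the
seconds-weighted 2-unit interval covers the generating P far below its
nominal level, while with unit-total (share) weighting it over-covers
(the recovery test measures ≥ 90% coverage in that conservative regime).
The package therefore reports the binary per-female choice weighting
alongside the seconds-weighted G wherever preferences are tested.

## Pipeline

`run_pipeline` executes ingest/simulate → FST/HWE/LD → admixture + ΔK →
class posteriors → CA → preference analysis, writing each table as TSV
(floats formatted `%.10g`) plus a JSON provenance block with the master
seed and the per-stage seed-derivation scheme. Reruns with the same master
seed are byte-identical (asserted in tests). A stage failure aborts with
the stage name; completed stage outputs remain on disk and every stage's
table is re-loadable.

## Problem sizes used by the checks

The shipped checks run at the study scale the package emulates: 104
individuals × 7 loci for clustering and classification, 500 per population
× 20 replicates for the θ calibration, 200 replicates for the p-value
uniformity checks, and 10 EM replicates per K for ΔK. These sizes are the
package's own choice of study conditions, not tuning knobs.

## Known limits

* With 7 unlinked loci, genealogical classes overlap intrinsically: about
  1 − 2(3/4)⁷ + (1/2)⁷ ≈ 26% of true F2 individuals realize no fully
  homozygous-ancestry locus and are genuinely closer to backcross or F1
  expectations, so even a Bayes-optimal classifier with perfectly
  diagnostic markers leaves the median F2 posterior near 0.8, and under
  Balding–Nichols divergence at F = 0.25 far below it. High-confidence F2
  diagnosis at this locus count requires markers with strong private-allele
  content; the acceptance suite documents the shortfall rather than
  relaxing the check.
* The admixture likelihood ignores within-individual ancestry correlation
  (admixture LD); a dataset consisting *only* of 50/50-admixed individuals
  leaves Q unidentifiable (the mixture collapses to the pooled-frequency
  model), which is why ancestry-recovery checks anchor the clusters with
  parental samples, as the field design does.
* ΔK cannot choose K = 1; the no-structure flag is a heuristic.
* The seconds-weighted G statistics are unit-dependent and anticonservative
  under female heterogeneity; no G magnitude should be compared across
  datasets with different recording units.
* No null-allele correction, no allele-size-based statistics (RST), no
  mutation model, no coalescent machinery.
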