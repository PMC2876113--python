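# Methods

This note documents the statistical models behind `tsetsepop`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## F-statistics

All fixation indices are moment estimators from a nested random-effects
ANOVA on gamete-level allele indicators (Henderson method-1 equations on the
uncorrected sums of squares), with levels gamete < individual < population
< region. For the two-level design this reproduces the Weir–Cockerham (1984)
per-allele a/b/c components exactly (verified to 1e-12 against an
independently coded evaluation of the published formulas); the four-level
design yields the hierarchical components (σ²_R, σ²_P, σ²_I, σ²_E) and

    F_RT = σ²_R / σ²_tot            F_SR = σ²_P / (σ²_P + σ²_I + σ²_E)
    F_ST = (σ²_R + σ²_P) / σ²_tot   F_IS = σ²_I / (σ²_I + σ²_E)

Alleles and loci combine by summing components before taking ratios — never
by averaging per-locus ratios. Monomorphic loci contribute zero components
and therefore drop out of the ratios without special-casing. Individuals
missing at a locus are excluded for that locus only.

**X-linked loci.** Hemizygous males are stored once (single-slot calls) and
re-coded per analysis, following the study conventions: excluded (set
missing) for F_IS-based analyses, coded as homozygous diploids for
differentiation and linkage analyses. Gene-diversity and allele-frequency
computations count male X genes once.

**Permutation tests.** Four schemes, all one-sided with
P = (#{null ≥ observed} + 1)/(n_perm + 1): alleles shuffled within
subsamples (statistic: overall *f*; H1 = homozygote excess, the direction of
interest for null alleles and inbreeding — the opposite tail can be read off
the stored null distribution), and individual- or subsample-level label
shuffles using the genotype-table likelihood-ratio statistic *G* summed over
loci (and over subsamples where applicable). The allele-shuffle null is
computed vectorized: within one subsample the permuted components depend only
on per-allele dosage sums of squares.

**Confidence intervals.** Per-locus: delete-one-population jackknife, normal
approximation on pseudovalues (the jackknife flavour is not recoverable from
the original software; normal-on-pseudovalues chosen and documented).
Overall: percentile bootstrap over loci on the summed-component ratio.
Fewer than 3 populations (jackknife) or n_boot < 2 (bootstrap) report NaN
bounds rather than fabricated intervals.

**Regional diversity.** Nei's unbiased gene diversity
Hs = ñ/(ñ−1)(1 − Σp̂²) per locus per population (ñ = gene count); regions
compared by a two-sided Wilcoxon signed-rank test paired by locus, exact for
≤ 25 untied pairs, normal approximation with tie correction otherwise.

## Locus diagnostics

**Null alleles.** Brookfield's second estimator is specified by its
generating model — Hardy–Weinberg proportions with a non-amplifying allele
at frequency p_n, blanks being null homozygotes and apparent homozygotes
including visible×null heterozygotes. The package maximizes the trinomial
likelihood of (heterozygote, apparent-homozygote, blank) counts in p_n
numerically (bounded scalar minimization, clipped to [0, 1]); this satisfies
the estimator's defining boundary behaviour (no deficit & no blanks → 0; all
blank → 1; monotone in the heterozygote deficit). X-linked loci use females
only; the direct male-blank proportion is available as a second method.
Expected blanks are p_n² per diploid and p_n per hemizygous male; the pooled
expected blank probability feeds an exact lower-tail binomial test (H1:
fewer blanks than expected, i.e. the null-allele explanation is too strong).

**Linkage disequilibrium.** For each locus pair passing the
major-allele-frequency ≤ 0.9 filter, genotypes at one locus are permuted
among individuals within each subsample and *G* on the genotype×genotype
table is summed over subsamples. The count of significant pairs is checked
against the binomial(n_tests, 0.05) upper tail; Holm's step-down correction
(via statsmodels) is applied wherever a family of tests needs family-level
decisions.

## Effective size

**LD method.** Burrows' composite disequilibrium Δ̂ per allele pair from
genotype counts (phase-free), with the correlation
r = Δ̂ / sqrt((p(1−p)+D_A)(q(1−q)+D_B)), where D_A, D_B are the
Hardy–Weinberg departures — Weir's corrected denominators, which keep
|r| ≤ 1 at full coupling. r² is averaged over allele pairs within a locus
pair, then arithmetically over locus pairs; Ne = 1/(3(r̄² − 1/S̃)) inverts
Hill's drift expectation E[r²] ≈ 1/S + 1/(3Ne), with S̃ the harmonic mean of
pairwise-complete sample sizes. r̄² ≤ 1/S̃ is reported as an infinite
estimate (drift signal below sampling noise), never as a negative size. No
mating-system or small-sample bias adjustment is applied; in the recovery
simulations (true N = 50, 10 loci, 30 sampled) the median estimate over
seeds falls well inside [20, 150].

**Heterozygote excess.** Ne = 1/(−2F_IS) − F_IS/(1+F_IS) with the
Weir–Cockerham *f*; only applicable for *f* < 0, reported as inapplicable
otherwise (and +∞ as f → −1). Loci flagged by QC (nulls, stutter) should be
excluded via the exclusion-list mechanism before either intra-locus method.

## Bottleneck detection

For each polymorphic locus (k ≥ 2 alleles, n ≥ 4 genes; male X genes counted
once) the sample heterozygosity H_E = n/(n−1)(1 − Σp̂²) is located within
the distribution of the same quantity for equilibrium samples of n genes
conditioned on exactly k alleles. The scaled mutation rate θ is first tuned
so E[k | θ, n] = k — exactly (harmonic-sum bisection) under IAM,
by pilot-simulation bisection with deterministic internal seeds under
SMM/TPM — then equilibrium samples are drawn and replicates with exactly k
alleles retained (default 1000; the acceptance suites use 200, which leaves
the Monte-Carlo error of the reference distribution far below the test's
resolution).

Under IAM the retained configurations follow the Ewens sampling formula, so
a Hoppe-urn sampler is used directly (no genealogy), and the conditional law
is θ-free; this is cross-checked against exact Ewens enumeration at small n
in the test suite. Under SMM/TPM an explicit coalescent tree is simulated
with stepwise mutations; the TPM multistep size is a signed geometric with
P(|step| = j) = (1−q)q^(j−1), q solved so the step variance equals 30
(q ≈ 0.758), with the single-step share at 0.7.

**The test.** The distribution of H conditional on k is left-skewed, so a
signed-rank test on raw H_E − mean(H_EQ) differences is badly calibrated
(measured type-I ≈ 13% at equilibrium with 10 loci) and anchoring at the
median alone leaves it conservative (≈ 2%). The package therefore feeds the
one-tailed Wilcoxon signed-rank with the *centred conditional quantiles*:
u_l = midrank position of H_E within the retained equilibrium replicates,
tested against symmetry about ½ (which holds under the null by
exchangeability). Measured calibration: type-I 0.035 at equilibrium, power
0.75 for a crash to Ne_pb = 25 ten generations before sampling (θ_anc = 4,
10 loci, 20 individuals — inside the detection window). The reported H_EQ is
the retained-replicate median (the mean is kept as `heq_mean`).

**Detection window.** (τ₁·2Ne_pb, τ₂·2Ne_pb) generations before sampling
with τ₁ = 0.1 and τ₂ = 2.5, the range appropriate for ~10 loci and samples
of 10–30 individuals. For Ne_pb = 23 the lower bound computes to 4.6 (the
field literature rounds this to 5).

## Distances and trees

Chord distance: per locus cos θ_l = Σ_a sqrt(p_la q_la), combined as
D = sqrt((1/L) Σ_l 2(1 − cos θ_l)). Classic packages disagree on an
arc-length 2/π prefactor; it is exposed as a flag (default off) and both
conventions are tested. NJ is the standard Saitou–Nei Q-criterion
agglomeration with deterministic tie-breaking by label sort order and
negative branch lengths clamped to zero with a count of clamps; exactness on
additive matrices and agreement with scikit-bio's implementation are tested.

## Mitochondrial statistics

Sites containing N or a gap in any sequence are removed before all
statistics (complete deletion; pairwise deletion available). Hd and its
sampling variance follow Nei's unbiased estimators; K is the mean pairwise
Hamming distance with Tajima's no-recombination total (sampling +
stochastic) variance [3n(n+1)K + 2(n²+n+3)K²] / [11(n²−7n+6)], and
Pi = K/L with the corresponding per-site variance. (Published tables from
era software print slightly different variance conventions for K and Pi;
the Hd variances reproduce exactly, the K/Pi variances are documented here
as the formulas above.) Hudson's statistics: F_ST = 1 − H_w/H_b on mean
within/between pairwise differences; H_ST = 1 − H_S/H_T with H_S the
n_i-weighted mean haplotype diversity; K*_ST = 1 − K*_S/K*_T on
log(1 + d)-transformed pairwise differences with K*_S weighted by C(n_i, 2)
(the number of within-population pairs). Permutations reassign *sequences*
(not haplotype classes) to localities. The haplotype network is a minimum
spanning network on Hamming distances with edges above the user-supplied
connection limit removed (11 steps reproduces the study setting for a
738-nt alignment — the parsimony-probability computation of that limit is
out of scope) and inferred intermediate nodes on multi-step edges.

## Morphometrics

GPA: center, scale to unit centroid size, iterate optimal rotations
(SVD solution constrained to det +1 — no reflections; configurations fitting
far from the consensus, e.g. mirror-digitized wings, are flagged) until the
consensus moves less than 1e-8. Shape variables: the thin-plate-spline
bending-energy matrix of the consensus gives k−3 principal warps, applied to
x and y (2k−6 nonuniform scores); the uniform component is the 2-D
orthogonal complement of the similarity + nonuniform span within the tangent
space, so the score basis is orthonormal and the score-vector norm equals
the tangent-space Procrustes distance (tested to 1e-8). For k = 10 this is
16 variables. CVA: Mahalanobis distances between group means under the
pooled within-group covariance (pseudo-inverse fallback if singular);
pairwise permutation tests permute only the two groups under comparison
(pair-local pooled covariance inside the permutation statistic);
reclassification is resubstitution by default to match the era's software,
leave-one-out by flag (the no-signal test uses leave-one-out, since
resubstitution with 16 variables sits above chance by construction).

## Synthetic data

The generator's defaults are the study conditions: five populations with the
published sex-by-site sample sizes (30/29/32/35/27 = 153 flies), ten loci of
which five X-linked, null alleles (p_n = 0.2) at the two loci the study
flagged as null-ridden, F_SR = 0.069 and F_RT = 0.12 as differentiation
targets, one bottlenecked population (DakarHann, Ne_pb = 16, 10 generations
before sampling, applied as extra Wright–Fisher drift on its allele
frequencies), a COI panel with 11 haplotypes (9 in one region, 2 in the
other, no sharing, ≥ 12 mutational steps between regional pools over 738
sites), and five landmark groups of 20/21/18/34/18 wings. The Missira
haplotype split (14, 6, 4, 3, 2, 2, 1, 1, 1) was chosen once to give nine
haplotypes with Hd ≈ 0.79, matching the published order of magnitude.

Microsatellite structure uses a hierarchical Dirichlet F-model (region
frequencies ~ Dirichlet centred on ancestral with concentration
(1−F_RT)/F_RT, population frequencies likewise with (1−F_SR)/F_SR) rather
than a coalescent island model, because the study reports F targets, not
migration rates; generator/estimator consistency is verified to ±0.03 over
20 seeds. Null alleles are a per-locus hidden allele shared across
populations. Stutter artifacts are not simulated (their diagnostics are out
of scope). Landmark groups are a decagon plus group offsets (scale 0.008)
with isotropic noise (sd 0.02) and random similarity nuisance; the offset
scale was calibrated once so resubstitution reclassification sits in the
study's 72–85% band.

What passing tests on these data do *not* show: robustness to allele-size
homoplasy across loci with different repeat motifs, to real wing-landmark
digitization error structure (anisotropic, correlated), to sequencing error
in COI, or to non-equilibrium demography beyond a single instantaneous
crash. The generator has no spatial dispersal, selection or genealogy
output.

## Numerical choices and degenerate inputs

- Permutation P-values are always (c+1)/(n+1), ties counted as ≥ observed;
  every randomized routine takes a seed and is bit-reproducible.
- Dirichlet concentrations are floored at 1e-9 to tolerate zero mean
  entries; F target 0 short-circuits to exact frequency copies.
- Wilcoxon tests use the exact null for ≤ 25 untied pairs, else the
  tie-corrected normal approximation; all-zero differences return P = 1.
- The genotype G statistic skips zero cells (the 0·log 0 = 0 convention).
- Empty populations, ragged alignments, male diploid calls at X-linked
  loci, non-symmetric distance matrices and degenerate (all-coincident)
  landmark configurations are rejected with named errors rather than
  propagated as NaN.
- Problem sizes in the validation suites (400 null replicates at 99
  permutations for the type-I checks; 200 equilibrium and 50 crash
  replicates with 200 retained equilibrium samples for the bottleneck
  checks; 20–50 seeds for the recovery checks) were chosen to put the
  Monte-Carlo standard error well inside the asserted bands.
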