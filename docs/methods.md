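# Methods

## Genotype model and calling

GBS tag pairs give, per sample and biallelic locus, read counts for the two
alleles. In an autotetraploid the five dosage classes {0..4 copies of the
major allele} cannot be resolved at routine depths: distinguishing a simplex
heterozygote (AAAa, read ratio 3:1) from a homozygote requires depth far
beyond what GBS delivers per locus. The calling rule therefore works at the
presence/absence level:

* both alleles observed → heterozygote (code 1) if total depth ≥ 4, else
  missing;
* one allele observed → homozygote (code 2 for the major allele, 0 for the
  minor) if depth ≥ 11, else missing;
* no reads → missing.

The homozygous threshold controls the dominant error mode: a heterozygote
whose reads all happen to carry one allele. For per-read major-allele
probability p and depth d that probability is `p^d + (1-p)^d`; at the simplex
ratio p = 3/4 and d = 11 it is 4.22% (the minority term 0.25¹¹ ≈ 2.4e-7 is
negligible — conventions with and without it agree to three significant
figures). The probability is strictly decreasing in depth, so the threshold
is a guaranteed ceiling on this miscall rate.

Tetraploid heterozygous classes are collapsed to one diploid-style code
(0/1/2 with −1 as the missing sentinel; `./.` in VCF). Markers missing in
strictly more than 30% of samples are removed (call rate ≥ 70%); the
comparison is strict, so a marker missing in exactly 30% of samples is kept.
Calling is cell-local and idempotent; the call-rate filter never alters
retained values.

Note that collapsing is lossy beyond the calling step: a trait that is
additive in allele dosage is only partly linear in the collapsed code
(dosages 1, 2, 3 become indistinguishable), which attenuates downstream
marker-based prediction relative to a true dosage assay.

## KNN imputation

Remaining missing codes are imputed from the K = 4 most similar samples.
The distance between two samples is the mean mismatch over their co-observed
markers; pairs with no co-observed markers (configurable minimum) are
infinitely distant. Each missing cell takes the mode of the K nearest
samples observed at that marker. Tie rules are deterministic so seeded runs
are exactly reproducible: equal distances order by ascending sample index,
and a tied mode resolves to the nearest neighbour's value. The neighbour
space is samples, not markers, which preserves marker independence and
matches how KNN imputation is applied to GBS genotype matrices. The method
assumes missingness is unrelated to genotype given depth — true for the
depth-threshold mechanism that generates it here.

## Trial model and quantitative genetics

Phenotypes follow the two-way random model

    y_icr = mu_c + g_i + (ge)_ic + e_icr

with condition fixed, progeny g and progeny-by-condition (ge) random. For
balanced tables the components come from expected mean squares:
σ²_e = MS_E, σ²_gc = (MS_PC − MS_E)/k, σ²_g = (MS_P − MS_PC)/(ck); negative
estimates are truncated at zero and flagged. Unbalanced tables fall back to
REML, implemented directly: because progenies are independent, the REML
likelihood factors into small per-progeny blocks; the residual variance is
profiled out and the two variance ratios are maximised by Nelder-Mead in log
space (relative agreement with the balanced closed form is better than 1e-6,
which the suite asserts). The trial layout is simplified to complete
randomised blocks — incomplete-block (alpha-lattice) effects are not
modelled, as they are not needed to exercise the estimators.

Derived statistics:

* CV_g = 100·σ_g/x̄ per condition (only meaningful for traits on a positive
  scale; the generator's default standardized traits have mean 0 and no
  CV_g);
* h²_B = σ²_g / (σ²_g + σ²_gc/c + σ²_e/(ck)) on a progeny-mean basis over
  c conditions and k replicates — monotone in σ²_g, c and k;
* type-B genetic correlation r_g = r_p/√(h²_i h²_j) with per-condition
  heritabilities from single-condition ANOVA (σ²_g/(σ²_g + σ²_e/k)),
  truncated into [−1, 1] as reported tables conventionally cap it;
* progeny BLUPs: grand mean + h²_B·(progeny mean − grand mean) on balanced
  data (general mixed-model shrinkage otherwise). Deviations sum to zero.
  Shrinkage reduces mean-squared error against true breeding values but —
  being affine in the progeny means on balanced data — leaves their Pearson
  correlation with any target exactly unchanged; claims of "improved
  correlation" from BLUP adjustment on balanced designs are vacuous, and the
  test suite asserts the MSE improvement instead.

## GWAS

The scan regresses the BLUP-adjusted progeny phenotype on each marker code
separately (no kinship term: the target population shows no subpopulation
structure, and the half-sib design gives near-uniform relatedness).
The squared t statistic is treated as a 1-df chi-square, and the vector of
statistics is corrected for residual inflation by genomic control:
λ = median(χ²)/0.4549 (the 1-df chi-square median), floored at 1.0 so a
deflated scan is never made more significant. Significance uses the fixed
threshold −log₁₀(p) ≥ 3.0 (P < 0.001) with no further multiple-testing
correction — the deliberate convention for this marker density, where
Bonferroni is over-conservative and LD-aware FDR is not estimable.
Monomorphic markers are flagged and excluded from p-value computation.

Gene context is assigned on 1-based inclusive GFF3 coordinates: C within an
exon, I within the gene span but outside exons, F strictly closer than
3000 bp to a gene span, else 0; ambiguity resolves to the nearest gene
boundary, exact ties to the lower gene id; the classification is
strand-agnostic. Markers lacking a chromosome assignment are placed on a
trailing pseudo-chromosome ("chr9"), ordered by input index, for Manhattan
plotting.

## Genomic prediction

All five models operate on the centered marker matrix (no variance
standardisation, matching the ridge equation operating on raw codes) and
expose fitted marker effects plus an intercept.

**RidgeBLUP.** The mixed model y = 1μ + Gu + e with u ~ N(0, σ²_u I) is
fitted by REML on the equivalent single-kernel form (kernel GG′). After one
eigendecomposition of the kernel projected orthogonally to the intercept,
each candidate λ = σ²_e/σ²_u costs O(n); the profiled restricted
log-likelihood is maximised by bounded scalar minimisation in log λ over
[1e-6, 1e6] (xatol 1e-8). Effects are û = G′(GG′ + λI)⁻¹(y − μ̂) with μ̂ the
GLS mean; marker-effect and kernel-form predictions agree to numerical
precision (asserted at 1e-8). A constant response makes λ unbounded; the fit
returns zero effects with a degeneracy flag.

**Bayes A / Bayes B.** Gibbs samplers with marker-specific effect variances
under a scaled inverse-chi-square prior (df 5; scale set so the prior
explains 50% of phenotypic variance, divided by the inclusion probability
for Bayes B); Bayes B adds a point mass at zero with prior inclusion
probability 0.5 (configurable `pi_zero`). Residual variance carries a
matching scaled inverse-chi-square prior. Defaults: 3,000 iterations,
burn-in 500, thinning 5; posterior means are reported. These priors are the
standard defaults of the Bayesian whole-genome-regression software family
and are recorded in the fitted object as configuration.

**Bayesian Lasso.** Double-exponential effect prior via its exponential
scale mixture of normals; 1/τ²_j updates are inverse-Gaussian and λ² carries
a gamma hyperprior (shape 1.1, rate anchored at the standard
data-scaled initial value 2(1−R²)/R²·Σvar(x_j)).

The samplers' single-site updates are sequential, so the kernels are
numba-jitted; chains are seeded and exactly reproducible, and a non-finite
chain state aborts with the iteration index. Monte Carlo noise means
posterior means vary at O(1/√(kept samples)); the suite checks stability
under chain doubling at that tolerance.

**Linear SVR.** ε-insensitive support vector regression with a linear
kernel. The 6 × 10 grid C ∈ {2¹…2⁶} × ε ∈ {0, 0.1, …, 0.9} is scored by
5-fold MSE cross-validation on a seeded random 10% subset of the training
data (the full training data, with a warning, when the subset is too small
for internal CV), and the winner is refit on all training data. The
response is standardised internally — the ε grid only makes sense on a
unit-variance scale — and effects are mapped back to trait units.

## Cross-validation

`kfold_accuracy` repeats, per repetition, a fresh seeded random partition
into 10 near-equal folds, refits the model on each training split (including
any internal tuning, so no test-fold information leaks), and scores accuracy
as the Pearson correlation of pooled out-of-fold predictions with the
observations; the distribution over repetitions (500 by default) is
reported. Folds are unstratified simple random partitions.

A `pooled=False` switch scores the mean of within-fold correlations
instead. The pooled statistic is stable with small folds but is biased
negative for an uninformative model: each fold's predictions track its
training mean, which is anti-correlated with the held-out fold mean, so a
pure-noise phenotype scores below zero rather than at zero (never spuriously
positive — the convention is conservative). The per-fold mode is unbiased
under the null but noisy with ~15-sample folds. Tests calibrate the null in
per-fold mode and assert non-positivity of the pooled null.

## Synthetic data

The generator emulates the study design this package targets: ~154
tetraploid genotypes × ~10⁴ biallelic GBS markers, progenies evaluated in
3 conditions × 3 replicates. Defaults: mean depth 30 reads (sequencing
throughput of ~2.9M reads/sample over ~10⁵ loci), negative-binomial depth
with dispersion 2 (GBS depths are overdispersed; dispersion → ∞ recovers
Poisson), minor-allele frequencies uniform on (0.05, 0.5), target progeny-
mean h² 0.5 (mid-range for fibre-quality traits in this design),
σ²_gc/σ²_g = 0.3 (consistent with mostly high across-condition genetic
correlations and weak progeny-by-condition interaction), condition means 0
(traits are standardized, unitless; configurable to mimic real trait
levels).

Dosages are binomial(4, allele frequency) per sample — panmictic, no
subpopulation structure, matching the target population. By default markers
are independent, which gives a clean null for GWAS calibration but is
pessimistic for prediction: a real reduced-representation panel has strong
local LD, and the effective number of independent segments, not the marker
count, limits accuracy. An optional block-LD mode (`ld_blocks`) draws a
latent dosage per block that each member marker copies with probability
`ld_rho` (default 0.95); the genomic-prediction recovery studies use ~150
blocks, the effective dimensionality implied by moderate prediction
accuracies (0.3–0.4) at n ≈ 154 under the standard accuracy expectation
sqrt(h²·nh²/(nh² + M_e)).

Phenotype calibration is analytic, not post-hoc: marker effects are normal
draws on the chosen QTL (scaled 1/√n_qtl so σ²_g stays O(1)); σ²_gc and
σ²_e are computed from the realized variance of the breeding values so that
h²_B on a progeny-mean basis equals the target in expectation. Replicates
are therefore independent across simulated datasets, and estimator-recovery
studies are unbiased.

What the generator does not emulate: meiotic pedigree structure and
tetrasomic inheritance (dosages are exchangeable draws, not gametes),
realistic allele-frequency spectra, position-dependent LD decay,
genotyping batch effects, and trait scales/units. Passing recovery tests
shows the estimators are correct under their stated model, not that real
alfalfa data meets that model.

## Numerical choices and degenerate inputs

* Missing sentinel −1 (int8) everywhere; VCF `./.`.
* REML searches log λ on [1e-6, 1e6], xatol 1e-8; variance floors 1e-12 in
  the Gibbs chains guard zero-variance responses.
* Negative variance components truncate to 0 with a flag; r_g truncates
  into [−1, 1].
* Genomic-control λ floors at 1.0.
* Imputation, neighbour and mode ties are index-/proximity-deterministic
  (documented above) so permuting samples permutes outputs exactly when
  distances are distinct.
* Empty matrices, constant phenotypes, monomorphic markers and unimputed
  inputs are either handled with flags or rejected with specific errors;
  the pipeline aborts a failed stage by name and leaves `.partial`
  artifacts.

## Scale of the validation studies

The calibration suites run at desk scale: 500 balanced trials for
variance-component recovery (n = 150), 50 null scans of 2,000 markers for
GWAS calibration, 20 seeded chains for Bayes B sparse-QTL recovery
(n = 200, p = 500), and 50 cross-validation repetitions (10 populations × 5
repetitions) for the ridge-BLUP accuracy band — sizes chosen so the full
suite completes in minutes while keeping Monte Carlo error well inside the
asserted tolerances.
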