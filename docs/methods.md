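# Methods

This note documents the statistical models, the numerical choices behind
them, the synthetic data generator's assumptions, and the limitations a user
should know before trusting the output on real data.

## 1. Allele-specific expression (ASE)

### Model

For one SNP/direction pair, condition c and replicate i, the
reference-allele RNA count k_i out of n_i total reads is modelled as

    k_i | n_i ~ BetaBinomial(n_i, mu_c, rho_c),    beta_c = logit(mu_c)

The beta-binomial's overdispersion rho in [0, 1) captures extra-binomial
variance from transfection complexity, PCR and biological noise:
Var(k|n) = n mu (1-mu) (1 + (n-1) rho).  The null expectation for mu is not
0.5 but the reference proportion p0 of the plasmid DNA input library, which
is uneven by construction and estimated from pooled DNA counts with a 0.5
pseudocount (Haldane–Anscombe; keeps monoallelic observations finite).

### Per-replicate fit

`fit_betabinom_mle` maximizes the beta-binomial likelihood of the
pseudocounted counts over beta in [-10, 10] by three-stage grid refinement
(201 points per stage, final resolution ~1e-5).  Grid refinement was chosen
over Newton steps because it is immune to the flat/shouldered likelihoods
that arise at zero-ish depth, vectorizes over hundreds of thousands of fits,
and is exactly allele-swap antisymmetric by construction (the grid and the
likelihood are evaluated in a form where swapping ref/alt negates beta
bitwise, up to refinement-basin ties of order 1e-5).  The standard error is
the inverse root of the negative finite-difference curvature (h = 1e-4) at
the optimum.

### Dispersion

rho is estimated once per condition by maximizing the pooled likelihood over
all pairs and replicates with each pair's mean fixed at its DNA proportion,
bounded to [1e-6, 0.999].  One global rho trades per-SNP flexibility for
stability at 6 replicates.  Two caveats are deliberate:

- With true effects present, fixing the mean at p0 inflates rho (apparent
  dispersion includes real allelic signal).  The per-condition z calibration
  (below) absorbs the resulting deflation of z, so calls remain calibrated;
  the rho *estimate* itself is only unbiased under the null, which is how
  the recovery check is run.
- At least 50 pairs with RNA depth are required; below that the estimator
  refuses and asks for a fixed rho.

### Meta-analysis and the z-score

Replicate effects are combined by a fixed-effect weighted mean.  Weights are
**not** each replicate's own 1/se^2: at effective sample sizes around
n/(1+(n-1)rho) ~ 19 (depth 300, rho 0.05) the estimated se co-varies with
the estimate (information is largest at mu = 0.5), and weighting by it pulls
the mean toward the DNA proportion by several percent of logit(p0).  Because
that bias is shared between conditions it also correlates the two
conditions' z-scores and visibly deflates the GxE statistic.  Instead each
replicate is weighted by its expected information at the pair's pooled
proportion — proportional to its beta-binomial effective sample size — which
is deterministic given the depths and removes the correlation.  The
classical weighting remains available (`weighting="replicate"`), as does
`meta_analyze()`, which applies the textbook 1/se^2 weighting to externally
supplied fits.

The standardized effect is

    z = (beta_meta - logit(p0_hat)) / se_meta

with two corrections applied by default:

- **DNA noise propagation** (`propagate_dna_noise=True`): p0 is itself
  estimated from counts; the delta-method variance of logit(p0_hat),
  1/(dna_ref + 0.5) + 1/(dna_alt + 0.5), is added to se_meta^2.
- **Per-condition genomic control** (`calibrate=True`): lambda_z =
  median(z^2)/median(chi2_1) rescales z (and inflates se_meta by
  sqrt(lambda_z), so z = (beta_meta - logit p0)/se_meta continues to hold
  exactly).  This absorbs the few-percent finite-sample underdispersion of
  the beta-binomial MLE relative to its information-based se, and the rho
  inflation under signal.  It assumes most pairs are null (true for
  realistic effect fractions; the median is robust to ~10-20%
  contamination).

Pairs with fewer than 4 usable replicates (RNA depth > 0) carry no p-value.
BH adjustment runs within condition across all tested pairs (both directions
in one family); significant ASE is q < 0.10.

## 2. Conditional ASE (GxE)

The statistic is (dZ)^2 = (Z_T - Z_C)^2 / 2, chi-squared(1) when both
conditions share one true effect and the z's are independent standard
normals.  Genomic control divides by lambda_GC =
median((dZ)^2)/median(chi2_1) — the chi2_1 median (~0.4549) is computed from
the inverse CDF at run time — before upper-tail chi-squared p-values.
lambda is not floored at 1; deflation is real here and allowed (a warning is
logged).  Only pairs tested in both conditions are eligible; BH across all
eligible pairs, calls at FDR < 5%, plus a nominal p < 0.0215 follow-up set
(a conventional cutoff exposed as a parameter).

A structural note: the two z's share the same DNA-proportion estimate, so
they are never exactly independent — with deep DNA sequencing the shared
variance fraction is ~2%, and Var(z)=1 and Var(Z_T - Z_C)/2 = 1 cannot hold
simultaneously.  Genomic control exists precisely to absorb this; the raw
(dZ)^2 ensemble sits a few percent below chi2_1 and the calibrated
statistic (dZ)^2/lambda_GC is the one that follows chi2_1.

## 3. Differential activity

Per target and orientation, construct counts y (2 alleles x all RNA samples)
follow a negative-binomial GLM with log link:

    log E[y] = log(size_factor) + b0 + b_allele I[alt] + b_trt I[treatment]

- **Size factors**: median-of-ratios over rows with all-positive counts,
  rescaled to geometric mean 1; column-total fallback with a warning.
- **Dispersion**: per-target, profiled by Cox–Reid adjusted likelihood
  (-0.5 log det X'WX penalty), floored at 1e-8, alternating with IRLS
  coefficient fits until convergence.  The CR adjustment matters: at 24
  observations the unadjusted profile MLE underestimates dispersion enough
  to push the 5% type-I error to ~10%.
- **Test**: Wald b_trt/se referred to Student t with residual df (n - 3).
  The t reference compensates for dispersion-estimation noise; measured null
  type-I error is 0.054 at nominal 0.05 with uniform null p-values
  (KS p = 0.65).  A likelihood-ratio variant (`test="lr"`) exists for
  cross-checks.
- No dispersion shrinkage across targets, no independent filtering, no LFC
  shrinkage: this is a deliberately plain, fully specified GLM, not a
  DESeq2 re-implementation, and its outputs will differ from one.

Directions are disjoint BH families; a target is called at q < 0.10 in
either direction, with the sign taken from the qualifying direction
(smaller q on ties).  `pca_qc` provides sample-level QC (SVD of row-centered
log2 normalized counts); `allele_qc_matrix` reshapes to
target-by-(sample, allele) columns so allelic imbalance appears as the
dominant component.

## 4. Motif and annotation enrichment

- **PWM**: entry(b, j) = log2(((count + 0.25)/(colsum + 1)) / 0.25) —
  uniform background, 0.25 per-cell pseudocount (scanner-style defaults; the
  upstream analysis fixes only the threshold).
- **Scan**: additive score over every window, both strands by default
  (the library carries elements in both orientations), windows containing N
  skipped, threshold 10 bits.  The vectorized scanner is tested for exact
  hit equality against an all-windows brute-force oracle.
- **Occurrence filter**: motifs present in fewer than 100 targets (counted
  once per target) are removed; the boundary keeps exactly-100 (`strict=True`
  switches to the greater-than reading).
- **Test of proportions**: observed n_c/n_d against null n_a/n_b, one-sample
  chi-squared with Yates continuity correction and Wilson
  continuity-corrected 95% CI — semantics verified digit-for-digit against
  R's `prop.test`.  Significance at nominal p < 0.05 per the field's
  convention; a BH option exists but is off by default.  Deep in the tail
  the chi-squared p and an exact binomial p diverge by orders of magnitude
  (both microscopic); agreement is on the evidence scale, which is what the
  tests assert.
- **Fisher**: two-sided exact p on the 2x2 significance-by-annotation table,
  conditional-MLE odds ratio, and fold enrichment
  (annotated|significant)/(annotated|non-significant).  Zero margins give
  p = 1 and a missing odds ratio.

Coordinates are 0-based half-open everywhere; a variant is the interval
[pos, pos+1), so `intersect_variants` uses start <= pos < end with literal
chromosome-name matching.

## 5. Synthetic data generator

The generator emulates the statistical structure the analyses assume, at any
scale, with every planted quantity recorded in `SimTruth`:

- **Library**: n targets of 200 nt (even length required; the SNP sits at
  position L/2, 0-based), random uniform sequence, alt allele differing only
  at the center; four FASTA records per target (2 alleles x 2 orientations,
  reverse = reverse complement).  The negative-control fraction defaults to
  the designed library's share (1676/43,556 ~ 3.8%); negative controls have
  all effects exactly zero.
- **Effects**: a fraction `frac_ase` (default 0.1) of SNPs get one shared
  log-odds effect ~ N(0, effect_sd^2), effect_sd default 1; `frac_case`
  (default 0.05) get independent per-condition effects — the simplest
  structure that makes Z_T != Z_C detectable.  The defaults for these
  fractions and the effect scale are conventions chosen to represent "a
  minority of real effects at reporter-assay-sized magnitudes"; the source
  study does not report its true fractions.  Both directions share the same
  effects unless `direction_specific_effects` is set.
- **DNA library**: per-pair reference proportions p0 ~ Beta(c, c), c = 5 by
  default (visibly uneven input proportions).  DNA depth is 20x the RNA
  per-replicate depth with mild depth dispersion (0.05) and binomial allele
  sampling (rho_dna = 0): one deeply sequenced input pool, which is also
  what makes the no-DNA-noise-in-the-truth comparison meaningful.
- **RNA counts**: per SNP/direction/condition/replicate, total depth ~
  NB(mean 300, dispersion 0.3) — heavy-tailed on purpose, to stress the
  >= 4-replicate filter — and reference counts ~ BetaBinomial(depth, mu,
  rho = 0.05) with logit(mu) = logit(p0) + beta_condition.
- **Activity counts**: NB with mean baseline x size_factor x
  2^(lfc_allele I[alt] + true_da_lfc I[treatment]); log-normal baselines
  around the RNA depth, log-normal size factors (sd 0.2), NB dispersion
  0.05, `da_frac` targets (default 0.1) with treatment log2 fold-changes ~
  N(0, 0.5^2).  The allele activity effect is derived from the allelic
  expression truth (lfc_allele = -mean(true betas)/ln 2), so negative
  controls stay flat and allele is the dominant PCA component, as in real
  data.
- **Motif planting**: consensus sequences of supplied PFMs substituted at
  random offsets; the first motif is planted at `motif_ase_multiplier` (2x)
  the base rate (0.15) in true-ASE targets, the rest uniformly.  If a
  planted consensus covers the center position the SNP is re-derived so the
  target stays biallelic.
- **Determinism**: one integer seed; identical configs give byte-identical
  FASTA/TSV outputs.  Sub-streams for library, allele counts and activity
  counts are spawned from (seed, stage) so the stages are independently
  reproducible.

### What the generator does not emulate

No read-level artifacts (mapping bias, UMI errors, PCR duplicates), no
linkage between SNPs, no batch structure beyond scalar size factors, no
condition-dependent dispersion, and planted motifs carry no actual
regulatory mechanism — enrichment is induced by correlated planting, not by
sequence function.  Passing tests therefore demonstrate statistical
correctness and calibration of the pipeline under its assumed model, not
robustness to upstream experimental artifacts.

## 6. Problem sizes used in the checks

The shipped test suite and acceptance script run at desk scale, chosen so
each stage's sampling error is well below the tolerances asserted: 20,000
SNP/direction pairs for null calibration and FDR checks (the study's own
test set is ~50,914 pairs), 5,000 pairs for dispersion recovery, 2,500
targets x 2 directions for differential-activity type-I error, 400 targets
at depth 500 for fold-change recovery, and 20 seeded replicates of a
2,000-target library for enrichment power.  Full-library scale (43,556
targets) changes nothing but runtime; the combinatorics are verified
exactly.

## 7. Known limitations

- One global rho per condition; SNPs with genuinely atypical dispersion are
  mis-weighted (standard for this assay class).
- The z genomic control assumes a mostly-null ensemble; on a library where
  most variants are functional, lambda_z would absorb real signal.
- The cASE statistic inherits the shared-DNA-noise correlation described in
  section 2; with a shallow DNA library (< ~5x RNA depth) lambda_GC drifts
  further below 1 and power is lost, though calibration is maintained.
- The differential-activity GLM has no DNA-input offset; it measures
  treatment effects on output counts, not on activity normalized to input.
- Negative controls are carried as labels and simulated as exact nulls; the
  analyses do not use them for calibration (mirroring how computational
  negative-control predictions are treated with suspicion in this assay).
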