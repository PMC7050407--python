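# Methods

## The scientific problem

At a heterozygous SNP, RNA-seq reads can be assigned to the two alleles;
an imbalance between the allelic read counts (allele-specific expression,
ASE) indicates cis-acting regulation.  This package tests whether that
imbalance *differs between two subject groups* (here alcohol-use-disorder
cases vs controls, across several brain regions), screens candidate 3'UTR
variants for regulatory activity with a pooled reporter assay read out by
UMI-tagged sequencing, and asks whether allelic ratios respond to an
ethanol dose in cultured cells.  Because each analysis contrasts
conditions at the same site, reference-mapping bias — which affects both
conditions identically — largely cancels; no per-allele bias correction
is applied, and this is a stated assumption, not a correction.

## Count model

All tests are negative-binomial (NB2) regressions with a log link:

    log mu = b0 + b1*X1 + b2*X2 + b12*X1*X2 [+ offset] [+ b_s]

* `X1` — allele (0 reference, 1 alternative)
* `X2` — condition (0 control/DNA/dose-0, 1 AUD/RNA; or a continuous
  dose in mM)
* `b12` — the quantity of interest: the change of the log alt:ref ratio
  between conditions ("adjusted log2 fold change" = `b12 / ln 2`)
* `b_s ~ Normal(0, sigma_b^2)` — a random intercept per subject (brain
  analysis) or per replicate library (dose analysis) absorbing the
  pairing of the two allele counts measured in the same RNA pool
* NB2 dispersion `theta`: `Var(y) = mu + mu^2/theta`, one `theta` per
  fit; `theta -> inf` recovers Poisson.

The null hypothesis in every screen is `b12 = 0` (no condition-dependent
allelic imbalance).

## Fitting

**Fixed-effects GLM** (reporter assay): `beta` is profiled out by IRLS
with Fisher weights `mu*theta/(mu+theta)`; `log theta` is maximised by a
bounded scalar search, capped at 1e8 (Poisson limit).  Library depth
enters as an offset (log total UMI count of each replicate-source
library), not as free parameters.

**Random-intercept GLMM** (brain and dose analyses): Laplace-approximate
marginal likelihood.  The conditional mode of each subject's `b_s` is
found by a per-subject Newton solve (the conditional log-density is
strictly concave; tolerance 1e-10), and the outer problem over
`(beta, log theta, log sigma_b)` is solved by L-BFGS-B with *analytic*
gradients of the Laplace objective, including the implicit dependence of
the modes and curvatures on the parameters (verified against numeric
differentiation in the test suite).  `sigma_b` below 1e-6 is declared on
the zero boundary and the fit demotes to the GLM.  Degenerate designs
(an all-zero design cell) are flagged and excluded downstream, never
patched with pseudocounts, because pseudocounts bias `b12`.

### Dispersion estimation: Cox–Reid adjustment

Plain ML underestimates dispersion in small samples (it ignores the
degrees of freedom spent on `beta`), which makes Wald tests
anticonservative.  By default both fitters therefore estimate
`theta` (and `sigma_b`) by maximising the Cox–Reid adjusted profile
likelihood — the (Laplace) log-likelihood minus half the log-determinant
of the fixed-effect Fisher information — the same REML-like correction
used by standard count-model packages.  `beta` itself stays at its ML
value given the dispersions (two alternating refinement passes).
`dispersion="ml"` disables the adjustment.

### Standard errors: dispersion uncertainty and moment matching

The covariance of the fixed effects is the `beta` block of the inverse
*observed* information over all parameters, so dispersion and
variance-component uncertainty propagate into the standard errors.  Even
then, a Wald statistic normalised by an SE computed at *estimated*
dispersions behaves like a t variable with finite degrees of freedom,
not a normal one.  Each coefficient's effective degrees of freedom are
estimated by Satterthwaite's rule (delta method on the plug-in variance
over the dispersion parameters) and the variance is inflated by the t
moment ratio `nu/(nu-2)`, so the normal-referenced Wald p-value has
approximately the t calibration.  With both corrections the measured
type-I error at alpha = 0.05 is ~0.05 under the small-sample null
conditions exercised in the acceptance suite (5+5 heterozygotes at depth
50 for the GLMM; 6 replicates for the reporter GLM); without them it is
0.09–0.11.  A likelihood-ratio mode (`test="lrt"`) is available but is
not better calibrated at these sizes and is not the default.

### Quadrature oracle

`loglik_oracle` evaluates the marginal likelihood independently by
adaptive Gauss–Hermite quadrature (default 32 nodes, centred and scaled
at each subject's conditional mode, log-sum-exp guarded).  It was
verified against direct numerical integration to 1e-13.  The test suite
compares the Laplace value against it on datasets with deep
(~1000 reads/observation), weakly-overdispersed counts, where the
approximation error is below 3e-4 and any disagreement indicates an
implementation defect.  **Limitation:** for strongly over-dispersed
shallow data (theta ~ 10, tens of reads) the intrinsic Laplace error is
of order 1e-3–1e-2 log-likelihood units per fit.  This displaces the
likelihood value, but the induced bias on `b12` is negligible at the
study scale (measured recovery bias < 0.01 on the natural-log scale).

## Multiple testing and significance calls

Benjamini–Hochberg q-values are computed within each brain region (and
within each cell line) separately; a pooled mode exists behind a flag.
The headline call combines `q < 0.05` with an effect-size threshold
`|adj log2 FC| > 1`; because "log2 fold change" and the natural-log model
coefficient differ by `ln 2`, the scale the threshold applies to is an
explicit option (`effect_scale="log2"` default, `"natural"` available)
rather than a silent choice.  Cross-region consistency anchors on SNPs
passing FDR alone in a primary region (no effect-size cut) and counts
sign-concordant replications at `p < 0.05` elsewhere; SNPs missing from
a secondary region are skipped, not counted discordant.

## Testability filters

A subject contributes to a SNP only when genotyped heterozygous (array
genotypes; a count-based het heuristic exists but is off by default and
flagged) and carrying strictly more than 10 reads at the site; a SNP is
testable with at least five qualifying heterozygotes in *both* groups.
The ">10" and ">15" (ethanol mean depth) thresholds are strict
inequalities — the plain reading of "more than".  Every exclusion is
written to an audit table with its reason.  Multi-allelic sites and
multiple samples per subject-region are rejected outright.

## Reporter-assay pipeline

Reads are `barcode (8 nt) + UMI (10 nt) + designed insert`; the exact
layout of any particular assay varies, so both lengths are parameters
and the defaults are this package's documented convention.
Demultiplexing matches the leading barcode exactly by default
(`max_mismatch` optional; equidistant ties are always unassigned).
Allele assignment is by exact sequence identity against the designed
inserts — the inserts are short synthetic sequences whose single variant
base is known, so alignment heuristics would add only nondeterminism; a
read covering only shared flank is "ambiguous".  UMI deduplication
defaults to `unique` (count distinct UMIs — deterministic and exact in
error-free simulation); `directional` implements the standard
count-adjacency network collapse (absorb B into A when Hamming(A,B) = 1
and count(A) >= 2*count(B) - 1).  Read tallies are conserved at every
stage and checked.

A SNP is "detected" when both alleles have nonzero RNA UMI counts in
every cell line screened (expression is the readout; plasmid DNA counts
are nearly always present by construction).  The activity test requires
both alleles in both sources.

## Synthetic data generator

The generator emulates the statistical structure the models assume — it
is the study stand-in, not a sequencing simulator:

* **Brain cohort**: 30+30 subjects by default, four regions, one sample
  per subject per region; heterozygosity i.i.d. per (subject, SNP) with
  probability `het_prob` (default 0.5; non-het mass split evenly between
  homozygotes).  Counts are NB draws under the GLMM above with a fresh
  `b_s` per (subject, SNP, region) — matching the per-SNP model, which
  treats SNPs independently.  `beta0` is calibrated so the expected
  total per heterozygote equals `depth_mean` in both groups, including
  the log-normal mean factor `exp(sigma_b^2/2)` of the random intercept,
  keeping the depth filters group-neutral.
* **Reporter reads**: NB molecule counts per construct and condition
  (mean 300, theta 20, six replicates, two cell lines); planted allelic
  activity scales the RNA alternative-allele mean by `exp(effect)`.
  Each molecule draws a random 10-nt UMI and is emitted
  `Geometric(1 - duplication_rate)` times (a single-parameter PCR model);
  the truth table records distinct-UMI molecule counts so the error-free
  round trip is exact by construction.  Constant Q30 qualities.
* **Dose counts**: NB draws with `log(alt/ref) = base + slope*dose` and
  a per-replicate library intercept (SD 0.1).

Defaults `theta = 10` and `sigma_b = 0.3` are plausible mid-range values
for deep bulk RNA-seq, chosen once; the real study's per-SNP dispersions
are unpublished, so these are stand-ins, not estimates.  What passing
tests show is therefore that the *pipeline* is correct and calibrated
under its own assumptions — not that real brain data meet those
assumptions (no mapping bias, no genotyping error, no correlated SNPs,
no sequencing-error model beyond optional uniform substitution).

## Randomness and determinism

Every generator takes an explicit integer seed and threads a single
`numpy.random.Generator`; identical configs give byte-identical outputs
(including FASTQ order, which is shuffled deterministically).  Fitting
contains no randomness.  `scripts/acceptance.py` derives all child seeds
from its `--seed`.

## Problem sizes in the checks

The acceptance suite runs 2000 null cohorts for GLMM calibration, 1000
for the reporter GLM, 500 replicates for effect recovery, 20 runs of
475 null + 25 planted SNPs for FDR control, and 200 dose-response
recoveries; the acceptance script reports the same quantities at
somewhat smaller replicate counts.  These sizes give Monte-Carlo
standard errors comfortably inside each stated tolerance.

## Known limitations

* Laplace accuracy at strongly over-dispersed shallow counts (above).
* The Satterthwaite inflation is itself a first-order approximation;
  calibration was verified at the study design points, not asymptotically.
* The dose-response model (continuous dose, allele-by-dose interaction,
  replicate random intercept, pooled timepoints with an optional
  timepoint covariate) is this package's reconstruction of an
  incompletely specified analysis; a categorical-dose LRT mode exists.
* The generator plants a single common effect size per run rather than a
  distribution of effects.
* No beta-binomial alternative, no random slopes, no haplotype models.
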