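# Methods

## Model and tests

For a gene with m SNPs the outcome model is
Y = Zβ + diag(E)Gπ + diag(E)Gδ with Z = [X, E, G].  π is read as a
scalar coefficient on the weighted SNP sum (the burden reading); an
m-vector fixed-effect reading is not estimable when m approaches or
exceeds n and is not attempted.  δ are exchangeable random interaction
effects with variance τ; testing τ = 0 gives the heterogeneous
component.

**Null model.**  X and E enter unpenalized; the G main-effect block is
ridge-penalized because m (tens to ~1000 SNPs per gene) routinely
exceeds n (~130–160 subjects per timepoint).  The unpenalized block is
partialled out by QR, the residualized G block is decomposed by SVD,
and the ridge penalty λ is chosen by generalized cross-validation on a
45-point log-spaced grid centred on the mean squared singular value
(user-fixable; λ = 0 reproduces OLS exactly on full-rank problems).
The residual operator M = I − P_U − S_λ is symmetric but not
idempotent; everywhere a variance is needed we use M² rather than M,
which coincides with the projection formula in the unpenalized case.
Residual variance is σ̂² = ‖r‖²/(n − edf) with edf the effective
degrees of freedom p_U + tr(S_λ).  An alternative to ridge (top
principal components of G) was considered and rejected: ridge keeps
every SNP's main effect partially in the model and has the GESAT-style
precedent for this test family.

**Burden (accumulative) test.**  s = diag(E_c)Gw with equal weights by
default (Beta(1,25)-of-MAF weights by flag); the score statistic
(sᵀr)²/(σ̂²‖Ms‖²) is referred to χ²₁.  E_c is the mean-centred
exposure: interaction regressors are always built from centred E, which
makes every reported p-value exactly invariant to location shifts of
the exposure (the E main-effect column's location is absorbed by the
intercept).  The exposure's scale and the outcome's units cancel in the
statistics; invariance is asserted to 1e-10 in the test suite.

**Variance-component (heterogeneous) test.**  With
C = diag(E_c)GW^{1/2}, Q = rᵀCCᵀr/(2σ̂²).  The large-sample null is
Σλᵢχ²₁ with λᵢ the nonzero eigenvalues of ½(MC)ᵀ(MC); these are
reported for diagnostics.  The p-value itself uses the exact
finite-sample construction: the event Q ≥ q is the indefinite
quadratic form Yᵀ(M₂CCᵀM₂ − (2q/ν)M²)Y ≥ 0 (ν = n − edf), evaluated by
signed-eigenvalue characteristic-function inversion.  This absorbs the
randomness of the plug-in σ̂², which at ν ≈ 130 otherwise distorts the
bulk of the null distribution noticeably (the combined p-value's
KS-uniformity fails without it); a 200,000-draw residual-permutation
oracle in the test suite confirms the construction.

**Mixture tail probabilities.**  P(Σλᵢχ²₁ ≥ q) is computed by an
error-bounded Gil–Pelaez midpoint sum (the Davies/Imhof approach): the
grid step places the aliasing period beyond q + |Σλ| + 30·sd(Q), and
the truncation point bounds the integrand tail analytically.  Exact
closed forms are used when all eigenvalues coincide (scaled χ²,
covering the single-eigenvalue case).  When the inversion is infeasible
(e.g. two highly unequal eigenvalues demand >2.5M grid points) or
returns a value outside (0, 1] — in practice the far tail below ~1e-15
— a Liu-style non-central-χ² moment match is substituted and flagged
`liu_fallback`.  Eigenvalues below 1e-10 of the largest are truncated.

**Combination.**  p_combined = Fisher's χ²₄ combination of p_fixed and
p_vc.  The variance-component stage is computed on residuals deflated
by the (M-transformed) burden regressor, supporting the independence
assumption; the decomposition is always reported alongside the
combination so the rule is auditable.  An optional small-sample guard
recomputes p_vc by seeded residual permutation (default 1e5
permutations, full statistic recomputation per permutation) whenever
the Davies and Liu values disagree by more than a factor of 2.

## Input handling

* Genotypes: VCF v4.x via cyvcf2 (DS dosage field preferred, GT hard
  calls otherwise, multi-allelic records skipped with a warning) or a
  plain CSV dosage table (`subject_id` column plus one column per SNP,
  values in [0,2] or NA; SNP metadata from an optional sidecar table,
  otherwise synthesized).  Coordinates are 1-based inclusive; BED locus
  files are converted from 0-based half-open.
* Gene windows: locus ± 1 kb flank by default.
* Hardy–Weinberg: the exact conditional test on heterozygote counts,
  computed in log-space with a parity-respecting enumeration; exact at
  the small per-gene sample sizes involved.  Fractional dosages are
  rounded to hard calls for counting (ties round half up).  Correction
  is Bonferroni by default (Benjamini–Hochberg by flag) across the SNPs
  of the extracted window.  Monomorphic SNPs are removed regardless.
* Missingness: dosages mean-imputed per SNP (2×allele frequency); SNPs
  with >10% missing dropped.
* Phenotypes: listwise-complete rows; sex coded female = 0; education
  and ethnicity dummy-coded against the most frequent category (coding
  affects only intercept interpretation — the tests are invariant, and
  the suite asserts it).  Questionnaire totals are prorated by
  n_items/n_answered when at least 8 of 10 items were answered and kept
  fractional; fewer answered items give a missing total.
* The postnatal exposure enters X whenever the analyzed timepoint is
  not "birth" and the column exists.  Timepoints are analyzed
  independently; there is no longitudinal pooling.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not any real cohort's raw data:

* Genotypes: latent AR(1) Gaussian per subject thresholded at the
  normal quantiles of (1−p)² and (1−p)²+2p(1−p), giving hard calls that
  are marginally in Hardy–Weinberg proportions with LD controlled by
  ld_rho; MAFs uniform on [0.05, 0.5]; optional clipped Gaussian jitter
  mimics imputed fractional dosages.
* Exposure: Normal(8.56, 4.50) rounded and clamped to [0, 30] — the
  first two moments and support of a 10-item 0–3 screening scale.
  Item-level questionnaire simulation is deliberately omitted: only the
  score's moments and support reach the analysis.
* Covariates: sex 87/161 male; ethnicity 45.3/41.6/13.0% in three
  groups; education in five bands (3.7/33.5/44.7/14.3/3.7%); age
  0.027 ± 0.01 years at the birth timepoint.
* Outcome: intercept 1700 mm³ and residual SD 250 mm³, scaled like a
  neonatal amygdala volume; per-SNP main effects N(0, 10²) mm³ per
  allele; exposure main effect 5 mm³ per point.  Interaction terms use
  the raw exposure, as in the analysis model; δ is redrawn per
  replicate (a fixed-δ mode supports exact recovery tests).
* Scenario presets fix the study conditions for testing: null
  (π = τ = 0), burden (π = 1.2, τ = 0), heterogeneous (π = 0, τ = 25),
  mixed (π = 0.8, τ = 12).  The magnitudes were set once by a power
  calculation targeting mid-range (~20–50%) power at n = 161, m = 50 so
  that power orderings are informative rather than saturated.
* `simulate_scan_dataset` places independent gene blocks 100 kb apart
  with interaction effects confined to one causal gene.

What passing tests on these data do **not** show: robustness to
realistic LD (AR(1) only), to population stratification, to
non-Gaussian residuals, to informative missingness, or to measurement
error in the exposure; and the generator's covariate mixes carry no
real confounding structure.

## Post-hoc analysis

The gene-expression score sums, per subject, the dosage of the
expression-increasing allele over eQTL-annotated SNPs (dosage d if that
allele is alt, 2−d if ref).  Annotations are a declared input file, so
the pipeline is reproducible offline; no live eQTL lookup is performed.
The "low/high expression group" analysis is implemented as simple
slopes of the continuous-interaction model Y ~ covariates + E + GES +
E×GES evaluated at GES mean ± 1 SD, which is what a simple-slope
analysis names; a subgroup-split mode (separate regressions above and
below the GES mean) is available behind a flag for sensitivity.

## Scan and sensitivity pipeline

The scan iterates genes × outcomes × timepoints, recording skipped
genes (zero surviving SNPs) without aborting, and emits a long table
with full diagnostics, a wide genes-by-columns table of combined
p-values, uncorrected significance flags at 0.05 and 0.1,
Benjamini–Hochberg-adjusted columns, and JSON run metadata (seed,
version, config hash).  Any outcome column runs through identical
machinery, so a reference-region control (e.g. a cortical-thickness
column) needs no special casing.  The maternal sensitivity re-analysis
compresses maternal dosages of the same SNP window to principal
components retaining 90% variance, capped at n/10 columns, and appends
them to X.

## Numerical choices and degenerate inputs

* GCV grid: 45 points, 1e-4–1e4 × mean squared singular value.
* Burden regressors numerically inside the null span (sᵀM²s ≤
  1e-12 sᵀs) yield p = 1 with a degeneracy flag; an exposure without
  variance is an error.
* All-zero C gives Q = 0, p = 1; eigenvalues below 1e-10 of the
  largest are truncated.
* Ties in the exact HWE test are compared with a 1e-10 log-scale
  tolerance; the exhaustive oracle comparison (all genotype triples
  with total ≤ 200) bounds the resulting error below 1e-12.
* Seeds: every stochastic component takes an explicit seed; the scan
  records it in the output metadata.

## Known limitations

* A very strong interaction at one gene leaks, at finite n, into other
  genes' tests through the shared exposure (their interaction
  regressors are all modulated by the same E); with moderate effects
  the leakage is negligible, but extreme spike-ins visibly inflate
  neighbouring genes.  This is a property of gene-by-gene G×E scans,
  not of the implementation.
* The ridge null model absorbs G main effects only partially; with
  very large main effects relative to noise, a small conservative bias
  remains.
* The burden p-value uses the χ²₁ reference with plug-in σ̂² (adequate
  at ν ≳ 100 and empirically uniform in the suite); only the
  variance-component stage uses the exact ratio construction.
* Proration of questionnaire totals assumes missing items are
  exchangeable with answered ones.

## Problem sizes in the test suite

Calibration and power checks run at the emulated study's scale
(n = 160, m = 50): 2000 null replicates for size and uniformity, 500
replicates per power scenario, 100 ten-gene scans for spike-in ranking
(spike effects π = 8, τ = 500 — deliberately strong so ranking, not
power, is what is measured), 200 moderation replicates at n = 500 for
slope coverage, and exhaustive HWE verification to totals of 200.
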