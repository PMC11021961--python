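# Methods

This note documents the models and procedures implemented in `glycopanel`,
the assumptions they rest on, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Composition model and annotation

Glycans are represented as monosaccharide compositions over the residue
alphabet Hex / HexNAc / dHex / NeuAc, with residue monoisotopic masses
162.05282 / 203.07937 / 146.05791 / 291.09542 Da (verified in the tests
against elemental summation), plus 18.01056 Da of water for the free
reducing end. N-glycan validity requires HexNAc ≥ 2 and Hex ≥ 3 (the
chitobiose core with the trimannosyl arms) and dHex ≤ HexNAc. Ions are
modeled exclusively as singly charged [M+Na]⁺ (sodium cation mass 22.98922
Da, electron-corrected): MALDI of underivatized neutral and acidic glycans
with NaCl-doped matrix is dominated by this species, and multiple adducts,
salt exchange on sialic acids, in-source decay and isotope envelopes are out
of scope. Sialylated compositions are therefore matched at their plain
sodiated mass.

The structural classification is composition-based and is a convention, not
a structure determination: HexNAc = 2 with Hex ≥ 5 and no fucose/sialic acid
is high-mannose; HexNAc ≥ 4 is complex; HexNAc = 3 with Hex ≥ 5 is hybrid;
every other valid composition (paucimannose/truncated) defaults to complex.
MS of intact glycans cannot resolve isomers, so any composition-level class
assignment embodies exactly this kind of rule; users with orthogonal
evidence can redefine class-dependent traits through the catalog.

Peak matching assigns each target the nearest peak within ±0.2 Da, the
centroiding peak width reused as tolerance — appropriate for reflectron
MALDI-TOF resolution in the 1000–3000 Da range, and unambiguous for the
bundled registry, whose pairwise target spacing exceeds 1 Da. Conflicts are
resolved globally by ascending absolute mass error with ties broken toward
the lower theoretical mass; a target whose nearest peak is claimed falls
back to its next-nearest free peak. Target pairs closer than twice the
tolerance are logged as ambiguous rather than rejected.

### Default registry

The bundled 27-composition registry (5 high-mannose, 3 hybrid, 19 complex,
including H5N4, H5N5F1 and H5N4S2) is this package's own plausible serum
panel: serum cohorts quantify on the order of two to three dozen reliably
detected compositions spanning these classes. It is a default annotation
target list, not a claim about any particular cohort, and is replaceable by
a one-composition-per-line text file.

## Replicate QC and normalization

Technical replicates (three by design) are averaged per composition. An
unmatched target contributes area 0 to the mean by default (absence =
below detection, keeping the replicate count as denominator); a
`skip` policy averaging only matched replicates is available. The replicate
CV uses the sample standard deviation (n−1) over the mean and is undefined
(missing) when the mean is zero. Compositions are kept when detected in
strictly more than 50% of all individual spectra (spectrum-wise, not
sample-wise, counting) and when their median across-sample replicate CV is
strictly below 20%; the per-composition aggregate over samples is the
median, which is robust to the occasional sample whose low abundance
inflates its CV. Normalization divides each sample's mean areas by that
sample's total over the selected compositions, so fractions sum to one by
construction; all downstream quantities consume these closed fractions and
are invariant to any per-spectrum intensity scale.

## Derived traits

A trait is Σ(numerator fractions)/Σ(denominator fractions), with the
denominator keyword `total` meaning the full quantified set (denominator 1
after normalization). Fraction-type traits require the numerator subset to
lie inside the denominator subset and are bounded in [0, 1]; ratio-type
traits (e.g. neutral:sialylated) are free ratios of disjoint subsets. A zero
denominator yields a missing value — never zero, never an error — and
missing values are dropped pairwise by downstream tests, not imputed.
Predicates are data: a whitelisted expression subset (attributes, integer or
string constants, comparisons, and/or/not) validated on the syntax tree, so
catalogs remain auditable, portable and safe to load.

The bundled 47-trait catalog (IGP28–IGP74) covers charge fractions and their
conditional variants, fucosylation overall and within charge/antennarity
strata, structural-class fractions and shares, galactosylation proxies by
hexose count, antennarity by HexNAc count, and three free ratios. Like the
registry it is the package's own documented trait set; a study with its own
formula sheet reproduces it exactly by supplying a replacement YAML catalog.
IGP28 (neutral) and IGP29 (sialylated) are exact complements, which the
tests use as a closure check.

## Differential screening

All unordered group pairs are tested per feature. The rank-sum p-value uses
exact enumeration when the combined sample size is ≤ 20 with no ties, and
the tie-corrected normal approximation with continuity correction otherwise;
samples in which every pooled observation is identical return p = 1. The
flag gate is ((FC > 1.1 or FC < 0.9) and p < 0.05) with strict inequalities
at the fold-change boundaries; fold change is the ratio of group means
(median mode available) of the normalized features. No multiplicity
correction is applied by default — the screening design treats the gate as a
descriptive filter — and Benjamini–Hochberg adjustment is available for
reuse where control of the false discovery rate matters. The combined gate
keeps the null flag rate far below the nominal 5% (the fold-change condition
and the p-value condition must coincide), which the calibration test
verifies on 1000 null features.

## Panel models

Candidates are standardized (z-score) before penalization; reported
coefficients are on the original scale. The λ grid is glmnet-style: 100
log-spaced values from λ_max = max|Xᵀ(y − ȳ)|/n (the smallest penalty
zeroing every slope) down to 10⁻³λ_max, with the intercept unpenalized.
λ.min minimizes the stratified 10-fold cross-validated binomial deviance;
the fold assignment is a pure function of the seed, and every stochastic
step in a multi-contrast analysis consumes a deterministic sub-seed of the
single root seed. The ℓ1 solver is liblinear with C = 1/(nλ) and a fixed
internal ordering, making the whole path bit-reproducible.

The features with nonzero coefficients at λ.min are refitted by unpenalized
maximum likelihood (Newton/IRLS to tight tolerance) and reduced by backward
elimination: the least significant term is removed and the model refitted
until every retained term has Wald p < 0.05. This iterated rule — rather
than a single pruning pass — is the standard construction of a panel of
*independent* contributors: after a removal the remaining terms'
significance must be re-established, and the final model then satisfies its
own retention criterion. If no term ever reaches significance the selected
set is retained whole and the results are flagged. Exactly collinear
selections (e.g. complement traits that sum to one) are reduced greedily
before refitting. Perfect separation is detected from a diverging fitted
linear predictor and triggers a documented ridge fallback (L2-penalized
coefficients, no Wald inference, flagged in the results) so that small or
strongly separated cohorts still yield a scored model.

Odds ratios are exp(β) with Wald 95% intervals. The AUC is the Mann–Whitney
statistic with ties counted one half; its confidence interval uses the
DeLong placement-value variance, truncated to [0, 1]. The nomogram maps each
feature's observed range linearly onto points, anchored at the range end
minimizing β·x so points are non-negative, scaled so the largest
|β|·range spans 0–100 points; the total-points → probability map inverts the
implied linear predictor exactly, so nomogram probabilities equal model
probabilities to numerical precision (verified to 1e-9).

Five default contrasts mirror the study design: stenosis
(1/2/3-CAD) vs pooled no-stenosis (H1 + 0-CAD) on glycan features, and
one-vs-rest for each grade within the four patient groups, the latter each
rerun with the clinical covariates (age, sex, LDL, HDL, TC) added to the
candidate set to report whether any covariate survives selection. One-vs-rest
framing is a design choice — cumulative (≥ grade) classifiers are an equally
defensible reading and can be expressed through custom `ContrastSpec`s.
Forest plots in the clinical literature sometimes label these effects "HR";
a logistic model has no hazard scale and this package reports odds ratios.

## Synthetic cohorts

Three generators, all pure functions of configuration and seed:

* **Spectral cohorts** (`generate_cohort`) emulate the full study design:
  27 + 4×33 samples, three replicates each (477 spectra). Per-composition
  baseline abundances ramp log-linearly over two orders of magnitude (serum
  glycomes are heavily skewed toward a few dominant species); per-sample
  biological variation is log-normal with σ_log = 0.25; replicate rendering
  applies multiplicative log-normal noise of CV 5%, Gaussian m/z jitter of
  SD 0.03 Da (≈6.7 SD inside the 0.2 Da tolerance), per-replicate dropout at
  a configurable missingness rate (default 0), and 60 decoy peaks per
  spectrum drawn uniformly over the scan range but excluded from ±0.5 Da of
  every target, with S/N straddling the acquisition threshold. Group effects
  are multiplicative on the raw-abundance scale; the induced fold change on
  normalized fractions — including the closure effect pushing all other
  fractions the opposite way — is recorded in closed form in the ground
  truth. Clinical covariates default to group-independent normals
  (age ~ N(65, 8) years; LDL/HDL/TC/TG ~ mmol/L-scale normals; sex
  Bernoulli(½)), supporting the null-covariate exclusion test.
* **Feature-level cohorts** (`simulate_feature_table`) draw the 74-feature
  table directly as log-normal features with multiplicative group shifts on
  named features, σ_log = 0.10 by default. This is the differential-stage
  fixture: planting at the composition level necessarily leaks into every
  other fraction (closure) and into the derived traits, so "exactly the
  planted features respond" is only a well-posed contract at feature level.
  σ_log = 0.10 was chosen by a power argument: a 1.5-fold shift at
  n = 25/group is then detected with probability ≈ 1, while a null feature
  needs a ≈3.4-SD excursion of its mean difference to clear the
  fold-change gate, keeping the expected count of false any-flags well below
  one across 74 features × 10 pairs. The default planted set is the 18
  feature labels the screening stage is expected to recover.
* **Panel cohorts** (`simulate_panel_cohort`) use a Gaussian location-shift
  construction with an exactly known optimum: k independent unit-variance
  informative features shifted by δ in the stenosis classes give the optimal
  discriminant AUC = Φ(√(kδ²)/√2), inverted to hit a configured
  construction AUC (default 0.9 with k = 3). All other features and all
  clinical covariates are independent of the outcome.

What passing these tests shows — and does not. The generators reproduce the
statistical structure the pipeline assumes: planted signal recovery through
annotation/QC, calibration of the screening gate, and parameter/AUC recovery
of the panels. They do not reproduce instrument physics (isotope envelopes,
detector saturation, matrix clusters, mass-dependent resolution or
calibration drift), batch effects, biological covariance among glycan
features, or missingness correlated with abundance. Success on synthetic
cohorts therefore validates the *computation*, not the biology; in-sample
panel AUCs on small cohorts remain optimistically biased, here as in the
study design this package mirrors, and external validation is the only cure.

## Numerical choices and degenerate inputs

* S/N threshold is closed (≥ 4); peaks with unknown S/N are retained unless
  strict mode is requested.
* Matching ties (equal |mass error|) resolve toward the lower theoretical
  mass; assignment is invariant to peak and target ordering.
* Row-sum closure after normalization is exact to 1e-9 and asserted.
* The exact/asymptotic Wilcoxon switch is at combined n = 20; the two
  branches agree to ~0.01 in the decision-relevant p < 0.1 region at sizes
  8–10 (the continuity-corrected approximation can differ by up to ~0.015
  near p ≈ 0.5, where nothing depends on it).
* IRLS convergence is to gradient norm < 1e-8 equivalent (statsmodels
  Newton, tol 1e-10); the ℓ1 path at λ = 0 matches the unpenalized MLE to
  1e-4 and at λ ≥ λ_max is exactly null.
* All-zero quantified samples, empty selections, one-class contrasts,
  zero-range nomogram features and zero-replicate samples raise named
  errors; zero denominators in traits propagate as missing.
* Group pairs with fewer than two samples a side are skipped with a warning;
  cross-validation folds reduce automatically to the minority class size.

## Problem sizes used in the test suite

The acceptance-style checks run the full 159 × 3 design for annotation/QC
recovery (50 seeds) and the screening and panel recoveries at the design
sizes stated above (20 seeds each); null calibration uses 1000 simulated
features in one cohort. These sizes make the whole suite complete in a few
minutes on one CPU while leaving the Monte-Carlo margins comfortable.

## Known limitations

* Composition-level annotation cannot distinguish isomers; the structural
  classes and the galactosylation/antennarity traits are proxies.
* The default registry and trait catalog are field-plausible stand-ins, not
  a reproduction of any specific study's supplementary formula sheet; exact
  reproduction requires supplying that sheet as configuration.
* Sodiated singly charged ions only; potassiated/protonated species and
  sialic-acid salt forms are not modeled.
* No batch-effect handling or cross-run recalibration: inputs are assumed to
  come from one calibrated acquisition campaign.
* The screening stage is uncorrected for multiplicity by design; its output
  is a candidate list for the modelling stage, not an inferential endpoint.
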