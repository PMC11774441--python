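# Methods

## ComBat core

The per-feature model is `y_ijg = α_g + X_j β_g + γ_ig + δ_ig ε_ijg` with
batch (protocol-instance) location effects γ and scale effects δ.  Fitting
follows the standard parametric empirical-Bayes recipe:

1. **Least squares.**  The design stacks a full set of batch indicator
   columns with one-hot covariate columns (reference level = most frequent
   label, dropped).  The grand effect is the batch-size-weighted average of
   the batch coefficients, which is equivalent to estimating α and γ under
   the constraint Σᵢ nᵢ γ̂_ig = 0 (verified to 1e-8 in the tests).  The
   pooled variance is the mean squared residual (denominator N, matching
   the reference implementation).
2. **Standardization.**  z = (y − α̂ − Xβ̂)/σ̂.
3. **Empirical Bayes.**  Per batch, γ̂ (batch mean of z) and δ̂ (batch
   variance, ddof 1) are shrunk with a Normal prior on γ and an
   inverse-gamma prior on δ², hyperparameters by method of moments across
   features; the conditional posterior updates are iterated to a fixed
   point (max relative change < 1e-4, cap 500 iterations — the reference
   defaults).  With fewer than two usable features the prior moments are
   undefined and the direct estimates are used unshrunk.

Harmonized values are `σ̂ (z − γ*)/δ* + α̂ + Xβ̂`.  `transform` never
refits: unseen batch or covariate levels raise an error so the caller can
apply the test-side exclusion rule.  Zero-variance features cannot be
standardized; they are flagged, warned about, and passed through untouched.

The implementation numerically matches Bioconductor's parametric ComBat
(`sva`): a committed 40-sample × 6-feature fixture generated with
`sva::ComBat` agrees with this implementation to ~3e-13 relative
(tested at 1e-6).

### Empirical-Bayes shrinkage behaviour

The shrinkage factor for a batch's location effect is t²n/(t²n + δ*), with
t² the across-feature moment estimate of the prior variance.  When true
effects are *heterogeneous* across features, t²n ≫ δ* and γ* ≈ γ̂.  When
true effects are *homogeneous*, t² converges to the sampling variance of
γ̂ (≈ δ/n), leaving a fixed ≈ 50% shrinkage toward the across-feature mean
no matter how many features there are — which is fine, because that mean
is then itself the common truth.  The shrinkage-vanishes property test
therefore uses the heterogeneous regime.

## Nested harmonization and permutation choice

Parameters are harmonized sequentially; model k is fitted on data already
transformed by models 1..k−1, so the result is order-dependent.  The
optimizer enumerates all orderings (4 parameters → 24), scores each by the
number of acquisition-independent features its harmonized training table
retains under the same Kruskal–Wallis gate used for the final analysis,
and keeps the best; permutations are visited in lexicographic order of
parameter names and displaced only by a strictly greater score, so ties
resolve deterministically.  The ordering is re-optimized per trial, since
it is a property of each training set.

Exclusion rules, applied once per trial and shared by all methods so every
method sees the identical train/test partition: training scans in a
(parameter, instance, subgroup) cell with fewer than `min_batch_size`
(default 3) scans are dropped (`rare_instance`), iterating until stable;
test scans carrying an instance absent from the surviving training set
within their fitting scope are dropped (`unseen_instance`).  Counting is
per subgroup (the separate-mode requirement), which subsumes the pooled
count rule.  If exclusion empties a fitting scope the whole trial is
unusable.  In separate mode, a (parameter, subgroup) pair left with a
single instance has no within-scope variation to remove; it is recorded as
skipped and applied as identity.

## The acquisition-independence gate

Per feature, per acquisition parameter, per subgroup (benign and malignant
— the two scopes with known diagnosis), a k-group Kruskal–Wallis test with
midranks and the tie correction 1 − Σ(t³−t)/(N³−N) compares the feature's
distribution across the parameter's instances; p-values come from the
χ²_{k−1} upper tail.  A feature is acquisition-independent iff no test in
either subgroup has p ≤ α (default 0.05, no multiple-testing correction —
the gate is deliberately a strict filter).  All-identical samples give
(H, p) = (0, 1); scopes with a single instance present are untestable and
logged as passes.  The core is vectorized across feature columns;
`scipy.stats.kruskal` is the per-column cross-check oracle in the tests.

A calibration utility mirrors the natural sanity check for the gate:
within groups of scans that share *every* acquisition instance, a k-fold
split is drawn and every feature is KW-tested between the train and test
portions per subgroup; with no acquisition variability ≈ 1 − α of tests
should be non-significant, and an unmodelled batch factor depresses that
rate.

**Known limitation.**  The χ² approximation is poor at very small N: for
{1,1,2} vs {2,3,3} the exact permutation p is 0.200 while the χ² tail
gives 0.068.  The gate is meant for cells with dozens of scans; below
N ≈ 10 exact enumeration (used as a test oracle here) would be the honest
p-value.

## Predictive pipeline

Features surviving the gate are z-scored with training statistics, an
L1-penalized least-squares regression of the 0/1 malignancy label
(`alpha = 0.05` in the (1/2n)·RSS + α‖w‖₁ parameterization — stated
explicitly because "α" is convention-dependent) selects the features with
nonzero coefficients, and a soft-margin linear SVM (hinge loss, C = 1,
unweighted classes) is trained on the selection.  Decision scores are
signed distances to the hyperplane, thresholded at 0.  An empty selection
yields a constant all-benign fallback (sensitivity 0, specificity 100,
balanced accuracy 50) — the honest degenerate behaviour when harmonization
leaves nothing both acquisition-independent and predictive.  An
L1-logistic selection variant exists behind a flag for sensitivity
analyses.

## Evaluation harness

Stratified k-fold (stratification on subgroup × malignancy label, scan
level), repeated; defaults k = 5, 10 repeats → 50 trials.  Per trial and
method: exclusion → (optimized) plan fit on the training scans → gate →
LASSO → SVM → frozen application to the test fold → sensitivity,
specificity, balanced accuracy and rank-based ROC-AUC, overall and on the
LCS subset (the clinically realistic target, diagnosis unknown at scan
time).  Trials where a method falls back keep their recorded metrics but
are excluded from that method's metric means; means carry t-based 95%
confidence intervals across trials.  Per trial, method pairs are compared
with the paired DeLong test (midrank placements, structural-component
variance of the AUC difference; identical scores → p = 1); within each
pair the per-trial p-values are Holm-adjusted and significant trials are
counted per direction.  Scan-level splitting mirrors the study design it
emulates; because patients contribute multiple scans this leaks patients
across folds, so a grouped-split variant is a sensible extension for real
deployments.

## Synthetic cohorts

Clean values: y = μ_g + a·κ_g + ε with ε ~ N(0, σ_g²); a = 1 for
malignant scans, 0 for benign and presumed-benign screening (LCS) scans,
and 0.5 (configurable) for LCS nodules that later turn malignant — their
state at scan time is unknown, so they get an attenuated shift.  Batch
effects are injected deterministically on top: location effects add across
parameters, scale effects multiply, both indexed by (parameter, instance,
subgroup, feature).  Subgroup scan/nodule/patient totals follow the
configured proportions through largest-remainder apportionment, so the
default reproduces the reference cohort exactly (567 scans = 323 LCS + 58
benign + 186 malignant; 305 nodules; 193 patients); nodules nest in
patients, scans-per-nodule follow a truncated-geometric draw repaired to
the exact total (mean ≈ 1.9, mimicking longitudinal re-scanning).  One
root seed feeds separate child streams for structure, labels, acquisition
and noise, so cohorts are bit-reproducible.

Default conditions (the `default_config` scenario, 107 features):

* features 0–24: malignancy shift κ = 2σ, no CE effect — these exist to
  carry signal and to expose the confounding artefact of collective
  harmonization (the CE batch mean absorbs the class difference, so the
  pooled correction injects a within-subgroup CE shift);
* features 25–74: divergent CE location effects, +1.5σ for malignant
  tissue and −1.5σ for benign/LCS (opposite-sign response to contrast),
  with divergent scale effects (δ 1.6 vs 0.8) on 25–40;
* features 75–89: protocol effects shared by all tissues (manufacturer
  +0.8σ, KVP −0.6σ, focal-spot scale 1.4) — fixable by every mode;
* features 90–106: pure noise.
* CE frequencies: 70% of malignant, 20% of benign, 10% of LCS scans are
  contrast-enhanced (the quasi-systematic confounding); other parameters
  are distributed identically across subgroups.

`shared_effects_config` keeps the structure but makes every batch effect
identical across subgroups; `null_config` removes biology and batch
effects entirely (gate calibration).  Magnitudes are in the range radiomic
harmonization studies report for CE and scanner effects (one to two
standard deviations on affected features) and are deliberately strong
enough that method differences are visible at desk-scale cohort sizes.

What the generator does **not** emulate: feature–feature correlation
(independent by default; an equicorrelation knob exists because real
radiomic features are strongly correlated), heavy-tailed or bounded
feature marginals, scanner-model/kernel heterogeneity beyond the four
modelled parameters, and within-subgroup biological heterogeneity beyond
the binary malignancy shift.  Passing tests therefore demonstrate correct
mechanics and the direction of method differences under the assumed
Gaussian location/scale world — exactly the world in which ComBat's
assumptions hold — not clinical effect sizes; the reference study's
percentages (e.g. 90.9 / 27.3 / 2.1) are properties of its private
dataset and are not reproduction targets.

## Why separate and covariate modes differ even with shared effects

Separate-mode ComBat aligns each subgroup's batch moments on the same
scans the gate then tests, so its post-harmonization KW tests are strongly
conservative (rejection ≪ α).  Covariate-mode correction is pooled: the
residual within-subgroup batch difference of a subgroup with small pooled
weight is essentially its own sampling noise, so its tests reject at
nearly the nominal α per test, and with 4 parameters × 2 subgroups = 8
tests per feature the covariate independent fraction is capped near
(1−α)⁸ ≈ 66–85% even when every true effect is shared.  The two modes'
fractions converge only when every subgroup carries substantial weight in
the pooled fit (the equivalence checks use two balanced subgroups at
n = 3000, where the gap is ≈ 4 points).  This asymmetry also means
fraction comparisons between modes should be read together with the
test-set predictive metrics, not alone.

## Problem sizes

The shipped experiments use a 500-scan cohort with 10 trials for the
method-ordering comparison and 50 trials for the harness-integrity check;
moment-matching and calibration checks use 10³–10⁴ samples/tests, the
DeLong bootstrap 10⁵ replicates.  These sizes make every documented
quantity stable to well within the tolerances asserted while keeping the
whole suite in the minutes range on a single CPU.
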