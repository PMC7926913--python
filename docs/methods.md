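# Methods

This note documents the modelling choices behind `oliveauth`: what each
stage assumes, which parameters matter, what the synthetic cohorts do and
do not emulate, and where the design was genuinely open.

## Synthetic cohorts

The generator (`synthdata`) emulates the data a non-targeted LC-qToF-MS
origin study produces *after* vendor peak picking; raw spectra, isotope
patterns, adducts and peak shapes are out of scope.  Its defaults are the
reference study design: 95 oils (Esp 26, Gre 13, Ita 39, Pt 17) analysed
in duplicate, one solvent blank per ten injections (19 blanks), and a
catalogue of ~2000 background compounds per sample spread over RT
0.5–17 min and *m/z* 50–1000.

Intensity model, per compound *j* with base intensity *B_j* drawn
log-uniformly over 10⁴–10⁶ counts:

* oil-level latent intensity `L_ij = B_j · f_j(g_i) · exp(σ_bio·z)`, with
  `σ_bio = 0.35` (oil-to-oil biological variation; lognormal, the typical
  heavy right tail of metabolomic intensities);
* injection intensity `L_ij · exp(σ_inj·z′)` with `σ_inj = 0.10`, giving a
  duplicate CV of ≈ 10%, the level a well-behaved QC series shows;
* `f_j(g)` is the planted marker effect: `marker_fold_change` (default 4)
  for a marker's own origin group, 1 otherwise.  Markers are multiplicative
  group effects on otherwise shared compounds, not group-exclusive
  presences, so the fold-change filter — not mere presence — must find
  them.

Detection is Bernoulli per compound *per oil* (duplicates agree on
presence; only intensity differs between injections), with probability
`presence_prob` (default 0.95), or per-feature probabilities drawn from a
Beta distribution when a `(a, b)` pair is given — the latter produces the
many rarely-detected features that make the presence criterion the
dominant reduction step, as on real data.  Missing compounds are absent
from the feature list and become zeros in the bucket table.

Observed coordinates are jittered per injection with SD 0.1 s in RT and
1 mDa in mass — well inside the 0.5 s / 5 mDa bucket windows, so bucketing
is exercised non-trivially but the true clustering remains recoverable.
Blanks carry a configurable fraction (default 0.3) of the background
catalogue at a reduced level (default 0.1×) plus `n_contaminants`
blank-borne compounds at full level in both blanks and oils; the latter
are what the blank criterion exists to remove.  Blanks never contain
markers.

One marker per origin group is the default because it is the minimal
planted structure whose recovery is unambiguous: every country model needs
exactly its own marker, so a selection that misses one has failed, whereas
with redundant markers a correctly working BIC- or entropy-R²-sized
search legitimately stops early (see *Stepwise selection* below).  More
markers per group are a config switch away.

What passing tests on these cohorts shows: the pipeline's stages do what
they claim on data with known truth — planted effect sizes are recovered,
filters keep exactly what their criteria describe, selection finds planted
markers, validation rates beat permutation nulls.  What it does not show:
performance on real oils, where markers are weaker, correlated, matrix
effects and batch drift exist (drift is deliberately not simulated), and
class differences are diffuse rather than planted.  Synthetic rates are
therefore optimistic and are never compared against published numbers.

## Bucketing

"Bucket width of 0.5 s and 5 mDa" admits two readings, and the vendor
behaviour at bucket borders is not documented, so both are implemented:

* **cluster** (default): greedy agglomeration.  Features are visited in
  order of decreasing intensity; a feature may join an existing bucket if
  the bucket's member span would stay within one window in *both*
  dimensions, and joins the one with the nearest intensity-weighted
  centroid (window-normalised Euclidean distance; exact ties go to the
  earlier-created bucket).  This makes the invariant "contributing
  features span ≤ 0.5 s and ≤ 5 mDa" exact, merges features that a fixed
  grid would split across an edge, and on well-separated compounds equals
  transitive-closure clustering (the test oracle).
* **grid**: fixed rectangular bins of exactly one window, anchored at the
  low end of the valid ranges — the literal reading.

Two features of one sample falling in one bucket are summed (split
detections of a single compound) and counted in the table's QC dict.
Features outside the RT/mass validity ranges are excluded with a logged
warning.  RT is stored in minutes; the RT window is given in seconds and
converted at the API boundary.  Feature lists are assumed mono-isotopic
(one representative mass per compound); isotope/adduct grouping is an
upstream responsibility.

## Filter cascade

Order is fixed: blank criterion (i), presence criterion (ii), duplicate
averaging, fold-change criterion (iii).  Boundary semantics follow the
criteria's wording literally: "two-fold higher" and "at least two-fold
change" are inclusive (≥), "more than 50%" is strict (>).  All three
thresholds are config fields, never hard-coded.

Group means for (i) are computed on injection-level rows, because
averaging is defined to happen only between (ii) and (iii).  Blanks are
excluded from all group statistics after stage (i) and dropped entirely
after the cascade.  Zero denominators (blank mean or lowest group mean of
0) pass when the numerator is positive — the ratio is unbounded — and are
logged.  An oil with a missing duplicate contributes the mean of its
available injections, with a warning.  A table without blanks is an error
unless the blank stage is skipped explicitly.

## Variable selection

**ANOVA/Tukey screen.** Per bucket, all-pairs Tukey HSD on the four origin
groups using the studentized-range distribution with pooled within-group
variance; unequal group sizes use the Tukey–Kramer standard error.  The
keep/remove gate is the Tukey test itself (a bucket is kept when at least
two group means differ at α = 0.05); the one-way ANOVA p-value is computed
and reported alongside but is not a second gate, so the null keep-rate is
the Tukey FWER ≈ α.  Because the two published phrasings of the rule
differ, both are available: `any_pair` (default — any significant pair)
and `two_plus` (some group significant against ≥ 2 others).  Buckets with
zero pooled within-group variance are decided by exact equality of the
group means and logged.  The screen is vectorised (one studentized-range
critical value, pairwise q statistics in bulk); `scipy.stats.tukey_hsd`
serves as the independent per-bucket oracle in the tests.

**Correlation pruning.** Among selected buckets whose RT centroids lie
within the bucketing RT window (0.5 s) of each other, pairs with
|Pearson r| > 0.8 are reduced to the bucket with the larger grand-mean
intensity (ties: lower bucket id) — the method's source does not say which
of a correlated pair was dropped, so the more abundant, better-measured
one is kept.  The operation is idempotent and leaves no same-RT pair with
|r| > 0.8.

**Stepwise selection.** Both searches are plain forward selection
(backward/bidirectional modes and penalised selection are non-goals).
Stepwise LDA adds, at each step, the variable minimising training
misclassification (ties: larger Wilks' Λ reduction), stops when no
candidate avoids increasing the training error, and sizes the final model
at the step maximising the validation-set entropy R² — McFadden's
pseudo-R², `1 − ℓ(model)/ℓ(null)`, computed from the LDA posteriors on a
stratified 25% holdout, with validation misclassification then smaller
size as tie-breakers.  Stepwise LR adds the variable with the largest BIC
decrease (`BIC = −2ℓ + k·ln n`) and stops when no addition decreases BIC;
its trace is strictly decreasing by construction.

A consequence worth knowing: sized forward searches stop as soon as the
criterion stops improving, so when planted markers are redundant (any 3 of
4 single-country markers already separate four classes) the stepwise-LDA
model legitimately contains a *subset* of the markers, while the markers
still lead the search path.  Per-country stepwise LR does not share this
ambiguity — each country model needs its own marker — which is why marker
recovery is quantified on the union of the four per-country selections.

## Models

**LDA** is the classical Gaussian classifier: class means, one pooled
within-class covariance (divisor n − k), priors defaulting to training
class frequencies because the design is unbalanced (uniform priors are a
config option).  Fitting requires more samples than variables and a
numerically non-singular pooled covariance (condition number < 10¹²);
violations raise an error naming the offending dimensionality, directing
the user to selection or PCA first.  No variance scaling or log transform
is applied by default — the reference workflow describes none — though raw
MS intensities are heavy-tailed, so both remain sensible user-side
transforms.

**PCA** is mean-centred principal components via exact SVD
(scikit-learn's full solver behind the module surface), used to compress
the table before LDA.  The component count is chosen by cross-validated
PCA-LDA test error, with PCA and LDA refit inside each training fold;
ties go to the smaller count.  The error-vs-count curve is returned for
plotting; on data with low-rank class structure it shows the
characteristic dip-then-rise of overfitting.

**Binary logit.**  Maximum-likelihood fit by IRLS on internally
standardised predictors (the MLE is unaffected; coefficients are reported
on the original scale).  Convergence: max |Δβ| < 10⁻⁸ or 100 iterations.
Perfect separation — likely when training rates are 100% — has no finite
MLE; it is detected when IRLS diverges, the normal equations go singular,
the fit reproduces the labels to < 10⁻⁵, or a standardised slope exceeds
30 log-odds per SD, and triggers a refit with a ridge penalty of 10⁻⁶ on
the standardised slopes (never the intercept) plus a `separation` flag on
the model.  Verdicts use a probability threshold of 0.5 (the published
workflow states none); the threshold is a model field for ROC-style
exploration.  Probabilities are clipped to (10⁻¹⁵, 1−10⁻¹⁵) in
likelihoods.

## Cross-validation

Plans assign every oil to exactly one test fold; fold sizes are
⌊N/k⌋–⌈N/k⌉ and per-country test counts are bounded per fold (bounds
default to ⌊n_g/k⌋–⌈n_g/k⌉, which reproduces Esp 2–3 / Gre 1–2 / Ita 3–4 /
Pt 1–2 for the 26/13/39/17 design).  Layouts are found by rejection
sampling over per-country surplus placements, which preserves the
per-sample uniformity of the assignment; infeasible bounds raise an error
showing the violated arithmetic.

CV operates on duplicate-averaged oil rows, so the two injections of one
oil can never be split across train and test.  Variable selection, PCA
and model fitting all happen inside each training fold.  The reference
protocol instead selected stepwise-LR variables once on all 95 samples;
that information leak is reproduced *only* behind an explicit
`reference_mode=True` flag for comparability and is never the default.

The headline correct-classification rate is pooled over all test
predictions (micro-average); per-fold mean rates are reported alongside
since the published tables do not say which was used.  Folds whose
training labels collapse to a single class for a binary target are
flagged and excluded from the rates; an empty BIC selection degrades the
logit model to intercept-only (majority verdict) rather than invalidating
the fold.  Every plan and result records its seed for exact re-runs.

## Problem sizes

The test suite and the acceptance script run on simulated cohorts sized
so the full workflow is exercised in minutes on one core: unit fixtures
use 22–24 oils with 80–200 background compounds; the full-design checks
use the complete 95-oil layout with 300–2000 background compounds.  These
sizes are the package's own choice of test conditions; all of them are
config fields.

## Known limitations

* No normalisation, batch correction, drift modelling or imputation —
  none are part of the reference workflow; tables are filtered and
  modelled as-is.
* The generator's markers are independent compounds; real markers can be
  correlated families (the correlation-pruning step is exercised by
  construction in tests instead).
* Multinomial logistic regression, kernel/quadratic discriminants and
  nested cross-validation are out of scope.
* Published classification rates stem from the authors' physical 95-oil
  dataset, which is not machine-readable anywhere; nothing here attempts
  to reproduce those exact numbers, only the workflow's properties.
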