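# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the limitations of `cpinet`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and consolidation

The unit of observation is a clinical pharmacy intervention (CPI): a
pharmacist's recommendation about one patient's drug therapy during one
admission, accepted or rejected by the treating physician. Admission
state (demographics, 20 hospitalization-risk flags, pre-index stays,
diagnoses) repeats across the CPI of an admission; the per-CPI fields
(type flags, complexity/intention/domain judgments, consult origin) do
not.

Consolidation collapses each admission to at most one accepted and one
rejected record. Two score families behave differently:

* **subgroup-descriptive** scores (problem complexity, intention,
  clinical domain, prescribing step, consultancy, outcomes-driven) are
  means over the status subgroup's own CPI — they describe the
  recommendations in that record;
* **admission-wide** scores (rejection fraction, combined CP success,
  physician rejection, diagnosis revision) are defined over the whole
  admission or over provider history and are shared by both records.

`score_scope="admission"` or `"subgroup"` force a uniform
interpretation; the mixed split is the default because the admission-
wide four are defined "in that admission" / "over the whole study
period" while the other six describe the recommendation itself.
Provider rates come from a first pass over the full dataset
(accepted/made per pharmacist, rejected/addressed per physician).

Type flags aggregate by logical OR over the subgroup. The phase of a
mixed-phase admission is its modal phase (earliest CPI on ties).

## Feature encoding

54 inputs (36 matched + 18 unmatched between the status groups) plus an
optional status indicator. Two-level categoricals (gender, nationality,
age group, phase) enter as single 0/1 columns so the input-layer count
stays auditable at 54/55; the encoder also supports one-hot groups for
multi-level categoricals, scaled by 1/√2 per indicator so one category
flip contributes unit squared distance. Continuous columns are
z-standardized with training-set center/spread only (min–max scaling is
available); scores stay on their natural [0, 1] scale; a zero-variance
column keeps spread 1 so encoding stays defined.

## The exemplar network

Prediction is Nadaraya–Watson kernel regression — the network reading
is one pattern node per training record plus a numerator/denominator
summation pair. Predictions are convex combinations of training
targets, hence always within [min y, max y]. The categorical analog
accumulates kernel mass per class (ties: more frequent training class,
then lexicographic).

**Bandwidth selection.** The only trained quantity. The criterion is
leave-one-out mean squared error (misclassification rate for classes),
with one crucial modification: exclusion is **by admission**, not by
row. An admission's accepted and rejected records share the observed
outcome; under plain row-wise LOO a record is predicted almost
perfectly from its twin, and the optimizer is actively rewarded for
*ignoring* the status-linked inputs (that makes twins closer). Grouped
exclusion removes the leak.

* *Shared σ*: 32-point log grid on [1e-3, 1e3] (scaled-feature units)
  plus golden-section refinement; ties prefer the smaller σ.
* *Per-feature relevances* rₖ = 1/(2σₖ²): L-BFGS on log rₖ (bounded to
  ±40) with an analytic gradient, started from the shared optimum. The
  gradient and criterion are evaluated with matrix products only, so a
  fit at n ≈ 550, d = 55 takes a few seconds on one core.
* *Pruning*: with a validation split, features whose learned
  contribution to a typical squared distance (2·rₖ·Var(xₖ)) falls below
  a threshold from the fixed grid {0.01 … 10} are zeroed; the most
  parsimonious candidate within one standard error of the best
  validation MSE wins (1-SE rule), and the survivors are refit.
  Rationale: with 55 inputs and ~550 rows the relevance optimizer
  chases small spurious correlations; a spurious relevance on an input
  that the reassignment policy edits translates directly into a biased
  scenario contrast. Pruning makes "irrelevant" mean *exactly zero
  influence*. A 2-SE variant was evaluated and rejected — it prunes
  the genuine rejection relevance in roughly one replicate in five at
  study scale.

Equal-relevance distance in 55 dimensions is provably ineffective here:
pairwise distances concentrate, so any single input's contrast is
diluted and input-editing effects shrink toward zero. The pipeline
therefore uses per-feature relevances for continuous outcomes; shared σ
remains the `fit` default and serves the categorical outcomes.

**Stop conditions.** Training stops at 1,000,000 criterion evaluations
("cycles"), 120 s on a monotonic clock, or no further error reduction
(1e-10), whichever fires first; the model records which.

**Split.** 80/20 train/test with largest-remainder rounding, after
removing 4 randomly drawn holdout scenarios (684 records → 544/136/4).
The test split doubles as the pruning-validation set; the holdout
scenarios stay untouched for spot checks.

## Reassignment (counterfactual) analysis

The factual scenario predicts each consolidated record from observed
inputs; the counterfactual edits the inputs as if physicians had
accepted every CPI and predicts again with the frozen model.

* **Default policy**: status → accepted, rejection score → 0.
* **Extended policy**: additionally combined CP success → 1 and
  physician rejection → 0. Under 100 % acceptance those scores take
  these values *by definition* (they are averages of provider
  acceptance histories), so the extended policy is the logically
  complete edit; both are reported side by side. The two coincide
  whenever pruning assigns the provider-history inputs zero relevance.

**Out-of-admission prediction.** Both scenario predictions for a record
hide the exemplars of that record's own admission. A training exemplar
carries the record's factual outcome; letting the edited query match
itself (or its twin) drags the counterfactual prediction back toward
the factual value. Measured at study scale with own-admission exemplars
included, 57 % of the counterfactual prediction weight of treated
records fell on their own admission, biasing the scenario contrast
toward zero. `out_of_admission=False` restores plain prediction.

**Comparison.** Paired Wilcoxon signed-rank for continuous outcomes
(zeros dropped; exact null for ≤ 25 untied non-zero differences, else
normal approximation with tie correction; all-zero differences give
p = 1 by convention) and continuity-corrected McNemar,
χ² = (max(|b−c|−1, 0))²/(b+c), for categorical ones. Two estimands are
reported: the mean factual-minus-counterfactual difference over all
records, and over *affected* records (admissions that contained at
least one rejection), where any real effect is concentrated.

**Attenuation.** Kernel smoothing shrinks input-editing contrasts even
with a well-chosen metric. At study scale with a planted 0.5-day
admission-level effect, the affected-records estimate recovers about
80 % of the truth on average (the acceptance suite measures the exact
coverage). The three mechanisms, in decreasing order: (i) smoothing
across the rejection-score boundary at the LOO-optimal relevance;
(ii) an information limit of the encoding — an admission with many CPI
and one rejection has rejection score 1/k ≈ 0, nearly indistinguishable
from 0, so part of its effect is invisible to *any* model on these 54
inputs; (iii) mean-reversion of sparse treated-exemplar neighborhoods
on a right-skewed outcome.

This module is a predictive what-if on a fitted regression surface,
not causal identification: it assumes the 54 inputs capture the
outcome-relevant differences between admissions with and without
rejections. No propensity scores or instruments are involved, and
results inherit any unmeasured confounding in the data.

## Variable impacts

Permutation importance: shuffle one input (one-hot groups as a block)
across records, average the increase in squared prediction error
(misclassification rate for classes) over `n_repeats`, floor negative
values at zero, normalize to 100 %. A flat model distributes evenly. A
"range sweep" alternative (vary one input over its observed quantiles,
score the induced output spread) is provided for robustness comparison
under its own method tag.

## Univariate tables and sample sizes

Mann–Whitney U (exact for untied samples with min n ≤ 8, else normal
approximation with tie correction) for continuous and score variables;
Pearson χ² without continuity correction for categorical ones — the
uncorrected form is the one consistent with the published
polypharmacy table. p ≥ 0.10 is blanked in the display column but kept
machine-readable. No multiple-testing correction is applied (matching
the source analyses); treat the table descriptively.

Important caveat measured during calibration: accepted and rejected
consolidated records usually share admissions, so the two "groups" are
not independent samples and the tests run conservatively on admission-
level variables (measured type-I rate ≈ 1 % at a nominal 5 %). The
`null_config()` calibration harness therefore fixes one CPI per
admission, making the groups disjoint; under it the empirical type-I
rate is nominal.

Sample-size calculators: paired mean-change n = ⌈((z₁₋α/₂ + z_power)·
σ/δ)²⌉, and the t form iterated to self-consistency from the z
solution, stepping df upward one at a time (jumping by the requirement
itself can overshoot the smallest fixed point at small df). Sizes
always round up. The network sizing rule is inputs × 10 × second-layer
neurons (= 2).

## Synthetic data-generating process

Scale defaults: 542 patients, 5.9 % readmission probability (~574
admissions), CPI per admission 1 + negative binomial (r = 0.7, mean
1.85, frailty-scaled, capped at 38; median 2–3), phase II probability
0.49. Three pharmacists with acceptance 0.57/0.95/0.86 and phase-
specific workload shares reproducing both the overall 84 % acceptance
and the junior pharmacist's smaller phase-II share; 40 physicians with
mean-one lognormal rejection propensities. Per-CPI rejection
probability = (1 − pharmacist acceptance) × physician propensity.

A standard-normal latent **frailty** per admission induces positive
correlation among the risk flags and drives pre-index stay and CPI
count. Flag marginals are preserved exactly by solving each logistic
intercept against the frailty distribution (Gauss–Hermite quadrature);
dependence strength is a config knob (default 0.6, mild).

**Outcome truth.** Post-index stay = 0.4 + 0.45·(stay before index)
+ 1.2·critical + delta_reject·1{admission has ≥ 1 rejection}
+ N(0, 0.3), truncated non-negative, rounded to half days.
Deliberately low-dimensional and driven by *observed* covariates:

* the study's model fit (cross-validated R² ≈ 0.99) implies the
  outcome is nearly a function of the recorded inputs, with a residual
  of ~0.3 days at the study's outcome variance;
* the covariate drivers are independent of the rejection process, so
  the causal effect is identifiable by covariate adjustment. A direct
  CPI-count effect was considered and excluded: with per-CPI Bernoulli
  rejection, P(≥ 1 rejection | k CPI) → 1 at high k, so a CPI-count
  outcome effect would be confounded with treatment *with no overlap*,
  and no adjustment method could separate them. Comorbidity flags
  remain marginally correlated with the outcome through frailty but
  carry no conditional effect.

delta_reject defaults to 0.4 days at admission level (a per-CPI
additive variant sits behind `per_cpi_effect`). The ledger stores each
admission's factual and all-accepted counterfactual stay; by
construction counterfactual = factual − effect exactly, which is what
parameter-recovery tests compare against.

Secondary outcomes: ICU stays as Beta-thinned fractions of the
corresponding ward stays (critical admissions only); readmission
(~15 %) and mortality (~2 %) as logistic functions of risk flags; cost
in JD = (230 + 420·total stay)·lognormal(0, 0.32), calibrated so the
mean sits near the published ~2100 JD.

**What the generator does not emulate**: within-admission temporal
structure beyond an order index, disease-specific realism, informative
missingness (there is none), drug-taxonomy structure behind the
antibiotic and high-alert flags, and any dependence of physician
decisions on unobserved patient state. Passing recovery tests therefore
show the pipeline estimates what it claims *under the stated DGP*; they
cannot rule out unmeasured confounding in real data.

`null_config()` additionally equalizes pharmacists, removes physician
heterogeneity, makes rejection a fair coin per CPI, zeroes flag
dependence and the rejection effect, clips prevalences into [0.1, 0.9]
(non-degenerate 2×2 cells), and fixes one CPI per admission — the
configuration under which every input is genuinely null and the
group-comparison tests can be held to their nominal level.

## Numerical choices

* Kernel weights are computed after subtracting the row-minimum
  energy, so normalized weights never under/overflow; fully masked rows
  yield zero weights.
* Relevance optimization is bounded (|log r| ≤ 40) and deterministic;
  the L-BFGS path evaluates criterion and gradient via GEMM identities
  validated against the direct per-feature sums.
* Sample sizes round up; the 554/556 z/t pair fixes the convention.
* Wilcoxon uses `scipy.stats.wilcoxon`; Mann–Whitney uses
  `scipy.stats.mannwhitneyu`; χ² uses `scipy.stats.chi2_contingency`
  (no correction). McNemar is computed directly from the closed form
  and cross-checked against statsmodels in the tests.
* Problem sizes in the test suite: recovery runs 20 replicates per
  arm at the full study scale (~700 consolidated records each);
  type-I calibration runs 50 datasets × 51 variables; the oracle
  comparisons use 100 random instances at n ≤ 20.

## Known limitations

* The what-if estimand is predictive, not causal-identified (above).
* Recovery of an admission-level effect is attenuated ~20 % by
  smoothing and by the 1/k encoding limit of the rejection score.
* Wilcoxon on paired scenario predictions treats records as
  independent; predictions are smoothing-correlated, so its p-values
  overstate precision when the fitted relevance on an edited input is
  spurious. Relevance pruning keeps that rate near nominal at study
  scale but cannot make it exact.
* Per-feature bandwidths are limited to the continuous task (the
  misclassification criterion is not differentiable).
* Categorical reassignment rarely flips predictions for rare events
  (mortality ~2 %), mirroring the source study's null secondary
  findings rather than contradicting them.
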