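# Methods

This note documents the models, parameter choices and numerical decisions
behind `comorec`, and what the synthetic validation does and does not
demonstrate about real claims data.

## Unit of analysis and code handling

The observational unit is the **patient-year**: national claims samples of
the kind emulated here are drawn annually, so a patient sampled in several
years contributes independent records, and "concurrent" (as in *diagnosis
with concurrent treatment code*) means *within the same patient-year
record* — no finer time resolution exists.  Longitudinal linkage across
years is deliberately out of scope.

ICD-10 codes are normalized internally to uppercase with the dot removed
("N80.1" → "N801"); the three-character **category** is the first three
characters.  Code ranges such as C51~C58 are inclusive and lexicographic,
which coincides with numeric order inside a letter block.  The six
gynecologic exclusion ranges (C51–C58, D06–D07, D25–D28, O00–O99, N70–N77,
N80–N98) cover malignant and in-situ neoplasms of the female genital
organs, benign neoplasms of uterus/ovary/adnexa, pregnancy and puerperium,
and inflammatory plus noninflammatory disorders of the female genital
tract — the categories a gynecologic work-up detects preferentially.

## Recommender stage

The incidence matrix is binary (a category is present or absent in a
patient-year, regardless of how many sibling codes were recorded), sparse,
with the category index sorted lexicographically; that order is also the
deterministic tie-break for equal similarities.  Similarity is the Jaccard
index between patient sets, appropriate for implicit (presence-only) data
with no ratings.  Categories carried by no patients get similarity zero to
everything, including themselves, and are never recommended.

Recommendation extracts the top-K categories (query excluded) **first**
and applies the gynecologic exclusion **after** the cut, mirroring the
extract-30-then-exclude workflow this pipeline automates; consequently
fewer than K candidates may survive.  `exclude_before_ranking=True`
provides the alternative (exclude first, then return K survivors) for
reuse in settings where a fixed candidate count matters.

Hold-out validation uses a standard single-held-out-item protocol: for
each test patient with at least two distinct categories, one category
known to the model is held out uniformly at random as the query; precision
is hits/n_rec and recall is hits/|remaining categories|, averaged over
patients.  Two caveats.  First, there is no single canonical definition of
recommender precision/recall; numbers produced under other protocols are
not directly comparable.  Second, these metrics depend strongly on the
size of the category universe: the bundled synthetic preset has ~30
categories, so a top-30 recommendation list covers nearly the whole
universe and recall saturates near 1, whereas real claims data span well
over a thousand categories and yield precision/recall in the few-percent
range.  The metrics are reported for protocol transparency, not as a
quality bar.

The train/test split is patient-level, deterministic under a fixed seed,
with the train size equal to round(n × fraction).  Whether the similarity
model should be trained on all patients or only on the confirmation-stage
demographic (women 15–45) is left as a flag; the default trains on all
patients, since co-occurrence information from the full population
stabilizes similarities for rare diseases.

## Synthetic populations and planted associations

The generator emulates the *already-sampled* weighted claims file: each
record carries age (uniform 15–45), calendar year (uniform 2009–2015),
admission type (Bernoulli, default 60% inpatient — the emulated sample is
inpatient-dominated by design), the corresponding sampling weight (7.692
inpatient, 100 outpatient, i.e. 13% and 1% sampling fractions), a low-SES
flag (default 2.8%, the control-group rate of the reference table), a set
of diagnosis codes and a set of procedure codes.

Disease indicators are drawn sequentially in spec order.  A disease with
planted associations to earlier diseases uses a logistic conditional
model: the coefficient on each earlier indicator is the log of the
specified odds ratio, and the intercept is solved by bracketed
root-finding (Brent, tolerance 1e-12) so that the realized marginal
prevalence matches the requested base prevalence.  This gives *exact*
conditional odds ratios and calibrated margins without MCMC; when a
disease has a single partner, the marginal 2×2 odds ratio equals the
conditional one, which is what `empirical_pairwise_or` (cross-product
ratio, +0.5 Haldane–Anscombe correction only when a cell is zero) verifies
on large samples.  An optional log-linear age slope per disease makes age
confounding plantable, so tests can verify that covariate adjustment moves
estimates in the planted direction.

Each present disease contributes one full code from its configured
mixture, plus its linked test codes with probability
`test_code_sensitivity` (default 0.8 in the preset) — emulating
diagnosis-plus-test-code definitions.  N80-coded patients receive
treatment tokens (default `SURG_GYN`, `RX_GNRH`) with probability
`endometriosis_treatment_rate` (default 0.8); the real procedure-code
identifiers of such claims systems are not public, so all procedure codes
are configurable tokens.

What the generator does **not** emulate: the two-stage sampling mechanism
itself (weights are attached, not realized by sampling), the true
prevalence spectrum and full ICD-10 catalogue of a real claims year,
provider/household clustering, and within-year visit structure.  Passing
tests therefore demonstrate correctness of the pipeline's logic and
statistics under known truth, not that any particular real-data estimate
is right.

## Cohort construction

Cases require an N80.x diagnosis **and** a treatment code in the same
record; controls require the absence of any N80.x code; women with an
N80.x code but no treatment satisfy neither definition and are dropped
(their count is logged) — together the three sets partition the filtered
input.  Age bands are 5-year intervals anchored at 15 ([15,20), …, [40,45]
with 45 folded into the last band), entering the regression as a single
ordinal term so that one odds ratio "per 5 years" is reported.  Data year
enters as a single linear term.  Percentages in the characteristics table
are rounded half-up to one decimal; diseases below 0.1% prevalence in both
groups are suppressed from the table.  The displayed mean ages and their
standard errors are the weighted means/SEs of the weighted t-test that
compares them.

## Confirmation statistics

The weighted logistic model maximizes the weight-multiplied Bernoulli
log-likelihood Σ wᵢ[yᵢ log pᵢ + (1−yᵢ) log(1−pᵢ)].  Fitting is IRLS
(via statsmodels GLM) followed by explicit Newton refinement until the
score's max-norm is below 1e-8 × max(1, max weight); the refinement exists
because a deviance-change stopping rule can stall at floating-point
precision when the weighted deviance is of order 10⁶, while the
closed-form equivalences in the test suite require coefficient accuracy
well beyond six significant digits.  Complete separation is detected
before fitting and reported with the offending term's name.

Two variance estimators are available:

* **model-based** (`robust=False`): the inverse of the weighted
  information matrix — the pure frequency-weight convention, under which
  multiplying all weights by c scales standard errors by 1/√c.  This is
  the right convention when weights are genuine multiplicities.
* **sampling-weight sandwich** (`robust=True`, the default in
  `run_confirmation`): H⁻¹(Σ(wᵢsᵢ)(wᵢsᵢ)ᵀ)H⁻¹ with sᵢ the unweighted
  per-record score.  Survey weights are inverse sampling probabilities,
  not multiplicities; the model-based variance under-states uncertainty by
  roughly the mean weight (weights ~44 on average here), which would make
  every null covariate spuriously significant.  The sandwich is invariant
  to rescaling all weights and is what the Monte-Carlo calibration and
  coverage experiments validate.  It is computed directly (statsmodels
  silently ignores `cov_type` when frequency weights are supplied).

Crude (single-flag) odds ratios use the 2×2 cross-product ratio with the
Woolf interval when unweighted, and an intercept-plus-flag weighted fit
when weighted.  Categorical comparisons use Pearson chi-square without
continuity correction, falling back to Fisher's exact test (2×2 only) when
any expected cell is below 5 — the paper-style pairing of the two tests
needs an explicit switching rule, and expected-cell-below-5 is the
conventional one.  The weighted t-test is Welch-style on Kish effective
sample sizes nₑff = (Σw)²/Σw², with weighted variances under the
reliability-weight normalization and Welch–Satterthwaite degrees of
freedom; with unit weights it reduces exactly to Welch's t-test.  Mean
imputation replaces missing covariate entries by the column's observed
unweighted mean (counts logged); the synthetic generator produces no
missingness, so this path exists for real data ingestion.

`run_confirmation` fits, in order: one crude model per candidate; one
multivariable model with age band, year, low SES and *all* candidate flags
simultaneously.  At full-code level (categories expanded to one definition
per observed full code) a final model keeping only the disease terms with
p < 0.05, plus the covariates, is refit — the significance gate belongs to
the full-code workflow, where dozens of sparse sibling-code flags would
otherwise destabilize a single joint fit.

### Small-cell fragility

With a case prevalence below 1% and candidate flags below 1%, a weighted
estimate can rest on a handful of flagged cases; whether those few records
happen to be inpatients (weight 7.692) or outpatients (weight 100) then
dominates the weighted cell totals, and the sandwich variance — estimated
from the same few records — can understate the true sampling variability.
An unlucky draw can produce a confidently wrong odds ratio for such a
flag.  This is a property of survey-weighted estimation at rare-event
scale, not of the implementation; interpret weighted estimates for flags
with fewer than a few dozen flagged cases with caution, and prefer larger
populations (the worked example uses 500,000 patient-years) when planting
rare diseases.

## Randomness and reproducibility

Every pipeline stage draws from a named substream spawned from one root
seed (`SeedSequence([root, stage_index])`), so changing, say, the
evaluation protocol does not perturb the cohort stage.  A fixed seed makes
the generator byte-identical, the split deterministic, and the full
pipeline's artifacts byte-for-byte reproducible from the manifest.

## Validation experiment sizes

The Monte-Carlo experiments use moderate disease prevalences (5–10%) so
that Wald-based inference operates in its asymptotic regime: planted-OR
recovery and CI coverage run 100 replicates at n = 50,000 (≈2,500 cases
each); type-I calibration runs 200 all-null replicates at n = 40,000 with
four candidate terms per replicate (800 p-values).  These sizes are the
package's validation conditions; rarer diseases require proportionally
larger populations for the same stability, as the small-cell discussion
above explains.

## Known limitations

* Patient-years are treated as independent; repeated sampling of the same
  person across years is not modelled.
* The endometriosis treatment codes and all test codes are placeholder
  tokens; real analyses must supply the actual procedure/prescription
  codes of their claims system.
* The recommender supports Jaccard similarity only (by design); no
  user-based filtering or matrix factorization.
* No multiple-testing correction is applied in the confirmation stage,
  matching the analysis style this pipeline automates; with many
  candidates, p-values should be read accordingly.
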