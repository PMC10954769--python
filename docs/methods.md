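# Methods

## The classification model

`probdem` labels 'probable dementia' from a minimal predictor set: the
10-word recall sum *S* ∈ {0, …, 20} (immediate plus delayed recall) and,
in the combined variants, the count of limitations in instrumental
activities of daily living (IADL) *I* ∈ {0, …, 9}. All cutoffs are
country-specific and fitted on training data only.

**Recall cutoffs.** Classification is *S* strictly below the cutoff.
Because *S* is discrete on 21 points, no cutoff can match a target share
exactly; we take the *largest* integer cutoff whose weighted classified
share does not exceed the target. This is conservative: the classified
share never exceeds the reference prevalence, and incrementing the cutoff
by one would (floor effects aside) push it past the target. Two targets
are supported: the country's external prevalence estimate (equipercentile
equating) and a fixed percentile (default 2.5%, chosen as an outlier
definition — two standard deviations below the mean for a normally
distributed score, and close to the population-weighted average
self-reported dementia prevalence in European survey data). Weighted
shares use cumulative normalised sampling weights, since the equating
target is population-level; an unweighted option exists
(`weighted=False`).

**IADL cutoff.** *Q3 + 1.5·IQR* of the training IADL distribution, the
conventional boxplot outlier fence. Quartiles use linear interpolation of
the empirical distribution (the default of mainstream statistical
software) and are unweighted — this 'naïve' cutoff is a robustness device,
not an equating step. Where *Q3* = 0 (most respondents report no
limitation, a common situation in healthier countries) the fence would
collapse to 0; the cutoff is then set to 1, so the strict 'above' rule
requires at least two limitations. Both combined variants share the same
IADL cutoff regardless of which recall cutoff they use.

**Strictness.** Both comparisons are strict ('below' / 'above'). A score
equal to the recall cutoff, or an IADL count equal to the fence, is
negative. Users replicating variants with inclusive rules can pre-shift
cutoffs by one.

**Degenerate distributions.** If a country's training scores have no mass
below any achievable cutoff at the target (e.g. all scores equal), the
fitted cutoff classifies nobody; a warning is logged because this floor
effect silently zeroes sensitivity in that country.

## Benchmark models

The benchmarks predict the *self-reported* diagnosis (the only label
available in real data) from recall items, the IADL count, age, sex,
education, interviewer-rated items and proxy presence; one-hot encoding
uses declared level lists with the first level as reference so train and
test matrices always align.

Class imbalance (~2% cases) is addressed three ways: the raw 50:50 split
(SPLIT), downsampling the majority to the minority count (DOWN), and
SMOTE. Our SMOTE interpolates continuous features between a minority row
and one of its k = 5 nearest minority neighbours (Euclidean distance on
standardised continuous features) at a uniform random fraction;
categorical features are copied from the base row (the majority vote over
the base/neighbour pair, ties broken toward the base). Defaults add 100%
synthetic minority rows and subsample the majority to 5× the minority
count, so 585 original cases yield a 4095-row training set at 28.6% case
share — the proportions a 50:50 split of a ~56 000-person cohort at 2.1%
prevalence produces. Synthetic rows are flagged and their latent
ground-truth columns blanked.

The weighted logistic regression uses prevalence-derived case weights
1/*p_c* (cases) and 1/(1−*p_c*) (controls); the parenthetical could also
be read as weight = 1−*p_c*, but the inverse reading keeps the weighted
class masses equal when the empirical prevalence equals *p_c*, which is
the point of the weighting. RF and XGB are tuned by grid search under
stratified 5-fold CV with mean AUC as criterion; ties select the first
grid point in declared order. The shipped grids are modest (RF: depth ∈
{∞, 8}; XGB: depth ∈ {2, 4} × learning rate ∈ {0.1, 0.3}) because the
contract is the selection protocol, not a particular grid; pass `grids=`
to widen them. The decision threshold is 0.5 — no principled operating
point exists for this design, and AUC-based comparisons do not depend on
it. Only GLM (weighted), RF (SMOTE) and XGB (SMOTE) are first-class
report outputs; the other family × strategy combinations are available
through the library.

## Underreporting

Per country, `underreporting = 1 − n_alg/n_ext`, where `n_ext` applies
the external prevalence to the weighted test-set size and `n_alg` applies
the algorithm's survey-weighted prevalence to the same size (the mirror
construction — raw classified counts reweighted would differ only through
weight/label covariance; the prevalence-based construction is the
default because the external side is defined that way). The cross-country
summary is the arithmetic mean with a t-based 95% CI treating countries
as units; with one country the CI is undefined. Undefined metrics
propagate as NaN and are skipped (with counts reported) in summaries.

Validity checks compare auxiliary domains (depressive symptoms, verbal
fluency, numeracy, grip strength, orientation to date) between each
algorithm's positives and the self-reported-diagnosis group with
two-sample t-tests — Welch by default (robust to unequal variances;
`equal_var=True` gives Student's pooled test) — Bonferroni-adjusted with
family size m = algorithms × domains in the run.

## The synthetic cohort generator

The generator produces the study conditions under which the pipeline is
validated; every latent quantity is a config parameter.

* **Latent dementia**: Bernoulli with logistic age tilt in
  (age − 70)/10, intercept solved numerically so the country marginal
  equals *p_ext* exactly in expectation — the equating target is
  preserved while ML benchmarks see a real age signal.
* **Reporting**: `self_report_dx = true_dementia × Bernoulli(r_c)`.
  Reporting is a pure thinning — never a false positive — so the
  self-report underreporting converges to 1 − *r_c* by construction.
  Default *r_c* = 0.4, the order implied when European survey
  self-reports are compared with OECD-style projections (~60%
  underreporting).
* **Recall**: each of immediate/delayed recall is a sum of 10 Bernoulli
  trials; the logit success probability contains a base rate (0.0
  immediate, −0.6 delayed → means ≈ 5 and 3.5 words), a per-country shift
  (N(0, 0.15) by default, so cutoffs genuinely differ by country) and the
  dementia effect (−2.0 → case mean ≈ 2/20 words, a severe deficit with
  visible floor effects).
* **IADL**: zero-inflated Poisson truncated to [0, 9]; structural-zero
  probability 0.70 (0.10 under dementia — loss of independent function is
  near-definitional), log-rate 0.20 + 1.50·dementia + 0.25·(age−70)/10.
* **Prevalence range**: reference prevalences default to Uniform(0.03,
  0.08), typical projected dementia prevalence among the 60+ population
  of European countries.
* **Weights**: population-proportional, `pop_weight_total/n`. Real survey
  calibration weights (nonresponse, post-stratification) are richer; this
  is a deliberate simplification.

What the generator does **not** emulate: household clustering, proxy
interviews, attrition, item missingness patterns, education/sex gradients
in cognition, and measurement error in self-reports beyond thinning.
Passing tests therefore demonstrate the pipeline's internal logic
(equating, thinning recovery, orderings) — not that real-survey
performance will match any particular number.

## Problem sizes and determinism

Unit and property tests run on cohorts of 4–8 countries × 400–2000
respondents; the recovery test uses 26 × 5000 (the full study scale) and
`scripts/acceptance.py` re-runs the complete protocol at that scale in
under a minute. All randomness flows from explicit seeds (simulation,
split, resampling, model seeds are separate and echoed to the persisted
config); two runs of the same configuration produce byte-identical
tables. CSV model files are written with 17 significant digits and read
with round-trip float parsing so fitted objects survive serialisation
exactly.

## Known limitations

* The eligibility rule (≥ 5 self-reported cases per country) interacts
  with small `n_per_country`: at the defaults the expected case count per
  country is far above 5, but tiny simulations can lose countries.
* Cutoff equating targets the *training* distribution; sampling noise
  means the test-half classified share can slightly exceed the target.
* SMOTE-trained models are known to be poorly calibrated; predicted
  probabilities are used for ranking (AUC) and a fixed 0.5 threshold,
  not as calibrated risks.
* The LW variants emit binary labels, not scores; their reported 'AUC'
  is the label-based operating point and is informative only relative to
  the threshold-free benchmark AUCs.
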