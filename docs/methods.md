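# Methods

This note documents the statistical procedures the package implements,
the assumptions behind them, the synthetic-data model used for testing,
and the design choices made where practice was genuinely open.

## The case/non-case design

Spontaneous-report databases such as FAERS contain no denominators of
drug use, so absolute risks cannot be estimated. The case/non-case
design instead contrasts, within the database, reports of the target
event ("cases") with reports of any other adverse event ("non-cases").
For an exposure E (here: denosumab as primary-suspect drug, optionally
refined by regimen, demographics or co-reported drugs) and the target
event Y (the preferred term *Osteonecrosis of jaw*), the 2×2 table is

|            | event Y | other events |
|------------|---------|--------------|
| exposed    | a       | c            |
| unexposed  | b       | d            |

and the reporting odds ratio is ROR = (a/c)/(b/d), with the log-Wald
95% interval exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)). A safety
signal is declared when the interval's lower bound exceeds 1 **and**
a ≥ 3. The counting unit is the deduplicated report: each report
contributes to exactly one cell, even if it lists the event twice.

Choices that were open:

* **Zero cells.** No Haldane–Anscombe 0.5 correction is applied; a table
  with any empty cell yields an explicit undefined-ROR sentinel carrying
  the counts. The signal rule already requires three cases, so the
  correction would only perturb estimates without changing decisions.
* **Comparator.** The comparator is always "all other reports in the
  cleaned dataset". In stratified analyses, exposure filters that a
  report *fails* (wrong sex, wrong regimen) send it to the comparator,
  while filters it *cannot answer* (missing sex, missing dose text)
  exclude it from that stratum's table only ("not classifiable"). A
  consequence worth knowing: in a regimen stratum the comparator
  contains the target drug's other-regimen reports. At realistic
  exposure prevalences (<1% of reports) this contamination is
  negligible; the test suite computes exact mixture expectations where
  it is not.
* **Counting unit.** Denominators are report-level, not drug–event-pair
  level. Published analyses of this drug–event pair do not always state
  which unit they used, and the two do not reconcile when a report lists
  many events; this package computes report-level counts only and makes
  no attempt to reproduce pair-level figures.

## Deduplication

FAERS distributes report *versions*: the same case identifier (CASEID)
can appear in many quarters with different primary identifiers
(PRIMARYID). The rule applied is the standard one: keep the version with
the most recent FDA receipt date (FDA_DT); when dates tie, keep the
higher PRIMARYID. The operation is idempotent and its output is sorted
by case id. Two reports sharing a PRIMARYID violate the FAERS identifier
contract and abort the run.

## Logistic regression within the cohort

Within the target-drug cohort (primary-suspect reports only), case
status is regressed on sex, age ≥ 65, regimen (120 mg Q4w vs 60 mg Q6m)
and one indicator per configured co-drug.

* **Complete-case filtering.** A report missing any required covariate
  is dropped and tallied per missing field. A dose text that parses to
  neither regimen ("other") counts as missing for the 60-vs-120
  dichotomy, since the dichotomy is the covariate.
* **Screen.** Univariate fits; a variable enters the multivariate model
  when its likelihood-ratio P < 0.20 or it is force-included. Age ≥ 65
  is force-included by default: age is a textbook baseline confounder
  here and the screen is not allowed to drop it.
* **Estimates.** Crude and adjusted ORs are exp(coefficient) with Wald
  95% CIs; per-variable P values are likelihood-ratio tests against the
  nested model without that variable (df = 1). Fitting uses
  Newton–Raphson with log-likelihood tolerance 1e-8 and an iteration cap
  of 100 (statsmodels `Logit`).
* **Separation.** Sparse co-drug indicators can separate; any fitted
  |coefficient| > 15 on the logit scale flags the variable, which is
  reported crude-only and excluded from the joint model. Collinear
  columns are greedily dropped with a warning. Both mechanisms preserve
  the output-table shape with empty adjusted columns.

For every binary covariate the crude OR equals the classical
(a·d)/(b·c) of its 2×2 table; the suite asserts this identity to six
decimals on every dataset it touches.

## Time-to-onset and the Weibull shape-parameter test

Latency is the number of days from the earliest target-drug therapy
start to the event onset date, available only for exposed cases with
both dates and a positive interval (exclusions are tallied). A config
switch (`anchor="earliest"`) instead anchors on the earliest start among
target and required co-drugs, for exposures defined by drug
combinations where the biologically relevant clock may start with the
first antiresorptive.

The sample is summarized by median and IQR (linear-interpolation,
"type 7" quartiles) and fitted with a two-parameter Weibull by maximum
likelihood (no censoring model — reports without an onset contribute
nothing, which mirrors practice and understates late-onset risk; this
bias is acknowledged, not corrected). The shape β is solved from the
profile score equation by bracketed root-finding (numerically guarded
with shifted exponentials), after which the scale α follows in closed
form from α^β = mean(tᵝ). 95% CIs are Wald intervals on (log α, log β)
using the observed Fisher information at the MLE, back-transformed;
profile-likelihood intervals would be a reasonable alternative and the
log-Wald choice is documented so users can compare. The fit agrees with
an independent MLE (lifelines' `WeibullFitter`) to five significant
figures in the tests.

Hazard-trend classification uses only the β interval: entirely below 1
→ early failure (decreasing hazard), containing 1 → random failure
(constant hazard), entirely above 1 → wear-out failure (increasing
hazard, i.e. cumulative toxicity). Fits are refused below n = 10 and on
degenerate (constant) samples.

Subgroup latencies are compared with the two-sided Mann–Whitney U test:
the exact null distribution when both samples have ≤ 8 values and no
ties, the normal approximation with tie correction otherwise.

## Synthetic-data model

The generator plants every quantity the analyses estimate:

* a target-drug exposure indicator with configurable prevalence;
* an event indicator following a logistic model (intercept + sex +
  age band + regimen + co-drug terms) among exposed reports and a
  constant background rate elsewhere — the ground truth records both
  the conditional ORs and the exact *marginal* ROR (the exposed event
  probability averaged over the covariate distribution, in odds against
  the background odds);
* whole-day Weibull latencies per regimen stratum, realized as therapy
  start plus onset date so extraction recovers them exactly;
* missingness masks (age, sex, dose text, reporter, onset dates)
  applied only after the latent truth is recorded;
* duplicate report versions with earlier receipt dates (or equal dates
  and lower PRIMARYIDs) that perturb only mutable fields, with the
  canonical survivor set recorded.

Default parameters follow the reporting patterns of denosumab-related
osteonecrosis of the jaw in the public FAERS archive: ~0.9% of reports
name the drug, male share 13.1%, age ≥ 65 share 76%, missing sex 12%,
missing age 41%, onset dates present for ~21.5% of cases, and Weibull
strata (α = 712.8 d, β = 1.06) for 60 mg Q6m vs (α = 576.5 d, β = 1.33)
for 120 mg Q4w. Event dates are never clamped to the calendar window
(clamping would bias β); the window constrains therapy starts only.

What the generator does **not** emulate: the marginal distribution of
thousands of background drugs and events, free-text narratives,
correlated missingness, reporting waves, or indication channeling
(co-drugs are drawn independently of dose). Passing recovery tests
therefore demonstrates the estimators are correct under the stated
model, not that real FAERS data meet its assumptions.

### Problem sizes used in tests and the acceptance script

Simulation checks run at the scales at which their operating
characteristics are meaningful: signal-rule calibration and planted-ROR
coverage at n = 50,000 reports × 100–200 replicates, adjusted-OR
recovery at n = 40,000 × 100 replicates, Weibull shape recovery at
n = 1,652 (the reference fit size) × 100 replicates and hazard
classification at n = 300 × 100 replicates. For these desk-scale runs
the exposure prevalence is set to 10% and the background event rate to
2% — archive-scale prevalences would leave near-empty cells at these
sample counts — and these rates are part of the stated study conditions,
fixed once.

## Known limitations

* Disproportionality quantifies reporting, not risk; all the usual
  spontaneous-report caveats (underreporting, notoriety, channeling)
  apply to any interpretation.
* The Weibull fit ignores truncation and censoring; latencies are
  conditioned on an onset being reported.
* Wald intervals (ROR, OR, Weibull parameters) are first-order
  asymptotic; they degrade for very small cells even when defined.
* Drug-name standardization is only as good as the user-supplied
  synonym map; no structured-product-label resolution is attempted, and
  event terms are opaque strings compared case-insensitively.
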