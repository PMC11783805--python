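# Methods

This note records the statistical procedures the package implements,
the assumptions behind them, the defaults and why they were chosen,
and what the synthetic-data generator does and does not emulate.

## Cleaning cascade

The analysis set is built in two steps from the four source tables.
Step 1 removes cases with unknown sex or age band and removes drug
*records* (not cases) whose route is outside {oral, transdermal}; a
case survives the route rule if at least one eligible drug record
remains.  This record-level reading preserves the most data while
still excluding every route the risk scale does not cover; a stricter
case-level reading (drop any case containing an ineligible route)
would discard polypharmacy cases that the load analysis is most
interested in.  Step 2 removes cases with no registry-scored drug,
since their load is undefined (zero by construction, but they are
outside the scale's scope).  The `CleaningLog` satisfies an exact
conservation identity — input = Σ removals + survivors — asserted on
every run.

Duplicate (drug name, involvement) rows within a case collapse to one
entry.  Report databases repeat drug rows per dosage form; without
deduplication a drug dispensed as tablet and syrup would count its
score twice in the load.

Unrecognized vocabulary values degrade softly with a warning counter:
sex/age to `unknown` (and the case is then excluded in step 1), routes
to `other` (the record is then excluded), involvement to `concomitant`
— the neutral label that can never inflate suspect-only exposure.
Blank fields are ordinary missingness and are not counted as
vocabulary violations.

## Case classification

The anticholinergic-syndrome query partitions its preferred terms into
categories A (the syndrome term), B (nervous system), C (psychiatric)
and D (other anticholinergic effects).  A case is labelled SYNDROME if
it has a category-A PT, or one PT from each of B, C and D; category A
dominates any other flag combination, so the eight group labels
(SYNDROME, B, C, D, B&C, B&D, C&D, OTHER) are mutually exclusive and
exhaustive.  PTs outside the dictionary never affect grouping.  Whether
a supplied dictionary reflects the narrow or broad scope of the query
is the supplier's choice; the package only enforces that each PT maps
to exactly one category.

Composition percentages are rounded half-up at two decimals, printed
with one decimal when the value is exact at one decimal (so an exact
half prints `50.0`).  This specific rule reproduces, digit for digit,
the printed percentages of published composition tables from their own
counts, which is what the acceptance suite checks.

## Disproportionality

Exposure is defined at case level: at least one registry-scored drug
reported as *suspect*.  Suspect-only exposure follows the reporting
convention that suspect drugs carry the causal claim; concomitant and
interaction drugs still contribute to the load (below).  One 2×2 table
per preferred term yields

* ROR = ((a+½)(d+½))/((b+½)(c+½)), the Haldane–Anscombe correction
  applied unconditionally to every cell so the estimate is finite for
  any table (zero cells included);
* a two-sided Fisher exact p on the *uncorrected* integer counts,
  using the standard "probability no larger than the observed table"
  rule (delegated to `scipy.stats.fisher_exact`; the test suite checks
  it against an exact rational-arithmetic enumeration oracle at
  relative tolerance 1e-7).

Events with fewer than `min_reports` (default 100) total reports
(a + c, i.e. event frequency in the whole analysis set, not only among
the exposed) are flagged `included=False` but still reported.  Volcano
coordinates are ln ROR (natural log) against −log₁₀ p (base 10), with
the reference line at −log₁₀(0.05) ≈ 1.301, conventionally printed as
1.3.  No multiplicity correction is applied across events and no
confidence intervals are produced; other disproportionality statistics
(PRR, IC, EBGM) are out of scope.

## Propensity matching

The related group (SYNDROME plus all six subgroups) is the treated
side; the other-ADE group is the control reservoir.  The propensity
model is maximum-likelihood logistic regression fit by iteratively
reweighted least squares with step-halving, which guarantees a
monotone non-decreasing log-likelihood path (asserted each iteration).
Convergence requires a gradient infinity-norm below 1e-8 (default,
100 iterations max).  Perfect separation is flagged two ways:
coefficients exceeding 30 in absolute value during iteration, or a
saturated fit at convergence; one-class labels are flagged
immediately.  Constant non-intercept columns are rejected as collinear
with the intercept.

The default covariates are sex (female indicator), age band as an
ordinal rank (10s→1 … 90s+→9; ranks preserve ordering without
inventing midpoint precision), and indicators for the top-3 most
frequent indications.  Any other covariate list can be supplied; a
generic categorical kind expands to reference-dropped indicators.  The
covariate list is configuration, not method: the matching and balance
machinery is the contribution here.

Matching is greedy 1:1 nearest-neighbor without replacement on the
logit of the score, visiting treated cases in descending score order
(hardest-to-match first); distance ties are broken by a seeded uniform
draw so runs are reproducible.  No caliper is applied by default.
Balance is the absolute standardized difference in percent —
continuous: 100·|m₁−m₂|/√((s₁²+s₂²)/2) with sample variances; binary:
the proportion analogue — computed before matching (all treated vs all
controls) and after (matched pairs only), with 0/0 defined as 0 and
the conventional 10% threshold.

## Total anticholinergic load and Steel's test

TAL is the sum of registry scores over the distinct scored drug names
in a case, counting suspect, concomitant and interaction drugs alike —
the load is a property of the whole regimen, not of the causal claim.
An optional route restriction supports route-stratified analyses.
By construction TAL ≥ number of scored drugs, and TAL = 0 iff no
scored drug remains.

Group comparisons use Steel's many-to-one procedure.  For group i with
n_i observations and the shared control with n₀, the statistic is the
mid-rank sum W_i of the group within the pooled (group + control)
sample, standardized by its null mean n_i(N+1)/2 and tie-corrected
variance n₀n_i/(N(N−1))·Σ(r−r̄)².  Familywise adjustment follows the
max-T resampling principle: all observations are jointly relabelled
across the k+1 samples (preserving sizes), and the adjusted p for
group i is the probability that max_j |Z_j| over the relabelled groups
reaches |Z_i|.  This implementation was chosen over the classical
multivariate-normal table lookup because it is exact by enumeration on
small inputs, handles unequal group sizes and the heavy small-integer
ties of load data without asymptotic assumptions, and is directly
verifiable against a brute-force oracle; the classical equicorrelated
normal approximation is retained as `method="normal"` for
cross-checking and agrees with the permutation reference to a few
percent at moderate sizes.

Numerical conventions: exact enumeration is used when the number of
distinct relabelings is at most 20,000, otherwise seeded Monte Carlo
with the observed relabeling counted in both numerator and denominator
((1+exceedances)/(B+1)); exceedance comparisons carry a 1e-9 tolerance
so mathematically tied statistics are never split by float noise; a
pooled sample with zero rank variance yields Z=0, so fully tied data
give p=1.  Mid-ranks are used for ties throughout.  Testing is
two-sided.  The adjusted p never falls below the single-comparison
permutation p computed on the same relabelings, and with one group the
two coincide.

In the group summary, the mean number of scored drugs is pooled across
the blocks that share one printed value in the conventional table
layout (syndrome; the three single-category groups; the three paired
groups; the control), mirroring its merged cells.  Sample SD (ddof=1)
is reported as missing for singleton groups.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with known
ground truth:

* **Confounders** are binary baseline conditions (defaults: dementia,
  prevalence 0.10, exposure log-odds +0.9, event log-odds +0.7;
  insomnia, 0.20, +0.5, +0.4).  They raise both the per-slot
  probability that a drug is registry-scored and every event
  category's log-odds, and they are emitted as indications — exactly
  the structure the matching stage must remove.
* **Drugs**: case drug count is 1+Poisson(2.5) capped at 8 (mean 3.5,
  reflecting multi-drug regimens typical of reports); each slot is a
  registry drug with base probability 0.6 (confounder-shifted),
  otherwise a filler drug; routes are drawn from (oral 0.78,
  transdermal 0.12, other 0.10).
* **Events**: for each category c ∈ {B, C, D}, P(event) =
  expit(β₀c + β_TAL·TAL + confounder effects) with defaults
  β₀ = (−3.6, −3.8, −3.2) and β_TAL = 0.25, where TAL is the true load
  over route-eligible distinct registry drugs.  This per-category
  logistic model in the load is the minimal generative mechanism
  consistent with the cumulative-burden hypothesis the pipeline
  examines.  The baselines were set so the related fraction of the
  cleaned set is roughly a fifth to a quarter — spontaneous-report
  composition territory — leaving the control reservoir several times
  the treated group, the overlap regime in which 1:1 matching can
  balance.  The syndrome term itself appears with probability 0.02
  only when TAL ≥ 6, making syndrome cases rare and high-load, and a
  mean TAL near 3 in the control and 4–5 in event groups lands in the
  2.5–4.5 range typical for three-point risk scales.
* **Involvement** is assigned after the events, the way reporters
  assign it: the first registry drug is labelled suspect with
  probability 0.8 when a query-category event occurred and 0.45
  otherwise.  This causality-attribution step is what couples
  suspect-drug exposure to the events; with involvement drawn
  independently of the outcome, exposure would be independent of the
  load among cleaned cases and the signal scan would correctly find
  nothing.  Remaining drugs are concomitant with a 5% interaction
  fraction.
* **Demographics and noise**: sex (55% female), age bands skewed
  older, 8% of cases get one demographic field blanked, one-or-more
  background PTs per case from a non-query pool, occasional background
  indications.

A master seed drives per-case substreams
(`default_rng([seed, case_index])`), so enlarging a simulation never
perturbs earlier cases — stable regression fixtures.  The emitted
ground truth (true load, exposure, confounders, mechanistic events) is
recomputable from the tables, and the suite asserts exact integer
agreement between generated and pipeline-computed loads.

The generator does **not** emulate real report databases' marginal
distributions, Japanese text fields, quarterly file splits, duplicate
follow-up reports, or dose information.  Passing tests therefore
demonstrate that the pipeline recovers known mechanisms from
correctly-shaped data — not that any particular real-data estimate is
correct.  Published real-data values (e.g. a syndrome-group mean load
of 4.20 ± 3.09 from hundreds of thousands of reports) require the
licensed sources and are documented as out of reach for this test
bed.

A null configuration (`null_config`) sets β_TAL = 0, removes the
syndrome term and drops the confounders' event effects, so group
membership is genuinely independent of the load; it raises the
baseline event rates so all groups are populated at small n.  The
suite uses it for a familywise type-I-error check: 100 replicate
pipelines at 300 cases and 800 permutations each, requiring at most
10% of replicates to reject anywhere at α = 0.05 (the band around the
nominal 5% allows for permutation discreteness and binomial noise).
Problem sizes for the heavier checks — 5,000 cases for effect
recovery and balance, 8,000 for the consolidated acceptance run with
4,000 permutations — were chosen as the package's own defaults for
stable stochastic assertions.

## Known limitations

* Greedy matching is order-dependent and not optimal; no caliper means
  poor-overlap treated cases still consume controls.
* The Monte Carlo Steel p has resolution 1/(B+1); exact enumeration is
  only feasible for tiny groups.
* The registry scores ingredients, not products; a combination product
  must be supplied as separate ingredient rows.
* Deduplication of follow-up reports of the same underlying case is
  out of scope; the pipeline treats case IDs as distinct reports.
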