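# Methods

## Data model

An event log has three tables: `demographics` (patient id, birth date,
gender, education, registration date), `bp_records` (patient id,
timestamp, systolic and diastolic pressure in mmHg) and `followups`
(patient id, date, type ∈ {compliance, regular, abnormal}). Diastolic
pressure is read and validated but never analyzed (systolic and diastolic
values are strongly correlated; the analysis uses SBP only). Synthetic
logs carry a fourth table, `truth.csv`, with each patient's planted
archetype.

Weeks are anchored at the registration date and half-open: week *w*
covers days `[7(w−1), 7w)`, with day boundaries at midnight of the date
field. Engagement PE\[w] is the number of distinct calendar dates in the
week with ≥1 BP record (intra-day duplicates count once); the weekly SBP
series is the mean of all systolic values in the week and is missing
exactly when PE\[w] = 0. A follow-up on a week boundary belongs to the
later week by the same half-open rule.

## Inclusion criteria

Patients are retained when (in attribution order, first matching rule
reported): age ≥ 18 whole years at registration; registration between
2016-03-27 and 2019-07-10; and a BP recording span — last record date
minus first — strictly greater than 28 days. The span reading is the
weakest operationalization of "continuously recorded for more than 4
weeks" consistent with a near-zero fourth-week engagement level in the
lowest archetype; a stricter mode (`strict_weekly=True`: ≥1 record in
each of the first 4 weeks) is available.

## Simulation horizon

The analysis covers weeks 1–4, but the internal horizon is 5 weeks: the
effect estimator needs a "week after" for week-4 follow-ups. Week-5
engagement follows the week-4 law and is never analyzed directly. A
`strict_4week_mode` drops week-4 events instead of using week-5 data.

## Synthetic cohort generator

The generator is parameterized entirely by the published cohort summaries
and emulates the *post-selection* cohort:

- **Engagement.** Per patient and week, the recording count is
  `round(clip(Normal(μ_w, σ_w), 0, 7))` with archetype-specific weekly
  means and SDs (PELL μ = 1.9, 0.8, 0.8, 0.6; PEHH 6.4, 6.6, 6.4, 6.3;
  PEHL 5.8, 4.8, 3.2, 1.8; PELH 2.4, 3.5, 4.3, 4.6 days/week). Rounding
  and clipping bias the realized means away from μ by up to ≈0.3
  days/week at the scale ends; tests compare empirical means against the
  analytic rounded/clipped expectation rather than μ.
- **Selection guarantee.** Records live in `[registration, +35 d)`, so a
  patient without week-1 records could never satisfy the span filter.
  Because the published weekly means describe patients who *passed*
  selection, every planted passer records on day 0 and at least once on
  days 29–34; equivalently the week-1 and week-5 counts are floored at 1.
  Exactly 562 patients therefore pass the filters, alongside 50 planted
  patients that each violate exactly one rule (age / window / duration,
  round-robin).
- **Demographics and SBP strata.** Age band, gender, education and the
  first-week SBP stratum are assigned to match the published per-cluster
  counts *exactly* (deterministic category lists, seed-shuffled within
  cluster, attributes independent). Week-1 SBP levels are uniform within
  the stratum band; each within-week record adds Normal(0, 5 mmHg) noise
  (a value chosen well below the reported between-patient SDs; the paper
  is silent on within-week dispersion). Weekly levels drift by a small
  archetype-specific amount per week (declines early in all archetypes,
  with a week-4 rebound in the lowest-engagement group), mimicking the
  reported qualitative trend; the drift values are package choices, as no
  numeric weekly SBP curve is published.
- **Follow-ups.** The published counts give two marginal views that do
  not share a total (661 by type, 680 by week). The generator realizes
  the week margin exactly and rescales the type margin per cluster to the
  week total by largest-remainder rounding; each event carries both
  labels, assigned independently (the joint distribution is unpublished —
  a modelling choice). Events are placed on distinct patient-weeks, on a
  uniform day within the event week.
- **Injected effects.** After a follow-up in week *w*, the patient's
  pre-noise engagement level for week *w+1* is the *realized* week-*w*
  count plus the injected engagement effect, and the SBP level for week
  *w+1* is the week-*w* level plus the injected SBP effect (replacing the
  archetype mean/drift for that one transition). Anchoring on the
  realized value makes the injected quantity exactly the estimand of the
  pre–post estimator, so estimator tests are parameter-recovery tests.
  Because one additive per-event effect cannot reproduce both published
  marginal views of the same samples, the defaults inject the engagement
  effects keyed by (cluster, type) and the SBP effects keyed by (cluster,
  week). A zero-injection event still re-anchors the next week on the
  realized count (introducing one week of autocorrelation); with a flat
  engagement law this leaves stratum means at zero, which is tested.

What the generator does **not** emulate: within-patient engagement
autocorrelation beyond the post-follow-up week, provider-side trigger
logic (follow-up counts are taken as given), seasonal or day-of-week
recording structure, medication/diet/exercise logs, and measurement-level
SBP trends within a week. Passing tests therefore certify the pipeline's
statistical machinery on data with the published low-order structure, not
behavioral realism beyond it.

## DTW distance

`dtw(a, b)` is the minimal cumulative local cost over monotone,
boundary-anchored warping paths with steps {(1,0), (0,1), (1,1)}, no
window constraint (series have length 4; the constraint space is tiny)
and no path normalization (equal lengths). The default local cost is
|a−b|, keeping units in days/week for count series; squared cost is a
flag. The implementation is validated against exhaustive path enumeration
for all short series.

## Clustering

Lloyd iteration under DTW: assign each trajectory to the nearest
centroid, refit each centroid by DBA (10 inner iterations of aligning
members to the centroid and replacing each centroid coordinate with the
weighted mean of values aligned to it), stop when assignments stabilize
or after 100 rounds; best of `n_init = 10` seeded k-means++-style
restarts by inertia. As in Euclidean k-means — which minimizes squared
distances while distances are reported unsquared — the clustering
objective uses the squared local cost (under which the DBA mean update
descends; the barycenter step is additionally safeguarded to never return
a costlier centroid, making the recorded inertia provably non-increasing),
while the silhouette is evaluated on the absolute-cost DTW distance
matrix. An `objective="abs"` mode and a medoid centroid mode exist for
sensitivity analysis. Determinism: initialization draws from the sorted
distinct trajectories, assignment ties break to the lowest cluster index,
inertia ties to the lowest restart index, and empty clusters are reseeded
from the point farthest from its centroid. Duplicate trajectories are
collapsed before the distance computations (≈600 length-4 count series
contain only a few hundred distinct patterns), which keeps a full model
scan at n ≈ 600 under half a minute on one CPU.

The silhouette of a labeled distance matrix is the mean over points of
(b−a)/max(a,b) (a = mean intra-cluster distance excluding self, b =
smallest mean distance to another cluster; singletons score 0). `select_k`
maximizes it over k ∈ {3..7}, ties toward the smaller k. Trajectories are
clustered as raw day counts — units are already common across patients,
so no z-normalization is applied.

Cluster naming for k = 4 splits centroids on the week-1 level (high ≥ 4
days/week) and, within each half, ranks by the week-4 − week-1 trend: the
higher-trend member is the stable/rising archetype (PEHH / PELH). A
strict sign-of-trend rule would misname the stable-high archetype, whose
published trend is slightly negative (6.3 vs 6.4). Any non-2/2 week-1
split raises an explicit naming failure rather than forcing labels.

**Known limitation — boundary bias.** With the published weekly SDs (up
to 2.0 days/week) the archetypes overlap, and any hard partition —
including assignment to the true planted centroids — shifts recovered
cluster means in the wide-SD interior weeks by up to ≈0.7 days/week
(members near a boundary are exchanged asymmetrically). Recovery tests
therefore pin the endpoint weeks (1 and 4, SDs ≤ 1.5; observed error
≤ 0.3) and overall partition agreement (> 85%), not the interior weeks.

## Effect estimation

One sample per follow-up event (a patient followed up twice contributes
twice; the estimator divides by the number of follow-ups, not patients):
`delta_pe = PE[w+1] − PE[w]`, `delta_sbp = SBP[w+1] − SBP[w]` with
missing propagation (no imputation; a sample missing SBP still
contributes to CPE). Events in the final horizon week are dropped and
counted. Stratum tables report n (non-missing samples), mean, and the
n−1 sample SD (missing for n < 2).

## Characterization statistics

Pearson chi-square without continuity correction (warning when an
expected count < 5); pairwise pooled-variance two-proportion z tests,
Bonferroni-adjusted within the family of cluster pairs; two-way
fixed-effects ANOVA with interaction using Type III sums of squares and
sum-to-zero contrasts (the convention of the major commercial packages
for unbalanced designs; on balanced data it coincides with sequential
ANOVA, which is tested); Bonferroni pairwise equal-variance t post-hocs;
and paired t comparisons of weekly mean SBP between weeks within each
cluster, Bonferroni-adjusted over the six week pairs. α = .05 throughout;
no correction is applied *across* analyses. Repeated samples from one
patient enter the ANOVA as independent observations — mirroring the
estimator's definition — which inflates the effective n; a mixed-effects
treatment is deliberately out of scope. An all-constant response reports
F = 0, p = 1.

## Reproducibility

Every stage is deterministic given its seed. The pipeline derives
independent substreams for cohort generation and clustering from one
master seed, echoes its configuration and artifact hashes into
`manifest.json`, and re-running a configuration reproduces byte-identical
artifacts. Problem sizes used by the test suite: the full 612-patient
default cohort for acceptance-level checks, a 5,000-patient single
archetype for the law-convergence test, and an 82-patient four-archetype
miniature for end-to-end pipeline tests.
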