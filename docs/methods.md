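# Methods

## The score and its vocabulary

A patient-day is summarised by binary indicators over a fixed EEG feature
vocabulary: dominant background slowing subdivided into 1 Hz bins (delta
≤1, 1–2, 2–3, 3–4 Hz; theta 4–5, 5–6, 6–8 Hz; alpha ≤8, 8–9, ≥9 Hz — each
band reports at most one bin, since a segment has one dominant frequency
per band), plus beta activity, posterior dominant rhythm, awake signs,
GRDA, GPDs, LPDs, LRDA, moderately low voltage, intermittent brief
attenuation, and four severe patterns (NCSE, extreme low voltage/ECS, burst
suppression, unreactive EEG). Electrographic seizures are carried in data
files but excluded from scoring and training because they fix the clinical
grade directly (automatic ICANS ≥ 3), which would make them a tautological
predictor.

The VE-ICANS score is the sum of integer point values over present
features; any severe pattern overrides the sum with the maximal score. The
published maximal score is not printed as a number, so by default it is
computed from the table itself as the largest score achievable without
severe patterns under the one-bin-per-band rule (18 for the shipped table:
delta ≤1 Hz 10, theta 4–5 Hz 2, low voltage 2, GRDA 2, GPDs 2). This
guarantees severe patterns rank at least as high as every non-severe EEG;
an explicit integer in the table file overrides it. Scores are not floored:
a normal awake EEG (PDR plus alpha ≥ 9 Hz) scores −2. The theta 5–6 and
6–8 Hz input bins share one merged +1 entry, the form the published table
takes after equal coefficients were recombined.

## Deriving tables by pairwise ranking

Training data are graded records (subject, day, feature vector, ICANS grade
0–4 in half steps; half grades arise when two chart reviewers disagreed and
their grades were averaged). Every unordered pair of records with strictly
different grades becomes one example, oriented higher-grade first; exact
ties are dropped, and half-grade differences (2 vs 2.5) do count as ordered
pairs. The pair count obeys C(n,2) − Σ_g C(n_g,2) exactly. Days showing a
severe pattern are excluded from pair construction: their score is assigned
a priori, and co-occurring features on such days would otherwise absorb
spurious weight.

The fit minimises the mean logistic ranking loss over pair difference
vectors plus an ElasticNet penalty λ(α‖w‖₁ + (1−α)‖w‖₂²/2), without
intercept, subject to sign constraints (abnormal ≥ 0, normal ≤ 0) and
ordinal constraints (within each slowing band, the lower-frequency bin's
coefficient ≥ the higher-frequency bin's). Because the sign of each
coefficient is constrained, |w_i| = s_i·w_i is linear and the whole
objective is smooth and convex over a polyhedron; it is solved with SLSQP
from a zero start (deterministic), with analytic gradients and a tight
tolerance (ftol 1e−10), and boundary noise is snapped to exact
feasibility afterwards. λ is chosen on an inner grouped CV loop by held-out
pairwise accuracy (ties prefer the stronger penalty); α defaults to 0.5.
Features occurring fewer than 5 times are excluded before training.

Integerisation — needed so the table can be used as a bedside point system —
scales the real coefficients so the largest magnitude maps to
`target_max_points` (default 10, matching the published table's largest
value), rounds, repairs any constraint violated by rounding, and then
greedily applies ±1 coordinate moves within `search_radius` (default 2) of
the rounded point, accepting a move only if it strictly improves pairwise
training accuracy or matches it with a smaller total of absolute points.
The search is deterministic and terminates because every accepted move
strictly improves that lexicographic key. Already-integer feasible input is
returned unchanged. Exact integer programming was deliberately avoided in
favour of this auditable local search.

## Evaluation protocol

Folds are assigned per subject (never per record): a greedy bin-packing
pass takes subjects largest-first and places each in the fold, among those
below the subject-capacity ceiling, whose grade distribution deviates least
from the cohort's after the addition; ties in subject size are shuffled by
the seed. Stratification under a grouping constraint is necessarily
approximate; the test suite checks the resulting fold grade-mean spread
lands in the best decile of random groupings. Nested CV trains on four
folds (with the λ grid resolved by the inner grouped CV), scores the
held-out fold with the resulting integer table, and pools the five held-out
prediction sets, so every record is scored exactly once by a model that
never saw its subject — asserted on every run.

Pearson correlation between pooled out-of-sample scores and grades carries
a 1000-replicate percentile bootstrap CI; the resampling unit is the record
by default, with a subject-level cluster bootstrap available since days
within a patient are correlated. Discrimination for "no neurotoxicity vs
grade ≥ x" is the Mann–Whitney rank statistic U/(n₁n₀) with ties counted
half (records with 0 < grade < x are excluded from the comparison), with a
class-stratified bootstrap CI.

Cohort 2×2 tests use the Yates continuity correction in the form
Σ(|O−E|−0.5)²/E **without** flooring the corrected deviation at zero. The
two conventions differ only when |O−E| < 0.5; the unfloored form is the one
consistent with the packaged cohort contingency fixture, equals the
textbook shorthand N(|ad−bc|−N/2)²/(n₁n₂(a+c)(b+d)), and is what the tests
certify to 1e−10 against that closed form. Mann–Whitney U p-values use the
normal approximation with tie correction. Feature–feature association is
the Spearman matrix of the binary indicators; constant features yield NaN
entries (flagged, not zeroed).

## Clinical grading

ICE components (naming 0–3, orientation 0–4, command 0–1, attention 0–1,
writing 0–1) are mapped from structured chart findings by a rule table, not
free-text NLP: months/days-of-week backward, WORLD backward or serial 7s
substitute for serial 10s attention; date/state/president/senator
substitute for orientation items; "fully alert and oriented" grants full
orientation; fluent speech without noted deficits grants full naming; and
absence of aphasia and tremor grants the writing point (writing samples
were not routinely requested before ICE was instituted). Each applied
substitution is recorded in the assessment's notes.

The ICANS grade is the maximum of the grade implied by the ICE band and the
four domain grades (consciousness, motor, seizures, edema). The ASTCT
consensus band mapping (10→0, 7–9→1, 3–6→2, 0–2→3; grade 4 arises from the
domains, e.g. unarousable consciousness) is shipped as editable
configuration and is external clinical knowledge rather than something
derivable from data in this package. Reviewer reconciliation passes
unanimous grades through and averages discrepancies, which is where
half-grades come from. Inter-rater agreement is summarised by the mean and
SD (ddof = 1) of absolute score deviations and the percentage with
difference 0, 1, or ≥ 2; deviations are taken pairwise over all rater pairs
by default (equivalent to the two/three-rater settings the statistic is
typically reported for), with a consensus-mean basis as an option.

## The synthetic cohort generator

The generator emulates the structure of an EEG-monitored CAR-T cohort, not
any real patient: 120 subjects by default; per subject a truncated
geometric number of monitored days (p = 1/3, capped at 14; mean ≈ 2.9,
matching a cohort averaging 3 EEG days with range 1–14); a grade trajectory
that keeps yesterday's grade with probability 0.8 and otherwise redraws
from the marginal grade distribution (0.10, 0.18, 0.22, 0.30, 0.20 over
grades 0–4, chosen so severe days — grade > 2 — are about half of all days,
as in the study cohort). This "sticky" chain honours slow grade evolution
while keeping the marginal distribution exact. Each day's latent severity
is the grade plus Gaussian noise (SD 0.5), representing chart-review noise
and within-grade physiological spread.

Features are emitted from the latent severity. Slowing bands use a
multinomial logit over {absent} ∪ bins so one bin at most fires per band;
bin loadings are the planted scoring table's coefficients times a common
`loading_scale` (default 0.4), which makes lower-frequency bins dominate at
high severity and gives recovery experiments a ground truth whose ordinal
and sign structure matches the constraints. Other features are independent
logistic emissions with loadings from the same rule. Baselines are
calibrated numerically (Gauss–Hermite quadrature over the severity
marginal, damped fixed-point iteration for the multinomial intercepts) so
marginal prevalences match the published all-time-point prevalences (PDR
13.3%, GPDs 5.1%, delta 1–2 Hz 36.5%, ...); beta and awake-sign prevalences
are not tabulated in the source cohort and are set to plausible values
(20%, 60%) for maximally-awake segment selection. Severe patterns are
emitted only on grade-4 days with probability 0.02 each, and seizures only
at grade ≥ 3 with probability 0.03, mirroring their rarity. At
`loading_scale` ≳ 1 with the default grade mix the published prevalence
targets become unreachable (deep-delta days would exceed the 11% target)
and calibration reports failure instead of silently drifting; the
strong-signal/noiseless consistency check therefore runs at 0.8.

What the generator deliberately does not model: the exclusion of ~26% of
recorded days for artifact or missing exams (so default cohorts have ~350
days rather than 315), feature co-occurrence beyond what the shared latent
severity induces, CRS or treatment covariates, and timestamped within-day
grade dynamics. Passing recovery tests therefore show the training
machinery recovers a planted additive structure under realistic prevalence
and noise — not that the published coefficients are correct for real
patients.

## Numerical and design choices

- Pair weighting is uniform by default; subjects with many days dominate
  the pair set, so an inverse-product-of-day-counts weighting is available
  (`weight_pairs_by_subject`).
- The grade-0 threshold convention: AUC levels compare grade == 0 against
  grade ≥ x; the cohort dichotomy for contingency tests is grade ≤ 2 vs
  > 2, with half-grades compared numerically (a reconciled 2.5 is severe).
- Ties in integerisation break toward smaller absolute points; ties in λ
  selection toward stronger regularisation; both keep the pipeline
  deterministic at fixed seed, and the only randomness the seed governs is
  fold-assignment tie-breaking and the generator itself.
- Degenerate inputs fail loudly: all-equal grades (no informative pairs),
  constant vectors in correlation, empty AUC classes, zero expected
  contingency counts, single-rater agreement.

## Problem sizes used by the test and acceptance runs

Recovery experiments use default cohorts (~350 days, ~44k pairs) over 20
seeds; the prevalence-calibration checks use ~10k-day cohorts; nested CV
runs on one default cohort with a two-point λ grid. These sizes keep the
full suite around two minutes while leaving the binomial error on checked
prevalences well below the asserted margins.
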