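# Methods

## Model and estimands

For each patient, survival from randomization is partitioned into three
mutually exclusive health states measured in integer study days
(day 1 = day of randomization):

* `TOX` = number of pre-progression days (days 1..PFS) covered by at least
  one qualifying adverse event;
* `TWiST` = PFS − TOX;
* `REL` = OS − PFS.

Qualifying events are grade 3/4 treatment-emergent adverse events in the
primary definition, or any serious TEAE in the sensitivity definition.
Adverse-event intervals are closed on both ends (a one-day event contributes
one day) and overlapping intervals are resolved by a day-level union — a day
with several qualifying events counts once. Days are converted to months by
dividing by 30.437.

The arm-level estimands are the mean state durations restricted to a common
time τ. They are estimated by partitioned survival: fit Kaplan–Meier curves
for cumulative toxicity duration, PFS and OS (nested by construction) and
take differences of their restricted areas,

    mean_TOX  = AUC(TOX curve, τ)
    mean_TWiST = AUC(PFS, τ) − AUC(TOX, τ)
    mean_REL   = AUC(OS, τ) − AUC(PFS, τ),

so the three state means add to the restricted mean OS exactly. Q-TWiST is
the utility-weighted sum `u_TOX·TOX + u_TWiST·TWiST + u_REL·REL` with
defaults (0.5, 1, 0.5); utilities of 1 recover the restricted mean OS. The
relative improvement is 100 × (Q-TWiST difference) / (control mean OS), with
strict >10% / >15% classification thresholds (boundary values classify
downward). A utility-threshold grid tabulates the difference over all
(u_TOX, u_REL) in [0,1]² with u_TWiST fixed at 1; the difference is affine
in each weight.

## Conventions and numerical choices

* **Restriction time.** τ defaults to the smaller of the two arms' largest
  observed OS times, so the between-arm contrast compares the arms over a
  common horizon. An explicit τ can be supplied instead.
* **Ties.** Subjects censored at a time remain at risk for events at that
  same time (standard product-limit convention).
* **Tail policy.** The KM curve is undefined past the last observed time
  when that observation is censored; `rmst` then refuses rather than
  extrapolates. When the estimate has reached zero the area is complete and
  any τ is accepted. The toxicity-duration curve is the exception: its
  support is much shorter than τ, so its final plateau is carried forward to
  τ (`tox_tail="carry"`), which is exact for fully-observed data where the
  plateau is zero and is the conventional partitioned-survival treatment
  under censoring. Bootstrap replicates use the carry policy for all three
  curves so that resamples that happen to drop the extreme observation remain
  well defined.
* **Toxicity-curve censoring.** A patient with censored PFS has toxicity
  accrual observed only up to censoring, so the toxicity-duration curve
  inherits the PFS event indicator.
* **Progression-day convention.** The progression day belongs to the
  pre-progression window (TOX + TWiST = PFS exactly); REL starts the day
  after. Death before documented progression must be encoded as a PFS event
  at the death day (REL = 0); validation rejects a death without a PFS event.
* **Ongoing adverse events.** A missing resolution day is kept missing at
  I/O and imputed at partition time to min(PFS day, data-cutoff day):
  toxicity cannot extend past progression by definition, and extrapolating
  beyond the cutoff is unsupported.
* **Bootstrap.** Patients are resampled with replacement independently
  within arm (the allocation ratio is fixed by design); a patient's
  adverse-event records travel with the patient. Default B = 1000
  replicates; SE = sample SD (ddof = 1) of the replicates. Since the
  partition of a patient is deterministic, the analysis bootstrap resamples
  the per-patient durations directly — equivalent to resampling raw records
  and repartitioning, at a fraction of the cost. τ is recomputed on every
  resample by default (τ is data-dependent; freezing it understates
  variance); `BootstrapConfig(frozen_tau=True)` is available for comparison.
  A statistic failing on a degenerate resample is not silently retried; the
  error propagates with the replicate index.
* **Intervals.** z-method: estimate ± z·SE with the exact normal quantile
  (1.959964 at 95%), not the rounded 1.96. Two-sided p-values are normal
  against a null of zero; with SE = 0 a nonzero contrast is reported as
  p = 0 (below machine floor).
* **Relative improvement** is computed from unrounded estimates. Applying
  the formula to values already rounded to one decimal can move the result
  by a few tenths of a percentage point (e.g. 100·2.0/6.5 = 30.8% where the
  unrounded inputs give a slightly different figure), which is why worked
  examples on printed tables differ slightly from values computed on the
  underlying data.

## Subgroups and sensitivity analysis

Subgroup reports rerun the full pipeline on the restricted dataset with its
own common τ and independent bootstrap — no pooling or shrinkage across
subgroups. Categories below a minimum size (default 10 patients total, and
both arms non-empty) are reported as skipped with a reason. The
serious-TEAE sensitivity analysis is the identical pipeline with the
toxicity definition switched; primary and sensitivity reports differ only
through that definition.

## Synthetic data generator

The generator emulates the data structure the analysis consumes, not any
particular trial: a 2:1 randomized two-arm design (461 vs 230 by default)
with, per patient,

* PFS sojourn ~ Exponential(rate λ_pfs) months and post-progression sojourn
  ~ Exponential(λ_rel), discretized to integer days (×30.437, rounded);
* a toxicity fraction f ~ Beta(f̄·c, (1−f̄)·c) of the observed
  pre-progression days, realized as `ae_fragmentation` overlapping grade-3/4
  treatment-emergent intervals whose day-union has exactly ⌊f·PFS_days⌉
  days (exercising the count-once rule); blocks shorter than the fragment
  count reduce it with a warning;
* i.i.d. serious flags on qualifying intervals (P = 0.6), plus background
  grade 1/2 events and occasional non-treatment-emergent grade-3 events that
  the qualifying rule must ignore;
* optional administrative censoring at a cutoff month, truncating PFS and OS
  at the cutoff day;
* independent categorical covariates (age group, sex, region, ECOG, liver
  metastases) with marginals typical of a late-line metastatic colorectal
  cancer population.

Exponential sojourns and Beta fractions give closed-form unrestricted truth:
mean PFS = 1/λ_pfs, mean REL = 1/λ_rel, mean TOX = f̄/λ_pfs, mean TWiST =
(1−f̄)/λ_pfs. The default scenario is calibrated to the magnitudes of a
late-line mCRC trial — control mean OS 6.5 months, active 8.4, control mean
PFS 2.1, active 4.5, mean toxicity time 0.2 and 0.5 months — giving a true
Q-TWiST difference of exactly 2.0 months at the default utilities.

What the generator does **not** emulate: correlated covariates and
covariate-dependent hazards, non-exponential (e.g. Weibull or cured-fraction)
survival shapes, informative censoring, toxicity episodes correlated with
progression risk, or recurrent post-progression toxicity. Passing tests
therefore demonstrate estimator correctness under the generative model and
internal consistency of the pipeline, not robustness to the full complexity
of real trial data.

## Verification strategy and problem sizes

* Worked examples: the day-union and partition rules are checked against
  brute-force day enumeration; the KM fit against hand product-limit
  computations and against an independent survival library on random
  censored data; the uncensored restricted mean against the arithmetic mean
  (property-based).
* Parameter recovery: at n = 5000 per arm without censoring, every state
  mean and the Q-TWiST difference must land within 3 Monte-Carlo SEs of the
  closed form.
* Calibration: across 200 simulated trials of 200 patients per arm with
  B = 500, the 95% z-interval for the Q-TWiST difference must cover the true
  value 90–99% of the time.
* Null behavior: cloning the control arm as the active arm must give a
  difference within two bootstrap SEs of zero and p > 0.05.

These sizes keep the full suite to a few minutes on one core while leaving
the Monte-Carlo checks well powered.

## Known limitations

* Utility coefficients are fixed inputs; no mapping from quality-of-life
  instruments is provided.
* The simultaneous-toxicity limitation is inherent to the method: a day with
  several qualifying events carries the same weight as a day with one.
* No covariate adjustment, competing-risks treatment, or percentile/BCa
  bootstrap intervals (z-method only).
* Under heavy censoring the carried-forward toxicity plateau and the
  refuse-don't-extrapolate OS/PFS tails mean results depend on τ; the report
  records the τ used.
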