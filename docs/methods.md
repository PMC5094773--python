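# Methods

## Setting and outcome strata

The package models second-trimester cervical-length (CL) surveillance of
singleton pregnancies after excisional cervical treatment.  Three
screening windows are fixed by protocol — A: 13+0–15+6, B: 16+0–18+6,
C: 20+0–22+6 weeks — and ultrasound-indicated cerclage is offered at
CL < 25 mm before 24+0.  Records are stratified by outcome:

* **Group 1 (low risk)** — term birth (≥ 37+0) without cerclage;
* **Group 2 (high risk)** — preterm birth (< 37+0, i.e. < 259 days)
  and/or cerclage insertion, split into preterm without cerclage,
  preterm with cerclage, and term with cerclage.

The preterm boundary is strict (`total_days < 259`); "term" is its
complement.  A woman who *declined* an offered cerclage is flagged but
grouped by what actually happened: she is high-risk only if she delivered
preterm, because the stratum definition keys on cerclage insertion, not
the offer.

Interval shortening is %ΔCL = 100·(CL_early − CL_late)/CL_early, with
the **earlier** measurement as denominator and positive values denoting
shortening.  Per-record %ΔCL exists only when both endpoints are
observed, and stored CL values are pre-cerclage by construction (the
generator censors everything after insertion; files are expected to
contain pre-cerclage measurements only).

## The 3-step triage model

Each visit classifies the woman HIGH_RISK (leave surveillance for
intervention), DISCHARGE (leave as low risk) or CONTINUE:

* **Step A** (CL_A alone): HIGH if CL_A < 19 mm; DISCHARGE if ≥ 42 mm.
* **Step B** (CL_B and %ΔCL_AB): HIGH if CL_B < 23 mm **or**
  ΔCL_AB ≥ 21%; else DISCHARGE if CL_B ≥ 38 mm **or** ΔCL_AB < 6%.
* **Step C** (terminal): HIGH if (CL_A < 28 mm and ΔCL ≥ 5% over A–C)
  or CL_C ≤ 24 mm or (CL_A ≥ 24 mm and CL_B < 26 mm); otherwise
  surveillance is complete and the woman is low risk.

Numerical conventions, chosen once:

* HIGH rules are evaluated **before** LOW rules at B and C (the clauses
  can overlap; safety-first ordering).
* The B-step discharge rule is a literal OR, so a mid-range cervix that
  barely shortened (< 6%) is discharged at B.  Because the source rule
  set is stated only in prose, an AND variant is available behind
  `b_low_rule="and"` for sensitivity analyses; similarly the ΔCL interval
  of the first C-rule defaults to A–C (`c_rule1_delta_interval`) since
  the prose does not name the interval.
* A missing measurement makes the clauses that need it inert: a woman
  missing visit B entirely advances to C with a missed-visit flag; ΔCL
  clauses are skipped when CL_A is unobserved.  A record with no CL at
  any visit is ineligible and rejected.
* Final statuses: HIGH_RISK anywhere; DISCHARGE at A or B; COMPLETED for
  women reaching C without a high-risk call (their C decision is a
  discharge — the distinct label preserves how many scans were used).
  DISCHARGE and COMPLETED both count as low-risk calls in evaluation.

## Constrained derivation

`derive_triage_model` re-derives the rule shape from labelled data under
`DerivationConstraints`:

* **Objective** — maximise the number of records *resolved* (HIGH +
  DISCHARGE) at each step.
* **Safety constraint** — Group-2 members among cumulative DISCHARGE
  calls ≤ 5% of those calls (`max_false_low_risk_rate`, default 0.05).
  An alternative reading — discharged Group-2 women as a share of all
  Group-2 women — is selectable via `constraint_scope="group2"`.
* **Steps 1–2** are exhaustive integer-grid searches (mm over [10, 50],
  percent over [0, 40], covering all default thresholds).  Step 2 uses
  2-D cumulative histograms so the four-threshold search is O(grid²) per
  high rule.  Ties prefer the most conservative solution (smallest
  discharge region: largest discharge threshold, then smallest delta
  threshold).
* **Step 3** fits a deterministic CART (Gini impurity, depth ≤ 3, leaf
  ≥ 10) on CL_A, CL_B, CL_C and the three interval ΔCLs of the records
  still unresolved.  Split candidates are midpoints between consecutive
  distinct observed values; rows missing the split feature follow the
  child with more observed training rows (ties left); impurity ties break
  toward the lower feature index, then the lower threshold.  Leaves are
  labelled DISCHARGE greedily in order of increasing Group-2 fraction
  while the cumulative cap still holds, else HIGH.  The fitted tree is
  the authoritative step-C rule of a derived model; its top splits are
  additionally read off into the fixed three-clause shape when they match
  it, so the reported `TriageModelSpec` stays human-readable.
* **Degenerate data** — if no threshold pair admits any feasible
  discharge, the derivation returns a maximally conservative model
  (discharges nobody, flags everyone at the terminal visit) with a
  warning in the report.
* **Validation** — leave-one-hospital-out: derive on the other sites,
  report held-out sensitivity for Group 2 and the false-low-risk rate.

A known property of this objective: it places no precision requirement
on HIGH calls, so on data where the strata overlap heavily the searched
high-risk region inflates (everyone "resolved" as high risk is a valid
maximiser).  The safety cap on discharges — the clinically load-bearing
constraint — always holds; the derivation is therefore exercised and
validated on separation benchmarks (`generate_planted_cohort`), where
both thresholds are identifiable, rather than on the heavily overlapping
default synthetic cohort.

## Synthetic cohort generator

`SyntheticCohortConfig` defaults describe a three-site cohort of 725
pregnancies in four outcome subgroups (581 / 46 / 24 / 74).  Per
subgroup the generator draws:

* CL_A ~ Normal(μ, σ) truncated to the CL bounds [5, 60] mm, with
  subgroup (μ, σ): term/no-cerclage 33.6 ± 4.2, preterm/no-cerclage
  32.3 ± 6.0, preterm/with-cerclage 26.8 ± 5.4, term/with-cerclage
  25.8 ± 5.4;
* per-interval shortening fractions f_AB, f_BC ~ truncated Normal on
  (−50, 95)% — a cervix may lengthen by up to half its previous
  measurement but cannot shorten past zero — with subgroup means/SDs
  (3 ± 8, 2 ± 9), (4 ± 8, 6 ± 11), (18 ± 12, 39 ± 23), (12 ± 15,
  30 ± 15)%; then CL_B = CL_A·(1 − f_AB/100) and CL_C likewise, clipped
  to bounds.  Longitudinal dependence is therefore multiplicative: the
  interval %ΔCL moments are the direct calibration targets and the
  downstream CL_B/CL_C means are emergent, not asserted.
* per-visit missingness (visit-A rates from observed cell denominators:
  17.2 / 15.2 / 8.3 / 8.1% across the four subgroups; later-visit rates
  in cerclage subgroups are modest because post-cerclage censoring
  dominates there), conditioned on at least one observed visit
  (the eligibility contract);
* for cerclage subgroups, a cerclage at the first observed visit with
  CL < 25 mm — trajectories are resampled until one exists — with the
  insertion gestation drawn uniformly in that visit's window and all
  later CLs censored.  Suture material is allocated 60:38
  monofilament:braided across recipients, independently of outcome;
* gestation at birth from subgroup truncated normals: term/no-cerclage
  39.1 ± 1.8 weeks on [37, 43); cerclage subgroups share 38.0 ± 3.1
  (the recipient-weighted mixture of the two suture groups' moments)
  truncated below or above 37.0 so preterm/term status holds by
  construction; preterm/no-cerclage uses 35.5 ± 2.0 on [24, 37) — no
  printed moments exist for that subgroup, so a late-preterm-skewed
  choice was made once and kept;
* demographics (age 33.8 ± 4.1, BMI 24.1 ± 3.9, 78% nulliparous,
  smoking 7% / 23% by stratum, ethnicity 66/16/18%) sampled
  independently of CL — smoking is descriptive only and enters no rule.

All draws flow from one `numpy.random.Generator`; truncated normals are
sampled by inverse CDF on the truncated interval, so a (config, seed)
pair fully determines the cohort.  Infeasible truncations (μ more than
6σ outside the bounds) are rejected as configuration errors.

What the generator deliberately does **not** model: gestational-age CL
percentile curves, covariate effects on CL (smoking, BMI), measurement
error correlated within sonographer, or any causal effect of cerclage or
suture material on gestation at birth (suture is assigned at random, so
synthetic suture comparisons are null by construction).  Passing tests on
synthetic cohorts therefore demonstrate the *machinery* — calibration,
invariants, constraint logic — not clinical performance on real data.
Because cerclage-subgroup trajectories are resampled until they cross
the 25 mm threshold, their realised CL-at-A means sit slightly below the
configured location; the unconditioned subgroups match the
truncated-normal mean (checked against a numerical-integration oracle).

## Screening accuracy

The positive class is always Group 2.  Sweeps use "CL ≤ t" (default t
sets {20, 25, 30, 35, 40, 50} mm at A/B, {20, 25, 30, 35, 37} at C) and
"ΔCL ≥ d" ({5, 10, 20, 30, 40}%).  Each row's denominator is the set of
records with the required measurement observed, mirroring per-visit
attendance.  Metrics come from unrounded counts; LR⁺ = Se/(1 − Sp) is
computed from unrounded proportions (never from the displayed integers).
Report formatting rounds percentages to integers (one decimal below 10%)
and LR to one decimal; an undefined NPV from an empty test-negative set
is rendered 100% when no positive was missed, matching the conventional
display, and carries an explicit `undefined` flag internally.  ROC curves
enumerate all distinct observed thresholds; AUC is the trapezoid rule.

## Contingency and rank statistics

* Risk ratio with the Katz log-normal interval, using z = 1.959964
  (1.96-rounded is not accurate enough to reproduce 2-dp bounds stably).
  Zero event cells leave the interval undefined unless a flagged 0.5
  continuity correction is requested.  On the printed suture counts the
  published point estimate 0.7 (0.54–0.94) is reproduced by the
  term-birth direction, braided vs monofilament — the preterm-direction
  ratio of the same counts is ≈ 0.38 (monofilament vs braided); the
  package computes whichever table is requested and documents this
  direction as the one matching the printed interval, without asserting
  intent.
* Fisher's exact test uses the "probability at most that of the observed
  table" two-sided definition, summed in ascending order with a relative
  guard for floating-point ties; it is checked exactly against a
  rational-arithmetic enumeration for all small tables.
* Mann-Whitney U uses midranks; p is by full enumeration when both
  samples have ≤ 8 observations (two-sidedness as distance of U from its
  null mean) and by the tie-corrected normal approximation (with
  continuity correction by default) otherwise.  The reported U is
  min(U_x, U_y); both one-sided statistics are in the result object.
* Kruskal-Wallis delegates to the standard tie-corrected H with the
  χ²(k−1) reference.

## Scan accounting

Every woman is scheduled for three surveillance scans; an exit after
visit 1 or 2 — discharge or high-risk call alike, since a cerclage ends
CL surveillance — avoids the remaining scheduled scans.  With exits
(n₁, n₂) the avoided count is 2n₁ + n₂ out of 2N scheduled follow-ups;
conservation (performed + avoided = 3N) is enforced as an invariant.
The published exit pattern (40, 156) in 725 women gives 236/1450, which
the accounting reproduces exactly; the source's own "23%" headline does
not equal 236/1450 (≈ 16.3%) and is left as reported, not resolved.

## Problem sizes

Property suites run on a ~10,000-record synthetic cohort; generator
calibration uses 10,000 records per subgroup; derivation recovery uses a
2,000-record planted cohort across 3 sites.  These sizes make the Monte
Carlo tolerances (±0.2 mm on a calibrated mean, ±2 mm on recovered
thresholds, 3-binomial-SD missingness bands) comfortably tight while the
whole suite stays fast.

## Known limitations

* The triage thresholds are a fixed published rule set; nothing here
  estimates treatment effects of cerclage (no counterfactual modelling)
  or produces probabilistic risk scores.
* Table-shaped outputs reproduce *structure*; cell values from the
  original clinical cohort are functions of data that were never
  deposited and are not reproduction targets.
* The derivation objective's indifference to high-call precision (above)
  means derived models on weakly separated data should be read as
  conservative screens, not as clinically deployable rules.
* The Fisher implementation enumerates the hypergeometric support and is
  bounded at table totals of 10,000.
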